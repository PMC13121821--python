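"""Truncated (averaged) stochastic Newton recursion for streaming IRT.

One examinee's response vector arrives at a time.  For each item the engine
maintains three objects: the current iterate ``beta``, the weighted-average
iterate ``beta_avg`` (the reported estimate), and an accumulated curvature
matrix ``S`` seeded with a positive-definite prior term ``S0``.  On arrival
of examinee ``n``:

1. the per-item gradient of the examinee's negative log marginal likelihood
   is evaluated (by default at the current iterate), using the examinee's
   discrete ability posterior over the quadrature grid;
2. the per-item curvature (posterior-weighted Bernoulli information, with
   the variance term floored at a decaying truncation level ``lambda_n``) is
   evaluated at the *averaged* iterate;
3. a Newton step ``beta <- beta - nu_n * (S/n)^{-1} g`` is taken with step
   size ``nu_n = c_nu * (n + n0)^(-gamma)``;
4. the curvature is accumulated, ``S <- S + Phi``;
5. the average is refreshed, ``beta_avg <- (1 - tau_n) beta_avg + tau_n beta``.

With ``tau_n`` identically 1 the average tracks the iterate exactly and the
scheme is the non-averaged truncated stochastic Newton (TSNA); with a
log-weighted averaging sequence it is the truncated *averaged* variant
(TASNA), which damps the stochastic fluctuation of individual updates.

The examinee's ability is scored immediately after the item update by the
expected-a-posteriori (EAP) mean over the grid, so every record in the
stream yields both refreshed item estimates and an ability estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import (
    ItemParamSet,
    ItemParamVector,
    QuadratureGrid,
    ResponseVector,
    _cond_loglik,
    _posterior_from_loglik,
    build_quadrature_grid,
    prob_matrix,
)

__all__ = [
    "EstimatorConfig",
    "OnlineItemState",
    "OnlineEstimator",
    "TrajectoryRecord",
    "step_size",
    "truncation_floor",
    "averaging_weight",
    "item_gradient",
    "item_curvature",
    "accumulate_hessian",
    "update_item",
    "eap_ability",
    "standard_errors",
]


@dataclass(frozen=True)
class EstimatorConfig:
    """Schedule constants and model settings for the online recursion.

    Parameters
    ----------
    gamma
        Step-size exponent; must lie in (1/2, 1].  Defaults to 0.65,
        the recommended averaged-variant setting (0.75 suits the
        non-averaged variant, see :meth:`tsna`).
    c_nu
        Step-size scale (> 0).
    n0
        Delay constant in the step denominator; damps the earliest,
        least-reliable updates.
    c_lambda, alpha_lambda
        Scale and exponent of the decaying curvature floor
        ``lambda_n = c_lambda * (n + 1)^(-alpha_lambda)``.  The Bernoulli
        variance ``P(1-P) = 1 / (2 + 2 cosh(eta))`` never exceeds 1/4, so
        ``c_lambda <= 1/4`` is enforced; ``alpha_lambda < 1/2`` keeps the
        floor decaying slowly enough for the curvature average to converge.
    avg_mode
        ``"none"`` (non-averaged, TSNA), ``"uniform"`` (arithmetic mean of
        iterates), or ``"log"`` (log-weighted average with exponent
        ``avg_w``, the default).
    avg_w
        Exponent of the log-weighted averaging sequence
        ``omega_i = ln(1 + i)^avg_w``.
    K
        Gauss–Hermite nodes per latent dimension.
    gradient_at
        Where the per-examinee gradient is evaluated: ``"current"``
        (default) or ``"averaged"``.
    hessian_init
        ``"expected"`` seeds ``S0`` with the prior-weighted expected item
        information at the initial parameters (plus a small ridge);
        ``"identity"`` uses the identity matrix.
    ridge
        Ridge added to the expected-information ``S0``.
    force_tau
        Diagnostic override: when set, the averaging weight is this
        constant regardless of ``avg_mode`` (``force_tau=1`` reproduces
        the non-averaged recursion through the averaged code path).
    """

    gamma: float = 0.65
    c_nu: float = 1.0
    n0: float = 20.0
    c_lambda: float = 0.2
    alpha_lambda: float = 0.49
    avg_mode: str = "log"
    avg_w: float = 2.0
    K: int = 11
    Q: int = 1
    seed: int | None = None
    gradient_at: str = "current"
    hessian_init: str = "expected"
    ridge: float = 1e-3
    force_tau: float | None = None

    def __post_init__(self) -> None:
        if not (0.5 < self.gamma <= 1.0):
            raise ValueError(f"gamma must be in (1/2, 1], got {self.gamma}")
        if self.c_nu <= 0:
            raise ValueError("c_nu must be positive")
        if self.n0 < 0:
            raise ValueError("n0 must be nonnegative")
        if not (0.0 < self.c_lambda <= 0.25):
            raise ValueError(
                f"c_lambda must be in (0, 1/4] (Bernoulli curvature bound), "
                f"got {self.c_lambda}"
            )
        if not (0.0 < self.alpha_lambda < 0.5):
            raise ValueError(
                f"alpha_lambda must be in (0, 1/2), got {self.alpha_lambda}"
            )
        if self.avg_mode not in ("none", "uniform", "log"):
            raise ValueError(f"unknown avg_mode {self.avg_mode!r}")
        if self.avg_w < 0:
            raise ValueError("avg_w must be nonnegative")
        if self.gradient_at not in ("current", "averaged"):
            raise ValueError(f"unknown gradient_at {self.gradient_at!r}")
        if self.hessian_init not in ("expected", "identity"):
            raise ValueError(f"unknown hessian_init {self.hessian_init!r}")

    @classmethod
    def tasna(cls, **kw) -> "EstimatorConfig":
        """Averaged defaults: gamma = 0.65, log-weighted averaging."""
        return cls(**{"gamma": 0.65, "avg_mode": "log", **kw})

    @classmethod
    def tsna(cls, **kw) -> "EstimatorConfig":
        """Non-averaged defaults: gamma = 0.75, no averaging step."""
        return cls(**{"gamma": 0.75, "avg_mode": "none", **kw})


def step_size(n: int, config: EstimatorConfig) -> float:
    """Step size ``nu_n = c_nu * (n + n0)^(-gamma)``; decreasing in n."""
    return config.c_nu * float(n + config.n0) ** (-config.gamma)


def truncation_floor(n: int, config: EstimatorConfig) -> float:
    """Curvature floor ``lambda_n = c_lambda * (n + 1)^(-alpha_lambda)``.

    Stays below 1/4 (the Bernoulli curvature maximum) and decays to 0.
    """
    return config.c_lambda * float(n + 1) ** (-config.alpha_lambda)


def _omega(i: np.ndarray | float, config: EstimatorConfig) -> np.ndarray:
    if config.avg_mode == "uniform":
        return np.ones_like(np.asarray(i, dtype=float))
    return np.log1p(i) ** config.avg_w


def averaging_weight(
    n: int, config: EstimatorConfig, omega_cumsum: float | None = None
) -> float:
    """Averaging weight ``tau_n`` for the update of the averaged iterate.

    ``tau_n = omega_n / sum_{i<=n} omega_i`` with ``omega_i = 1`` (uniform
    mean of the iterates beta_1..beta_n) or ``omega_i = ln(1+i)^avg_w``
    (log-weighted; ``avg_w = 0`` recovers the uniform mean).  With
    ``avg_mode="none"`` the weight is identically 1, so the averaged
    iterate coincides with the current one.  ``omega_cumsum``, when given,
    supplies ``sum_{i<=n} omega_i`` so streaming callers avoid the O(n)
    recomputation.
    """
    if config.force_tau is not None:
        return float(config.force_tau)
    if config.avg_mode == "none":
        return 1.0
    if omega_cumsum is None:
        omega_cumsum = float(_omega(np.arange(1, n + 1, dtype=float), config).sum())
    return float(_omega(float(n), config)) / omega_cumsum


# ---------------------------------------------------------------------------
# per-item kernels (shared by the vectorized engine and the per-item API)

def _gradient_kernel(
    y: np.ndarray, post: np.ndarray, P: np.ndarray, X: np.ndarray,
    free: np.ndarray,
) -> np.ndarray:
    """Stacked item gradients ``-(y_j - P_jk)`` posterior-weighted.

    ``y`` (J,), ``post`` (M,), ``P`` (J, M), ``X`` (M, Q+1) augmented nodes,
    ``free`` (J, Q+1).  Anchored entries are zeroed.
    """
    G = -(((y[:, None] - P) * post) @ X)
    G[~free] = 0.0
    return G

def _curvature_kernel(
    post: np.ndarray, P: np.ndarray, X: np.ndarray, floor: float,
    free: np.ndarray,
) -> np.ndarray:
    """Stacked truncated curvatures ``(J, Q+1, Q+1)``.

    ``Phi_j = sum_k post_k * max(P_jk (1 - P_jk), floor) * x_k x_k'`` with
    anchored rows and columns zeroed (so accumulation never perturbs the
    anchored block of ``S``).
    """
    W = post * np.maximum(P * (1.0 - P), floor)
    Phi = np.einsum("jm,mp,mq->jpq", W, X, X, optimize=True)
    if not free.all():
        Phi *= free[:, :, None]  # zero anchored rows
        Phi *= free[:, None, :]  # zero anchored columns
    return Phi


def _anchored_embed(S: np.ndarray, free: np.ndarray) -> np.ndarray:
    """Force anchored rows/cols of each S_j to the identity pattern."""
    J, P, _ = S.shape
    for j in range(J):
        fixed = ~free[j]
        if fixed.any():
            S[j][fixed, :] = 0.0
            S[j][:, fixed] = 0.0
            S[j][fixed, fixed] = 1.0
    return S


def _initial_hessian(
    beta: np.ndarray, free: np.ndarray, grid: QuadratureGrid,
    config: EstimatorConfig,
) -> np.ndarray:
    """Positive-definite seed ``S0`` for the accumulated curvature.

    ``"expected"`` integrates the per-examinee item information at the
    initial parameters against the prior grid weights, plus a ridge;
    ``"identity"`` is the sanctioned fallback.
    """
    J, P = beta.shape
    if config.hessian_init == "identity":
        S0 = np.broadcast_to(np.eye(P), (J, P, P)).copy()
    else:
        Pm = prob_matrix(beta, grid.nodes)
        S0 = _curvature_kernel(grid.weights, Pm, grid.augmented, 0.0, free)
        S0 = S0 + config.ridge * np.eye(P)
    return _anchored_embed(S0, free)


# ---------------------------------------------------------------------------
# spec-level per-item API

def item_gradient(
    y_j: float, post: np.ndarray, beta_j: ItemParamVector, grid: QuadratureGrid
) -> np.ndarray:
    """Gradient of the examinee objective w.r.t. item j's free entries.

    ``g = -sum_k post_k (y_j - P_jk) x_k`` restricted to the free entries,
    with ``x_k`` the augmented node ``(theta_k, 1)``.  Because the ability
    posterior's own parameter dependence cancels in the score of the
    marginal likelihood, this is the exact per-examinee gradient.
    """
    P = prob_matrix(beta_j.beta[None, :], grid.nodes)
    G = _gradient_kernel(
        np.array([float(y_j)]), np.asarray(post), P, grid.augmented,
        beta_j.free_mask[None, :],
    )
    return G[0][beta_j.free_mask]


def item_curvature(
    post: np.ndarray,
    beta_j: ItemParamVector,
    grid: QuadratureGrid,
    floor: float = 0.0,
) -> np.ndarray:
    """Truncated per-examinee information matrix over item j's free entries.

    Posterior-weighted ``max(P(1-P), floor) x x'``; symmetric PSD, and
    positive definite whenever ``floor > 0`` and the grid spans the
    augmented space.
    """
    P = prob_matrix(beta_j.beta[None, :], grid.nodes)
    Phi = _curvature_kernel(
        np.asarray(post), P, grid.augmented, floor, beta_j.free_mask[None, :]
    )
    return Phi[0][np.ix_(beta_j.free_mask, beta_j.free_mask)]


@dataclass
class OnlineItemState:
    """Streaming state of a single item.

    ``S`` is the accumulated curvature over the full ``(Q+1)`` entries with
    the anchored block held at the identity pattern; the normalized
    curvature used by the Newton step is ``S / (n + 1)`` (the prior seed
    counts as one pseudo-observation).
    """

    beta_current: ItemParamVector
    beta_avg: ItemParamVector
    S: np.ndarray
    n: int = 0
    omega_cumsum: float = 0.0


def accumulate_hessian(state_j: OnlineItemState, Phi: np.ndarray) -> OnlineItemState:
    """Add a (full-dimension, anchored-zeroed) curvature term into ``S``."""
    state_j.S = state_j.S + Phi
    return state_j


def update_item(
    state_j: OnlineItemState,
    y_j: float,
    grid: QuadratureGrid,
    config: EstimatorConfig,
    post_for_gradient: np.ndarray,
    post_for_hessian: np.ndarray,
) -> OnlineItemState:
    """One stochastic Newton update of a single item's state.

    Mirrors the vectorized engine exactly: gradient at the current iterate
    (or averaged, per ``config.gradient_at``), truncated curvature at the
    averaged iterate, Newton step against ``S/n`` from *before* this
    examinee's curvature is accumulated, then the averaging step.  Anchored
    entries never move.
    """
    free = state_j.beta_current.free_mask
    n = state_j.n + 1
    X = grid.augmented

    beta_g = (
        state_j.beta_current.beta
        if config.gradient_at == "current"
        else state_j.beta_avg.beta
    )
    Pg = prob_matrix(beta_g[None, :], grid.nodes)
    G = _gradient_kernel(
        np.array([float(y_j)]), np.asarray(post_for_gradient), Pg, X,
        free[None, :],
    )[0]

    Ph = prob_matrix(state_j.beta_avg.beta[None, :], grid.nodes)
    Phi = _curvature_kernel(
        np.asarray(post_for_hessian), Ph, X, truncation_floor(n, config),
        free[None, :],
    )[0]

    if free.any():
        Hbar = state_j.S / n
        try:
            delta = np.linalg.solve(Hbar, G)
        except np.linalg.LinAlgError as exc:  # unreachable with PD S0
            raise np.linalg.LinAlgError(
                f"singular scaled Hessian at n={n}: {exc}"
            ) from exc
        new_beta = state_j.beta_current.beta - step_size(n, config) * delta
        new_beta[~free] = state_j.beta_current.beta[~free]
    else:
        new_beta = state_j.beta_current.beta

    state_j.beta_current = ItemParamVector(
        new_beta[:-1], new_beta[-1], free.copy()
    )
    state_j.S = state_j.S + Phi
    state_j.omega_cumsum += float(_omega(float(n), config))
    tau = averaging_weight(n, config, state_j.omega_cumsum)
    avg = (1.0 - tau) * state_j.beta_avg.beta + tau * state_j.beta_current.beta
    avg[~free] = state_j.beta_avg.beta[~free]
    state_j.beta_avg = ItemParamVector(avg[:-1], avg[-1], free.copy())
    state_j.n = n
    return state_j


def eap_ability(
    y: ResponseVector, params: ItemParamSet, grid: QuadratureGrid
) -> np.ndarray:
    """Expected-a-posteriori ability: posterior mean of theta on the grid."""
    from .model import posterior_node_weights

    post = posterior_node_weights(y, params, grid)
    return post @ grid.nodes


@dataclass
class TrajectoryRecord:
    """Per-examinee snapshot emitted by the streaming engine."""

    n: int
    examinee_id: str
    beta_avg: np.ndarray  # (J, Q+1)
    eap: np.ndarray  # (Q,)
    step: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "examinee_id": self.examinee_id,
            "beta_avg": self.beta_avg.tolist(),
            "eap": self.eap.tolist(),
            "step": self.step,
        }


class OnlineEstimator:
    """Streaming TSNA/TASNA engine over a full item set.

    Holds stacked per-item states (iterate, average, accumulated curvature)
    and processes one :class:`~irtstream.model.ResponseVector` at a time.
    All items are updated jointly from the examinee's two ability
    posteriors — one at the current iterates (gradient) and one at the
    averaged iterates (curvature) — and the examinee is EAP-scored with the
    just-updated averaged parameters.
    """

    def __init__(
        self,
        init_params: ItemParamSet,
        config: EstimatorConfig,
        grid: QuadratureGrid | None = None,
    ) -> None:
        self.config = config
        self.grid = grid if grid is not None else build_quadrature_grid(
            config.K, init_params.Q
        )
        if self.grid.Q != init_params.Q:
            raise ValueError("grid dimension does not match item dimension")
        self.item_ids = list(init_params.item_ids)
        self.beta = init_params.beta_matrix()
        self.free = init_params.free_matrix()
        self.beta_avg = self.beta.copy()
        self.S = _initial_hessian(self.beta, self.free, self.grid, config)
        self.n = 0
        self._omega_cumsum = 0.0

    @classmethod
    def with_default_start(
        cls,
        J: int,
        config: EstimatorConfig,
        free: np.ndarray | None = None,
        item_ids: Sequence[str] | None = None,
    ) -> "OnlineEstimator":
        """Start from discriminations 1 and intercepts 0 for all items."""
        Q = config.Q
        beta = np.hstack([np.ones((J, Q)), np.zeros((J, 1))])
        params = ItemParamSet.from_arrays(beta, free, item_ids)
        return cls(params, config)

    # -- accessors ---------------------------------------------------------

    @property
    def J(self) -> int:
        return self.beta.shape[0]

    @property
    def Q(self) -> int:
        return self.beta.shape[1] - 1

    def params(self, averaged: bool = True) -> ItemParamSet:
        """Current estimates as an :class:`ItemParamSet` (averaged by default)."""
        b = self.beta_avg if averaged else self.beta
        return ItemParamSet.from_arrays(b.copy(), self.free.copy(), self.item_ids)

    # -- core update -------------------------------------------------------

    def _posterior(self, y: ResponseVector, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        P = prob_matrix(beta, self.grid.nodes)
        ll = _cond_loglik(y.values, P, y.mask)
        return _posterior_from_loglik(ll, self.grid.log_weights), P

    def process_examinee(
        self, y: ResponseVector, compute_eap: bool = True
    ) -> TrajectoryRecord:
        """Consume one response vector; update every item, then EAP-score.

        Returns a :class:`TrajectoryRecord` with the post-update averaged
        estimates, the examinee's EAP ability, and the step size used.
        ``compute_eap=False`` skips the scoring pass (the record carries an
        all-NaN ability) for item-recovery runs where only the item
        trajectory matters.
        """
        if y.J != self.J:
            raise ValueError(f"response length {y.J} != J={self.J}")
        if y.mask is not None:
            free_eff = self.free & y.mask[:, None]
        else:
            free_eff = self.free
        n = self.n + 1
        nu = step_size(n, self.config)
        lam = truncation_floor(n, self.config)
        X = self.grid.augmented

        beta_g = self.beta if self.config.gradient_at == "current" else self.beta_avg
        post_g, Pg = self._posterior(y, beta_g)
        if self.config.gradient_at != "current":
            Pg = prob_matrix(self.beta, self.grid.nodes)
        # gradient residual at the current iterate's probabilities
        G = _gradient_kernel(y.values, post_g, Pg, X, free_eff)

        post_h, Ph = self._posterior(y, self.beta_avg)
        Phi = _curvature_kernel(post_h, Ph, X, lam, free_eff)

        Hbar = self.S / n
        delta = np.linalg.solve(Hbar, G[:, :, None])[:, :, 0]
        delta[~free_eff] = 0.0
        self.beta = self.beta - nu * delta
        self.S = self.S + Phi

        self._omega_cumsum += float(_omega(float(n), self.config))
        tau = averaging_weight(n, self.config, self._omega_cumsum)
        self.beta_avg = np.where(
            self.free, (1.0 - tau) * self.beta_avg + tau * self.beta, self.beta_avg
        )
        self.n = n

        if compute_eap:
            post_eap, _ = self._posterior(y, self.beta_avg)
            eap = post_eap @ self.grid.nodes
        else:
            eap = np.full(self.Q, np.nan)
        return TrajectoryRecord(
            n=n,
            examinee_id=y.examinee_id or str(n),
            beta_avg=self.beta_avg.copy(),
            eap=eap,
            step=nu,
        )

    def run(
        self,
        stream: Iterable[ResponseVector],
        checkpoints: Sequence[int] | None = None,
        collect_eap: bool = True,
    ) -> "OnlineFitResult":
        """Stream a sequence of examinees through the recursion.

        ``checkpoints`` selects the examinee counts at which a full
        :class:`TrajectoryRecord` is retained (all of them when None would
        be memory-hostile for large streams, so None keeps only the final
        record); EAP scores are collected for every examinee when
        ``collect_eap`` is set.
        """
        cps = set(int(c) for c in checkpoints) if checkpoints is not None else None
        records: list[TrajectoryRecord] = []
        eaps: list[np.ndarray] = []
        last: TrajectoryRecord | None = None
        for y in stream:
            rec = self.process_examinee(y, compute_eap=collect_eap)
            last = rec
            if collect_eap:
                eaps.append(rec.eap)
            if cps is not None and rec.n in cps:
                records.append(rec)
        if last is not None and (cps is None or last.n not in cps):
            records.append(last)
        return OnlineFitResult(
            estimator=self,
            records=records,
            eap=np.array(eaps) if eaps else np.empty((0, self.Q)),
        )

    def standard_errors(self) -> np.ndarray:
        """Per-item SEs from the inverse accumulated curvature.

        ``SE_j = sqrt(diag(S_j^{-1}))`` — the unnormalized ``S`` makes the
        1/sqrt(n) asymptotic scale automatic.  Anchored entries are NaN.
        """
        return standard_errors(self)


def standard_errors(state: "OnlineEstimator | OnlineItemState") -> np.ndarray:
    """Square roots of the diagonal of the inverse accumulated Hessian.

    Accepts the full engine (returns a ``(J, Q+1)`` array, NaN at anchored
    entries) or a single :class:`OnlineItemState` (returns a vector over
    free entries).
    """
    if isinstance(state, OnlineItemState):
        free = state.beta_current.free_mask
        sub = state.S[np.ix_(free, free)]
        return np.sqrt(np.diag(np.linalg.inv(sub)))
    out = np.full(state.beta.shape, np.nan)
    for j in range(state.J):
        free = state.free[j]
        if not free.any():
            continue
        sub = state.S[j][np.ix_(free, free)]
        inv = np.linalg.inv(sub)
        d = np.diag(inv)
        if (d <= 0).any():
            raise np.linalg.LinAlgError(
                f"non-positive variance from accumulated Hessian of item {j}"
            )
        out[j, free] = np.sqrt(d)
    return out


@dataclass
class OnlineFitResult:
    """Outcome of streaming a dataset through :class:`OnlineEstimator`."""

    estimator: OnlineEstimator
    records: list[TrajectoryRecord]
    eap: np.ndarray  # (N, Q) per-examinee EAP scores in arrival order

    @property
    def params(self) -> ItemParamSet:
        return self.estimator.params()

    def record_at(self, n: int) -> TrajectoryRecord:
        for r in self.records:
            if r.n == n:
                return r
        raise KeyError(f"no trajectory record at n={n}")
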