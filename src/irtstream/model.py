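"""Response model, quadrature, and per-examinee likelihood quantities.

The two-parameter logistic (2PL) and multidimensional 2PL (M2PL) models are
handled through a single slope–intercept parameterization: item ``j`` has a
loading vector ``a_j`` over ``Q`` latent dimensions and a scalar intercept
``d_j``, and the probability of a correct response for an examinee with
latent trait ``theta`` is ``sigma(a_j' theta + d_j)`` with ``sigma`` the
standard logistic function.  The unidimensional 2PL with discrimination
``a`` and difficulty ``b`` is the ``Q = 1`` case with ``d = -a * b``.

The latent trait carries a standard (multivariate) normal population prior;
the marginal likelihood of a response vector integrates the trait out against
that prior, approximated on a fixed tensor-product Gauss–Hermite grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit, logsumexp

__all__ = [
    "PROB_EPS",
    "GRID_SIZE_GUARD",
    "ItemParamVector",
    "ItemParamSet",
    "QuadratureGrid",
    "ResponseVector",
    "build_quadrature_grid",
    "response_probability",
    "prob_matrix",
    "conditional_node_likelihoods",
    "marginal_likelihood",
    "posterior_node_weights",
    "examinee_objective",
]

#: Response probabilities are clipped to [PROB_EPS, 1 - PROB_EPS] so log
#: terms stay finite; far below any achievable estimation precision.
PROB_EPS = 1e-12

#: Default ceiling on the number of tensor-product quadrature nodes K**Q.
GRID_SIZE_GUARD = 10**6


@dataclass
class ItemParamVector:
    """Parameters of one item in slope–intercept form.

    Parameters
    ----------
    loadings
        Length-``Q`` discrimination (slope) vector.
    intercept
        Scalar intercept ``d`` (logit units).
    free_mask
        Boolean vector of length ``Q + 1`` marking which entries
        (loadings first, intercept last) are estimable.  Anchored
        (non-free) entries are never changed by any estimator.
    """

    loadings: np.ndarray
    intercept: float
    free_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.loadings = np.atleast_1d(np.asarray(self.loadings, dtype=float))
        self.intercept = float(self.intercept)
        if self.free_mask is None:
            self.free_mask = np.ones(self.Q + 1, dtype=bool)
        self.free_mask = np.asarray(self.free_mask, dtype=bool)
        if self.free_mask.shape != (self.Q + 1,):
            raise ValueError(
                f"free_mask must have length Q+1={self.Q + 1}, "
                f"got {self.free_mask.shape}"
            )

    @property
    def Q(self) -> int:
        return self.loadings.size

    @property
    def beta(self) -> np.ndarray:
        """Stacked parameter vector ``(a_1, ..., a_Q, d)``."""
        return np.append(self.loadings, self.intercept)

    @classmethod
    def from_2pl(cls, a: float, b: float, free_mask=None) -> "ItemParamVector":
        """Build from 2PL discrimination/difficulty; ``d = -a * b``."""
        return cls(np.array([float(a)]), -float(a) * float(b), free_mask)

    def to_2pl(self) -> tuple[float, float]:
        """Return ``(a, b)`` with ``b = -d / a`` (requires ``Q == 1``)."""
        if self.Q != 1:
            raise ValueError("2PL conversion requires a unidimensional item")
        a = float(self.loadings[0])
        return a, -self.intercept / a


@dataclass
class ItemParamSet:
    """Ordered collection of ``J`` items sharing a common dimension ``Q``."""

    items: list[ItemParamVector]
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("ItemParamSet requires J >= 1 items")
        qs = {it.Q for it in self.items}
        if len(qs) != 1:
            raise ValueError(f"all items must share one Q, got {sorted(qs)}")
        if not self.item_ids:
            self.item_ids = [f"item{j + 1}" for j in range(len(self.items))]
        if len(self.item_ids) != len(self.items):
            raise ValueError("item_ids length must match number of items")

    @property
    def J(self) -> int:
        return len(self.items)

    @property
    def Q(self) -> int:
        return self.items[0].Q

    def beta_matrix(self) -> np.ndarray:
        """``(J, Q + 1)`` array of stacked ``(loadings, intercept)`` rows."""
        return np.stack([it.beta for it in self.items])

    def free_matrix(self) -> np.ndarray:
        """``(J, Q + 1)`` boolean array of free-parameter masks."""
        return np.stack([it.free_mask for it in self.items])

    @classmethod
    def from_arrays(
        cls,
        beta: np.ndarray,
        free: np.ndarray | None = None,
        item_ids: Sequence[str] | None = None,
    ) -> "ItemParamSet":
        beta = np.asarray(beta, dtype=float)
        J, P = beta.shape
        if free is None:
            free = np.ones((J, P), dtype=bool)
        items = [
            ItemParamVector(beta[j, :-1].copy(), beta[j, -1], free[j].copy())
            for j in range(J)
        ]
        return cls(items, list(item_ids) if item_ids is not None else [])


@dataclass(frozen=True)
class QuadratureGrid:
    """Tensor-product Gauss–Hermite grid for a standard normal prior.

    ``nodes`` is an ``(M, Q)`` matrix of evaluation points and ``weights``
    a length-``M`` probability vector, with ``M = K**Q``.
    """

    nodes: np.ndarray
    weights: np.ndarray
    K: int
    Q: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "log_weights", np.log(self.weights))
        # column of ones appended once: the augmented point (theta, 1) used
        # by gradients/curvatures w.r.t. (loadings, intercept)
        object.__setattr__(
            self,
            "augmented",
            np.hstack([self.nodes, np.ones((self.nodes.shape[0], 1))]),
        )

    @property
    def M(self) -> int:
        return self.nodes.shape[0]


def build_quadrature_grid(
    K: int,
    Q: int,
    size_guard: int = GRID_SIZE_GUARD,
    rule: str = "gauss-hermite",
    lim: float = 4.0,
) -> QuadratureGrid:
    """Tensor-product quadrature grid adapted to a N(0, I_Q) prior.

    ``rule="gauss-hermite"`` (default): physicists' Gauss–Hermite
    abscissae ``t`` scaled by ``sqrt(2)`` so the rule integrates against
    the standard normal density; per-dimension weights are the GH weights
    renormalized to a probability vector, and the joint weight of a tensor
    node is the product over dimensions (again renormalized, so the
    discrete prior is exactly proper).  This is the estimation default:
    it integrates the prior's moments essentially exactly at modest K.

    ``rule="rectangle"``: ``K`` equally spaced nodes on ``[-lim, lim]``
    per dimension with weights proportional to the standard normal density
    at each node — the classic histogram-weighted grid of fixed-quadrature
    IRT.  Its uniform spacing resolves the *narrow* ability posterior an
    examinee accumulates over many items far better than GH node
    placement, so prefer it (e.g. ``K=21``) for precise EAP scoring.

    Raises
    ------
    ValueError
        If ``K**Q`` exceeds ``size_guard`` (dimensionality guard).
    """
    if K < 1 or Q < 1:
        raise ValueError("K and Q must both be >= 1")
    M = K**Q
    if M > size_guard:
        raise ValueError(
            f"quadrature grid of K^Q = {K}^{Q} = {M} nodes exceeds the "
            f"size guard ({size_guard}); reduce K or Q"
        )
    if rule == "gauss-hermite":
        t, w = hermgauss(K)
        x1 = np.sqrt(2.0) * t  # abscissae on the N(0,1) scale
        w1 = w / w.sum()
    elif rule == "rectangle":
        x1 = np.linspace(-lim, lim, K) if K > 1 else np.zeros(1)
        w1 = np.exp(-0.5 * x1**2)
        w1 = w1 / w1.sum()
    else:
        raise ValueError(f"unknown quadrature rule {rule!r}")
    if Q == 1:
        nodes = x1[:, None]
        weights = w1.copy()
    else:
        grids = np.meshgrid(*([x1] * Q), indexing="ij")
        nodes = np.stack([g.ravel() for g in grids], axis=1)
        wg = np.meshgrid(*([w1] * Q), indexing="ij")
        weights = np.prod(np.stack([g.ravel() for g in wg], axis=1), axis=1)
        weights = weights / weights.sum()
    return QuadratureGrid(nodes=nodes, weights=weights, K=K, Q=Q)


@dataclass
class ResponseVector:
    """One examinee's binary responses to ``J`` items.

    In strict mode every entry must be 0 or 1.  In masked mode ``mask``
    flags which entries are present; absent items are skipped in all
    likelihood quantities.
    """

    values: np.ndarray
    examinee_id: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
        observed = self.values if self.mask is None else self.values[self.mask]
        if not np.isin(observed, (0, 1)).all():
            bad = observed[~np.isin(observed, (0, 1))]
            raise ValueError(
                f"responses must be binary; found value(s) {np.unique(bad)}"
            )
        self.values = self.values.astype(float)

    @property
    def J(self) -> int:
        return self.values.size


def response_probability(beta: ItemParamVector, point: np.ndarray) -> float:
    """Correct-response probability ``sigma(a' theta + d)`` at one point."""
    point = np.atleast_1d(np.asarray(point, dtype=float))
    if point.size != beta.Q:
        raise ValueError(
            f"ability point has dimension {point.size}, item has Q={beta.Q}"
        )
    eta = float(beta.loadings @ point + beta.intercept)
    return float(np.clip(expit(eta), PROB_EPS, 1.0 - PROB_EPS))


def prob_matrix(beta: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """``(J, M)`` matrix of response probabilities at all grid nodes.

    ``beta`` is ``(J, Q + 1)`` with the intercept last; ``nodes`` ``(M, Q)``.
    """
    eta = beta[:, :-1] @ nodes.T + beta[:, -1:]
    return np.clip(expit(eta), PROB_EPS, 1.0 - PROB_EPS)


def _cond_loglik(
    y: np.ndarray, P: np.ndarray, mask: np.ndarray | None
) -> np.ndarray:
    logP = np.log(P)
    log1mP = np.log1p(-P)
    if mask is None:
        return y @ logP + (1.0 - y) @ log1mP
    ym = y[mask]
    return ym @ logP[mask] + (1.0 - ym) @ log1mP[mask]


def conditional_node_likelihoods(
    y: ResponseVector, params: ItemParamSet, grid: QuadratureGrid
) -> np.ndarray:
    """Log conditional likelihood of ``y`` at every grid node.

    Entry ``k`` is ``sum_j [y_j log P_jk + (1 - y_j) log(1 - P_jk)]``;
    masked-out items are skipped.
    """
    if y.J != params.J:
        raise ValueError(f"response length {y.J} != number of items {params.J}")
    P = prob_matrix(params.beta_matrix(), grid.nodes)
    return _cond_loglik(y.values, P, y.mask)


def marginal_likelihood(
    y: ResponseVector, params: ItemParamSet, grid: QuadratureGrid
) -> tuple[float, float]:
    """Quadrature-approximated marginal likelihood of ``y`` and its log.

    Computed via log-sum-exp over nodes: ``sum_k w_k exp(loglik_k)``.
    """
    ll = conditional_node_likelihoods(y, params, grid)
    log_m = float(logsumexp(ll + grid.log_weights))
    return float(np.exp(log_m)), log_m


def posterior_node_weights(
    y: ResponseVector, params: ItemParamSet, grid: QuadratureGrid
) -> np.ndarray:
    """Discrete posterior of the examinee's ability over the grid nodes."""
    ll = conditional_node_likelihoods(y, params, grid)
    return _posterior_from_loglik(ll, grid.log_weights)


def _posterior_from_loglik(
    cond_loglik: np.ndarray, log_weights: np.ndarray
) -> np.ndarray:
    z = cond_loglik + log_weights
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def examinee_objective(
    y: ResponseVector, params: ItemParamSet, grid: QuadratureGrid
) -> float:
    """Per-examinee negative log marginal likelihood (nonnegative)."""
    return -marginal_likelihood(y, params, grid)[1]
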