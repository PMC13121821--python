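"""Fixed-quadrature Bock–Aitkin marginal-maximum-likelihood EM baseline.

The offline reference the streaming recursion is compared against.  The
E-step computes, for every examinee, the discrete ability posterior over
the Gauss–Hermite grid and aggregates it into expected counts per node
(``nbar``) and expected correct counts per item per node (``rbar``).  The
M-step maximizes each item's expected complete-data log-likelihood by a
damped Newton iteration using the node-weighted Bernoulli information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import (
    ItemParamSet,
    QuadratureGrid,
    build_quadrature_grid,
    prob_matrix,
)

__all__ = ["ExpectedCounts", "EMConfig", "EMResult", "e_step", "m_step_item", "em_fit"]


@dataclass
class ExpectedCounts:
    """Sufficient statistics of one E-step.

    ``nbar[k]`` is the expected number of examinees at node ``k``;
    ``rbar[j, k]`` the expected number of correct responses to item ``j``
    at node ``k``.  Invariants: ``0 <= rbar <= nbar`` and ``nbar`` sums
    to the sample size.
    """

    nbar: np.ndarray
    rbar: np.ndarray


@dataclass(frozen=True)
class EMConfig:
    max_cycles: int = 500
    loglik_tol: float = 1e-6
    newton_tol: float = 1e-8
    newton_max_iter: int = 50
    max_halvings: int = 30
    K: int = 11


def _posterior_matrix(
    data: np.ndarray, beta: np.ndarray, grid: QuadratureGrid
) -> tuple[np.ndarray, float]:
    """(N, M) posterior matrix and the total marginal log-likelihood."""
    P = prob_matrix(beta, grid.nodes)
    ll = data @ np.log(P) + (1.0 - data) @ np.log1p(-P)  # (N, M)
    z = ll + grid.log_weights
    log_m = logsumexp(z, axis=1)
    post = np.exp(z - log_m[:, None])
    return post, float(log_m.sum())


def e_step(
    data: np.ndarray, params: ItemParamSet, grid: QuadratureGrid
) -> ExpectedCounts:
    """Expected per-node examinee and correct counts under current params."""
    data = np.asarray(data, dtype=float)
    post, _ = _posterior_matrix(data, params.beta_matrix(), grid)
    nbar = post.sum(axis=0)
    rbar = data.T @ post
    return ExpectedCounts(nbar=nbar, rbar=rbar)


def _item_expected_loglik(
    beta_j: np.ndarray, nbar: np.ndarray, rbar_j: np.ndarray, grid: QuadratureGrid
) -> float:
    P = prob_matrix(beta_j[None, :], grid.nodes)[0]
    return float(rbar_j @ np.log(P) + (nbar - rbar_j) @ np.log1p(-P))


def m_step_item(
    counts: ExpectedCounts,
    j: int,
    beta_j: np.ndarray,
    free_j: np.ndarray,
    grid: QuadratureGrid,
    config: EMConfig = EMConfig(),
) -> np.ndarray:
    """Damped Newton maximization of one item's expected log-likelihood.

    Solves the score equation ``sum_k (rbar_jk - nbar_k P_jk) x_k = 0``
    over the free entries with the weighted information matrix
    ``sum_k nbar_k P_jk (1 - P_jk) x_k x_k'``; steps are halved when the
    expected log-likelihood would decrease or the iterate goes non-finite.
    """
    if not free_j.any():
        return beta_j.copy()
    beta = beta_j.copy()
    X = grid.augmented
    nbar, rbar_j = counts.nbar, counts.rbar[j]
    obj = _item_expected_loglik(beta, nbar, rbar_j, grid)
    for _ in range(config.newton_max_iter):
        P = prob_matrix(beta[None, :], grid.nodes)[0]
        score_full = (rbar_j - nbar * P) @ X
        score = score_full[free_j]
        if np.max(np.abs(score)) < config.newton_tol:
            break
        W = nbar * P * (1.0 - P)
        info = (X.T * W) @ X
        info = info[np.ix_(free_j, free_j)]
        step = np.linalg.solve(info, score)
        for halving in range(config.max_halvings + 1):
            trial = beta.copy()
            trial[free_j] = beta[free_j] + step
            if np.isfinite(trial).all():
                new_obj = _item_expected_loglik(trial, nbar, rbar_j, grid)
                if new_obj >= obj - 1e-12:
                    beta, obj = trial, new_obj
                    break
            step = step / 2.0
        else:
            raise RuntimeError(
                f"M-step for item {j} failed after {config.max_halvings} "
                "step halvings"
            )
    return beta


@dataclass
class EMResult:
    params: ItemParamSet
    loglik_trace: list[float] = field(default_factory=list)
    n_cycles: int = 0
    converged: bool = False

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def em_fit(
    data: np.ndarray,
    init_params: ItemParamSet,
    grid: QuadratureGrid | None = None,
    config: EMConfig = EMConfig(),
) -> EMResult:
    """Alternate E- and M-steps until the marginal log-likelihood stalls.

    The observed-data log-likelihood is asserted non-decreasing each cycle
    (classical EM guarantee; a drop beyond 1e-8 raises a diagnostic
    failure).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != init_params.J:
        raise ValueError("data must be an (N, J) binary matrix")
    if grid is None:
        grid = build_quadrature_grid(config.K, init_params.Q)
    beta = init_params.beta_matrix()
    free = init_params.free_matrix()
    trace: list[float] = []
    converged = False
    cycle = 0
    for cycle in range(1, config.max_cycles + 1):
        post, loglik = _posterior_matrix(data, beta, grid)
        if trace and loglik < trace[-1] - 1e-8:
            raise RuntimeError(
                f"EM log-likelihood decreased at cycle {cycle}: "
                f"{trace[-1]:.10f} -> {loglik:.10f}"
            )
        if trace and abs(loglik - trace[-1]) < config.loglik_tol:
            trace.append(loglik)
            converged = True
            break
        trace.append(loglik)
        nbar = post.sum(axis=0)
        rbar = data.T @ post
        counts = ExpectedCounts(nbar=nbar, rbar=rbar)
        beta = np.stack(
            [
                m_step_item(counts, j, beta[j], free[j], grid, config)
                for j in range(beta.shape[0])
            ]
        )
    params = ItemParamSet.from_arrays(beta, free, init_params.item_ids)
    return EMResult(
        params=params, loglik_trace=trace, n_cycles=cycle, converged=converged
    )
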