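"""Synthetic response data, identifiability constraints, and recovery studies.

The generator emulates the standard Monte Carlo design for 2PL/M2PL
recovery experiments: abilities drawn i.i.d. from a standard (multivariate)
normal, discriminations from a uniform distribution, difficulties (2PL) or
intercepts (M2PL) from a standard normal, and Bernoulli responses from the
logistic response function.  For multidimensional models, rotational and
scale indeterminacy is resolved by anchoring the first ``Q`` items to an
identity loading pattern with zero intercepts before responses are
generated; the unidimensional model is identified by the standard-normal
ability prior alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .em import EMConfig, em_fit
from .model import (
    ItemParamSet,
    ItemParamVector,
    QuadratureGrid,
    ResponseVector,
    build_quadrature_grid,
)
from .online import EstimatorConfig, OnlineEstimator, OnlineFitResult

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "Dataset",
    "BiasRmseTable",
    "generate_dataset",
    "apply_identifiability",
    "evaluate_bias_rmse",
    "item_param_errors",
    "pooled_item_rmse",
    "eap_scores",
    "stream_fit",
    "recovery_run",
    "run_replication_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated recovery condition.

    ``a_low``/``a_high`` bound the uniform discrimination distribution
    (default U(0.5, 2.0), covering typical operational item slopes);
    difficulties/intercepts are standard normal and abilities standard
    multivariate normal.  ``J > Q`` is required so the anchor items leave
    free items to estimate.
    """

    N: int = 2500
    J: int = 20
    Q: int = 1
    a_low: float = 0.5
    a_high: float = 2.0
    K_fit: int = 11
    replications: int = 20
    base_seed: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.a_low < self.a_high):
            raise ValueError("need 0 < a_low < a_high")
        if self.J <= self.Q:
            raise ValueError("need J > Q so anchors leave free items")


@dataclass
class Dataset:
    """One simulated dataset: latent truths plus the observed responses."""

    thetas: np.ndarray  # (N, Q)
    params: ItemParamSet  # true item parameters (anchors already applied)
    responses: np.ndarray  # (N, J) in {0, 1}

    def iter_responses(self):
        for n in range(self.responses.shape[0]):
            yield ResponseVector(self.responses[n], examinee_id=str(n + 1))


def apply_identifiability(params: ItemParamSet, Q: int) -> ItemParamSet:
    """Anchor the first ``Q`` items to fix rotation and scale (M2PL).

    For ``Q >= 2`` item ``q`` gets intercept 0 and loadings equal to the
    ``q``-th identity row, all entries anchored.  For ``Q == 1`` nothing is
    anchored: the standard-normal ability prior fixes the scale.
    """
    if params.J < Q:
        raise ValueError(f"need J >= Q anchors, got J={params.J}, Q={Q}")
    if Q == 1:
        return params
    items = [
        ItemParamVector(it.loadings.copy(), it.intercept, it.free_mask.copy())
        for it in params.items
    ]
    for q in range(Q):
        loadings = np.zeros(Q)
        loadings[q] = 1.0
        items[q] = ItemParamVector(loadings, 0.0, np.zeros(Q + 1, dtype=bool))
    return ItemParamSet(items, list(params.item_ids))


def generate_dataset(simconfig: SimulationConfig, seed: int) -> Dataset:
    """Draw items, abilities, and Bernoulli responses for one replication.

    The RNG order is items, then abilities, then response uniforms, so the
    same seed always yields the same dataset.  Identifiability anchors are
    applied *before* responses are generated, so anchored values are part
    of the data-generating truth.
    """
    rng = np.random.default_rng(seed)
    J, Q = simconfig.J, simconfig.Q
    a = rng.uniform(simconfig.a_low, simconfig.a_high, size=(J, Q))
    if Q == 1:
        b = rng.standard_normal(J)
        d = -a[:, 0] * b
    else:
        d = rng.standard_normal(J)
    params = ItemParamSet.from_arrays(np.hstack([a, d[:, None]]))
    params = apply_identifiability(params, Q)
    beta = params.beta_matrix()
    thetas = rng.standard_normal((simconfig.N, Q))
    probs = expit(thetas @ beta[:, :-1].T + beta[:, -1])
    responses = (rng.random((simconfig.N, J)) < probs).astype(np.int8)
    return Dataset(thetas=thetas, params=params, responses=responses)


# ---------------------------------------------------------------------------
# evaluation


def item_param_errors(
    est: ItemParamSet | np.ndarray, truth: ItemParamSet
) -> tuple[np.ndarray, np.ndarray]:
    """Flat error vector over free item parameters, with class labels.

    For the unidimensional model errors are reported on the
    discrimination/difficulty scale ``(a, b = -d/a)``; for ``Q >= 2`` on
    the slope–intercept scale ``(a_1..a_Q, d)``.  Anchored entries are
    excluded (their error is identically zero by construction).
    """
    beta_est = est.beta_matrix() if isinstance(est, ItemParamSet) else np.asarray(est)
    beta_true = truth.beta_matrix()
    free = truth.free_matrix()
    Q = truth.Q
    if Q == 1:
        a_e, d_e = beta_est[:, 0], beta_est[:, 1]
        a_t, d_t = beta_true[:, 0], beta_true[:, 1]
        errs = np.concatenate([a_e - a_t, (-d_e / a_e) - (-d_t / a_t)])
        labels = np.array(["discrimination"] * truth.J + ["difficulty"] * truth.J)
        keep = np.concatenate([free[:, 0], free[:, 1]])
        return errs[keep], labels[keep]
    errs = (beta_est - beta_true)[free]
    labels = np.where(
        np.arange(Q + 1)[None, :] < Q, "discrimination", "intercept"
    )
    return errs, np.broadcast_to(labels, free.shape)[free]


def pooled_item_rmse(est: ItemParamSet | np.ndarray, truth: ItemParamSet) -> float:
    """RMSE pooled over all free item parameters of one fit."""
    errs, _ = item_param_errors(est, truth)
    return float(np.sqrt(np.mean(errs**2)))


@dataclass
class BiasRmseTable:
    """Per-parameter and per-class bias/RMSE summary across replications."""

    table: pd.DataFrame  # columns: parameter, class, bias, rmse

    def class_summary(self) -> pd.DataFrame:
        return (
            self.table.groupby("class")[["bias", "rmse"]]
            .mean()
            .reset_index()
        )

    def average_rmse(self) -> float:
        return float(self.table["rmse"].mean())


def evaluate_bias_rmse(
    estimates: np.ndarray,
    truth: np.ndarray,
    labels: Sequence[str] | None = None,
) -> BiasRmseTable:
    """Bias and RMSE of each parameter across replications.

    ``estimates`` is ``(R, P)``; ``truth`` either ``(P,)`` (shared truth)
    or ``(R, P)`` (per-replication truths).  Per parameter ``p``:
    ``bias_p = mean_r(est - truth)`` and ``rmse_p = sqrt(mean_r (est -
    truth)^2)``; RMSE >= |bias| always (Jensen).
    """
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    truth = np.asarray(truth, dtype=float)
    if truth.ndim == 1:
        truth = np.broadcast_to(truth, estimates.shape)
    if truth.shape != estimates.shape:
        raise ValueError(
            f"shape mismatch: estimates {estimates.shape}, truth {truth.shape}"
        )
    err = estimates - truth
    bias = err.mean(axis=0)
    rmse = np.sqrt((err**2).mean(axis=0))
    P = estimates.shape[1]
    if labels is None:
        labels = ["parameter"] * P
    table = pd.DataFrame(
        {
            "parameter": [f"p{i + 1}" for i in range(P)],
            "class": list(labels),
            "bias": bias,
            "rmse": rmse,
        }
    )
    return BiasRmseTable(table)


def eap_scores(
    responses: np.ndarray, params: ItemParamSet, grid: QuadratureGrid
) -> np.ndarray:
    """Batch EAP ability scores given fixed item parameters, ``(N, Q)``."""
    from .em import _posterior_matrix

    post, _ = _posterior_matrix(np.asarray(responses, dtype=float), params.beta_matrix(), grid)
    return post @ grid.nodes


# ---------------------------------------------------------------------------
# runners


def stream_fit(
    responses: np.ndarray,
    config: EstimatorConfig,
    template: ItemParamSet | None = None,
    checkpoints: Sequence[int] | None = None,
    collect_eap: bool = True,
) -> OnlineFitResult:
    """Stream a response matrix (row order = arrival order) through TASNA/TSNA.

    ``template``, when given, supplies the free-parameter masks and the
    values of anchored entries; free entries start from the conventional
    discrimination 1 / intercept 0.
    """
    responses = np.asarray(responses)
    J = responses.shape[1]
    if template is not None:
        free = template.free_matrix()
        beta0 = np.hstack([np.ones((J, config.Q)), np.zeros((J, 1))])
        beta0[~free] = template.beta_matrix()[~free]
        est = OnlineEstimator(
            ItemParamSet.from_arrays(beta0, free, template.item_ids), config
        )
    else:
        est = OnlineEstimator.with_default_start(J, config)
    stream = (
        ResponseVector(responses[n], examinee_id=str(n + 1))
        for n in range(responses.shape[0])
    )
    return est.run(stream, checkpoints=checkpoints, collect_eap=collect_eap)


def recovery_run(
    simconfig: SimulationConfig,
    est_config: EstimatorConfig,
    seed: int,
    checkpoints: Sequence[int] | None = None,
) -> dict:
    """One replication: generate, stream, and score item recovery.

    Returns the dataset, the fit, and pooled item RMSE at each checkpoint
    (final sample size always included).
    """
    data = generate_dataset(simconfig, seed)
    cps = sorted(set(list(checkpoints or []) + [simconfig.N]))
    config = replace(est_config, Q=simconfig.Q, K=simconfig.K_fit)
    fit = stream_fit(
        data.responses,
        config,
        template=data.params,
        checkpoints=cps,
        collect_eap=False,
    )
    rmse_at = {
        rec.n: pooled_item_rmse(rec.beta_avg, data.params) for rec in fit.records
    }
    return {"dataset": data, "fit": fit, "rmse_at": rmse_at}


#: Checkpoints used when reporting real-time trajectories against the
#: discrete-sample-size offline comparison points.
DEFAULT_CHECKPOINTS = (500, 1000, 2000, 2500, 5000, 7500, 10000, 15000, 20000)


def run_replication_study(
    simconfig: SimulationConfig,
    estimators: Mapping[str, EstimatorConfig | str],
    checkpoints: Sequence[int] | None = None,
    em_config: EMConfig | None = None,
) -> pd.DataFrame:
    """Factorial recovery study over replications and estimators.

    ``estimators`` maps a label to an :class:`EstimatorConfig` (streamed)
    or the string ``"em"`` (batch EM fit).  All estimators within a
    replication share the same dataset (paired design; replication ``r``
    uses seed ``base_seed + r``).  A failed replication is logged and
    skipped rather than aborting the study.

    Returns a tidy frame with one row per replication × estimator ×
    checkpoint × parameter class, plus pooled rows (class ``"all"``) and
    ability-recovery rows (online EAP vs EAP under the true item
    parameters).
    """
    cps = sorted(
        {c for c in (checkpoints or DEFAULT_CHECKPOINTS) if c <= simconfig.N}
        | {simconfig.N}
    )
    grid = build_quadrature_grid(simconfig.K_fit, simconfig.Q)
    rows: list[dict] = []
    for r in range(simconfig.replications):
        seed = simconfig.base_seed + r
        try:
            data = generate_dataset(simconfig, seed)
            theta_ref = eap_scores(data.responses, data.params, grid)
            for label, est in estimators.items():
                if isinstance(est, str) and est == "em":
                    free = data.params.free_matrix()
                    beta0 = np.hstack(
                        [np.ones((simconfig.J, simconfig.Q)),
                         np.zeros((simconfig.J, 1))]
                    )
                    beta0[~free] = data.params.beta_matrix()[~free]
                    start = ItemParamSet.from_arrays(beta0, free)
                    res = em_fit(
                        data.responses, start, grid,
                        em_config or EMConfig(K=simconfig.K_fit),
                    )
                    errs, labs = item_param_errors(res.params, data.params)
                    for cls in np.unique(labs):
                        rows.append(
                            _row(label, r, seed, simconfig.N, cls,
                                 errs[labs == cls])
                        )
                    rows.append(_row(label, r, seed, simconfig.N, "all", errs))
                else:
                    config = replace(est, Q=simconfig.Q, K=simconfig.K_fit)
                    fit = stream_fit(
                        data.responses, config,
                        template=data.params, checkpoints=cps,
                    )
                    for rec in fit.records:
                        errs, labs = item_param_errors(rec.beta_avg, data.params)
                        for cls in np.unique(labs):
                            rows.append(
                                _row(label, r, seed, rec.n, cls,
                                     errs[labs == cls])
                            )
                        rows.append(_row(label, r, seed, rec.n, "all", errs))
                    theta_err = (fit.eap - theta_ref).ravel()
                    rows.append(
                        _row(label, r, seed, simconfig.N, "ability", theta_err)
                    )
        except Exception:  # pragma: no cover - isolation path
            logger.exception("replication %d (seed %d) failed; skipping", r, seed)
    return pd.DataFrame(rows)


def _row(label, r, seed, n, cls, errs) -> dict:
    errs = np.asarray(errs, dtype=float)
    return {
        "estimator": label,
        "replication": r,
        "seed": seed,
        "n": n,
        "class": cls,
        "bias": float(errs.mean()),
        "rmse": float(np.sqrt(np.mean(errs**2))),
    }
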