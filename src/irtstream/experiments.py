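"""Canned recovery experiments at the standard desk-scale study conditions.

Each function regenerates its data, runs the streaming (or batch) fit from
scratch, and returns summary numbers; they back both the reproduction
script and the heavier end of the test suite.  The shared conditions are
the unidimensional 2PL design: J = 20 items, discriminations U(0.5, 2),
difficulties N(0, 1), abilities N(0, 1), K = 11 quadrature nodes, and the
averaged-recursion defaults (gamma 0.65, log-weighted averaging with
exponent 2).
"""

from __future__ import annotations

import numpy as np

from .em import EMConfig, em_fit
from .model import ItemParamSet
from .online import EstimatorConfig
from .simulate import (
    SimulationConfig,
    generate_dataset,
    pooled_item_rmse,
    stream_fit,
)

__all__ = [
    "streaming_rmse_experiment",
    "standard_error_experiment",
    "coverage_experiment",
    "em_agreement_experiment",
]


def _sim(N: int) -> SimulationConfig:
    return SimulationConfig(N=N, J=20, Q=1, a_low=0.5, a_high=2.0, K_fit=11)


def streaming_rmse_experiment(
    base_seed: int = 1,
    replications: int = 20,
    N: int = 5000,
    checkpoints: tuple[int, ...] = (2500, 5000),
    config: EstimatorConfig | None = None,
) -> dict[int, float]:
    """Pooled item-parameter RMSE at stream checkpoints, averaged over reps.

    One N-long stream per replication (seed ``base_seed + r``); the state
    at an intermediate checkpoint is by construction the fit a shorter
    stream would have produced.  RMSE pools discrimination and difficulty
    errors within a replication; the returned value is the mean over
    replications.
    """
    config = config or EstimatorConfig.tasna()
    cps = sorted(set(checkpoints) | {N})
    acc: dict[int, list[float]] = {c: [] for c in cps}
    for r in range(replications):
        data = generate_dataset(_sim(N), base_seed + r)
        fit = stream_fit(
            data.responses, config, template=data.params,
            checkpoints=cps, collect_eap=False,
        )
        for rec in fit.records:
            acc[rec.n].append(pooled_item_rmse(rec.beta_avg, data.params))
    return {c: float(np.mean(v)) for c, v in acc.items() if v}


def standard_error_experiment(
    base_seed: int = 1,
    replications: int = 10,
    N: int = 20000,
    checkpoints: tuple[int, ...] = (),
) -> dict:
    """Inverse-Hessian item-parameter SEs after a long stream.

    Returns the across-replication mean of the maximum (and mean) SE over
    the 2 x J item parameters at the final sample size, plus pooled RMSE
    at any requested checkpoints (the same streams serve both purposes).
    """
    cps = sorted(set(checkpoints) | {N})
    max_ses, mean_ses = [], []
    rmse_acc: dict[int, list[float]] = {c: [] for c in cps}
    for r in range(replications):
        data = generate_dataset(_sim(N), base_seed + r)
        fit = stream_fit(
            data.responses, EstimatorConfig.tasna(), template=data.params,
            checkpoints=cps, collect_eap=False,
        )
        ses = fit.estimator.standard_errors()
        max_ses.append(float(np.nanmax(ses)))
        mean_ses.append(float(np.nanmean(ses)))
        for rec in fit.records:
            rmse_acc[rec.n].append(pooled_item_rmse(rec.beta_avg, data.params))
    return {
        "max_se": float(np.mean(max_ses)),
        "mean_se": float(np.mean(mean_ses)),
        "per_rep_max_se": max_ses,
        "rmse_at": {c: float(np.mean(v)) for c, v in rmse_acc.items() if v},
    }


def coverage_experiment(
    base_seed: int = 1,
    replications: int = 200,
    N: int = 10000,
    level: float = 0.95,
) -> dict:
    """Empirical coverage of Wald intervals built from the recursion's SEs.

    For each replication, the interval ``beta_avg ± z * SE`` (slope and
    intercept per item, SEs from the inverse accumulated Hessian) either
    covers or misses the data-generating value.  Returns the overall
    coverage proportion and per-replication coverages.
    """
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    per_rep = []
    for r in range(replications):
        data = generate_dataset(_sim(N), base_seed + r)
        fit = stream_fit(
            data.responses, EstimatorConfig.tasna(), template=data.params,
            collect_eap=False,
        )
        est = fit.estimator.beta_avg
        ses = fit.estimator.standard_errors()
        truth = data.params.beta_matrix()
        hit = np.abs(est - truth) <= z * ses
        per_rep.append(float(hit.mean()))
    per_rep = np.array(per_rep)
    return {
        "coverage": float(per_rep.mean()),
        "per_rep": per_rep,
        "se_of_coverage": float(per_rep.std(ddof=1) / np.sqrt(len(per_rep))),
    }


def em_agreement_experiment(seed: int = 1, N: int = 20000) -> dict:
    """Batch EM vs streamed averaged-Newton estimates on one dataset.

    Returns the mean absolute per-parameter difference (slope-intercept
    scale) and both parameter matrices.
    """
    data = generate_dataset(_sim(N), seed)
    fit = stream_fit(
        data.responses, EstimatorConfig.tasna(), template=data.params,
        collect_eap=False,
    )
    start = ItemParamSet.from_arrays(
        np.hstack([np.ones((20, 1)), np.zeros((20, 1))])
    )
    res = em_fit(data.responses, start, config=EMConfig(K=11))
    online = fit.estimator.beta_avg
    batch = res.params.beta_matrix()
    return {
        "mean_abs_diff": float(np.abs(online - batch).mean()),
        "online": online,
        "em": batch,
        "truth": data.params.beta_matrix(),
    }
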