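"""File formats: CSV response matrices, JSONL streams, trajectories, configs.

Arrival order is file order throughout — the online recursion is
order-sensitive by design, so readers never shuffle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import ItemParamSet, ResponseVector
from .online import TrajectoryRecord

__all__ = [
    "RunConfig",
    "read_response_matrix",
    "write_response_matrix",
    "stream_responses",
    "write_response_stream",
    "write_trajectory",
    "read_trajectory",
    "write_parameter_table",
    "read_parameter_table",
]

#: floats are serialized with 17 significant digits so JSON round-trips
#: reproduce binary64 values exactly
_FLOAT_FMT = "%.17g"


def _format_float(x: float) -> float:
    return float(_FLOAT_FMT % x)


def read_response_matrix(
    path: str | Path, strict: bool = True
) -> tuple[list[ResponseVector], list[str]]:
    """Read a CSV response matrix into ordered per-examinee records.

    Expects a header row of item ids and one row per examinee with cells
    in {0, 1}; an optional first column named ``id`` labels examinees.  In
    strict mode any other cell value (including blanks) is rejected with
    its row and column named; in masked mode blank cells become absent
    entries carried in the record's mask.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"{path}: empty response file")
    cols = list(df.columns)
    has_id = cols[0].lower() in ("id", "examinee_id", "examinee")
    item_ids = cols[1:] if has_id else cols
    records: list[ResponseVector] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        cells = list(row)
        ex_id = str(cells[0]) if has_id else str(i)
        vals = cells[1:] if has_id else cells
        y = np.zeros(len(vals), dtype=float)
        mask = np.ones(len(vals), dtype=bool)
        for j, cell in enumerate(vals):
            cell = cell.strip()
            if cell in ("0", "1"):
                y[j] = int(cell)
            elif cell == "" and not strict:
                mask[j] = False
            else:
                raise ValueError(
                    f"{path}: non-binary cell {cell!r} at row {i}, "
                    f"column {item_ids[j]!r}"
                )
        records.append(
            ResponseVector(y, examinee_id=ex_id, mask=None if mask.all() else mask)
        )
    return records, item_ids


def write_response_matrix(
    responses: np.ndarray, path: str | Path, item_ids: Sequence[str] | None = None
) -> None:
    """Write an (N, J) binary matrix as a headered CSV."""
    responses = np.asarray(responses)
    J = responses.shape[1]
    ids = list(item_ids) if item_ids is not None else [f"item{j+1}" for j in range(J)]
    pd.DataFrame(responses.astype(int), columns=ids).to_csv(path, index=False)


def stream_responses(path: str | Path, J: int | None = None) -> Iterator[ResponseVector]:
    """Lazily iterate a JSONL stream of ``{"id": ..., "y": [0, 1, ...]}``.

    Constant memory in the number of records; malformed lines raise with
    their line number, and a ``J`` mismatch is a validation error.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                y = obj["y"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})")
            if J is not None and len(y) != J:
                raise ValueError(
                    f"{path}:{lineno}: record has {len(y)} responses, expected {J}"
                )
            yield ResponseVector(
                np.asarray(y), examinee_id=str(obj.get("id", lineno))
            )


def write_response_stream(
    responses: np.ndarray, path: str | Path, ids: Sequence[str] | None = None
) -> None:
    """Write an (N, J) binary matrix as a JSONL stream."""
    responses = np.asarray(responses)
    with open(path, "w") as fh:
        for n in range(responses.shape[0]):
            rec = {
                "id": str(ids[n]) if ids is not None else str(n + 1),
                "y": [int(v) for v in responses[n]],
            }
            fh.write(json.dumps(rec) + "\n")


def write_trajectory(records: Iterable[TrajectoryRecord], path: str | Path) -> None:
    """Write trajectory records as JSONL, one checkpoint per line."""
    with open(path, "w") as fh:
        for rec in records:
            d = rec.to_dict()
            d["beta_avg"] = [[_format_float(v) for v in row] for row in d["beta_avg"]]
            d["eap"] = [_format_float(v) for v in d["eap"]]
            d["step"] = _format_float(d["step"])
            fh.write(json.dumps(d) + "\n")


def read_trajectory(path: str | Path) -> list[TrajectoryRecord]:
    """Read back a trajectory JSONL into records (full float precision)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            out.append(
                TrajectoryRecord(
                    n=int(d["n"]),
                    examinee_id=str(d["examinee_id"]),
                    beta_avg=np.asarray(d["beta_avg"], dtype=float),
                    eap=np.asarray(d["eap"], dtype=float),
                    step=float(d["step"]),
                )
            )
    return out


def write_parameter_table(
    params: ItemParamSet,
    path: str | Path,
    ses: np.ndarray | None = None,
) -> None:
    """Final estimates as tidy CSV: item_id, parameter, estimate, SE, anchored.

    Unidimensional items are reported as discrimination ``a`` and
    difficulty ``b = -d/a`` (the difficulty SE is left blank — the
    recursion estimates the slope–intercept form); multidimensional items
    as ``a1..aQ`` and intercept ``d``.
    """
    rows = []
    Q = params.Q
    beta = params.beta_matrix()
    free = params.free_matrix()
    for j, item_id in enumerate(params.item_ids):
        if Q == 1:
            a, d = beta[j]
            ests = {"a": a, "b": -d / a}
            se_map = {
                "a": ses[j, 0] if ses is not None else np.nan,
                "b": np.nan,
            }
            anch = {"a": not free[j, 0], "b": not free[j, 1]}
        else:
            ests = {f"a{q+1}": beta[j, q] for q in range(Q)}
            ests["d"] = beta[j, -1]
            se_map = {
                name: (ses[j, k] if ses is not None else np.nan)
                for k, name in enumerate(list(ests))
            }
            anch = {
                name: not free[j, k] for k, name in enumerate(list(ests))
            }
        for name, val in ests.items():
            rows.append(
                {
                    "item_id": item_id,
                    "parameter": name,
                    "estimate": _format_float(float(val)),
                    "standard_error": (
                        "" if not np.isfinite(se_map[name])
                        else _format_float(float(se_map[name]))
                    ),
                    "anchored": bool(anch[name]),
                }
            )
    pd.DataFrame(rows, columns=[
        "item_id", "parameter", "estimate", "standard_error", "anchored"
    ]).to_csv(path, index=False)


def read_parameter_table(path: str | Path) -> ItemParamSet:
    """Reconstruct an :class:`ItemParamSet` from a parameter-table CSV."""
    df = pd.read_csv(path)
    item_ids = list(dict.fromkeys(df["item_id"].astype(str)))
    by_item = {iid: g.set_index("parameter") for iid, g in df.groupby("item_id", sort=False)}
    first = by_item[item_ids[0]]
    if "b" in first.index:  # unidimensional a/b table
        betas, frees = [], []
        for iid in item_ids:
            g = by_item[iid]
            a = float(g.loc["a", "estimate"])
            b = float(g.loc["b", "estimate"])
            betas.append([a, -a * b])
            frees.append([not bool(g.loc["a", "anchored"]),
                          not bool(g.loc["b", "anchored"])])
        return ItemParamSet.from_arrays(
            np.array(betas), np.array(frees, dtype=bool), item_ids
        )
    a_names = sorted(
        (n for n in first.index if n.startswith("a")), key=lambda s: int(s[1:])
    )
    betas, frees = [], []
    for iid in item_ids:
        g = by_item[iid]
        row = [float(g.loc[n, "estimate"]) for n in a_names]
        row.append(float(g.loc["d", "estimate"]))
        betas.append(row)
        frees.append(
            [not bool(g.loc[n, "anchored"]) for n in a_names]
            + [not bool(g.loc["d", "anchored"])]
        )
    return ItemParamSet.from_arrays(
        np.array(betas), np.array(frees, dtype=bool), item_ids
    )


@dataclass
class RunConfig:
    """Validated run configuration loaded from YAML or JSON.

    Unknown keys are rejected by name so typos never silently fall back
    to defaults.
    """

    model: str = "2pl"  # "2pl" | "m2pl"
    estimator: str = "tasna"  # "tsna" | "tasna" | "em"
    Q: int = 1
    K: int = 11
    gamma: float | None = None
    c_nu: float = 1.0
    n0: float = 20.0
    c_lambda: float = 0.2
    alpha_lambda: float = 0.49
    avg_w: float = 2.0
    gradient_at: str = "current"
    hessian_init: str = "expected"
    seed: int = 1
    input: str | None = None
    output_dir: str = "."
    checkpoints: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.model not in ("2pl", "m2pl"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.estimator not in ("tsna", "tasna", "em"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.model == "2pl" and self.Q != 1:
            raise ValueError("2pl model requires Q=1")
        if self.model == "m2pl" and self.Q < 2:
            raise ValueError("m2pl model requires Q>=2")
        self.checkpoints = tuple(int(c) for c in self.checkpoints)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                raw = yaml.safe_load(fh)
            else:
                raw = json.load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"{path}: unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**raw)

    def estimator_config(self):
        from .online import EstimatorConfig

        base = (
            EstimatorConfig.tsna if self.estimator == "tsna"
            else EstimatorConfig.tasna
        )
        kw = dict(
            c_nu=self.c_nu, n0=self.n0, c_lambda=self.c_lambda,
            alpha_lambda=self.alpha_lambda, avg_w=self.avg_w,
            K=self.K, Q=self.Q, seed=self.seed,
            gradient_at=self.gradient_at, hessian_init=self.hessian_init,
        )
        if self.gamma is not None:
            kw["gamma"] = self.gamma
        return base(**kw)
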