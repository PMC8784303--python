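"""Brain-behavior association: item specificity vs memory performance.

Item specificity (the per-subject within-item minus within-category
similarity inside the significant-cluster mask) is correlated with a
scalar item-memory score, separately per group and pooled across groups.
The memory score is task-defined and treated as an opaque scalar.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_stats import SpecificitySummary

__all__ = [
    "BehaviorTable",
    "read_behavior_csv",
    "correlate_specificity_memory",
]


@dataclass(frozen=True)
class BehaviorTable:
    """One memory score per subject."""

    table: pd.DataFrame  # columns: subject_id, group, item_memory

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "item_memory"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"behavior table is missing columns {sorted(missing)}")
        if self.table["subject_id"].duplicated().any():
            dup = self.table.loc[self.table["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject ids {sorted(dup.unique())}")
        if not np.all(np.isfinite(self.table["item_memory"].to_numpy(dtype=float))):
            raise ValueError("item_memory scores must be finite")

    def scores_for(self, subject_ids: tuple[str, ...]) -> np.ndarray:
        lookup = dict(
            zip(self.table["subject_id"].astype(str), self.table["item_memory"])
        )
        missing = [s for s in subject_ids if str(s) not in lookup]
        if missing:
            raise ValueError(f"behavior table lacks subjects {missing}")
        return np.array([lookup[str(s)] for s in subject_ids], dtype=float)


def read_behavior_csv(path: str | Path) -> BehaviorTable:
    return BehaviorTable(pd.read_csv(path))


def _pearson(x: np.ndarray, y: np.ndarray) -> dict:
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x))}


def correlate_specificity_memory(
    summaries: list[SpecificitySummary],
    behavior: BehaviorTable,
    min_n: int = 3,
) -> dict[str, dict]:
    """Pearson correlation of item specificity with memory, per group and pooled.

    The two-sided p comes from t = r * sqrt((n-2)/(1-r^2)) with n-2 df.
    Groups with fewer than ``min_n`` matched subjects are reported as
    skipped. The pooled analysis concatenates the raw per-group values
    without any group-mean centering; with group differences in either
    variable the pooled r can therefore reflect between-group variance
    (a ``centered`` variant is available via
    :func:`correlate_specificity_memory_centered`).
    """
    out: dict[str, dict] = {}
    all_spec: list[np.ndarray] = []
    all_mem: list[np.ndarray] = []
    for summ in summaries:
        spec = np.asarray(summ.specificity, dtype=float)
        mem = behavior.scores_for(summ.subject_ids)
        all_spec.append(spec)
        all_mem.append(mem)
        if len(spec) < min_n:
            out[summ.group] = {"skipped": f"n={len(spec)} < {min_n}"}
        else:
            out[summ.group] = _pearson(spec, mem)
    spec = np.concatenate(all_spec)
    mem = np.concatenate(all_mem)
    if len(spec) >= min_n:
        out["pooled"] = _pearson(spec, mem)
    else:
        out["pooled"] = {"skipped": f"n={len(spec)} < {min_n}"}
    return out


def correlate_specificity_memory_centered(
    summaries: list[SpecificitySummary], behavior: BehaviorTable, min_n: int = 3
) -> dict[str, dict]:
    """Pooled correlation after subtracting each group's mean from both
    variables, removing between-group level differences from the pooled r.

    Group-wise results are identical to the uncentered variant (Pearson r
    is invariant to per-group centering within a group).
    """
    import warnings

    warnings.warn(
        "centered pooling removes group-level differences; group and "
        "individual effects are no longer confounded but pooled r is not "
        "comparable to the raw pooled analysis",
        stacklevel=2,
    )
    out = correlate_specificity_memory(summaries, behavior, min_n=min_n)
    spec_parts, mem_parts = [], []
    for summ in summaries:
        spec = np.asarray(summ.specificity, dtype=float)
        mem = behavior.scores_for(summ.subject_ids)
        spec_parts.append(spec - spec.mean())
        mem_parts.append(mem - mem.mean())
    spec = np.concatenate(spec_parts)
    mem = np.concatenate(mem_parts)
    if len(spec) >= min_n:
        out["pooled"] = _pearson(spec, mem)
    return out
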