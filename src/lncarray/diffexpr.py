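"""Per-probe differential expression screening.

Unpaired pooled-variance t-test on log2 intensities, fold change as the
absolute ratio of linear-scale group means (always >= 1, direction carried
by an Up/Down label), BH-FDR over raw P-values, and the strict
FC > 2 & P < 0.05 gate with ranked output tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_fdr as _bh_fdr
from ._stats import pooled_t_rows
from .iofmt import ExpressionMatrix, ProbeAnnotation, SchemaError

__all__ = [
    "DiffExprRecord",
    "normalize_quantile",
    "t_test_unpaired",
    "fold_change",
    "bh_fdr",
    "screen",
    "top_table",
    "records_frame",
]

RESULT_COLUMNS = ["seqname", "probe_name", "p_value", "fdr", "fc", "regulation", "chrom", "strand"]


@dataclass
class DiffExprRecord:
    """One screened probe in the ranked-table schema."""

    seqname: str
    probe_name: str
    p_value: float
    fdr: float
    fc: float
    regulation: str
    chrom: str
    strand: str

    def __post_init__(self) -> None:
        if self.fc < 1:
            raise ValueError("fc must be >= 1 (direction lives in regulation)")
        if not (0 <= self.p_value <= 1 and 0 <= self.fdr <= 1):
            raise ValueError("p_value and fdr must lie in [0, 1]")
        if self.regulation not in ("Up", "Down"):
            raise ValueError("regulation must be Up or Down")


def normalize_quantile(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization: each sample's sorted intensity vector is
    replaced by the across-sample mean sorted vector; ties within a sample
    receive the mean of the tied target values."""
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        v = values[:, j]
        order = np.argsort(v, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = ref
        _, inverse = np.unique(v, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return matrix.with_values(out)


def t_test_unpaired(matrix: ExpressionMatrix, probe: str) -> tuple[float, int, float]:
    """Pooled two-sample t on the probe's log2 intensities; returns
    (t, df, two-sided P)."""
    i = matrix.probe_index(probe)
    log2 = matrix.log2()
    case = log2[i][matrix.sample_indices("case")][None, :]
    ctrl = log2[i][matrix.sample_indices("control")][None, :]
    t, df, p = pooled_t_rows(case, ctrl)
    return float(t[0]), df, float(p[0])


def fold_change(matrix: ExpressionMatrix, probe: str) -> tuple[float, str]:
    """Absolute ratio of linear-scale group means with an Up/Down label.

    Equal means tie-break to Up by convention.
    """
    i = matrix.probe_index(probe)
    case_mean = matrix.group_values("case")[i].mean()
    ctrl_mean = matrix.group_values("control")[i].mean()
    r = case_mean / ctrl_mean
    if r >= 1.0:
        return float(r), "Up"
    return float(1.0 / r), "Down"


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (shared kernel)."""
    return _bh_fdr(p_values)


def _all_stats(matrix: ExpressionMatrix) -> pd.DataFrame:
    log2 = matrix.log2()
    case_idx = matrix.sample_indices("case")
    ctrl_idx = matrix.sample_indices("control")
    t, df, p = pooled_t_rows(log2[:, case_idx], log2[:, ctrl_idx])
    case_mean = matrix.values[:, case_idx].mean(axis=1)
    ctrl_mean = matrix.values[:, ctrl_idx].mean(axis=1)
    ratio = case_mean / ctrl_mean
    fc = np.where(ratio >= 1.0, ratio, 1.0 / ratio)
    regulation = np.where(ratio >= 1.0, "Up", "Down")
    return pd.DataFrame(
        {
            "probe_name": matrix.probe_ids,
            "t": t,
            "p_value": p,
            "fdr": _bh_fdr(p),
            "fc": fc,
            "regulation": regulation,
        }
    )


def screen(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    fc_cut: float = 2.0,
    p_cut: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the strict FC > fc_cut AND P < p_cut gate; returns
    (upregulated, downregulated) record tables carrying annotation fields."""
    missing = [p for p in matrix.probe_ids if p not in annotation.probes()]
    if missing:
        raise SchemaError(f"unannotated probes: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    stats = _all_stats(matrix)
    ann = annotation.table.set_index("probe_name")
    stats["seqname"] = [ann.at[p, "seqname"] for p in stats["probe_name"]]
    stats["chrom"] = [ann.at[p, "chrom"] for p in stats["probe_name"]]
    stats["strand"] = [ann.at[p, "strand"] for p in stats["probe_name"]]
    stats["biotype"] = [ann.at[p, "biotype"] for p in stats["probe_name"]]
    gated = stats[(stats["fc"] > fc_cut) & (stats["p_value"] < p_cut)]
    cols = RESULT_COLUMNS + ["biotype"]
    up = gated[gated["regulation"] == "Up"][cols].reset_index(drop=True)
    down = gated[gated["regulation"] == "Down"][cols].reset_index(drop=True)
    return up, down


def top_table(records: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Rank screened records by fc descending, ties by ascending p_value
    then seqname, and return the first k."""
    if k <= 0:
        raise ValueError("k must be positive")
    ranked = records.sort_values(
        ["fc", "p_value", "seqname"], ascending=[False, True, True], kind="mergesort"
    )
    return ranked.head(k).reset_index(drop=True)


def records_frame(records: list[DiffExprRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=RESULT_COLUMNS)
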