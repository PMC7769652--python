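"""Cohort summary-statistics tests.

Two-sample pooled-variance t-tests computed either from printed
mean/SD/n summaries or from raw vectors (both share one kernel, so the two
routes agree to machine precision), Fisher's exact test for 2x2 categorical
rows, and a chi-square test for wider contingency tables.

Pooled variance (rather than Welch) is deliberate: it is the computation
that reproduces the published blood-pressure P-values from the printed
summaries, which Welch does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pooled_t_from_summary, pooled_t_from_vectors

__all__ = [
    "GroupSummary",
    "t_test_from_summary",
    "t_test_from_vectors",
    "fisher_2x2",
    "chi_square_contingency",
    "summary_table_tests",
]


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be >= 2 for variance-based tests")


def t_test_from_summary(a: GroupSummary, b: GroupSummary) -> tuple[float, int, float]:
    """Pooled two-sample t-test (t, df, two-sided P) from group summaries."""
    return pooled_t_from_summary(a.mean, a.sd, a.n, b.mean, b.sd, b.n)


def t_test_from_vectors(a, b) -> tuple[float, int, float]:
    """Same test from raw observation vectors (shared kernel)."""
    return pooled_t_from_vectors(a, b)


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact P for a 2x2 count table (sum of probabilities
    of tables at most as likely as the observed one, at fixed margins)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise ValueError("counts must be nonnegative integers")
        arr = arr.astype(int)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def chi_square_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) for an r x c table;
    used for the multi-level comorbidity rows."""
    arr = np.asarray(table, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    # drop empty categories (all-zero rows/columns) before testing; the
    # comorbidity rows legitimately contain unobserved levels
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 nonempty rows and columns")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def summary_table_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Add t, df and P columns to a cohort summary table.

    Expected columns: variable, mean_a, sd_a, n_a, mean_b, sd_b, n_b.
    """
    required = ["variable", "mean_a", "sd_a", "n_a", "mean_b", "sd_b", "n_b"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    rows = []
    for row in table.itertuples(index=False):
        t, df, p = pooled_t_from_summary(
            row.mean_a, row.sd_a, int(row.n_a), row.mean_b, row.sd_b, int(row.n_b)
        )
        rows.append({"t": t, "df": df, "p_value": p})
    out = table.copy()
    out[["t", "df", "p_value"]] = pd.DataFrame(rows)
    return out
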