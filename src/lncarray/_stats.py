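"""Shared statistical kernels used across modules.

The pooled-variance two-sample t-test and the Benjamini-Hochberg step-up
adjustment are implemented once here and reused by :mod:`lncarray.diffexpr`,
:mod:`lncarray.cnc_network`, :mod:`lncarray.qpcr` and
:mod:`lncarray.clinical_stats`, so that summary-statistic and raw-vector
routes are guaranteed to agree.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pooled_t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from group summary statistics.

    Returns ``(t, df, p_value)`` with ``df = n_a + n_b - 2`` and a two-sided
    P from the t distribution. Degenerate zero-variance cases follow a fixed
    convention: equal means give ``P = 1``; unequal means give ``P = 0``
    (infinite evidence, flagged by ``t = inf``).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError(f"both groups need n >= 2 (got {n_a}, {n_b})")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    diff = mean_a - mean_b
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, min(p, 1.0)


def pooled_t_from_vectors(a, b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test on raw observation vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 observations")
    return pooled_t_from_summary(
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
    )


def pooled_t_rows(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Vectorised pooled t-test over matrix rows (probes).

    ``case``/``ctrl`` are (probes x samples) arrays. Zero pooled variance
    rows follow the same convention as the scalar kernel.
    """
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 samples")
    df = n1 + n2 - 2
    m1 = case.mean(axis=1)
    m2 = ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero_var = sp2 == 0.0
    t = np.where(zero_var, np.where(diff == 0.0, 0.0, np.copysign(np.inf, diff)), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_var & (diff == 0.0), 1.0, p)
    return t, df, np.minimum(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, original order restored.

    adjusted_(k) = min_{j >= k} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("all P-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out
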