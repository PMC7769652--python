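"""Coding-noncoding coexpression (CNC) network.

All lncRNA x mRNA Pearson correlations across samples (on log2
intensities), correlation P from the t transform, BH-FDR over the tested
grid, and a threshold gate |r| >= r_cut (non-strict), P <= p_cut,
FDR <= fdr_cut. Edges carry a positive/negative sign for Cytoscape export.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .iofmt import ExpressionMatrix

__all__ = ["CoexpressionEdge", "pearson_with_p", "build_cnc", "degree_table", "edges_frame"]

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionEdge:
    lnc_id: str
    mrna_id: str
    r: float
    p_value: float
    fdr: float
    sign: str

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [-1, 1]")
        if (self.sign == "positive") != (self.r > 0):
            raise ValueError("sign must match the sign of r")


def _p_from_r(r: np.ndarray, m: int) -> np.ndarray:
    """Two-sided P for Pearson r via t = r sqrt(m-2)/sqrt(1-r^2), m-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(m - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), m - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, np.minimum(p, 1.0))


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided P.

    Raises on zero variance (the caller decides whether to skip the pair).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    m = x.size
    if m < 3:
        raise ValueError("need >= 3 samples for a correlation P")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0.0:
        raise ZeroDivisionError("zero variance vector: correlation undefined")
    r = float(xc @ yc) / denom
    r = max(-1.0, min(1.0, r))
    p = float(_p_from_r(np.asarray([r]), m)[0])
    return r, p


def build_cnc(
    matrix: ExpressionMatrix,
    lnc_ids: list[str],
    mrna_ids: list[str],
    r_cut: float = 0.97,
    p_cut: float = 0.05,
    fdr_cut: float = 1.0,
) -> list[CoexpressionEdge]:
    """Build the thresholded coexpression network over the lnc x mRNA grid.

    |r| >= r_cut is non-strict; P <= p_cut and FDR <= fdr_cut likewise.
    Zero-variance profiles are skipped with a logged warning. The FDR is
    the BH transform of the P-values over every tested pair.
    """
    if set(lnc_ids) & set(mrna_ids):
        raise ValueError("lnc and mRNA id sets must be disjoint")
    log2 = matrix.log2()
    index = {p: i for i, p in enumerate(matrix.probe_ids)}
    for pid in [*lnc_ids, *mrna_ids]:
        if pid not in index:
            raise KeyError(f"probe {pid!r} not in matrix")
    m = len(matrix.sample_ids)
    if m < 3:
        raise ValueError("need >= 3 samples")

    lnc_mat = log2[[index[p] for p in lnc_ids], :]
    mrna_mat = log2[[index[p] for p in mrna_ids], :]
    lc = lnc_mat - lnc_mat.mean(axis=1, keepdims=True)
    mc = mrna_mat - mrna_mat.mean(axis=1, keepdims=True)
    ln = np.sqrt((lc * lc).sum(axis=1))
    mn = np.sqrt((mc * mc).sum(axis=1))
    zero_l = ln == 0
    zero_m = mn == 0
    for pid in np.asarray(lnc_ids)[zero_l]:
        logger.warning("lncRNA %s has zero variance; its pairs are skipped", pid)
    for pid in np.asarray(mrna_ids)[zero_m]:
        logger.warning("mRNA %s has zero variance; its pairs are skipped", pid)
    ln_safe = np.where(zero_l, 1.0, ln)
    mn_safe = np.where(zero_m, 1.0, mn)
    r_grid = (lc / ln_safe[:, None]) @ (mc / mn_safe[:, None]).T
    r_grid = np.clip(r_grid, -1.0, 1.0)
    valid = ~zero_l[:, None] & ~zero_m[None, :]

    p_grid = _p_from_r(r_grid, m)
    p_flat = p_grid[valid]
    fdr_flat = bh_fdr(p_flat)
    fdr_grid = np.full(r_grid.shape, np.nan)
    fdr_grid[valid] = fdr_flat

    keep = valid & (np.abs(r_grid) >= r_cut) & (p_grid <= p_cut) & (fdr_grid <= fdr_cut)
    edges = []
    for i, j in zip(*np.nonzero(keep)):
        r = float(r_grid[i, j])
        edges.append(
            CoexpressionEdge(
                lnc_id=lnc_ids[i],
                mrna_id=mrna_ids[j],
                r=r,
                p_value=float(p_grid[i, j]),
                fdr=float(fdr_grid[i, j]),
                sign="positive" if r > 0 else "negative",
            )
        )
    return edges


def degree_table(edges: list[CoexpressionEdge]) -> pd.DataFrame:
    """Per-node incident-edge counts, sorted descending."""
    degrees: dict[str, int] = {}
    for e in edges:
        degrees[e.lnc_id] = degrees.get(e.lnc_id, 0) + 1
        degrees[e.mrna_id] = degrees.get(e.mrna_id, 0) + 1
    table = pd.DataFrame(
        sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["node", "degree"],
    )
    return table


def edges_frame(edges: list[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [e.__dict__ for e in edges],
        columns=["lnc_id", "mrna_id", "r", "p_value", "fdr", "sign"],
    )
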