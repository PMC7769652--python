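"""Gene-set over-representation analysis.

One-sided Fisher's exact test (over-representation tail) and Pearson
chi-square (1 df, no continuity correction) on the 2x2 table
(c, n-c, K-c, N-K-n+c), BH-FDR within each gene-set category, and an
enrichment score defined as -log10(P).

Sets disjoint from the universe are skipped with a logged warning rather
than tested against an empty margin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from ._stats import bh_fdr
from .iofmt import GeneSetCollection

__all__ = ["EnrichmentResult", "fisher_enrichment", "chi_square_enrichment", "top_terms"]

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps -log10 finite for numerically-zero P


@dataclass
class EnrichmentResult:
    set_id: str
    category: str
    description: str
    p_value: float
    fdr: float
    enrichment_score: float
    c: int  # DE genes in the set
    n: int  # DE genes in the universe
    K: int  # set members in the universe
    N: int  # universe size
    significant: bool
    unreliable: bool = False  # chi-square with an expected count < 5

    def __post_init__(self) -> None:
        if self.c > min(self.n, self.K):
            raise ValueError("c cannot exceed min(n, K)")
        if self.N < self.n or self.N < self.K:
            raise ValueError("N must dominate n and K")


def _counts(de: set, universe: set, members: list[str]) -> tuple[int, int, int, int]:
    member_set = set(members) & universe
    c = len(de & member_set)
    return c, len(de), len(member_set), len(universe)


def _validate(de_genes, universe) -> tuple[set, set]:
    de = set(de_genes)
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    if not de <= uni:
        extra = sorted(de - uni)[:5]
        raise ValueError(f"DE genes not contained in universe, e.g. {extra}")
    return de, uni


def _finalize(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """BH-FDR within each category, then sort by enrichment score."""
    by_cat: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_cat.setdefault(r.category, []).append(r)
    for group in by_cat.values():
        fdrs = bh_fdr([r.p_value for r in group])
        for r, f in zip(group, fdrs):
            r.fdr = float(f)
    results.sort(key=lambda r: (-r.enrichment_score, r.set_id))
    return results


def fisher_enrichment(
    de_genes,
    universe,
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided (over-representation) Fisher's exact test per gene set.

    P = Pr(X >= c) under the hypergeometric null with the set intersected
    with the universe first. Returns results sorted by enrichment score.
    """
    de, uni = _validate(de_genes, universe)
    results: list[EnrichmentResult] = []
    for s in sets:
        c, n, K, N = _counts(de, uni, s.members)
        if K == 0:
            logger.warning("gene set %s is disjoint from the universe; skipped", s.set_id)
            continue
        p = float(stats.hypergeom.sf(c - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        results.append(
            EnrichmentResult(
                set_id=s.set_id,
                category=s.category,
                description=s.description,
                p_value=p,
                fdr=p,
                enrichment_score=-math.log10(max(p, P_FLOOR)),
                c=c,
                n=n,
                K=K,
                N=N,
                significant=p < alpha,
            )
        )
    return _finalize(results)


def chi_square_enrichment(
    de_genes,
    universe,
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Pearson chi-square (1 df, no continuity correction) on the same 2x2
    table; results with any expected count < 5 carry ``unreliable=True``."""
    de, uni = _validate(de_genes, universe)
    if not de:
        raise ValueError("empty DE gene list gives degenerate margins")
    results: list[EnrichmentResult] = []
    for s in sets:
        c, n, K, N = _counts(de, uni, s.members)
        if K == 0:
            logger.warning("gene set %s is disjoint from the universe; skipped", s.set_id)
            continue
        if K == N or n == N:
            raise ValueError(f"degenerate margins for set {s.set_id}")
        observed = [[c, n - c], [K - c, N - K - n + c]]
        row = [n, N - n]
        col = [K, N - K]
        expected = [[row[i] * col[j] / N for j in range(2)] for i in range(2)]
        stat = sum(
            (observed[i][j] - expected[i][j]) ** 2 / expected[i][j]
            for i in range(2)
            for j in range(2)
        )
        p = float(stats.chi2.sf(stat, df=1))
        results.append(
            EnrichmentResult(
                set_id=s.set_id,
                category=s.category,
                description=s.description,
                p_value=p,
                fdr=p,
                enrichment_score=-math.log10(max(p, P_FLOOR)),
                c=c,
                n=n,
                K=K,
                N=N,
                significant=p < alpha,
                unreliable=any(e < 5 for r in expected for e in r),
            )
        )
    return _finalize(results)


def top_terms(results: list[EnrichmentResult], k: int = 10) -> dict[str, list[EnrichmentResult]]:
    """Top k terms per category by enrichment score, ties by set_id."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    by_cat: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_cat.setdefault(r.category, []).append(r)
    return {
        cat: sorted(group, key=lambda r: (-r.enrichment_score, r.set_id))[:k]
        for cat, group in by_cat.items()
    }
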