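"""Competing-endogenous-RNA (ceRNA) network via the shared-miRNA
hypergeometric test.

For a candidate pair (gene_a, gene_b): N = distinct miRNAs in the target
table, K = miRNAs targeting gene_a, n = miRNAs targeting gene_b, c = shared
miRNAs. The pair score is the upper hypergeometric tail

    P = sum_{i=c}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

computed with exact integer binomials for moderate N and a log-space
(lgamma) summation beyond, so array-scale N cannot overflow.

Retention requires c >= min_shared AND P < p_cut; candidates are the
differentially expressed lncRNA x mRNA pairs present in the target table.
An optional MRE weighting counts each shared miRNA by its smaller
MRE count on the two transcripts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .iofmt import MiRNATargetTable

__all__ = ["CeRNAPair", "shared_mirnas", "cerna_p", "build_cerna", "pairs_frame"]

logger = logging.getLogger(__name__)

_EXACT_N_MAX = 1000  # exact integer route below this; log-space above


@dataclass
class CeRNAPair:
    gene_a: str
    gene_b: str
    N: int
    K: int
    n: int
    c: int
    p_value: float
    shared: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.c <= min(self.K, self.n) <= self.N):
            raise ValueError("need 0 <= c <= min(K, n) <= N")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


def shared_mirnas(
    targets: MiRNATargetTable, gene_a: str, gene_b: str
) -> tuple[int, int, int, set[str]]:
    """(K, n, c, shared miRNA ids) for a candidate pair."""
    mir_a = targets.mirnas_for(gene_a)
    mir_b = targets.mirnas_for(gene_b)
    if not mir_a:
        raise KeyError(f"gene {gene_a!r} absent from target table")
    if not mir_b:
        raise KeyError(f"gene {gene_b!r} absent from target table")
    shared = mir_a & mir_b
    return len(mir_a), len(mir_b), len(shared), shared


def cerna_p(N: int, K: int, n: int, c: int) -> float:
    """Upper-tail shared-miRNA probability Pr(X >= c) for X hypergeometric.

    Exact integer arithmetic for N <= 1000; log-space summation beyond.
    c = 0 returns exactly 1.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("c", c)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    N, K, n, c = int(N), int(K), int(n), int(c)
    if K > N:
        raise ValueError(f"K <= N violated ({K} > {N})")
    if n > N:
        raise ValueError(f"n <= N violated ({n} > {N})")
    if c > min(K, n):
        raise ValueError(f"c <= min(K, n) violated ({c} > {min(K, n)})")
    if c == 0:
        return 1.0
    upper = min(K, n)
    if N <= _EXACT_N_MAX:
        total = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(c, upper + 1))
        return total / math.comb(N, n)
    log_denom = _log_comb(N, n)
    acc = 0.0
    for i in range(c, upper + 1):
        if n - i > N - K:
            continue
        acc += math.exp(_log_comb(K, i) + _log_comb(N - K, n - i) - log_denom)
    return min(acc, 1.0)


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def build_cerna(
    targets: MiRNATargetTable,
    de_lnc: list[str],
    de_mrna: list[str],
    min_shared: int = 3,
    p_cut: float = 0.05,
    weight_mre: bool = False,
) -> tuple[list[CeRNAPair], pd.DataFrame]:
    """Score every DE lncRNA x DE mRNA pair found in the target table and
    retain pairs with c >= min_shared and P < p_cut.

    Returns (retained pairs, tripartite edge table) where the edge table has
    directed miRNA->target rows (edge_type "targets") for the shared miRNAs
    of retained pairs plus one undirected "cerna" row per retained pair.

    With ``weight_mre`` the shared-count gate uses, per shared miRNA, the
    smaller of its MRE counts on the two transcripts (unequal MREs weaken a
    sponge pair); the hypergeometric test always uses plain counts.
    """
    known = targets.genes
    N = len(targets.mirnas)
    pairs: list[CeRNAPair] = []
    for lnc in de_lnc:
        if lnc not in known:
            logger.info("DE lncRNA %s has no miRNA targets; skipped", lnc)
            continue
        for mrna in de_mrna:
            if mrna == lnc:
                continue
            if mrna not in known:
                continue
            K, n, c, shared = shared_mirnas(targets, lnc, mrna)
            if weight_mre and shared:
                wa = targets.mre_weights_for(lnc)
                wb = targets.mre_weights_for(mrna)
                shared_weight = sum(min(wa[m], wb[m]) for m in shared)
            else:
                shared_weight = c
            p = cerna_p(N, K, n, c)
            if shared_weight >= min_shared and p < p_cut:
                pairs.append(
                    CeRNAPair(lnc, mrna, N, K, n, c, p, frozenset(shared))
                )
    if not pairs:
        logger.info("no ceRNA pairs passed the gate; emitting empty network")

    edge_rows = []
    for pair in pairs:
        for mir in sorted(pair.shared):
            edge_rows.append((mir, pair.gene_a, "targets", "directed"))
            edge_rows.append((mir, pair.gene_b, "targets", "directed"))
        edge_rows.append((pair.gene_a, pair.gene_b, "cerna", "undirected"))
    edges = pd.DataFrame(
        sorted(set(edge_rows)),
        columns=["source", "target", "edge_type", "directedness"],
    )
    return pairs, edges


def pairs_frame(pairs: list[CeRNAPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "N": p.N,
                "K": p.K,
                "n": p.n,
                "c": p.c,
                "p_value": p.p_value,
            }
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "N", "K", "n", "c", "p_value"],
    )
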