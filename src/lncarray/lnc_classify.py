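"""Positional classification of lncRNA loci against a coding annotation.

Each lncRNA locus receives exactly one of six categories decided by a fixed
precedence order over strand and overlap geometry:

1. ``exon_sense_overlapping`` — same strand, >= 1 bp exon-exon overlap;
2. ``intron_sense_overlapping`` — same strand, span overlap, no exon-exon
   overlap;
3. ``intronic_antisense`` — opposite strand, lnc span fully inside one
   intron of the gene;
4. ``natural_antisense`` — opposite strand, >= 1 bp span overlap, not 3;
5. ``bidirectional`` — no overlap, opposite strands, TSS-to-TSS distance
   within a window (default 1000 bp) with divergent orientation;
6. ``intergenic`` — none of the above.

The category names come from standard array-annotation practice; the rule
bodies are a documented reconstruction (no authoritative definition is
available), with precedence exon > intron within sense and intronic >
general within antisense. A lncRNA overlapping several genes takes the
highest-precedence class over any of them, further ties broken by nearest
TSS.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .iofmt import Locus

__all__ = ["LNC_CLASSES", "GeneIndex", "classify", "classify_all"]

LNC_CLASSES = (
    "intergenic",
    "natural_antisense",
    "intronic_antisense",
    "exon_sense_overlapping",
    "bidirectional",
    "intron_sense_overlapping",
)

# precedence rank of each non-intergenic class (lower wins)
_RANK = {
    "exon_sense_overlapping": 1,
    "intron_sense_overlapping": 2,
    "intronic_antisense": 3,
    "natural_antisense": 4,
    "bidirectional": 5,
}


class GeneIndex:
    """Per-chromosome sorted interval index over coding loci."""

    def __init__(self, genes: Iterable[Locus]) -> None:
        self._by_chrom: dict[str, list[Locus]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        self._max_len: dict[str, int] = {}
        for chrom, lst in self._by_chrom.items():
            lst.sort(key=lambda g: (g.start, g.end, g.name))
            self._starts[chrom] = [g.start for g in lst]
            self._max_len[chrom] = max(g.end - g.start for g in lst)

    def near(self, chrom: str, start: int, end: int, pad: int) -> list[Locus]:
        """Genes whose span intersects [start - pad, end + pad)."""
        lst = self._by_chrom.get(chrom)
        if not lst:
            return []
        starts = self._starts[chrom]
        lo = bisect_left(starts, start - pad - self._max_len[chrom])
        hi = bisect_right(starts, end + pad)
        return [g for g in lst[lo:hi] if g.end > start - pad and g.start < end + pad]


def _blocks_overlap(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> bool:
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i][1] <= b[j][0]:
            i += 1
        elif b[j][1] <= a[i][0]:
            j += 1
        else:
            return True
    return False


def _divergent(lnc: Locus, gene: Locus) -> bool:
    # transcription proceeds away from the shared promoter region: the
    # '+' member's TSS must lie to the right of the '-' member's TSS
    plus, minus = (lnc, gene) if lnc.strand == "+" else (gene, lnc)
    return plus.tss > minus.tss


def _class_vs_gene(lnc: Locus, gene: Locus, bidir_window: int) -> Optional[str]:
    overlap = lnc.span_overlaps(gene)
    if lnc.strand == gene.strand:
        if overlap:
            if _blocks_overlap(lnc.blocks, gene.blocks):
                return "exon_sense_overlapping"
            return "intron_sense_overlapping"
        return None
    if overlap:
        for a, b in gene.introns:
            if a <= lnc.start and lnc.end <= b:
                return "intronic_antisense"
        return "natural_antisense"
    if abs(lnc.tss - gene.tss) <= bidir_window and _divergent(lnc, gene):
        return "bidirectional"
    return None


def classify(lnc: Locus, genes: GeneIndex | Iterable[Locus], bidir_window: int = 1000) -> str:
    cls, _gene = classify_with_gene(lnc, genes, bidir_window)
    return cls


def classify_with_gene(
    lnc: Locus,
    genes: GeneIndex | Iterable[Locus],
    bidir_window: int = 1000,
) -> tuple[str, Optional[Locus]]:
    """Classify one lncRNA locus; also return the gene that decided the
    class (None for intergenic)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    best: tuple[int, int, str] | None = None
    best_gene: Optional[Locus] = None
    for gene in index.near(lnc.chrom, lnc.start, lnc.end, bidir_window):
        cls = _class_vs_gene(lnc, gene, bidir_window)
        if cls is None:
            continue
        key = (_RANK[cls], abs(lnc.tss - gene.tss))
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], cls)
            best_gene = gene
    if best is None:
        return "intergenic", None
    return best[2], best_gene


def classify_all(
    lncs: Sequence[Locus],
    genes: Iterable[Locus],
    bidir_window: int = 1000,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Classify every lncRNA locus.

    Returns (category counts over all six classes, per-lnc table with the
    matched gene where applicable). Counts always sum to ``len(lncs)``.
    """
    index = GeneIndex(genes)
    counts = {cls: 0 for cls in LNC_CLASSES}
    rows = []
    for lnc in lncs:
        cls, gene = classify_with_gene(lnc, index, bidir_window)
        counts[cls] += 1
        rows.append(
            {
                "lnc_id": lnc.name,
                "chrom": lnc.chrom,
                "start": lnc.start,
                "end": lnc.end,
                "strand": lnc.strand,
                "category": cls,
                "matched_gene": gene.name if gene is not None else ".",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["lnc_id", "chrom", "start", "end", "strand", "category", "matched_gene"],
    )
    return counts, table
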