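"""Readers and writers for every tabular and genomic format the pipeline
touches, with strict schema validation.

Conventions
-----------
* All tables are UTF-8 TSV; missing values are written as ``"."``.
* Genomic coordinates are 0-based half-open internally (BED convention);
  readers/writers convert explicitly where a format differs.
* Intensities are stored linear-scale; log transforms are explicit
  operations in the statistics modules, never implicit here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ExpressionMatrix",
    "ProbeAnnotation",
    "GeneSet",
    "GeneSetCollection",
    "MiRNATargetTable",
    "Locus",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_loci",
    "write_loci",
    "read_mirna_targets",
    "write_mirna_targets",
    "read_probe_annotation",
    "write_probe_annotation",
    "write_network_tables",
]

GROUPS = ("case", "control")
CATEGORIES = ("BP", "CC", "MF", "pathway")
MISSING = "."


class SchemaError(ValueError):
    """Raised when a file or object violates a declared schema invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of linear-scale intensities with a two-group
    design.

    ``values`` rows follow ``probe_ids`` and columns follow ``sample_ids``;
    ``group_labels[i]`` is the group of ``sample_ids[i]``.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise SchemaError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise SchemaError("one group label required per sample")
        bad = sorted(set(self.group_labels) - set(GROUPS))
        if bad:
            raise SchemaError(f"unknown group labels: {bad}")
        for g in GROUPS:
            if g not in self.group_labels:
                raise SchemaError(f"group {g!r} has no samples")
        seen: set[str] = set()
        for pid in self.probe_ids:
            if pid in seen:
                raise SchemaError(f"duplicate probe id: {pid!r}")
            seen.add(pid)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("intensities must be finite")
        if np.any(self.values <= 0):
            raise SchemaError("intensities must be > 0 (linear scale)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_indices(self, group: str) -> np.ndarray:
        return np.asarray([i for i, g in enumerate(self.group_labels) if g == group])

    def group_values(self, group: str) -> np.ndarray:
        return self.values[:, self.sample_indices(group)]

    def probe_index(self, probe_id: str) -> int:
        try:
            return self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not in matrix") from None

    def log2(self) -> np.ndarray:
        """Explicit log2 transform of the linear-scale values."""
        return np.log2(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.probe_ids), list(self.sample_ids), list(self.group_labels), values
        )


@dataclass
class ProbeAnnotation:
    """Per-probe annotation keyed by probe name.

    Columns: seqname (transcript id), probe_name, chrom, strand (+/-),
    biotype (lncRNA/mRNA), gene_symbol (optional, "." when absent).
    """

    table: pd.DataFrame

    REQUIRED = ("seqname", "probe_name", "chrom", "strand", "biotype", "gene_symbol")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"annotation missing columns: {missing}")
        bad_strand = set(self.table["strand"]) - {"+", "-"}
        if bad_strand:
            raise SchemaError(f"strand must be '+' or '-', got {sorted(bad_strand)}")
        bad_bio = set(self.table["biotype"]) - {"lncRNA", "mRNA"}
        if bad_bio:
            raise SchemaError(f"biotype must be lncRNA or mRNA, got {sorted(bad_bio)}")
        keys = list(zip(self.table["seqname"], self.table["probe_name"]))
        if len(set(keys)) != len(keys):
            raise SchemaError("(seqname, probe_name) pairs must be unique")
        self._by_probe = self.table.set_index("probe_name", drop=False)
        if self._by_probe.index.has_duplicates:
            raise SchemaError("probe_name must be unique")

    def lookup(self, probe_name: str) -> pd.Series:
        try:
            return self._by_probe.loc[probe_name]
        except KeyError:
            raise KeyError(f"probe {probe_name!r} not annotated") from None

    def probes(self) -> set[str]:
        return set(self.table["probe_name"])


@dataclass
class GeneSet:
    set_id: str
    category: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise SchemaError(f"gene set {self.set_id!r} has no members")
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"gene set {self.set_id!r}: category {self.category!r} "
                f"not in {CATEGORIES}"
            )


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise SchemaError("set_ids must be unique")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def by_category(self, category: str) -> list[GeneSet]:
        return [s for s in self.sets if s.category == category]


@dataclass
class MiRNATargetTable:
    """(mirna_id, target_gene_id, mre_count) relations."""

    table: pd.DataFrame

    REQUIRED = ("mirna_id", "target_gene_id", "mre_count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"target table missing columns: {missing}")
        keys = list(zip(self.table["mirna_id"], self.table["target_gene_id"]))
        if len(set(keys)) != len(keys):
            raise SchemaError("(mirna_id, target_gene_id) pairs must be unique")
        counts = self.table["mre_count"]
        if (counts < 1).any() or (counts != counts.astype(int)).any():
            raise SchemaError("mre_count must be a positive integer")
        self.table = self.table.reset_index(drop=True)
        self.table["mre_count"] = self.table["mre_count"].astype(int)

    @property
    def mirnas(self) -> set[str]:
        return set(self.table["mirna_id"])

    @property
    def genes(self) -> set[str]:
        return set(self.table["target_gene_id"])

    def mirnas_for(self, gene_id: str) -> set[str]:
        mask = self.table["target_gene_id"] == gene_id
        return set(self.table.loc[mask, "mirna_id"])

    def mre_weights_for(self, gene_id: str) -> dict[str, int]:
        mask = self.table["target_gene_id"] == gene_id
        sub = self.table.loc[mask]
        return dict(zip(sub["mirna_id"], sub["mre_count"]))


@dataclass
class Locus:
    """A stranded genomic interval with exon blocks, 0-based half-open.

    ``tss`` is strand-aware: ``start`` on '+', ``end - 1`` on '-'.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    blocks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SchemaError(f"locus {self.name!r}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise SchemaError(f"locus {self.name!r}: end <= start")
        if not self.blocks:
            self.blocks = [(self.start, self.end)]
        blocks = sorted((int(a), int(b)) for a, b in self.blocks)
        prev_end = None
        for a, b in blocks:
            if b <= a:
                raise SchemaError(f"locus {self.name!r}: empty block [{a}, {b})")
            if a < self.start or b > self.end:
                raise SchemaError(
                    f"locus {self.name!r}: block [{a}, {b}) outside span "
                    f"[{self.start}, {self.end})"
                )
            if prev_end is not None and a < prev_end:
                raise SchemaError(f"locus {self.name!r}: overlapping blocks")
            prev_end = b
        self.blocks = blocks

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
            if self.blocks[i + 1][0] > self.blocks[i][1]
        ]

    def span_overlaps(self, other: "Locus") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression_matrix(path, group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a probes x samples TSV (header = sample ids, first column =
    probe ids) and attach group labels from ``group_map``."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    probe_ids = [str(p) for p in frame.index]
    dupes = frame.index[frame.index.duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"duplicate probe id in {path}: {dupes[0]!r}")
    sample_ids = [str(c) for c in frame.columns]
    missing = [s for s in sample_ids if s not in group_map]
    if missing:
        raise SchemaError(f"samples missing from group map: {missing}")
    values = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError(f"{path}: intensities must be finite and > 0")
    groups = [group_map[s] for s in sample_ids]
    return ExpressionMatrix(probe_ids, sample_ids, groups, values)


def write_expression_matrix(matrix: ExpressionMatrix, path, group_path=None) -> None:
    """Write the matrix TSV; optionally write a 2-column sample->group TSV."""
    matrix.to_frame().rename_axis("probe_id").to_csv(path, sep="\t", float_format="%.10g")
    if group_path is not None:
        with open(group_path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\tgroup\n")
            for s, g in zip(matrix.sample_ids, matrix.group_labels):
                fh.write(f"{s}\t{g}\n")


def read_group_map(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["sample_id", "group"]:
        raise SchemaError(f"{path}: expected columns sample_id, group")
    return dict(zip(frame["sample_id"], frame["group"]))


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

_CATEGORY_PREFIX = {"BP": "BP", "CC": "CC", "MF": "MF", "pathway": "pathway"}


def _infer_category(set_id: str, description: str) -> str:
    # category is encoded as a "category:" prefix on the description, falling
    # back to "pathway" for bare GMT files
    for cat in CATEGORIES:
        if description.startswith(cat + ":"):
            return cat
    return "pathway"


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``set_id TAB description TAB member...`` per line.

    The gene-set category is carried in a ``<CAT>:`` prefix on the
    description field (written by :func:`write_gmt`); lines without a prefix
    default to ``pathway``.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            set_id, description = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            if not members:
                raise SchemaError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            category = _infer_category(set_id, description)
            if description.startswith(category + ":"):
                description = description[len(category) + 1 :]
            sets.append(GeneSet(set_id, category, description, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            desc = f"{s.category}:{s.description}"
            fh.write("\t".join([s.set_id, desc, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# BED12-like loci
# ---------------------------------------------------------------------------


def read_loci(path) -> list[Locus]:
    """Read a BED12-like file (0-based half-open) into validated loci."""
    loci: list[Locus] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise SchemaError(f"{path}:{lineno}: need >= 6 BED fields")
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            blocks: list[tuple[int, int]] = []
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                    raise SchemaError(f"{path}:{lineno}: blockCount mismatch")
                blocks = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            try:
                loci.append(Locus(name, chrom, start, end, strand, blocks))
            except SchemaError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from None
    return loci


def write_loci(loci: Sequence[Locus], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for loc in loci:
            sizes = ",".join(str(b - a) for a, b in loc.blocks)
            starts = ",".join(str(a - loc.start) for a, b in loc.blocks)
            fh.write(
                "\t".join(
                    [
                        loc.chrom,
                        str(loc.start),
                        str(loc.end),
                        loc.name,
                        "0",
                        loc.strand,
                        str(loc.start),
                        str(loc.end),
                        "0",
                        str(len(loc.blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# miRNA target tables and probe annotation
# ---------------------------------------------------------------------------


def read_mirna_targets(path) -> MiRNATargetTable:
    frame = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "target_gene_id": str})
    return MiRNATargetTable(frame)


def write_mirna_targets(table: MiRNATargetTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_probe_annotation(path) -> ProbeAnnotation:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return ProbeAnnotation(frame)


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cytoscape network tables
# ---------------------------------------------------------------------------


def write_network_tables(
    nodes: Iterable[tuple[str, str]],
    edges: Iterable[tuple[str, str, float, str]],
    path_prefix,
) -> tuple[Path, Path, Path]:
    """Write Cytoscape-importable node/edge attribute tables plus a SIF file.

    ``nodes`` are (id, biotype) pairs; ``edges`` are (source, target,
    weight, sign) with sign in {positive, negative} mapped to SIF
    interaction types ``pp``/``pn``. Returns the three paths written.
    """
    nodes = list(nodes)
    edges = list(edges)
    node_ids = {n for n, _ in nodes}
    for src, dst, _w, _sign in edges:
        if src not in node_ids or dst not in node_ids:
            raise SchemaError(f"edge ({src}, {dst}) references an unknown node")
    prefix = Path(path_prefix)
    node_path = prefix.with_name(prefix.name + "_nodes.tsv")
    edge_path = prefix.with_name(prefix.name + "_edges.tsv")
    sif_path = prefix.with_name(prefix.name + ".sif")
    with open(node_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "biotype"])
        w.writerows(nodes)
    with open(edge_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "target", "weight", "sign"])
        for src, dst, weight, sign in edges:
            w.writerow([src, dst, f"{weight:.10g}", sign])
    with open(sif_path, "w", encoding="utf-8") as fh:
        for src, dst, _weight, sign in edges:
            rel = "pp" if sign == "positive" else "pn"
            fh.write(f"{src}\t{rel}\t{dst}\n")
    return node_path, edge_path, sif_path
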