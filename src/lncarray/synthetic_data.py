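"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: expression
matrices with planted differential expression, planted coexpression pairs,
miRNA target tables with planted sponge pairs, genomic loci realising each
of the six positional lncRNA categories, triplicate Ct tables, and gene-set
collections with one planted enriched set.

All draws come from a single explicitly-passed :class:`numpy.random.Generator`
seeded by the caller; identical seed + parameters give bit-identical output.

The intensity model is log-normal (Gaussian in log2 space): per-probe
baseline + group shift (+/- log2FC for planted probes) + Gaussian noise,
then exponentiated. This is a stand-in for unstated array behaviour, chosen
because single-channel intensities are conventionally near log-normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .iofmt import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    Locus,
    MiRNATargetTable,
    ProbeAnnotation,
)
import pandas as pd

__all__ = [
    "SimulationTruth",
    "simulate_expression",
    "simulate_coexpression",
    "simulate_mirna_targets",
    "simulate_loci",
    "simulate_ct_table",
    "simulate_gene_sets",
    "annotation_for",
]

LNC_CLASSES = (
    "intergenic",
    "natural_antisense",
    "intronic_antisense",
    "exon_sense_overlapping",
    "bidirectional",
    "intron_sense_overlapping",
)


@dataclass
class SimulationTruth:
    """Planted ground truth for recovery tests.

    de_probes maps probe id -> (direction in {Up, Down}, linear fold change);
    coexpr_pairs maps (lnc, mrna) -> target correlation; sponge_pairs maps
    (gene_a, gene_b) -> shared-miRNA count; locus_classes maps lnc locus
    name -> planted positional class; enriched_sets lists planted enriched
    set ids.
    """

    de_probes: dict[str, tuple[str, float]] = field(default_factory=dict)
    coexpr_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    sponge_pairs: dict[tuple[str, str], int] = field(default_factory=dict)
    locus_classes: dict[str, str] = field(default_factory=dict)
    enriched_sets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for probe, (direction, fc) in self.de_probes.items():
            if fc <= 1:
                raise ValueError(f"planted fold change for {probe} must be > 1")
            if direction not in ("Up", "Down"):
                raise ValueError(f"bad planted direction {direction!r}")
        for cls in self.locus_classes.values():
            if cls not in LNC_CLASSES:
                raise ValueError(f"planted class {cls!r} not one of {LNC_CLASSES}")


def _probe_ids(n_lnc: int, n_mrna: int) -> tuple[list[str], list[str]]:
    lnc = [f"LNC{i:06d}" for i in range(n_lnc)]
    mrna = [f"MRNA{i:06d}" for i in range(n_mrna)]
    return lnc, mrna


def simulate_expression(
    seed: int,
    n_case: int = 5,
    n_ctrl: int = 3,
    n_lnc: int = 2000,
    n_mrna: int = 1200,
    frac_de: float = 0.05,
    fc_log2_range: tuple[float, float] = (1.5, 5.5),
    sigma_log2: float = 0.25,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Generate a two-group expression matrix with planted DE probes.

    Exactly ``round(frac_de * n)`` probes per biotype are planted, half Up /
    half Down (Up gets the extra one when odd), with log2 fold changes drawn
    uniformly from ``fc_log2_range``.
    """
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need >= 2 samples per group for a t-test")
    # frac_de = 0 is admitted for null-calibration runs
    if not (0 <= frac_de <= 0.5):
        raise ValueError("frac_de must lie in [0, 0.5]")
    if sigma_log2 < 0:
        raise ValueError("sigma_log2 must be nonnegative")
    lo, hi = fc_log2_range
    if lo <= 0 or hi < lo:
        raise ValueError("fc_log2_range must be a positive interval")
    rng = np.random.default_rng(seed)
    lnc_ids, mrna_ids = _probe_ids(n_lnc, n_mrna)
    probe_ids = lnc_ids + mrna_ids
    n_probes = len(probe_ids)
    samples = [f"case{i + 1}" for i in range(n_case)] + [
        f"ctrl{i + 1}" for i in range(n_ctrl)
    ]
    groups = ["case"] * n_case + ["control"] * n_ctrl

    baseline = rng.uniform(6.0, 12.0, size=n_probes)
    shift = np.zeros(n_probes)
    truth = SimulationTruth()
    offset = 0
    for ids in (lnc_ids, mrna_ids):
        n_de = int(round(frac_de * len(ids)))
        chosen = rng.choice(len(ids), size=n_de, replace=False)
        log2fc = rng.uniform(lo, hi, size=n_de)
        signs = np.ones(n_de)
        signs[n_de // 2 + n_de % 2 :] = -1.0
        for j, (idx, lfc, s) in enumerate(zip(chosen, log2fc, signs)):
            shift[offset + idx] = s * lfc
            direction = "Up" if s > 0 else "Down"
            truth.de_probes[ids[idx]] = (direction, float(2.0**lfc))
        offset += len(ids)

    log2_vals = np.empty((n_probes, len(samples)))
    case_mask = np.asarray([g == "case" for g in groups])
    log2_vals[:] = baseline[:, None]
    log2_vals[:, case_mask] += shift[:, None]
    log2_vals += rng.normal(0.0, sigma_log2, size=log2_vals.shape) if sigma_log2 > 0 else 0.0
    matrix = ExpressionMatrix(probe_ids, samples, groups, np.exp2(log2_vals))
    return matrix, truth


def simulate_coexpression(
    seed: int,
    matrix: ExpressionMatrix,
    pairs: int,
    rho: float,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Rewrite mRNA profiles so planted lncRNA-mRNA pairs correlate at rho.

    The mRNA log2 profile becomes a rho-weighted copy of the standardized
    lncRNA profile plus empirically-orthogonal noise, rescaled to the mRNA's
    original mean and spread, so the sample Pearson correlation of a planted
    pair equals rho exactly (up to floating point).
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError("rho must lie strictly inside (-1, 1)")
    rng = np.random.default_rng(seed)
    lnc_ids = [p for p in matrix.probe_ids if p.startswith("LNC")]
    mrna_ids = [p for p in matrix.probe_ids if p.startswith("MRNA")]
    if pairs > min(len(lnc_ids), len(mrna_ids)):
        raise ValueError("more pairs requested than disjoint lnc/mRNA probes")
    chosen_lnc = rng.choice(len(lnc_ids), size=pairs, replace=False)
    chosen_mrna = rng.choice(len(mrna_ids), size=pairs, replace=False)

    log2_vals = matrix.log2()
    index = {p: i for i, p in enumerate(matrix.probe_ids)}
    truth = SimulationTruth()
    m = len(matrix.sample_ids)
    for li, mi in zip(chosen_lnc, chosen_mrna):
        lnc, mrna = lnc_ids[li], mrna_ids[mi]
        x = log2_vals[index[lnc]]
        y = log2_vals[index[mrna]]
        z = x - x.mean()
        nz = np.linalg.norm(z)
        if nz == 0:
            continue  # constant lncRNA profile cannot carry correlation
        z = z / nz
        e = rng.normal(size=m)
        e = e - e.mean()
        e = e - (e @ z) * z
        ne = np.linalg.norm(e)
        if ne == 0:
            continue
        e = e / ne
        profile = rho * z + np.sqrt(1.0 - rho * rho) * e
        sd_y = y.std()
        if sd_y == 0:
            sd_y = 1.0
        log2_vals[index[mrna]] = y.mean() + profile * np.sqrt(m) * sd_y
        truth.coexpr_pairs[(lnc, mrna)] = rho
    return matrix.with_values(np.exp2(log2_vals)), truth


def simulate_mirna_targets(
    seed: int,
    n_mirna: int,
    genes: list[str],
    sponge_pairs: int,
    shared_per_pair: int,
    background_rate: float = 0.02,
) -> tuple[MiRNATargetTable, SimulationTruth]:
    """Generate a miRNA->target table with planted shared-miRNA sponge pairs.

    Planted pairs are consecutive gene pairs from the front of ``genes``;
    each shares exactly ``shared_per_pair`` miRNAs (plus disjoint private
    background targets). Non-planted genes acquire targets by independent
    Bernoulli(``background_rate``) draws per miRNA.
    """
    if shared_per_pair > n_mirna:
        raise ValueError("shared_per_pair cannot exceed n_mirna")
    if 2 * sponge_pairs > len(genes):
        raise ValueError("not enough genes to plant the requested pairs")
    if not (0.0 <= background_rate <= 1.0):
        raise ValueError("background_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mirnas = [f"MIR{i:04d}" for i in range(n_mirna)]
    rows: list[tuple[str, str, int]] = []
    truth = SimulationTruth()

    planted_genes: set[str] = set()
    for k in range(sponge_pairs):
        a, b = genes[2 * k], genes[2 * k + 1]
        planted_genes.update((a, b))
        shared = rng.choice(n_mirna, size=shared_per_pair, replace=False)
        shared_set = {mirnas[i] for i in shared}
        for m in sorted(shared_set):
            rows.append((m, a, int(rng.integers(1, 4))))
            rows.append((m, b, int(rng.integers(1, 4))))
        # private (non-shared) targets drawn from disjoint halves of the
        # remaining miRNA pool so the shared count stays exactly as planted
        rest = [m for m in mirnas if m not in shared_set]
        rng.shuffle(rest)
        half = len(rest) // 2
        for gene, pool in ((a, rest[:half]), (b, rest[half:])):
            for m in pool:
                if rng.random() < background_rate:
                    rows.append((m, gene, int(rng.integers(1, 4))))
        truth.sponge_pairs[(a, b)] = shared_per_pair

    for gene in genes:
        if gene in planted_genes:
            continue
        hits = rng.random(n_mirna) < background_rate
        for i in np.flatnonzero(hits):
            rows.append((mirnas[i], gene, int(rng.integers(1, 4))))

    frame = pd.DataFrame(rows, columns=["mirna_id", "target_gene_id", "mre_count"])
    frame = frame.sort_values(["mirna_id", "target_gene_id"], kind="mergesort")
    return MiRNATargetTable(frame), truth


# geometry constants for locus cassettes (bp)
_GENE_EXON = 400
_GENE_INTRON = 2000
_LNC_LEN = 500
_CASSETTE = 20_000
_BIDIR_GAP = 400


def simulate_loci(
    seed: int,
    per_class: int,
    genome_length: int = 10_000_000,
    bidir_window: int = 1000,
) -> tuple[list[Locus], list[Locus], SimulationTruth]:
    """Construct lncRNA/coding-gene geometries realising each of the six
    positional categories, ``per_class`` cassettes per category.

    Each cassette occupies its own genomic stripe so categories cannot
    interfere; a genome too short to hold all cassettes raises.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    n_cassettes = 6 * per_class
    if n_cassettes * _CASSETTE > genome_length:
        raise ValueError(
            f"genome of {genome_length} bp cannot hold {n_cassettes} cassettes "
            f"of {_CASSETTE} bp without collisions"
        )
    rng = np.random.default_rng(seed)
    lncs: list[Locus] = []
    genes: list[Locus] = []
    truth = SimulationTruth()
    chrom = "chr1"
    order = [cls for cls in LNC_CLASSES for _ in range(per_class)]
    rng.shuffle(order)

    for idx, cls in enumerate(order):
        base = idx * _CASSETTE + 1000
        gname = f"GENE{idx:05d}"
        lname = f"LNCLOC{idx:05d}"
        # two-exon '+' gene: exon1 [g, g+E), intron, exon2
        g = base
        e1 = (g, g + _GENE_EXON)
        e2 = (g + _GENE_EXON + _GENE_INTRON, g + 2 * _GENE_EXON + _GENE_INTRON)
        gene = Locus(gname, chrom, e1[0], e2[1], "+", [e1, e2])

        if cls == "intergenic":
            start = gene.end + 5 * bidir_window
            lnc = Locus(lname, chrom, start, start + _LNC_LEN, "+")
        elif cls == "natural_antisense":
            # '-' lnc crossing exon1 and upstream flank: span overlap, not
            # inside an intron
            start = g - _LNC_LEN // 2
            lnc = Locus(lname, chrom, start, start + _LNC_LEN, "-")
        elif cls == "intronic_antisense":
            start = e1[1] + 200
            lnc = Locus(lname, chrom, start, start + _LNC_LEN, "-")
        elif cls == "exon_sense_overlapping":
            start = g + _GENE_EXON // 2
            lnc = Locus(lname, chrom, start, start + _LNC_LEN, "+")
        elif cls == "intron_sense_overlapping":
            start = e1[1] + 200
            lnc = Locus(lname, chrom, start, start + _LNC_LEN, "+")
        elif cls == "bidirectional":
            # divergent '-' lnc upstream of the gene TSS, inside the window
            end = g - _BIDIR_GAP
            lnc = Locus(lname, chrom, end - _LNC_LEN, end, "-")
        else:  # pragma: no cover
            raise AssertionError(cls)
        lncs.append(lnc)
        genes.append(gene)
        truth.locus_classes[lname] = cls
    return lncs, genes, truth


def simulate_ct_table(
    seed: int,
    n_case: int = 11,
    n_ctrl: int = 12,
    true_log2_ratio: float = -1.0,
    ct_sd: float = 0.2,
    target_gene: str = "TARGET",
    reference_gene: str = "ACTB",
    replicates: int = 3,
) -> pd.DataFrame:
    """Generate a long-format triplicate Ct table (sample, group, gene,
    replicate, ct).

    The planted case-vs-control difference in (target - reference) Ct equals
    ``-true_log2_ratio``, so the 2^-ddCt relative quantity of a noiseless
    case sample is ``2**true_log2_ratio``.
    """
    if n_case < 2 or n_ctrl < 2:
        raise ValueError("need >= 2 samples per group")
    if ct_sd < 0:
        raise ValueError("ct_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    ref_base = 20.0
    target_base = 26.0
    for group, n in (("case", n_case), ("control", n_ctrl)):
        for i in range(n):
            sample = f"{group}{i + 1}"
            shift = -true_log2_ratio if group == "case" else 0.0
            for gene, base in ((target_gene, target_base + shift), (reference_gene, ref_base)):
                for rep in range(1, replicates + 1):
                    noise = rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0
                    rows.append((sample, group, gene, rep, base + noise))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "replicate", "ct"])


def simulate_gene_sets(
    seed: int,
    universe: list[str],
    de_genes: list[str],
    n_sets_per_category: int = 5,
    set_size: int = 30,
    planted_de_fraction: float = 0.5,
) -> tuple[GeneSetCollection, SimulationTruth]:
    """Generate gene sets over a universe, with one planted enriched set per
    category loaded with DE genes well above the background rate."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    de = [g for g in de_genes if g in set(universe)]
    non_de = [g for g in universe if g not in set(de)]
    sets: list[GeneSet] = []
    truth = SimulationTruth()
    for cat in ("BP", "CC", "MF", "pathway"):
        for j in range(n_sets_per_category):
            sid = f"{cat}:{j:03d}"
            if j == 0 and de:
                n_de = max(1, min(len(de), int(round(planted_de_fraction * set_size))))
                members = list(rng.choice(de, size=n_de, replace=False))
                fill = set_size - len(members)
                if fill > 0 and non_de:
                    members += list(
                        rng.choice(non_de, size=min(fill, len(non_de)), replace=False)
                    )
                truth.enriched_sets.append(sid)
                desc = "planted enriched set"
            else:
                members = list(
                    rng.choice(universe, size=min(set_size, len(universe)), replace=False)
                )
                desc = "background set"
            sets.append(GeneSet(sid, cat, desc, sorted(set(members))))
    return GeneSetCollection(sets), truth


def annotation_for(matrix: ExpressionMatrix, seed: int = 0) -> ProbeAnnotation:
    """Build a probe annotation covering every probe in a simulated matrix."""
    rng = np.random.default_rng(seed)
    rows = []
    for probe in matrix.probe_ids:
        biotype = "lncRNA" if probe.startswith("LNC") else "mRNA"
        rows.append(
            {
                "seqname": f"T{probe}",
                "probe_name": probe,
                "chrom": f"chr{int(rng.integers(1, 23))}",
                "strand": "+" if rng.random() < 0.5 else "-",
                "biotype": biotype,
                "gene_symbol": f"SYM_{probe}",
            }
        )
    return ProbeAnnotation(pd.DataFrame(rows))
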