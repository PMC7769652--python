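"""2^-ddCt relative quantification from replicate Ct tables.

Replicate Ct values are averaged per (sample, gene); dCt = target mean Ct -
reference mean Ct; ddCt is taken relative to the MEAN dCt of the calibrator
group (group-level calibration, not a single reference sample); the
relative quantity is rq = 2^-ddCt. Case-vs-control comparison reuses the
pooled t-test kernel, on rq by default or on -ddCt with ``log_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import pooled_t_from_vectors

__all__ = ["RelativeExpression", "read_ct_table", "ddct", "compare_groups", "rq_frame"]

CT_COLUMNS = ("sample_id", "group", "gene_id", "replicate", "ct")


@dataclass
class RelativeExpression:
    sample_id: str
    group: str
    delta_ct: float
    delta_delta_ct: float
    rq: float

    def __post_init__(self) -> None:
        if self.rq <= 0:
            raise ValueError("rq must be positive")


def read_ct_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.isfinite(frame["ct"]).all() or (frame["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and > 0")
    return frame


def ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str = "control",
) -> list[RelativeExpression]:
    """Per-sample 2^-ddCt relative expression of ``target_gene`` normalized
    to ``reference_gene`` and calibrated to the calibrator-group mean dCt."""
    means = (
        ct_table.groupby(["sample_id", "group", "gene_id"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    by_sample: dict[str, dict[str, float]] = {}
    groups: dict[str, str] = {}
    for row in means.itertuples(index=False):
        by_sample.setdefault(row.sample_id, {})[row.gene_id] = row.ct
        groups[row.sample_id] = row.group

    delta: dict[str, float] = {}
    for sample, genes in by_sample.items():
        if target_gene not in genes:
            raise ValueError(f"sample {sample!r} lacks target gene {target_gene!r}")
        if reference_gene not in genes:
            raise ValueError(f"sample {sample!r} lacks reference gene {reference_gene!r}")
        delta[sample] = genes[target_gene] - genes[reference_gene]

    calibrator = [s for s, g in groups.items() if g == calibrator_group]
    if not calibrator:
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    calibrator_mean = float(np.mean([delta[s] for s in calibrator]))

    results = []
    for sample in by_sample:
        ddct_val = delta[sample] - calibrator_mean
        results.append(
            RelativeExpression(
                sample_id=sample,
                group=groups[sample],
                delta_ct=float(delta[sample]),
                delta_delta_ct=float(ddct_val),
                rq=float(2.0 ** (-ddct_val)),
            )
        )
    return results


def compare_groups(
    rel: list[RelativeExpression], log_scale: bool = False
) -> dict[str, float]:
    """Pooled two-sided t-test of case vs control relative expression.

    Tests rq by default, or -ddCt (log2 scale) when ``log_scale``.
    """
    case = [r for r in rel if r.group == "case"]
    ctrl = [r for r in rel if r.group == "control"]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 samples per group")
    value = (lambda r: -r.delta_delta_ct) if log_scale else (lambda r: r.rq)
    a = [value(r) for r in case]
    b = [value(r) for r in ctrl]
    t, df, p = pooled_t_from_vectors(a, b)
    return {
        "t": t,
        "df": df,
        "p_value": p,
        "case_mean_rq": float(np.mean([r.rq for r in case])),
        "control_mean_rq": float(np.mean([r.rq for r in ctrl])),
        "significant": p < 0.05,
    }


def rq_frame(rel: list[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in rel],
        columns=["sample_id", "group", "delta_ct", "delta_delta_ct", "rq"],
    )
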