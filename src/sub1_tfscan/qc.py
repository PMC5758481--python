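"""Reaction-level quality control and delta-Ct normalization.

Reactions are rejected if they are undetermined (no Ct below the ceiling) or
if their amplification fit quality (R-squared) falls below threshold.  Kept
target-gene reactions are normalized against the per-plate, per-group mean Ct
of a chosen reference gene: deltaCt = Ct_target - mean(Ct_reference).  Genes
qualify for differential-expression testing only when enough deltaCt
replicates survive in both conditions of a genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import GROUPS, DEFAULT_RG_IDS

#: default working reference gene (actin, LOC_Os05g36290 on the real platform)
DEFAULT_RG = DEFAULT_RG_IDS[0]

REASON_UNDETERMINED = "undetermined"
REASON_LOW_R2 = "low_r2"


@dataclass
class QCReport:
    """Counts and per-reaction reasons from reaction filtering."""

    kept: int
    rejected_undetermined: int
    rejected_low_r2: int
    reasons: pd.DataFrame = field(repr=False)  # index-aligned: reason or ""

    @property
    def rejected(self) -> int:
        return self.rejected_undetermined + self.rejected_low_r2

    @property
    def total(self) -> int:
        return self.kept + self.rejected


@dataclass
class EligibilityResult:
    """Per-genotype eligible gene sets and their intersection (the funnel)."""

    ir64: frozenset[str]
    sub1: frozenset[str]

    @property
    def intersection(self) -> frozenset[str]:
        return self.ir64 & self.sub1

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "IR64": len(self.ir64),
            "IR64Sub1": len(self.sub1),
            "intersection": len(self.intersection),
        }


def filter_reactions(
    reactions: pd.DataFrame,
    r2_min: float = 0.995,
    ct_ceiling: float = 40.0,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the two quality rules and return kept reactions plus a report.

    A reaction is kept iff its Ct is numeric and below ``ct_ceiling`` and its
    R-squared is at least ``r2_min``.  Rejection reasons are assigned with
    undetermined taking precedence over low R-squared, so each rejected row
    carries exactly one reason.  Water-control wells (no Ct) count as
    undetermined.
    """
    if r2_min <= 0 or ct_ceiling <= 0:
        raise ValueError("thresholds must be positive")
    ct = pd.to_numeric(reactions["ct"], errors="coerce")
    r2 = reactions["r_squared"]
    if not pd.api.types.is_numeric_dtype(r2):
        r2num = pd.to_numeric(r2, errors="coerce")
        bad = r2num.isna() & r2.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric r_squared at row {row}: {r2.iloc[row]!r}")
        r2 = r2num
    undetermined = ct.isna() | (ct >= ct_ceiling)
    # NaN R-squared on a determined reaction is a data error, not a QC reason
    bad_r2 = r2.isna() & ~undetermined
    if bad_r2.any():
        row = int(np.flatnonzero(bad_r2.to_numpy())[0])
        raise ValueError(f"missing r_squared at row {row}")
    low_r2 = ~undetermined & (r2 < r2_min)
    keep = ~undetermined & ~low_r2

    reasons = pd.Series("", index=reactions.index, dtype=object)
    reasons[undetermined] = REASON_UNDETERMINED
    reasons[low_r2] = REASON_LOW_R2
    report = QCReport(
        kept=int(keep.sum()),
        rejected_undetermined=int(undetermined.sum()),
        rejected_low_r2=int(low_r2.sum()),
        reasons=pd.DataFrame({"reason": reasons}),
    )
    return reactions[keep].copy(), report


def reference_ct(
    kept: pd.DataFrame,
    plate: int,
    group: str,
    rg_gene: str = DEFAULT_RG,
    replicate: int | None = None,
) -> float:
    """Mean Ct of the reference gene's surviving wells on one plate/group.

    With ``replicate`` the mean uses only that technical run's quadruplicate
    (run-local normalization, the default in the deltaCt matrix builder);
    without it, all runs of the plate/group are pooled.  Raises if no
    reference well survived QC there: genes on that plate cannot be
    normalized for that group.
    """
    sel = kept[(kept["plate"] == plate) & (kept["group"] == group) & (kept["gene_id"] == rg_gene)]
    if replicate is not None:
        sel = sel[sel["replicate"] == replicate]
    if sel.empty:
        where = f"plate {plate}, group {group}" + (
            f", replicate {replicate}" if replicate is not None else ""
        )
        raise ValueError(f"no kept reference-gene ({rg_gene}) wells on {where}")
    return float(sel["ct"].mean())


def delta_ct(ct_sg: float, ct_rg: float) -> float:
    """deltaCt = Ct_target - Ct_reference (both in cycles)."""
    return float(ct_sg) - float(ct_rg)


def build_delta_ct_matrix(
    kept: pd.DataFrame,
    rg_gene: str = DEFAULT_RG,
    strict: bool = True,
    per_run: bool = True,
) -> pd.DataFrame:
    """Long-form deltaCt matrix: one row per kept target-gene reaction.

    Normalization is plate-local: each reaction is normalized against the
    reference mean of its own plate and sample group — by default against
    its own technical run's quadruplicate (``per_run``), which keeps
    reference noise independent across replicates; ``per_run=False`` pools
    the plate/group's runs.  The working reference gene and water wells are
    excluded from the output; the other reference genes pass through as
    ordinary platform genes.  With ``strict`` a plate/group (or run) lacking
    surviving reference wells raises; otherwise its reactions are dropped.
    """
    targets = kept[(kept["gene_id"] != rg_gene) & (kept["gene_id"] != "WATER")]
    key_cols = ["plate", "group", "replicate"] if per_run else ["plate", "group"]
    ref_means: dict[tuple, float] = {}
    for key, _ in targets.groupby(key_cols):
        try:
            ref_means[key] = reference_ct(
                kept, key[0], key[1], rg_gene, key[2] if per_run else None
            )
        except ValueError:
            if strict:
                raise
    ref_df = pd.DataFrame(
        [(*key, m) for key, m in ref_means.items()], columns=[*key_cols, "ref_mean"]
    )
    merged = targets.merge(ref_df, on=key_cols, how="inner")
    merged["delta_ct"] = merged["ct"] - merged["ref_mean"]
    return merged[["gene_id", "group", "plate", "replicate", "delta_ct"]].reset_index(drop=True)


def eligible_genes(
    matrix: pd.DataFrame,
    min_values: int = 2,
    groups: tuple[str, ...] = GROUPS,
) -> EligibilityResult:
    """Genes with enough deltaCt replicates per genotype, and the intersection.

    A gene is eligible for a genotype iff it has at least ``min_values``
    deltaCt values in that genotype's control group AND in its submerged
    group.  The intersection (eligible in both genotypes) is the input set
    for the genotype contrast.
    """
    counts = matrix.groupby(["gene_id", "group"]).size().unstack(fill_value=0)
    for g in groups:
        if g not in counts.columns:
            counts[g] = 0
    ir64 = counts.index[(counts[groups[0]] >= min_values) & (counts[groups[1]] >= min_values)]
    sub1 = counts.index[(counts[groups[2]] >= min_values) & (counts[groups[3]] >= min_values)]
    return EligibilityResult(ir64=frozenset(ir64), sub1=frozenset(sub1))
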