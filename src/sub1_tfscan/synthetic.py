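"""Synthetic qPCR plate data generator.

Emulates a transcription-factor qPCR profiling experiment in which a few
thousand target genes are distributed across multi-well plates, each plate
reserving twelve wells for three reference genes (in quadruplicate) and four
wells for negative water controls.  Four sample groups are measured (control
and submerged for each of two genotypes), each with a fixed number of
technical replicate runs per plate.

The generator plants known delta-delta-Ct effects for selected genes and
returns, alongside the reaction table, a ground-truth table used for
parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical sample-group order: genotype x condition (C control, S submerged)
GROUPS: tuple[str, ...] = ("IR64_C", "IR64_S", "IR64Sub1_C", "IR64Sub1_S")

#: default reference-gene identifiers (actin is the working reference)
DEFAULT_RG_IDS: tuple[str, ...] = ("RG_actin", "RG_2", "RG_3")

#: reserved wells per plate: 3 reference genes x 4 + 4 water controls
RG_WELLS_PER_PLATE = 12
WATER_WELLS_PER_PLATE = 4
RESERVED_WELLS = RG_WELLS_PER_PLATE + WATER_WELLS_PER_PLATE

#: contrast names used in the truth table (must match stats.DEFAULT_CONTRASTS)
CONTRAST_NAMES: tuple[str, ...] = (
    "SubmergenceIR64",
    "SubmergenceIR64Sub1",
    "Genotype",
)

REACTION_COLUMNS: tuple[str, ...] = (
    "plate",
    "well",
    "gene_id",
    "group",
    "replicate",
    "ct",
    "efficiency",
    "r_squared",
)


@dataclass(frozen=True)
class GeneEffect:
    """Planted effects for one gene, in delta-delta-Ct cycles.

    ``sub_ir64`` / ``sub_sub1`` shift the submerged sample of the respective
    genotype relative to its control.  ``genotype`` shifts both IR64-Sub1
    groups relative to IR64; on the (sum-form) Genotype contrast the planted
    value therefore appears doubled.
    """

    sub_ir64: float = 0.0
    sub_sub1: float = 0.0
    genotype: float = 0.0


@dataclass
class SyntheticConfig:
    """Study-design parameters for the simulated experiment."""

    n_genes: int = 2487
    wells_per_plate: int = 384
    n_plates: int | None = None  # None: smallest count that fits
    groups: Sequence[str] = GROUPS
    tech_reps_per_group: int = 3
    rg_ids: Sequence[str] = DEFAULT_RG_IDS
    water_wells: int = WATER_WELLS_PER_PLATE
    baseline_ct_range: tuple[float, float] = (20.0, 34.0)
    frac_low_expressors: float = 0.05
    effect_table: Mapping[str, GeneEffect] = field(default_factory=dict)
    tech_sd: float = 0.25
    qc_fail_prob: float = 0.02
    efficiency_mean: float = 1.85
    efficiency_sd: float = 0.05
    ct_ceiling: float = 40.0
    duplicate_controls: int = 0  # genes duplicated at a second plate position
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.wells_per_plate <= RESERVED_WELLS:
            raise ValueError("wells_per_plate must exceed the 16 reserved wells")
        if len(self.groups) != 4:
            raise ValueError("exactly four sample groups are required")
        if self.tech_reps_per_group <= 0:
            raise ValueError("tech_reps_per_group must be positive")
        if len(self.rg_ids) != 3:
            raise ValueError("exactly three reference genes are required")
        if self.tech_sd < 0:
            raise ValueError("tech_sd must be non-negative")
        if not 0.0 <= self.qc_fail_prob <= 1.0:
            raise ValueError("qc_fail_prob must lie in [0, 1]")
        lo, hi = self.baseline_ct_range
        if not (0.0 < lo < hi < self.ct_ceiling):
            raise ValueError("baseline_ct_range must lie within (0, ct_ceiling)")
        if not 0.0 <= self.frac_low_expressors <= 1.0:
            raise ValueError("frac_low_expressors must lie in [0, 1]")
        for rg in self.rg_ids:
            eff = self.effect_table.get(rg)
            if eff is not None and (eff.sub_ir64, eff.sub_sub1, eff.genotype) != (0, 0, 0):
                raise ValueError(f"reference gene {rg} must carry zero planted effect")

    @property
    def gene_ids(self) -> list[str]:
        return [f"TF{i + 1:04d}" for i in range(self.n_genes)]


@dataclass
class PlateLayout:
    """Assignment of genes, reference-gene quadruplicates and water wells."""

    wells_per_plate: int
    assignments: pd.DataFrame  # columns: plate, well, content, gene_id

    @property
    def n_plates(self) -> int:
        return int(self.assignments["plate"].max())


def _well_label(index: int, wells_per_plate: int) -> str:
    """Row-letter/column-number label (A01 ... P24 on a 384-well plate)."""
    ncol = 24 if wells_per_plate % 24 == 0 else int(math.ceil(math.sqrt(wells_per_plate)))
    row, col = divmod(index, ncol)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def plan_plates(config: SyntheticConfig) -> PlateLayout:
    """Distribute genes across plates, reserving RG and water wells.

    Every plate carries exactly twelve reference-gene wells (three genes in
    quadruplicate) and four water wells; the remaining capacity holds target
    genes, each assigned to exactly one well (plus optional duplicated
    internal-control genes).
    """
    capacity = config.wells_per_plate - RG_WELLS_PER_PLATE - config.water_wells
    gene_wells = list(config.gene_ids)
    if config.duplicate_controls:
        if config.duplicate_controls > config.n_genes:
            raise ValueError("duplicate_controls exceeds n_genes")
        gene_wells += gene_wells[: config.duplicate_controls]
    n_needed = len(gene_wells)
    n_plates = math.ceil(n_needed / capacity)
    if config.n_plates is not None:
        if config.n_plates * capacity < n_needed:
            shortfall = n_needed - config.n_plates * capacity
            raise ValueError(
                f"plate capacity exceeded: {n_needed} gene wells need "
                f"{n_plates} plates of capacity {capacity}; "
                f"{config.n_plates} plates fall short by {shortfall} wells"
            )
        n_plates = config.n_plates

    rows: list[tuple[int, str, str, str]] = []
    cursor = 0
    for plate in range(1, n_plates + 1):
        widx = 0
        for rg in config.rg_ids:
            for _ in range(4):
                rows.append((plate, _well_label(widx, config.wells_per_plate), "reference", rg))
                widx += 1
        for _ in range(config.water_wells):
            rows.append((plate, _well_label(widx, config.wells_per_plate), "water", "WATER"))
            widx += 1
        take = gene_wells[cursor : cursor + capacity]
        cursor += len(take)
        for gid in take:
            rows.append((plate, _well_label(widx, config.wells_per_plate), "gene", gid))
            widx += 1
    assignments = pd.DataFrame(rows, columns=["plate", "well", "content", "gene_id"])
    return PlateLayout(wells_per_plate=config.wells_per_plate, assignments=assignments)


def _group_shift(effect: GeneEffect, group_index: int) -> float:
    """Additive Ct shift for one sample group under the planted effects."""
    shift = 0.0
    if group_index == 1:  # IR64 submerged
        shift += effect.sub_ir64
    if group_index == 3:  # IR64-Sub1 submerged
        shift += effect.sub_sub1
    if group_index >= 2:  # both IR64-Sub1 groups
        shift += effect.genotype
    return shift


def build_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Ground-truth table of planted per-contrast effects.

    ``Genotype`` is reported on the contrast scale, i.e. twice the
    per-condition shift, matching the sum-form contrast tested downstream.
    Reference genes carry zero effect for all contrasts.
    """
    rows = []
    for gid in config.gene_ids + list(config.rg_ids):
        eff = GeneEffect() if gid in config.rg_ids else config.effect_table.get(gid, GeneEffect())
        true = {
            "SubmergenceIR64": eff.sub_ir64,
            "SubmergenceIR64Sub1": eff.sub_sub1,
            "Genotype": 2.0 * eff.genotype,
        }
        row: dict[str, object] = {"gene_id": gid}
        for name in CONTRAST_NAMES:
            row[f"true_effect_{name}"] = true[name]
            row[f"is_de_{name}"] = bool(abs(true[name]) > 0)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_experiment(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full reaction table plus the planted-effect truth table.

    Each plate is run once per sample group and technical replicate; every run
    re-measures the plate's reference-gene quadruplicates and water wells.
    Ct = gene baseline + group shift + Normal(0, tech_sd).  Reactions at or
    above the Ct ceiling, and all water wells, are emitted as undetermined
    (NaN Ct in memory, "Undetermined" on disk).  With probability
    ``qc_fail_prob`` a reaction's R-squared is drawn below the 0.995 QC
    threshold.  A fixed seed yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    layout = plan_plates(config)

    lo, hi = config.baseline_ct_range
    gene_ids = config.gene_ids
    baselines = dict(zip(gene_ids, rng.uniform(lo, hi, size=config.n_genes)))
    n_low = int(round(config.frac_low_expressors * config.n_genes))
    if n_low:
        low_idx = rng.choice(config.n_genes, size=n_low, replace=False)
        low_cts = rng.uniform(config.ct_ceiling - 2.0, config.ct_ceiling + 2.0, size=n_low)
        for i, ct in zip(low_idx, low_cts):
            baselines[gene_ids[i]] = ct
    for rg in config.rg_ids:
        baselines[rg] = rng.uniform(18.0, 26.0)

    groups = list(config.groups)
    records: list[tuple] = []
    asn = layout.assignments
    for plate in range(1, layout.n_plates + 1):
        plate_rows = list(
            asn[asn["plate"] == plate][["well", "content", "gene_id"]].itertuples(index=False)
        )
        for gi, group in enumerate(groups):
            for rep in range(1, config.tech_reps_per_group + 1):
                for well, content, gid in plate_rows:
                    if content == "water":
                        records.append((plate, well, gid, group, rep, np.nan, np.nan, np.nan))
                        continue
                    eff = (
                        GeneEffect()
                        if gid in config.rg_ids
                        else config.effect_table.get(gid, GeneEffect())
                    )
                    ct = baselines[gid] + _group_shift(eff, gi)
                    if config.tech_sd > 0:
                        ct += rng.normal(0.0, config.tech_sd)
                    efficiency = float(
                        np.clip(rng.normal(config.efficiency_mean, config.efficiency_sd), 1.0, 2.0)
                    )
                    if rng.random() < config.qc_fail_prob:
                        r2 = rng.uniform(0.95, 0.99499)
                    else:
                        r2 = rng.uniform(0.995, 1.0)
                    if ct >= config.ct_ceiling:
                        ct = np.nan
                    records.append((plate, well, gid, group, rep, ct, efficiency, r2))
    reactions = pd.DataFrame(records, columns=list(REACTION_COLUMNS))
    return reactions, build_truth(config)


def simulate_delta_ct_matrix(
    n_genes: int,
    effect_table: Mapping[str, GeneEffect] | None = None,
    tech_sd: float = 0.25,
    tech_reps_per_group: int = 3,
    seed: int = 0,
    groups: Sequence[str] = GROUPS,
) -> pd.DataFrame:
    """Simulate the deltaCt matrix directly, bypassing plates and QC.

    Each gene/group replicate is baseline + group shift + Normal(0,
    tech_sd), so the replicate noise is exactly ``tech_sd`` — the stated
    condition for the calibration and recovery simulations of the
    statistical stage.  Gene baselines (on the deltaCt scale) are drawn
    Uniform(-2, 8).
    """
    if tech_sd < 0 or n_genes <= 0 or tech_reps_per_group <= 0:
        raise ValueError("invalid simulation parameters")
    rng = np.random.default_rng(seed)
    effect_table = effect_table or {}
    gene_ids = [f"TF{i + 1:04d}" for i in range(n_genes)]
    baselines = rng.uniform(-2.0, 8.0, size=n_genes)
    rows = []
    for gid, base in zip(gene_ids, baselines):
        eff = effect_table.get(gid, GeneEffect())
        for gi, group in enumerate(groups):
            mu = base + _group_shift(eff, gi)
            noise = rng.normal(0.0, tech_sd, size=tech_reps_per_group) if tech_sd else np.zeros(tech_reps_per_group)
            for rep in range(1, tech_reps_per_group + 1):
                rows.append((gid, group, 1, rep, mu + noise[rep - 1]))
    return pd.DataFrame(rows, columns=["gene_id", "group", "plate", "replicate", "delta_ct"])
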