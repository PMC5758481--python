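"""Table/FASTA readers and writers, configuration, and the pipeline driver.

All tables are UTF-8, tab-delimited, one header line, preceded by a single
``#``-prefixed provenance comment.  The run report is JSON and carries the
eligibility funnel, category counts and input checksums; given the same
config and seed the whole bundle is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .classify import categorize
from .motifs import (
    align_alleles,
    call_snps,
    load_catalog,
    motif_frequency,
    motif_gain_loss,
    normalize_sequence,
)
from .qc import build_delta_ct_matrix, eligible_genes, filter_reactions, DEFAULT_RG
from .stats import run_contrasts
from .synthetic import REACTION_COLUMNS

log = logging.getLogger("sub1_tfscan")

UNDETERMINED_TOKENS = {"undetermined", "undet", "na", "nan", ""}


class ValidationError(ValueError):
    """Configuration or input-format error (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; round-trips losslessly through YAML."""

    reactions: str = ""
    out_dir: str = "results"
    promoters: str | None = None  # FASTA with two allele records, optional
    upstream: str | None = None  # FASTA of DEG upstream regions, optional
    catalog: str | None = None  # motif catalog TSV; None = packaged
    rg_gene: str = DEFAULT_RG
    r2_min: float = 0.995
    ct_ceiling: float = 40.0
    min_values: int = 2
    alpha: float = 0.01
    fdr_family: str = "per-contrast"
    log2_ct: bool = False  # optional log2 transform of Ct before deltaCt
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.reactions:
            raise ValidationError("config missing 'reactions' path")
        if not 0 < self.r2_min <= 1:
            raise ValidationError("r2_min must lie in (0, 1]")
        if self.ct_ceiling <= 0:
            raise ValidationError("ct_ceiling must be positive")
        if self.min_values < 1:
            raise ValidationError("min_values must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.fdr_family not in ("per-contrast", "global"):
            raise ValidationError("fdr_family must be 'per-contrast' or 'global'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _provenance(config_hash: str | None = None) -> str:
    tag = f" config={config_hash}" if config_hash else ""
    return f"# sub1-tfscan v{__version__}{tag}"


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """Tab-delimited table with a single provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(config_hash) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_reactions(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """Reaction table writer: NaN Ct is serialized as "Undetermined"."""
    out = df.copy()
    out["ct"] = out["ct"].map(lambda v: "Undetermined" if pd.isna(v) else f"{v:.4f}")
    write_table(out, path, config_hash)


def read_reactions(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Parse a delimited reaction table into typed records.

    ``column_map`` maps file column names to the canonical names (plate,
    well, gene_id, group, replicate, ct, efficiency, r_squared), supporting
    spreadsheet exports with different headers.  Ct values equal to
    "Undetermined" (case-insensitive) or blank become NaN.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"reaction table {path} missing required column(s): {missing}")
    out = df[list(REACTION_COLUMNS)].copy()

    def parse_ct(v: str) -> float:
        if v.strip().lower() in UNDETERMINED_TOKENS:
            return float("nan")
        return float(v)

    errors = []
    for col, parser in (("ct", parse_ct), ("efficiency", _parse_optional_float),
                        ("r_squared", _parse_optional_float)):
        parsed = []
        for i, v in enumerate(out[col]):
            try:
                parsed.append(parser(v))
            except ValueError:
                errors.append(f"line {i + 2}: bad {col} value {v!r}")
                parsed.append(float("nan"))
        out[col] = parsed
    if errors:
        raise ValidationError("; ".join(errors[:10]))
    out["plate"] = out["plate"].astype(int)
    out["replicate"] = out["replicate"].astype(int)
    return out


def _parse_optional_float(v: str) -> float:
    if v.strip().lower() in ("", "na", "nan"):
        return float("nan")
    return float(v)


def read_fasta(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    """FASTA sequences plus any ``tss=<pos>`` annotations from descriptions."""
    seqs: dict[str, str] = {}
    tss: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = normalize_sequence(str(rec.seq))
        for token in rec.description.split():
            if token.startswith("tss="):
                tss[rec.id] = int(token[4:])
    return seqs, tss


def write_fasta(seqs: Mapping[str, str], path: str | Path, tss: Mapping[str, int] | None = None) -> None:
    records = []
    for sid, seq in seqs.items():
        desc = f"tss={tss[sid]}" if tss and sid in tss else ""
        records.append(SeqRecord(Seq(seq), id=sid, description=desc))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """qc -> de -> classify (-> motifs when sequences are given).

    Writes every stage's table under ``config.out_dir`` plus ``report.json``
    and returns the report dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash the analysis parameters only, not the output location
    cfg_dict = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:12]

    log.info("qc: reading %s", config.reactions)
    reactions = read_reactions(config.reactions)
    if config.log2_ct:
        import numpy as np

        reactions = reactions.copy()
        reactions["ct"] = np.log2(reactions["ct"])
    kept, report_qc = filter_reactions(reactions, config.r2_min, config.ct_ceiling)
    matrix = build_delta_ct_matrix(kept, config.rg_gene)
    elig = eligible_genes(matrix, config.min_values)
    write_table(matrix, out / "delta_ct_matrix.tsv", cfg_hash)
    write_table(report_qc.reasons.assign(row=report_qc.reasons.index),
                out / "qc_reasons.tsv", cfg_hash)
    log.info("qc: kept %d of %d reactions; funnel %s",
             report_qc.kept, report_qc.total, elig.sizes)

    log.info("de: testing %d genes", len(elig.intersection))
    de, skipped = run_contrasts(
        matrix,
        alpha=config.alpha,
        genes=elig.intersection,
        fdr_family=config.fdr_family,
    )
    write_table(de, out / "de_results.tsv", cfg_hash)
    if not skipped.empty:
        write_table(skipped, out / "de_skipped.tsv", cfg_hash)

    categories, summary = categorize(de, config.alpha)
    write_table(categories, out / "gene_categories.tsv", cfg_hash)

    report: dict = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "qc": {
            "total": report_qc.total,
            "kept": report_qc.kept,
            "rejected_undetermined": report_qc.rejected_undetermined,
            "rejected_low_r2": report_qc.rejected_low_r2,
        },
        "funnel": elig.sizes,
        "de": {"n_tested": int(de["gene_id"].nunique()), "alpha": config.alpha},
        "categories": summary,
        "inputs": {"reactions": _sha256(config.reactions)},
    }

    if config.promoters:
        log.info("motifs: allele SNP/motif analysis of %s", config.promoters)
        seqs, tss = read_fasta(config.promoters)
        if len(seqs) != 2:
            raise ValidationError("promoter FASTA must contain exactly two allele records")
        (id_a, seq_a), (id_b, seq_b) = seqs.items()
        catalog = load_catalog(config.catalog)
        aln = align_alleles(seq_a, seq_b, id_a, id_b)
        snps = call_snps(aln)
        diffs = motif_gain_loss(aln, snps, catalog, tss.get(id_a), tss.get(id_b))
        write_table(
            pd.DataFrame(
                [(s.snp_id, s.column, s.pos_a + 1, s.pos_b + 1, s.base_a, s.base_b, s.kind)
                 for s in snps],
                columns=["snp_id", "column", "pos_a_1based", "pos_b_1based",
                         "base_a", "base_b", "kind"],
            ),
            out / "promoter_snps.tsv",
            cfg_hash,
        )
        write_table(
            pd.DataFrame(
                [(d.snp_id, d.motif, d.gained_in, d.hit.start + 1, d.hit.strand,
                  d.hit.matched, d.tss_distance)
                 for d in diffs],
                columns=["snp_id", "motif", "gained_in", "start_1based", "strand",
                         "matched", "tss_distance"],
            ),
            out / "promoter_motif_diffs.tsv",
            cfg_hash,
        )
        report["promoters"] = {
            "n_snps": len(snps),
            "n_substitutions": sum(1 for s in snps if s.kind == "substitution"),
            "n_motif_creating_snps": len({d.snp_id for d in diffs}),
            "inputs": _sha256(config.promoters),
        }

    if config.upstream:
        log.info("motifs: upstream motif frequencies from %s", config.upstream)
        seqs, _ = read_fasta(config.upstream)
        catalog = load_catalog(config.catalog)
        groups = {
            cat: categories[categories["category"] == cat]["gene_id"].tolist()
            for cat in ("submergence_IR64", "submergence_IR64Sub1", "common")
        }
        freq, missing = motif_frequency(groups, seqs, catalog)
        write_table(freq, out / "motif_frequencies.tsv", cfg_hash)
        report["motif_frequency"] = {
            "n_motifs": len(freq),
            "genes_without_sequence": sorted(missing),
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
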