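"""Allele-aware promoter cis-element analysis.

Aligns two promoter alleles globally, calls SNPs from the alignment, scans
IUPAC consensus motifs (PLACE-style catalog) on both strands, and calls
per-SNP allele-specific motif gains: a motif is gained in one allele when a
hit covers the SNP base there and no same-motif, same-strand hit covers the
homologous column in the other allele.  Motif frequencies across groups of
genes are tabulated as gene-level presence/absence.

Coordinates are 0-based half-open internally; TSS distances are negative
upstream (position minus TSS).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

#: degeneracy sets for IUPAC consensus symbols
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CATEGORIES = ("hypoxia_light", "energy_sugar", "transcription_cell_division", "hormone_stress")


def normalize_sequence(seq: str) -> str:
    """Uppercase and U->T normalize a DNA/RNA sequence string."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    name: str
    iupac: str
    category: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError(f"motif {self.name}: empty consensus")
        for sym in self.iupac:
            if sym not in IUPAC_SETS:
                raise ValueError(f"motif {self.name}: invalid IUPAC symbol {sym!r}")


def load_catalog(path=None) -> list[Motif]:
    """Load the tab-delimited (name, iupac, category) motif catalog.

    Without a path, the packaged PLACE-style catalog is used.
    """
    if path is None:
        with resources.files("sub1_tfscan.data").joinpath("motif_catalog.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [Motif(r.name, normalize_sequence(r.iupac), r.category)
            for r in df.itertuples(index=False)]


def iupac_match(consensus: str, window: str) -> bool:
    """True iff every window base lies in the degeneracy set of its symbol.

    Sequence bases outside A/C/G/T (ambiguity codes) match only the N symbol.
    """
    if len(consensus) != len(window):
        raise ValueError("consensus and window lengths differ")
    for sym, base in zip(consensus, window):
        sets = IUPAC_SETS.get(sym)
        if sets is None:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in consensus")
        if base in "ACGT":
            if base not in sets:
                return False
        elif sym != "N":
            return False
    return True


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 0-based, forward coordinates
    end: int  # half-open
    strand: str  # '+' or '-'
    motif: str
    matched: str  # forward-strand substring


def _consensus_regex(consensus: str) -> re.Pattern:
    parts = []
    for sym in consensus:
        if sym == "N":
            parts.append(".")
        else:
            parts.append("[" + "".join(sorted(IUPAC_SETS[sym])) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan(seq: str, motif: Motif, strands: str = "+-", seq_id: str = "seq") -> list[MotifHit]:
    """All (overlapping) consensus matches on the requested strands.

    Minus-strand matches are found on the reverse complement and mapped back
    to forward coordinates; hits are sorted by start, then strand.
    """
    seq = normalize_sequence(seq)
    L = len(motif.iupac)
    hits: list[MotifHit] = []
    pat = _consensus_regex(motif.iupac)
    if "+" in strands:
        for m in pat.finditer(seq):
            s = m.start()
            hits.append(MotifHit(seq_id, s, s + L, "+", motif.name, seq[s : s + L]))
    if "-" in strands:
        rc = reverse_complement(seq)
        n = len(seq)
        for m in pat.finditer(rc):
            s_fwd = n - m.start() - L
            hits.append(MotifHit(seq_id, s_fwd, s_fwd + L, "-", motif.name, seq[s_fwd : s_fwd + L]))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# pairwise allele alignment and SNP calling


@dataclass
class AlleleAlignment:
    """Global pairwise alignment of two alleles as gapped strings."""

    a: str  # gapped allele A
    b: str  # gapped allele B
    id_a: str = "allele_A"
    id_b: str = "allele_B"

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned sequences differ in length")
        if any(ca == "-" and cb == "-" for ca, cb in zip(self.a, self.b)):
            raise ValueError("alignment contains an all-gap column")

    @property
    def seq_a(self) -> str:
        return self.a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.b.replace("-", "")

    def column_positions(self) -> tuple[list[int], list[int]]:
        """Per-column ungapped positions (position of the base at or the
        next base after each column; for gap columns the count so far)."""
        pos_a, pos_b = [], []
        ia = ib = 0
        for ca, cb in zip(self.a, self.b):
            pos_a.append(ia)
            pos_b.append(ib)
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
        return pos_a, pos_b


def align_alleles(seq_a: str, seq_b: str, id_a: str = "allele_A", id_b: str = "allele_B") -> AlleleAlignment:
    """Deterministic global alignment with affine gap penalties.

    Scores: match +2, mismatch -1, gap open -5, gap extend -1.  Of the
    optimal alignments the aligner's first is taken, which is deterministic
    for fixed inputs.
    """
    seq_a, seq_b = normalize_sequence(seq_a), normalize_sequence(seq_b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    return AlleleAlignment(a=str(aln[0]), b=str(aln[1]), id_a=id_a, id_b=id_b)


@dataclass(frozen=True)
class SNPRecord:
    snp_id: str
    column: int  # alignment column (start column for indels)
    pos_a: int  # 0-based ungapped position in allele A
    pos_b: int
    base_a: str  # '-' for a gap in A (insertion in B)
    base_b: str
    kind: str  # 'substitution' or 'indel'


def call_snps(alignment: AlleleAlignment) -> list[SNPRecord]:
    """Substitution and indel records from an alignment.

    One record per mismatch column; consecutive gap columns (gap in the same
    allele) merge into a single indel record.  SNP ids number the variants
    1..n in alignment order (SNP1 most upstream).
    """
    pos_a, pos_b = alignment.column_positions()
    records: list[SNPRecord] = []
    i = 0
    n = len(alignment.a)
    counter = 0
    while i < n:
        ca, cb = alignment.a[i], alignment.b[i]
        if ca != "-" and cb != "-":
            if ca != cb:
                counter += 1
                records.append(
                    SNPRecord(f"SNP{counter}", i, pos_a[i], pos_b[i], ca, cb, "substitution")
                )
            i += 1
            continue
        gap_in_a = ca == "-"
        j = i
        while (
            j < n
            and ((alignment.a[j] == "-") != (alignment.b[j] == "-"))
            and (alignment.a[j] == "-") == gap_in_a
        ):
            j += 1
        counter += 1
        ins = (alignment.b if gap_in_a else alignment.a)[i:j]
        records.append(
            SNPRecord(
                f"SNP{counter}",
                i,
                pos_a[i],
                pos_b[i],
                "-" if gap_in_a else ins,
                ins if gap_in_a else "-",
                "indel",
            )
        )
        i = j
    return records


@dataclass(frozen=True)
class MotifDiff:
    snp_id: str
    motif: str
    gained_in: str  # 'A' or 'B'
    hit: MotifHit
    tss_distance: int | None  # hit start minus TSS; negative upstream


def _hits_by_motif(seq: str, catalog: Sequence[Motif], seq_id: str) -> dict[tuple[str, str], list[MotifHit]]:
    out: dict[tuple[str, str], list[MotifHit]] = {}
    for motif in catalog:
        for hit in scan(seq, motif, "+-", seq_id=seq_id):
            out.setdefault((motif.name, hit.strand), []).append(hit)
    return out


def motif_gain_loss(
    alignment: AlleleAlignment,
    snps: Sequence[SNPRecord],
    catalog: Sequence[Motif],
    tss_a: int | None = None,
    tss_b: int | None = None,
) -> list[MotifDiff]:
    """Allele-specific motif gains at substitution SNPs.

    For each substitution SNP, motif and strand: a gain is called for allele
    X when some hit covers the SNP base in X and no same-motif, same-strand
    hit covers the homologous column in the other allele.  Indel SNPs are
    not motif-called.  TSS coordinates (0-based position of the transcription
    start within each allele) annotate each gain with a signed distance.
    """
    seq_a, seq_b = alignment.seq_a, alignment.seq_b
    for tss, seq, label in ((tss_a, seq_a, "A"), (tss_b, seq_b, "B")):
        if tss is not None and not 0 <= tss <= len(seq):
            raise ValueError(f"TSS outside sequence for allele {label}")
    hits_a = _hits_by_motif(seq_a, catalog, alignment.id_a)
    hits_b = _hits_by_motif(seq_b, catalog, alignment.id_b)

    def covering(hits: list[MotifHit], pos: int) -> list[MotifHit]:
        return [h for h in hits if h.start <= pos < h.end]

    diffs: list[MotifDiff] = []
    for snp in snps:
        if snp.kind != "substitution":
            continue
        for motif in catalog:
            for strand in "+-":
                key = (motif.name, strand)
                cov_a = covering(hits_a.get(key, []), snp.pos_a)
                cov_b = covering(hits_b.get(key, []), snp.pos_b)
                if cov_a and not cov_b:
                    hit = cov_a[0]
                    dist = hit.start - tss_a if tss_a is not None else None
                    diffs.append(MotifDiff(snp.snp_id, motif.name, "A", hit, dist))
                elif cov_b and not cov_a:
                    hit = cov_b[0]
                    dist = hit.start - tss_b if tss_b is not None else None
                    diffs.append(MotifDiff(snp.snp_id, motif.name, "B", hit, dist))
    return diffs


def motif_frequency(
    groups: Mapping[str, Iterable[str]],
    upstream: Mapping[str, str],
    catalog: Sequence[Motif],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-group gene counts with at least one hit of each motif.

    Cell (motif, group) counts genes in the group whose upstream sequence
    carries >= 1 hit on either strand.  All-zero motif rows are dropped and
    rows are ordered by catalog category.  Genes without a sequence are
    skipped and reported.
    """
    skipped: list[str] = []
    presence: dict[str, set[str]] = {m.name: set() for m in catalog}
    genes_seen: dict[str, list[str]] = {}
    for group, gene_ids in groups.items():
        genes_seen[group] = []
        for gid in gene_ids:
            seq = upstream.get(gid)
            if seq is None:
                skipped.append(gid)
                continue
            genes_seen[group].append(gid)
            for motif in catalog:
                if scan(seq, motif, "+-", seq_id=gid):
                    presence[motif.name].add(gid)
    rows = []
    for motif in sorted(catalog, key=lambda m: (CATEGORIES.index(m.category), m.name)):
        counts = {
            g: sum(1 for gid in gids if gid in presence[motif.name])
            for g, gids in genes_seen.items()
        }
        if sum(counts.values()) == 0:
            continue
        rows.append({"category": motif.category, "motif": motif.name, **counts})
    table = pd.DataFrame(rows, columns=["category", "motif", *groups.keys()])
    return table, skipped


# ---------------------------------------------------------------------------
# synthetic allele pair for demonstrations and tests

#: per-SNP local contexts (allele A, allele B), 13 bp, substitution inside.
#: SNP3 plants an ABRE (minus strand) in B; SNP4 a Site I / G-box octamer in
#: A; SNP5 a CARE in A and a DRE/CRT core in B at the same site; SNP9 a
#: Site II in B (far from the TSS); SNP13 a Site II in A (near the TSS).
#: The remaining eight substitutions are motif-neutral in both alleles.
_SNP_CONTEXTS: tuple[tuple[str, str], ...] = (
    ("CTAGTCATCGATC", "CTAGTCTTCGATC"),  # SNP1 neutral
    ("GATCTGATAGCTA", "GATCTGCTAGCTA"),  # SNP2 neutral
    ("TTTGCTACGTTTT", "TTTGCCACGTTTT"),  # SNP3: ABRE minus strand in B
    ("TTTCCACGTGGTT", "TTTCCACATGGTT"),  # SNP4: Site I (G-box) in A
    ("TCAACTCCCGACT", "TCAACTGCCGACT"),  # SNP5: CARE in A / DRE-CRT in B
    ("CTTAGCACGATTC", "CTTAGCTCGATTC"),  # SNP6 neutral
    ("AGGATCTACCTGA", "AGGATCGACCTGA"),  # SNP7 neutral
    ("CCATGATTGGATC", "CCATGACTGGATC"),  # SNP8 neutral
    ("TTTTGAGCCTTTT", "TTTTGGGCCTTTT"),  # SNP9: Site II in B
    ("TTGACCATGGTCA", "TTGACCTTGGTCA"),  # SNP10 neutral
    ("CGGATAGCGTAAG", "CGGATACCGTAAG"),  # SNP11 neutral
    ("GTCTAGATCCAGT", "GTCTAGGTCCAGT"),  # SNP12 neutral
    ("TTTTGGGCTTTTT", "TTTTGAGCTTTTT"),  # SNP13: Site II in A
)

_SPACER = "CTTGTCTCGTTGC"
#: shared decorations: a truncated telo-box near each allele-specific
#: Site II, and one Site II core present in both alleles.
_AFTER = {
    8: "ACCCTA" + _SPACER,  # telo-box variant near the B-specific Site II
    10: "TGGGCC" + _SPACER,  # shared Site II core (present in both alleles)
    11: "AAACCCT" + _SPACER,  # telo-box variant near the A-specific Site II
}


def synthetic_promoter_alleles() -> tuple[str, str, int]:
    """Synthetic promoter allele pair with thirteen substitution SNPs.

    A constructed stand-in (synthetic, not the published allele sequences)
    emulating the structure reported for the two SUB1A promoter alleles:
    thirteen substitutions of which five create allele-specific
    cis-elements — a Site I/G-box (SNP4), a CARE (SNP5) and a TSS-proximal
    Site II (SNP13) in allele A; a minus-strand ABRE (SNP3), a DRE/CRT core
    (SNP5) and a TSS-distal Site II (SNP9) in allele B — with truncated
    telo-boxes near the Site II elements.  Returns (allele_a, allele_b,
    tss) where the TSS sits at the 3' end of the sequences.
    """
    parts_a, parts_b = [_SPACER], [_SPACER]
    for i, (ctx_a, ctx_b) in enumerate(_SNP_CONTEXTS):
        parts_a.append(ctx_a)
        parts_b.append(ctx_b)
        tail = _AFTER.get(i, _SPACER)
        parts_a.append(tail)
        parts_b.append(tail)
    seq_a, seq_b = "".join(parts_a), "".join(parts_b)
    return seq_a, seq_b, len(seq_a)
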