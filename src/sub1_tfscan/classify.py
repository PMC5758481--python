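"""Partition tested genes into submergence/genotype response categories.

A gene significant in both submergence contrasts is "common"; significant in
exactly one, it belongs to that genotype's submergence category; significant
only in the genotype contrast, it is "genotype_specific"; otherwise
"not_significant".  A gene that is both submergence- and genotype-significant
keeps its submergence category and is flagged ``also_genotype`` rather than
forming a fifth class.  Direction labels follow the log2FC sign convention
(negative = downregulated).
"""

from __future__ import annotations

import pandas as pd

CATEGORIES = (
    "genotype_specific",
    "submergence_IR64",
    "submergence_IR64Sub1",
    "common",
    "not_significant",
    "unclassifiable",
)

_SUB_IR64 = "SubmergenceIR64"
_SUB_SUB1 = "SubmergenceIR64Sub1"
_GENO = "Genotype"
REQUIRED_CONTRASTS = (_SUB_IR64, _SUB_SUB1, _GENO)


def _direction(log2fc: float) -> str:
    return "down" if log2fc < 0 else "up"


def categorize(results: pd.DataFrame, alpha: float = 0.01) -> tuple[pd.DataFrame, dict]:
    """Assign each gene exactly one category and summarize the counts.

    ``results`` is the long-form DE table (gene_id, contrast, log2FC, adj_p).
    Genes missing any of the three contrasts are reported as unclassifiable.
    The summary carries per-category counts and, for the submergence
    categories, up/down splits.
    """
    rows = []
    for gid, sub in results.groupby("gene_id"):
        by = {r.contrast: r for r in sub.itertuples(index=False)}
        if any(c not in by for c in REQUIRED_CONTRASTS):
            rows.append((gid, "unclassifiable", "", False))
            continue
        sig_i = by[_SUB_IR64].adj_p < alpha
        sig_s = by[_SUB_SUB1].adj_p < alpha
        sig_g = by[_GENO].adj_p < alpha
        if sig_i and sig_s:
            cat = "common"
            # direction taken from each genotype; report the IR64 side first
            direction = f"{_direction(by[_SUB_IR64].log2FC)}/{_direction(by[_SUB_SUB1].log2FC)}"
        elif sig_i:
            cat, direction = "submergence_IR64", _direction(by[_SUB_IR64].log2FC)
        elif sig_s:
            cat, direction = "submergence_IR64Sub1", _direction(by[_SUB_SUB1].log2FC)
        elif sig_g:
            cat, direction = "genotype_specific", _direction(by[_GENO].log2FC)
        else:
            cat, direction = "not_significant", ""
        also_genotype = bool(sig_g and cat in ("common", "submergence_IR64", "submergence_IR64Sub1"))
        rows.append((gid, cat, direction, also_genotype))
    table = pd.DataFrame(rows, columns=["gene_id", "category", "direction", "also_genotype"])

    summary: dict = {"n_genes": len(table), "alpha": alpha, "categories": {}}
    for cat in CATEGORIES:
        summary["categories"][cat] = int((table["category"] == cat).sum())
    for cat in ("submergence_IR64", "submergence_IR64Sub1"):
        sel = table[table["category"] == cat]
        summary[f"{cat}_up"] = int((sel["direction"] == "up").sum())
        summary[f"{cat}_down"] = int((sel["direction"] == "down").sum())
    return table, summary
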