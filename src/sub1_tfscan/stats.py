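"""Moderated t-tests over the four-group qPCR design.

Each gene's deltaCt replicates are fit with a group-means linear model; the
per-gene residual variances are shrunk toward a common prior by empirical
Bayes (closed-form moment matching of a scaled inverse-chi-square prior, with
hyperparameters estimated by inverting the trigamma function), and contrasts
of group means are tested with the moderated t-statistic on augmented degrees
of freedom.  P-values are corrected per contrast by the Benjamini-Hochberg
step-up procedure.

Sign convention: deltaCt is inversely related to abundance, so the reported
log2 fold change is the *negative* of the contrast estimate on the deltaCt
scale — downregulated genes carry negative log2FC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .synthetic import GROUPS

#: contrast coefficient vectors over (IR64_C, IR64_S, IR64Sub1_C, IR64Sub1_S)
#: Genotype is the literal sum form, (Sub1_S + Sub1_C) - (IR64_S + IR64_C)


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    coefficients: tuple[float, float, float, float]


DEFAULT_CONTRASTS: tuple[ContrastSpec, ...] = (
    ContrastSpec("SubmergenceIR64", (-1.0, 1.0, 0.0, 0.0)),
    ContrastSpec("SubmergenceIR64Sub1", (0.0, 0.0, -1.0, 1.0)),
    ContrastSpec("Genotype", (-1.0, -1.0, 1.0, 1.0)),
)


@dataclass
class GroupFit:
    """Group-means least-squares fit for one gene."""

    gene: str
    means: dict[str, float]  # group -> mean deltaCt (NaN when group empty)
    counts: dict[str, int]
    s2: float  # pooled residual variance; NaN when df == 0
    df: int  # residual degrees of freedom, sum over groups of (n-1)


@dataclass(frozen=True)
class ShrinkagePrior:
    """Scaled inverse-chi-square prior on gene variances."""

    d0: float  # prior degrees of freedom, may be math.inf
    s02: float  # prior variance (cycles^2)

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (possibly infinite)")
        if not (self.s02 > 0):
            raise ValueError("s02 must be positive")


def fit_group_means(
    gene: str, values_by_group: Mapping[str, Sequence[float]]
) -> GroupFit:
    """Per-group means plus pooled within-group residual variance.

    Groups with a single value contribute their mean but no residual degrees
    of freedom; when no group has two values the residual variance is NaN and
    the gene is excluded from prior estimation.
    """
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    ss = 0.0
    df = 0
    any_values = False
    for group, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        counts[group] = arr.size
        if arr.size == 0:
            means[group] = math.nan
            continue
        any_values = True
        mu = float(arr.mean())
        means[group] = mu
        ss += float(((arr - mu) ** 2).sum())
        df += arr.size - 1
    if not any_values:
        raise ValueError(f"gene {gene}: no values in any group")
    s2 = ss / df if df > 0 else math.nan
    return GroupFit(gene=gene, means=means, counts=counts, s2=s2, df=df)


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    The iteration works on 1/trigamma, which is nearly linear, so convergence
    is fast from the asymptotic starting value x = 0.5 + 1/y.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += step
        if abs(step) < tol * x:
            break
    return x


def estimate_prior(
    s2: Iterable[float], df: Iterable[float]
) -> ShrinkagePrior:
    """Estimate (d0, s0^2) by moment matching on log sample variances.

    Under the hierarchical model, log(s_g^2) has a shifted log-chi-square
    distribution whose mean and variance are expressible via digamma and
    trigamma functions; matching the observed dispersion of
    e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2) yields d0, and the
    location yields s0^2.  Zero excess dispersion gives an infinite d0
    (complete shrinkage to a common variance).
    """
    s2 = np.asarray(list(s2), dtype=float)
    df = np.asarray(list(df), dtype=float)
    ok = (df > 0) & (s2 > 0) & np.isfinite(s2)
    s2, df = s2[ok], df[ok]
    n = s2.size
    if n < 2:
        raise ValueError(
            "need at least two genes with positive residual df/variance; "
            "use an ordinary t-test instead"
        )
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(e.mean())
    target = float(np.mean((e - ebar) ** 2 * n / (n - 1) - special.polygamma(1, df / 2.0)))
    if target <= 0:
        # zero excess dispersion: common variance, estimated by the mean
        return ShrinkagePrior(d0=math.inf, s02=float(s2.mean()))
    x = trigamma_inverse(target)
    d0 = 2.0 * x
    if d0 > 1e7:
        return ShrinkagePrior(d0=math.inf, s02=float(s2.mean()))
    s02 = math.exp(ebar + float(special.digamma(x)) - math.log(x))
    return ShrinkagePrior(d0=d0, s02=s02)


@dataclass(frozen=True)
class ModeratedResult:
    log2fc: float
    t: float
    df_total: float
    p: float


def moderated_t(
    fit: GroupFit,
    contrast: ContrastSpec,
    prior: ShrinkagePrior | None,
    group_order: Sequence[str] = GROUPS,
) -> ModeratedResult:
    """Moderated t-test of one contrast for one gene.

    The posterior variance blends the gene's residual variance with the
    prior, weighted by their degrees of freedom; the statistic is referred to
    a t distribution on d0 + d_g df (normal when d0 is infinite).  log2FC is
    the negated contrast estimate on the deltaCt scale.  ``prior=None`` is
    the no-shrinkage (d0 = 0) limit: the ordinary pooled-variance t-test.
    """
    c = np.asarray(contrast.coefficients, dtype=float)
    mu = np.array([fit.means[g] for g in group_order])
    n = np.array([fit.counts[g] for g in group_order], dtype=float)
    used = c != 0
    if np.any(n[used] < 1):
        missing = [g for g, u, ng in zip(group_order, used, n) if u and ng < 1]
        raise ValueError(f"gene {fit.gene}: contrast {contrast.name} needs empty group(s) {missing}")
    beta = float(c[used] @ mu[used])
    u = math.sqrt(float(np.sum(c[used] ** 2 / n[used])))
    dg = fit.df
    s2 = fit.s2 if dg > 0 else 0.0
    if prior is None:
        if dg <= 0:
            raise ValueError(f"gene {fit.gene}: no residual df and no prior")
        s2_post = s2
        df_total = float(dg)
    elif math.isinf(prior.d0):
        s2_post = prior.s02
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s02 + dg * s2) / (prior.d0 + dg)
        df_total = prior.d0 + dg
    se = math.sqrt(s2_post) * u
    t = beta / se if se > 0 else math.inf * np.sign(beta) if beta != 0 else 0.0
    if math.isinf(df_total):
        p = 2.0 * float(sps.norm.sf(abs(t)))
    else:
        p = 2.0 * float(sps.t.sf(abs(t), df_total))
    return ModeratedResult(log2fc=-beta, t=t, df_total=df_total, p=p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_contrasts(
    matrix: pd.DataFrame,
    contrasts: Sequence[ContrastSpec] = DEFAULT_CONTRASTS,
    alpha: float = 0.01,
    genes: Iterable[str] | None = None,
    d0_override: float | None = None,
    fdr_family: str = "per-contrast",
    group_order: Sequence[str] = GROUPS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit all genes, estimate one shared prior, and test every contrast.

    Returns the result table (gene, contrast, log2FC, t, df, p, adj_p,
    significant) and a skip report (gene, contrast, reason).  Genes with zero
    residual variance are floored at the 1st percentile of positive variances
    before moderation (prior estimation uses only strictly positive
    variances).  FDR is adjusted within each contrast across genes by
    default; ``fdr_family="global"`` pools all three families.
    """
    if fdr_family not in ("per-contrast", "global"):
        raise ValueError("fdr_family must be 'per-contrast' or 'global'")
    gene_list = sorted(set(matrix["gene_id"])) if genes is None else sorted(set(genes))
    wanted = set(gene_list)
    grouped = {
        gid: {g: sub[sub["group"] == g]["delta_ct"].to_numpy() for g in group_order}
        for gid, sub in matrix.groupby("gene_id")
        if gid in wanted
    }
    fits: dict[str, GroupFit] = {}
    for gid in gene_list:
        vals = grouped.get(gid, {g: np.array([]) for g in group_order})
        try:
            fits[gid] = fit_group_means(gid, vals)
        except ValueError:
            continue

    s2_all = np.array([f.s2 for f in fits.values() if f.df > 0 and np.isfinite(f.s2)])
    pos = s2_all[s2_all > 0]
    floor = float(np.percentile(pos, 1)) if pos.size else 0.0
    prior: ShrinkagePrior | None
    if d0_override is not None:
        if d0_override == 0:
            prior = None  # ordinary pooled-variance t
        else:
            # location still estimated from the data so moderation is meaningful
            est = estimate_prior(pos, [f.df for f in fits.values() if f.df > 0 and f.s2 > 0])
            prior = ShrinkagePrior(d0=float(d0_override), s02=est.s02)
    else:
        prior = estimate_prior(
            [f.s2 for f in fits.values() if f.df > 0],
            [f.df for f in fits.values() if f.df > 0],
        )

    rows, skips = [], []
    for gid in gene_list:
        fit = fits.get(gid)
        if fit is None:
            for con in contrasts:
                skips.append((gid, con.name, "no data"))
            continue
        fit_use = fit
        if fit.df > 0 and fit.s2 == 0 and floor > 0 and prior is not None:
            fit_use = GroupFit(fit.gene, fit.means, fit.counts, floor, fit.df)
        for con in contrasts:
            try:
                res = moderated_t(fit_use, con, prior, group_order)
            except ValueError as exc:
                skips.append((gid, con.name, str(exc)))
                continue
            rows.append((gid, con.name, res.log2fc, res.t, res.df_total, res.p))
    out = pd.DataFrame(rows, columns=["gene_id", "contrast", "log2FC", "t", "df", "p"])
    if not out.empty:
        if fdr_family == "per-contrast":
            out["adj_p"] = out.groupby("contrast")["p"].transform(lambda s: bh_adjust(s.to_numpy()))
        else:
            out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["adj_p"] < alpha
    else:
        out["adj_p"] = []
        out["significant"] = []
    skipped = pd.DataFrame(skips, columns=["gene_id", "contrast", "reason"])
    return out, skipped
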