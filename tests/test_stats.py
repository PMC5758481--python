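"""Moderated t-statistics, shrinkage prior and FDR adjustment."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats as sps

from sub1_tfscan import (
    DEFAULT_CONTRASTS,
    GeneEffect,
    GroupFit,
    ShrinkagePrior,
    bh_adjust,
    estimate_prior,
    fit_group_means,
    moderated_t,
    run_contrasts,
    simulate_delta_ct_matrix,
    trigamma_inverse,
)

GROUPS = ("IR64_C", "IR64_S", "IR64Sub1_C", "IR64Sub1_S")


def _fit(values):
    full = {g: values.get(g, []) for g in GROUPS}
    return fit_group_means("g", full)


class TestGroupFit:
    def test_hand_least_squares(self):
        # SS = 2 + 2 over df 4 -> pooled variance 1.0
        fit = _fit({"IR64_C": [1, 2, 3], "IR64_S": [3, 4, 5]})
        assert fit.means["IR64_C"] == pytest.approx(2.0)
        assert fit.means["IR64_S"] == pytest.approx(4.0)
        assert fit.s2 == pytest.approx(1.0)
        assert fit.df == 4

    def test_identical_replicates_zero_variance(self):
        assert _fit({"IR64_C": [2, 2, 2]}).s2 == 0.0

    def test_singleton_group_contributes_no_df(self):
        fit = _fit({"IR64_C": [1.0], "IR64_S": [3, 4, 5]})
        assert fit.df == 2

    def test_empty_gene_raises(self):
        with pytest.raises(ValueError):
            _fit({})


class TestPrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = estimate_prior([0.04] * 200, [8] * 200)
        assert math.isinf(prior.d0)
        assert prior.s02 == pytest.approx(0.04, rel=1e-6)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(2024)
        d0, s02, dg, G = 4.0, 0.04, 8, 5000
        true_var = s02 * d0 / rng.chisquare(d0, G)
        s2 = true_var * rng.chisquare(dg, G) / dg
        prior = estimate_prior(s2, [dg] * G)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s02 == pytest.approx(s02, rel=0.10)

    def test_single_gene_raises(self):
        with pytest.raises(ValueError, match="ordinary t"):
            estimate_prior([0.1], [4])

    def test_trigamma_inverse_roundtrip(self):
        for x in (0.05, 0.5, 2.0, 17.0, 400.0):
            y = float(special.polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestModeratedT:
    def test_hand_example(self):
        # beta=1, u=sqrt(2/3), s2=s02=1, d0=dg=4 -> posterior s2=1, t=sqrt(3/2)
        fit = GroupFit(
            "g",
            {"IR64_C": 0.0, "IR64_S": 1.0, "IR64Sub1_C": math.nan, "IR64Sub1_S": math.nan},
            {"IR64_C": 3, "IR64_S": 3, "IR64Sub1_C": 0, "IR64Sub1_S": 0},
            1.0,
            4,
        )
        res = moderated_t(fit, DEFAULT_CONTRASTS[0], ShrinkagePrior(4.0, 1.0))
        assert res.t == pytest.approx(math.sqrt(1.5), abs=1e-10)
        assert res.df_total == 8
        assert res.log2fc == pytest.approx(-1.0)
        assert res.p == pytest.approx(2 * sps.t.sf(math.sqrt(1.5), 8), abs=1e-12)

    def test_infinite_prior_df_is_a_z_test(self):
        fit = GroupFit(
            "g",
            {"IR64_C": 0.0, "IR64_S": 1.0, "IR64Sub1_C": math.nan, "IR64Sub1_S": math.nan},
            {"IR64_C": 3, "IR64_S": 3, "IR64Sub1_C": 0, "IR64Sub1_S": 0},
            5.0,  # ignored under full shrinkage
            4,
        )
        res = moderated_t(fit, DEFAULT_CONTRASTS[0], ShrinkagePrior(math.inf, 1.0))
        assert res.t == pytest.approx(1.0 / math.sqrt(2.0 / 3.0))
        assert res.p == pytest.approx(2 * sps.norm.sf(res.t), abs=1e-12)

    def test_no_prior_is_ordinary_pooled_t(self):
        rng = np.random.default_rng(3)
        vals = {g: rng.normal(size=3) for g in GROUPS}
        fit = fit_group_means("g", vals)
        res = moderated_t(fit, DEFAULT_CONTRASTS[0], None)
        # oracle: direct pooled two-sample t over the contrast
        diff = vals["IR64_S"].mean() - vals["IR64_C"].mean()
        se = math.sqrt(fit.s2 * (1 / 3 + 1 / 3))
        assert res.t == pytest.approx(diff / se, abs=1e-12)
        assert res.df_total == fit.df

    def test_missing_required_group_raises(self):
        fit = _fit({"IR64_C": [1, 2]})
        with pytest.raises(ValueError, match="empty group"):
            moderated_t(fit, DEFAULT_CONTRASTS[0], ShrinkagePrior(4.0, 1.0))


class TestBH:
    def test_step_up_example(self):
        # direct enumeration: min_k>=i p_(k) * m / k
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_step_up_on_random_input(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=37)
        order = np.argsort(p, kind="stable")
        m = len(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            expected[order[rank]] = running
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_monotone_in_sorted_order_and_dominates_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        assert (np.diff(q[np.argsort(p, kind="stable")]) >= -1e-12).all()
        assert (q >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestRunContrasts:
    def test_sign_convention_examples(self):
        # submerged deltaCt 0.5 cycles above control -> log2FC -0.5 (down)
        rows = []
        rng = np.random.default_rng(0)
        for gid in ("gA", "gB", "filler1", "filler2", "filler3"):
            for g in GROUPS:
                base = {"gA": {"IR64_S": 3.5}.get(g, 3.0),
                        "gB": {"IR64Sub1_C": 2.32, "IR64Sub1_S": 2.32}.get(g, 2.0)}[gid] \
                    if gid in ("gA", "gB") else 1.0
                for rep in range(3):
                    noise = 0.0 if gid in ("gA", "gB") else rng.normal(0, 0.2)
                    rows.append((gid, g, 1, rep + 1, base + noise))
        mat = pd.DataFrame(rows, columns=["gene_id", "group", "plate", "replicate", "delta_ct"])
        de, _ = run_contrasts(mat)
        de = de.set_index(["gene_id", "contrast"])
        assert de.loc[("gA", "SubmergenceIR64"), "log2FC"] == pytest.approx(-0.5, abs=1e-9)
        # sum-form genotype contrast doubles the per-condition difference
        assert de.loc[("gB", "Genotype"), "log2FC"] == pytest.approx(-0.64, abs=1e-9)

    def test_equal_means_give_zero_log2fc(self):
        mat = simulate_delta_ct_matrix(10, tech_sd=0.0, seed=1)
        de, _ = run_contrasts(mat, d0_override=math.inf)
        np.testing.assert_allclose(de["log2FC"], 0.0, atol=1e-12)

    def test_scale_equivariance(self):
        mat = simulate_delta_ct_matrix(30, tech_sd=0.3, seed=12)
        de1, _ = run_contrasts(mat)
        scaled = mat.assign(delta_ct=mat["delta_ct"] * 3.0)
        de2, _ = run_contrasts(scaled)
        np.testing.assert_allclose(de2["log2FC"], 3.0 * de1["log2FC"], rtol=1e-8)
        np.testing.assert_allclose(de2["t"], de1["t"], rtol=1e-8)
        np.testing.assert_allclose(de2["p"], de1["p"], rtol=1e-6)

    def test_skips_are_reported_not_fatal(self):
        mat = simulate_delta_ct_matrix(10, tech_sd=0.2, seed=2)
        mat = mat[~((mat["gene_id"] == "TF0001") & (mat["group"] == "IR64_S"))]
        de, skipped = run_contrasts(mat)
        assert ("TF0001", "SubmergenceIR64") in set(zip(skipped["gene_id"], skipped["contrast"]))
        assert not de.empty


def test_moderated_results_match_limma_oracle(tmp_path):
    """Independent cross-check against the reference empirical-Bayes
    implementation (limma, via Rscript) on one small matrix."""
    rng = np.random.default_rng(99)
    n_genes, reps = 60, 3
    # heteroscedastic gene variances (scaled inverse chi-square, d0=6) so the
    # estimated prior df is finite and the t reference distribution is the
    # plain d0 + d_g t-distribution on both sides of the comparison
    gene_sd = np.sqrt(0.16 * 6.0 / rng.chisquare(6.0, size=n_genes))
    data = 5.0 + rng.normal(size=(n_genes, 4 * reps)) * gene_sd[:, None]
    data[:5, reps:2 * reps] += 1.0  # a few real effects
    genes = [f"g{i:03d}" for i in range(n_genes)]
    wide = pd.DataFrame(data, index=genes)
    wide.to_csv(tmp_path / "mat.tsv", sep="\t", header=False)

    rscript = textwrap.dedent(
        """
        suppressMessages(library(limma))
        args <- commandArgs(trailingOnly=TRUE)
        x <- as.matrix(read.delim(args[1], header=FALSE, row.names=1))
        groups <- factor(rep(c("IR64_C","IR64_S","IR64Sub1_C","IR64Sub1_S"), each=3),
                         levels=c("IR64_C","IR64_S","IR64Sub1_C","IR64Sub1_S"))
        design <- model.matrix(~0+groups)
        colnames(design) <- levels(groups)
        fit <- lmFit(x, design)
        cm <- makeContrasts(SubmergenceIR64=IR64_S-IR64_C,
                            SubmergenceIR64Sub1=IR64Sub1_S-IR64Sub1_C,
                            Genotype=(IR64Sub1_S+IR64Sub1_C)-(IR64_S+IR64_C),
                            levels=design)
        fit2 <- eBayes(contrasts.fit(fit, cm))
        out <- data.frame(gene=rownames(x),
                          coef=fit2$coefficients[,1], t=fit2$t[,1], p=fit2$p.value[,1],
                          d0=fit2$df.prior, s02=fit2$s2.prior)
        write.table(out, args[2], sep="\t", quote=FALSE, row.names=FALSE)
        """
    )
    (tmp_path / "oracle.R").write_text(rscript)
    subprocess.run(
        ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path / "mat.tsv"), str(tmp_path / "out.tsv")],
        check=True,
        capture_output=True,
    )
    oracle = pd.read_csv(tmp_path / "out.tsv", sep="\t").set_index("gene")

    rows = []
    for i, gid in enumerate(genes):
        for j, g in enumerate(GROUPS):
            for rep in range(reps):
                rows.append((gid, g, 1, rep + 1, data[i, j * reps + rep]))
    mat = pd.DataFrame(rows, columns=["gene_id", "group", "plate", "replicate", "delta_ct"])
    de, _ = run_contrasts(mat)
    ours = de[de["contrast"] == "SubmergenceIR64"].set_index("gene_id")

    np.testing.assert_allclose(-ours["log2FC"], oracle["coef"], atol=1e-8)
    np.testing.assert_allclose(ours["t"], oracle["t"], rtol=1e-4)
    np.testing.assert_allclose(ours["p"], oracle["p"], rtol=1e-3, atol=1e-12)
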