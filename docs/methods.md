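# Methods

## Experimental design being modelled

The pipeline assumes a plate-based qPCR profiling design: a fixed panel of
target genes distributed over multi-well plates (default 384 wells), each
plate reserving 12 wells for three reference genes in quadruplicate and 4
wells for negative water controls, leaving 368 target wells. Four sample
groups are measured — IR64 control/submerged and IR64-Sub1
control/submerged — and every plate is run once per group and technical
replicate (default 3). The statistical unit is the technical replicate;
biological replication is not modelled, because the design pools plant
material into one sample per group. The documentation of the statistical
stage should be read with that caveat: p-values quantify technical, not
biological, reproducibility.

## Quality control and normalization

A reaction is kept iff its Ct is numeric, below the ceiling (default 40
cycles) and its amplification R² is at least 0.995; rejected rows carry one
reason, with "undetermined" taking precedence over "low R²". The boundary
R² = 0.995 is kept, reading the exclusion rule as a strict inequality.

ΔCt = Ct_target − mean(Ct_reference) is computed plate-locally. The
reference mean is run-local by default: each technical run is normalized by
its own quadruplicate of the working reference gene (actin). The pooled
alternative (`per_run=False`) shares one reference mean across a
plate/group's runs; it was rejected as the default because a shared
reference error is invisible to the within-group variance and makes the
downstream t-tests anticonservative, whereas run-local normalization adds
an independent σ²/4 to every replicate and leaves the tests calibrated.
Ct values are used untransformed by default; a `log2_ct` switch applies a
log2 transform first for fidelity experiments, but the ΔCt arithmetic and
the magnitude of typical log2FC values are consistent with untransformed
cycles, so the switch is off unless requested. The two non-working
reference genes pass through QC as ordinary platform genes.

Eligibility requires at least `min_values` (default 2) ΔCt replicates in
*both* conditions of a genotype — the strictest consistent reading of
"at least two values in both genotypes and both conditions".

## Moderated t-tests

Per gene, a group-means linear model gives means μ_j, replicate counts
n_j, pooled residual variance s²_g and residual df d_g = Σ_j max(n_j−1, 0).
The empirical-Bayes prior (d₀, s₀²) is estimated by the closed-form moment
matching of log sample variances: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess dispersion of e over its
theoretical log-χ² variance determines d₀ through inversion of the
trigamma function (Newton iteration on 1/ψ′, start x = 0.5 + 1/target,
relative tolerance 1e-8), and the location determines s₀². When the excess
dispersion is non-positive or d₀ exceeds 1e7, d₀ is declared infinite and
s₀² is the arithmetic mean of the sample variances — the behaviour of the
reference implementation in that branch, which differs slightly from
exp(ē); the finite branch uses s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)).

The moderated statistic uses the posterior variance
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and is referred to a t distribution
on d₀ + d_g df; the normal tail is used when d₀ is infinite (no cap at the
pooled residual df — the cap matters only in the complete-shrinkage regime
and the uncapped form follows directly from the model). Genes with zero
residual variance are floored at the 1st percentile of the positive
variances before moderation; prior estimation uses only strictly positive
variances with d_g > 0. The d₀ = 0 limit reproduces the ordinary
pooled-variance contrast t exactly and is exposed via `d0_override=0`.

Contrasts are the two submergence differences and the *sum-form* genotype
contrast (−1, −1, +1, +1), implemented literally: its estimate is twice
the mean per-condition genotype difference. log2FC = −(c·μ), so genes whose
Ct (hence ΔCt) rises under treatment — lower expression — report negative
log2FC. FDR is Benjamini–Hochberg, adjusted within each contrast across
genes (three families), since results are reported per contrast; a global
family is available for sensitivity analysis. BH step-up adjustment is
monotone in sorted order but not idempotent; re-adjusting adjusted
p-values is meaningless and not supported as an invariant.

Category assignment: common (both submergence contrasts significant),
submergence_IR64 / submergence_IR64Sub1 (exactly one), genotype_specific
(only the genotype contrast), not_significant, unclassifiable (missing
contrast). A gene significant in a submergence contrast *and* the genotype
contrast keeps its submergence category with an `also_genotype` flag rather
than a fifth class, preserving the four reported buckets.

## Promoter cis-element analysis

Alleles are aligned globally with affine gap scoring (match +2, mismatch
−1, open −5, extend −1) through Biopython's pairwise aligner; of the
co-optimal alignments the aligner's first is used, which is deterministic
for fixed inputs (an exact diagonal-then-up tie-break is not exposed by the
library and the distinction never matters for substitution-only allele
pairs). Pre-computed aligned FASTA pairs are accepted and validated.
Mismatch columns become substitution records; runs of gap columns in the
same allele merge into single indel records. Positions are 0-based
half-open internally, 1-based inclusive in reports; TSS distances are
hit start − TSS, negative upstream.

Motif scanning is exhaustive IUPAC consensus matching on both strands
(minus strand scanned on the reverse complement and mapped back).
Sequence bases outside A/C/G/T match only the N symbol. A motif gain at a
substitution SNP requires the hit window to *cover* the SNP base in the
gaining allele with no same-motif/strand hit covering the homologous
column in the other allele — elements merely near a SNP are not
attributed to it. Indel SNPs are reported but not motif-called, since
coordinates of the missing base are undefined in one allele. Motif
frequency tables count gene-level presence (≥ 1 hit on either strand),
bounded by group size.

The catalog ships as an editable TSV of 34 PLACE-style entries (name,
IUPAC consensus, category). Consensus strings were transcribed from the
public PLACE compilation; only the two truncated telo-boxes (ACCCTA,
AAACCCT) have printed consensi in the source literature, so the remaining
entries are data, reviewable and replaceable without code changes.

`synthetic_promoter_alleles()` returns a constructed (synthetic) allele
pair — not real promoter sequences — with thirteen substitution SNPs of
which exactly five create allele-specific elements mirroring the
*SUB1A-1*/*SUB1A-2* structure: Site I (SNP4), CARE (SNP5) and TSS-proximal
Site II (SNP13) in allele A; minus-strand ABRE (SNP3), DRE/CRT core (SNP5,
the same site as the CARE gain in A) and TSS-distal Site II (SNP9) in
allele B; truncated telo-boxes sit near the Site II elements in both
alleles. The Site I octamer contains a G-box core, so SNP4 also gains the
G-box-containing IRO2 element — an expected overlap of that motif family.

## Synthetic data generator

`simulate_experiment` emits one reaction per gene × group × replicate with
Ct = baseline + group shift + N(0, tech_sd), plus reference quadruplicates
and water wells per plate run. Defaults mirror the modelled study: 2487
genes, 384-well plates (seven needed at that panel size), 3 technical
replicates, 3 reference genes, 4 water wells, baseline Ct uniform on
[20, 34] with a 5% low-expressor fraction near the 40-cycle ceiling
(producing realistic "undetermined" dropout), technical noise 0.25 cycles,
2% QC-failure probability (R² drawn below 0.995), amplification
efficiencies N(1.85, 0.05) recorded but unused downstream, matching a
protocol that logs them without efficiency correction. Planted effects are
expressed in ΔΔCt cycles: submergence effects shift the submerged group of
one genotype; the genotype effect shifts both IR64-Sub1 groups, so it
appears doubled on the sum-form contrast (the truth table reports the
contrast-scale value). Reference genes always carry zero effect. A fixed
seed gives byte-identical output.

What the generator does **not** emulate: amplification-curve shapes (Ct,
efficiency and R² are drawn, not fit), spatial plate effects, inter-plate
calibrators, biological replication, and correlated gene-gene variation.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the design's noise model, not robustness to
real-world artefacts such as plate gradients or sample swaps.

`simulate_delta_ct_matrix` bypasses plates and QC and draws ΔCt replicates
directly at exactly `tech_sd` noise — the stated conditions for the
calibration, recovery and prior-estimation simulations, where replicate
noise must equal the nominal value rather than include reference-well
noise.

## Problem sizes and numerical choices

The packaged simulations use 1000 genes × 20 seeded runs for null
calibration and planted-effect recovery, 5000 genes for prior recovery,
100 random small matrices for the d₀ = 0 equivalence (tolerance 1e-10),
and 1000 random sequences against the brute-force scanner oracle — sizes
at which the binomial/Monte-Carlo error of each check is well below its
acceptance band. The study-scale demonstration in `scripts/acceptance.py`
runs the full plate pipeline at 2487 genes with a planted partition of
26 + 19 (13 up / 6 down) + 1 + 4 genes; its planted magnitudes are 1.5
cycles (submergence) and 1.0 (genotype) so that the partition is
recoverable with high power at three technical replicates under run-local
reference noise — about a 3-fold expression change. Real effect sizes in
this kind of data can be far smaller; detecting them at this replication
level requires correspondingly lower platform noise.

## Known limitations

- Reproduction of the published gene counts requires the article's
  supplementary plate tables and promoter sequences, which have no public
  accession; the pipeline ingests such exports via a column-mapping reader
  but cannot ship them.
- PLACE consensus strings beyond the telo-boxes are transcribed catalog
  data; motif-frequency results depend on them and on the upstream
  sequence version used.
- Whether FDR was originally controlled per contrast or globally is not
  determinable; per-contrast is the default here, not a claim about the
  original analysis.
- Position-weight-matrix scoring, motif discovery, reference-gene
  stability selection and efficiency-corrected quantification are out of
  scope.
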