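# Methods

## The model

The package targets a paired observational design: obese patients
sampled before and after bariatric surgery, with a baseline diagnosis
(MDD vs non-MDD by structured interview) and a continuous severity score
(MADRS, 0–60 points) at both timepoints.  The scientific object is a
*composite transcription-factor z-score*: for a regulator with target
set T (e.g. ChIP-seq-derived targets of TP53, NR3C1 or RELA), each
expressed target gene is standardized over the analyzed cohort,

    z(g, i) = (x(g, i) − μ_g) / σ_g,

with μ_g the cohort mean and σ_g the **population** SD (divisor n, not
n − 1) of gene g's log2 expression, and the biomarker is the unweighted
mean of z over the usable targets.  Standardization makes the score
invariant to gene-wise affine rescaling of the raw intensities (tested),
so platform-level gain differences cannot move it.

Two standardization cohorts are supported.  The default standardizes
baseline and post-surgery arrays jointly, which places pre and post
scores on one scale — necessary for the group × surgery ANOVA and the
delta regression.  A `baseline-only` mode standardizes over the 33
baseline arrays alone; it is offered for sensitivity analysis because
either convention is defensible when only baseline inference is wanted.

## Stages around the biomarker

* **Quantile normalization** forces every sample onto the mean vector of
  order statistics; within-sample ties receive the interpolated mean of
  their tied quantile values (the convention of the standard microarray
  implementations), which makes the operation idempotent.
* **Expressed-gene filter**: median ≥ `min_median` (default 1.0 log2
  units) and across-sample SD strictly > `min_sd` (default 0).  The
  strict inequality guarantees σ > 0 for every gene that reaches
  z-scoring.  The surviving genes define the universe for gene-set
  statistics.  The original study's exact thresholds are not public;
  these defaults are the package's own.
* **Latent-factor adjustment** (optional, default off): subtract the
  projection onto the top-k principal components of the residual after
  removing group × timepoint means.  This is a deliberate simplification
  of factor-analytic multiple-testing adjustment: same goal (reduce the
  correlation structure that distorts FDR), transparent mechanics.
* **sPLS selection**: per component, the X-loading is the soft-thresholded
  covariance between standardized genes and the standardized response,
  with the threshold set by order statistic so exactly `keep_x` loadings
  survive (ties broken by gene id for determinism); X is deflated by its
  own scores (regression mode), the response is not.  One component is
  the default because the use case is selection, not prediction.  With
  one component the selected set provably equals the `keep_x` genes of
  largest |cov(gene, y)| — tested against a brute-force ranking oracle.
* **Differential expression**: Welch t per gene by default; a
  `moderated` mode shrinks gene variances toward a pooled prior
  (moment-matched on log sample variances, df increased accordingly) for
  users who want limma-flavored behavior without the full machinery.
  Paired contrasts use one-sample t on within-patient differences;
  patients lost to follow-up are excluded and counted.  All-zero
  difference genes are reported as t = 0, p = 1 with a `degenerate`
  flag.  BH step-up FDR is applied over all tested genes.
* **Upstream regulators**: overlap p is the hypergeometric upper tail
  (≡ one-sided Fisher exact); the activation z-score is
  (n_consistent − n_inconsistent)/√N over targets with a known expected
  direction (read from `+`/`−` suffixes in the GMT).  The conventional
  raw cutoff p < 0.001 is reported alongside BH q-values across
  regulators.  This is an open re-implementation of the commercial
  "upstream regulator analysis" idea; proprietary curated networks and
  their weighted z-scores are out of scope.
* **Transcript origin analysis**: diagnosticity = row-centered reference
  expression (difference, not ratio — the original method's
  normalization is not published; this choice keeps row sums exactly
  zero and is shift-invariant, both tested).  The bootstrap null draws
  equally sized gene lists **without replacement** from the scored
  universe; p is +1-smoothed so it can never be zero, with exact ties
  counted half (relevant only in degenerate cases such as testing the
  entire universe against itself).  The test is one-sided
  (overrepresentation), applied separately to up- and downregulated
  lists.

## The validation layer

The group × surgery ANOVA uses Type II sums of squares because the
post-dropout design is unbalanced and no main-effect hypothesis is
subordinated to the interaction; Type III is switchable.  Timepoint is
treated as a between-cell factor, matching the plain two-way analysis
convention for this design; a repeated-measures treatment is a possible
extension, not the default.  Post hocs are the four contrasts of
interest (group difference within each timepoint, surgery difference
within each group), t-tested against the model MSE with ×4 Bonferroni.

Regressions standardize all variables, so the score's coefficient is the
standardized β (the Pearson r in the crude model) and the score's
partial F equals t².  The remission delta regression uses
MADRS_pre − MADRS_post (positive = improvement) on score_pre − score_post
over complete pairs only.

## The synthetic cohort

The generator emulates the study conditions: 33 patients, 15 MDD
(45.45% prevalence), 9 lost to follow-up (4 MDD / 5 non-MDD), and
group × timepoint MADRS drawn from normals with the published means/SDs
(19.00 ± 3.87 and 6.56 ± 3.59 at baseline; 6.36 ± 5.09 and 2.08 ± 3.29
after surgery), truncated at zero because MADRS is non-negative.  Each
regulator r has a per-sample latent activation

    a_r(i) = α_r · zMADRS(i) + ε,   ε ~ N(0, 1),

with zMADRS standardized across all samples, so post-surgery remission
propagates to the biomarker by construction.  Target genes read
baseline_g + u_g(patient) + b_g·a_r(i) + N(0, noise_sd) with b_g drawn
positive U(0.5, 1.5); non-targets drop the coupling term.  Defaults:
1000 genes, 3 regulators × 40 targets, noise_sd = 0.5 log2 units,
patient offset SD 0.3, baseline N(7, 1.5).  The expression-scale effect
sizes have no published values; α defaults to 1.5 (chosen for test
power, not realism) and 0 gives the exchangeable null used for
calibration.  One seed drives everything; reference matrices use a
deterministically derived sub-stream.

What the generator does **not** emulate: microarray noise physics (dye
bias, spatial artifacts), batch structure, cell-proportion confounding
of the bulk signal (the optional mixture mode only ties regulator
targets to cell-type marker blocks so transcript origin analysis has a
truth to find), or cytokine measurements.  Passing tests therefore
demonstrate correctness of the statistical machinery and its calibration
under this generative model — not that the biomarkers generalize to any
real cohort.

## Calibration and a known power ceiling

Under the null (α = 0) the composite-score regression rejects at ~5%
(measured 3.5% over 200 seeds at seed 1) and the DE stage's average
false-discovery proportion at FDR 0.05 stays at ~0.05.  Under strong
coupling (α = 1.5) the causal regulator's score correlates with MADRS at
median r ≈ 0.84 and the delta regression detects remission coupling in
~98% of runs at 24 pairs.

The group × surgery interaction is different: the latent's unit
innovation ε and the within-cell MADRS scatter are both irreducible
noise for a cell-means contrast, and at 15/18/11/13 observations per
cell they cap the interaction's noncentrality near 2.4 — about 50%
power at p < 0.01 *even when the true latent a_r is tested directly*.
The composite score inherits this ceiling (measured 44–56% across seed
ranges).  A materially higher rate at this sample size would indicate a
miscalibrated test, not a better biomarker.

## Problem sizes

Monte-Carlo summaries use 240-gene cohorts (2000 genes for the FDR
study), 20 seeds for recovery medians, 50 for power estimates and 200
for null calibration — sizes at which every quantity above is stable to
within binomial noise while the whole suite stays interactive.

## Known limitations

* The moderated-t mode is a moment-matched approximation, not the exact
  empirical-Bayes posterior of the reference implementations.
* Activation z-scores ignore target-level confidence weights.
* The ANOVA treats repeated measures as independent cells; with larger
  designs a mixed model would be preferable.
* GMT direction annotation (`+`/`−` suffixes) is a package convention;
  undirected targets contribute to overlap but not to activation z.
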