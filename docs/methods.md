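# Methods

This note documents the statistical procedures, the synthetic-data
model, the numerical choices, and the known limitations of the package.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Microbiome preparation

Counts are taxa × samples integers. QC drops samples with library size
below 10,000 reads and zeroes individual cells with 0 < count < 10,
dropping taxa left all-zero. The "< 10 copies in individual samples"
rule is read as per-cell zeroing — the only reading that is genuinely
per-sample; a whole-taxon variant (`drop_low_abundance_taxa`) is
provided for comparison. OTUs sharing a genus are summed; an unresolved
genus is labelled `unclassified <lowest resolved rank>` so that, e.g.,
family-level rows remain distinguishable.

Rarefaction draws, for each sample, L reads without replacement (L =
minimum library size; multivariate hypergeometric), repeats this (1,000
iterations by default) and averages the tables cell-wise. Averages are
left real-valued; every column sums to L exactly. Alpha diversity
(observed richness, Shannon entropy in nats, Gini–Simpson) is computed
on pre-rarefaction counts. Shannon is reported in natural-log units —
the magnitudes of the reference cohort (≈ 3.15 for its most diverse
community type) are consistent with nats, not bits.

## Clustering

Beta diversity supports Jensen–Shannon divergence (natural log, with
0·log 0 = 0; bounded by ln 2), its square root (a metric), Bray–Curtis,
and Jaccard on presence/absence. The pipeline default is JSD.

PAM is the classical BUILD + SWAP: BUILD greedily accumulates medoids
that minimise total cost; SWAP repeatedly applies the single best
strictly-improving medoid/non-medoid exchange. All ties break to the
smallest sample index and assignment ties go to the smallest-index
medoid, so the procedure is deterministic without a seed. BUILD + SWAP
is a local search: on unstructured points it can stop in the same local
optima as R's `cluster::pam` (the test suite verifies cost-level
agreement with that implementation); global optimality holds in practice
on separated clusters, which is what the k-selection indices reward
anyway.

k is selected as the argmax of the mean silhouette over k = 2..10 (ties
to the smaller k), with the Calinski–Harabasz index reported for
inspection; CHI is computed on the classical principal-coordinate
embedding of the dissimilarity (double-centred Gram matrix, positive
eigenvalue axes), which reproduces the standard CHI exactly for
Euclidean inputs. Silhouette assigns s = 0 to singletons and to the
degenerate 0/0 case. Leave-one-out stability drops each sample, re-runs
k-selection and PAM, assigns the held-out sample to its nearest medoid,
and scores the full-length labelling against the all-samples solution
with the adjusted Rand index (held-out sample included). Clusters are
renamed by decreasing size, ties by smallest original medoid index.

## EWAS

M = log₂(β/(1−β)); regressions run on the M scale. The design uses
cell-means cluster indicators (no intercept) so every pairwise contrast
is a plain coefficient difference; covariates are sex, age, BMI z-score,
race/ethnicity (one-hot, reference dropped), maternal education, four
season harmonics sin/cos(2π d/365.25) and sin/cos(4π d/365.25) (annual
and biannual trends; a two-term variant is selectable), batch
indicators, ReFACTor components, and optional extras (e.g. medication
use as a sensitivity covariate). The design is checked for full column
rank.

The robust fit is Huber IRLS (c = 1.345) vectorised across CpGs: scale
ŝ = 1.4826 × median |r| per CpG per iteration, weights
w = min(1, cŝ/|r|), batched weighted normal equations, iterated to
coefficient convergence (non-converged CpGs fall back to OLS with a
warning). The residual variance is the Huber-weighted RSS divided by
(n − p)(2Φ(c) − 1); the (2Φ(c) − 1) factor is the Gaussian expectation
of min(z², c|z|) and keeps the t statistics calibrated — without it the
weighted RSS under-estimates σ² by ~18% and genome-wide family-wise
error is grossly inflated. Degrees of freedom are n − p with no
weight-based correction. Contrast SEs come from the weighted normal
equations; a cross-check against `statsmodels` RLM on single responses
is part of the suite.

Empirical-Bayes moderation (default on; the choice of moderated versus
ordinary robust t is exposed) fits a scaled-F prior to the s² by moment
matching on log s² (digamma/trigamma identities, trigamma inverse by
Newton), yielding posterior variances (d₀s₀² + d s²)/(d₀ + d) and
d₀ + d degrees of freedom; the fit is verified against R
`limma::squeezeVar` in the tests. Global significance is Bonferroni
over CpGs × contrasts with a strict inequality (the published cohort's
scale, 0.05/(715,023 × 15), gives the raw-p cut 4.66 × 10⁻⁹); pooled
Benjamini–Hochberg is available for enrichment-style inputs. A DMP is a
CpG significant in at least one contrast.

Inflation reporting: λ = median(z²)/χ²₁(0.5) with z the probit transform
of two-sided p (signed by t). The empirical-null location/scale — the
analogue of a Bayesian inflation factor — is the median and MAD of z on
the central 90%, with the MAD consistency constant for a ±q₀.₉₅
truncated normal (Φ⁻¹(0.725)); this replaces the original Gibbs-sampler
estimator with a far simpler robust estimator of the same estimand (the
null scale).

Effect conversion uses the M-model-M-mean rule as a one-sided logistic
difference at the CpG's mean M: Δβ = σ(M̄ + ΔM) − σ(M̄),
σ(m) = 2^m/(1+2^m); a centred ±ΔM/2 variant can be obtained by calling
the converter at shifted reference points.

### Permutation empirical null

Each permutation shuffles cluster labels uniformly (covariates fixed),
re-runs the robust EWAS and contrasts, and counts DMPs. The empirical
p-value uses the strict-exceedance formula
(1 + #{permuted > observed})/(B + 1), exactly as published, with B = 500
by default in the pipeline. One property deserves emphasis: with a
strict ">" the p-value is only super-uniform when the count statistic is
effectively untied. Under a genome-wide Bonferroni rule null DMP counts
are almost always zero, ties dominate, and the "p-value" concentrates
near (1 + small)/(B + 1) regardless of the data — a property of the
published formula, not of this implementation. The `alpha_rule`
parameter therefore selects the DMP-counting rule: `bonferroni` (the
pipeline default, matching the published analysis) or `nominal`
(per-test α, giving a continuously varying count), and the calibration
test in the acceptance suite uses the nominal rule, where
super-uniformity genuinely holds.

## Methylation utilities

Winsorization is per CpG: values below the 5th / above the 95th
linear-interpolation quantile are replaced by the nearest observed value
inside the band (not by the quantile itself). The quantile rule is
linear interpolation between order statistics — the most common default;
the source procedure does not state one.

ReFACTor uses k = 10 components and t = 500 selected sites (t is the
original algorithm's default; only k is stated by the reference
workflow): standardize CpG rows, score each row by the distance to its
rank-k SVD reconstruction, keep the t best-reconstructed sites, and take
the first k principal-component scores of that submatrix.

The meQTL-style screen groups a CpG's Beta values with exact 1-D k-means
(k ∈ {2,3}). In one dimension optimal k-means clusters are intervals, so
the global optimum is found by dynamic programming over cut points; this
replaces quantile-initialised Lloyd iteration, which is not guaranteed
to reach the optimum the screen's validity argument assumes, while
remaining deterministic. Group × cluster independence is tested by
Pearson chi-squared without continuity correction, with a warning when
any expected cell is below 5 and a skip flag for constant input.

## Differential abundance

The model is a deliberately simplified bias-corrected log-linear
regression, not a reimplementation of ANCOM-BC2: y = ln(count +
pseudo-count), per-sample offset = median over taxa of the row-centred
y (absorbing sample-specific sampling fractions exactly, as the tests
verify by rescaling columns), then per-taxon least squares of the
offset-corrected y on the exposure plus covariates. Iterative bias
estimation, structural-zero detection and mixed directional FDR are
intentionally out of scope; the estimand (covariate-adjusted
compositional logFC), the pseudo-count sensitivity scheme and the
per-exposure BH families are preserved. Methylation exposures are scaled
to IQR units; EAD exposures stay in years. The pseudo-count array is
{0.1, 0.5, 1.0} with 1.0 primary (the reference analysis names an
"array" without values); sensitivity passes when q < 0.05 with a
consistent sign at every pseudo-count.

## Epigenetic age

The clock is a linear predictor over Beta values with the pan-tissue age
transform: the inverse applied to the linear predictor L is
(adult_age+1)·e^L − 1 for L < 0 and (adult_age+1)·L + adult_age
otherwise, with adult_age = 20. Coefficients are caller-supplied (the
online calculator's internal renormalization is out of scope). At least
80% of weighted CpGs must be present; the remainder contribute their
weight times the cohort-mean Beta, with a logged warning. EAD is the
residual of a simple least-squares regression of epigenetic on
chronological age; cluster contrasts come from a cell-means linear model
with covariates, and taxon associations delegate to the
differential-abundance model with EAD (years) as exposure.

## Synthetic cohorts

The generator reproduces the data structure the analysis assumes, at the
reference cohort's published conditions:

- **Samples.** n = 372, six clusters with proportions 120/83/79/41/33/16.
  Covariates: sex ~ Bernoulli(0.51), age ~ N(13.0, 0.7) years, BMI
  z-score ~ N(0.44, 1.10), race/ethnicity at the published proportions,
  maternal education ~ Bernoulli(0.69), collection day uniform over the
  year, four assay batches.
- **Microbiome.** 39 genera. Six archetypes with the published dominant
  structure (Corynebacterium 0.67; Propionibacterium 0.50;
  Staphylococcus 0.65; Staphylococcus 0.14 + Streptococcus 0.16 diverse;
  unclassified Neisseriaceae 0.38; Moraxella 0.57); each archetype
  reserves 6% of its mass as a uniform background over its unlisted
  genera so every sample carries a rare biosphere that survives the
  10-copy QC rule and the ≥ 15% prevalence filter keeps all 39 genera.
  Genus proportions per sample ~ Dirichlet(50 × archetype) — the
  concentration is a modelling choice (within-cluster dispersion is not
  published) exposed as a parameter; depths are log-uniform on
  10,000–50,000 reads; counts are multinomial.
- **Methylation.** Baseline per-CpG mean M from a hypo/hemi/hyper
  mixture (−3/0/+3 ± 0.4); planted cluster effects add ΔM to the first
  cluster of their contrast pair at hemi-methylated baselines (default
  ΔM ±0.3–0.8, Beta differences ≈ 5–13 pp, the upper range of published
  cluster effects); taxon links add slope × centred log(relative
  abundance + 10⁻⁶); one latent cell factor loads on 20% of CpGs; i.i.d.
  N(0, 0.3) noise on the M scale; Beta = logistic₂(M) is strictly inside
  (0,1). Default taxon-link slopes (≈ 0.3–0.4 in |M| per log-abundance
  unit) produce realized logFC-per-IQR values near 1.
- **Clock.** Target ages = chronological age + N(0, 3.5 years) + a
  planted taxon effect (default Corynebacterium, −0.5 years per centred
  log abundance — a deliberately marginal effect, matching the marginal
  significance of the corresponding published finding). Dedicated clock
  CpGs get Beta profiles linear in the transformed target age and
  weights/intercept solved so the clock reproduces the targets exactly;
  with zero noise and no taxon effect the clock returns chronological
  age to machine precision.
- **Reproducibility.** One seed per cohort; per-stage child streams are
  spawned deterministically, so equal seeds give byte-identical fixture
  bundles.

What the generator does **not** emulate: read-level sequence artefacts,
array probe chemistry and normalization residue, correlated CpG blocks,
genotype-driven trimodal probes, non-Gaussian M-value noise, covariate–
cluster confounding, and real cell-type composition (the latent factor
is a single Gaussian surrogate). Passing tests therefore demonstrate
statistical correctness and calibration of the machinery under the
assumed model — not robustness to every artefact of real cohorts.

## Problem sizes in the test suite

Simulations are sized for a single-core run: cluster recovery uses 50
full-size cohorts; leave-one-out stability uses 100-sample cohorts;
family-wise error control uses 200 null cohorts at 2,000 CpGs × 15
contrasts; permutation calibration uses 40 null runs at B = 99
(scaled from the pipeline's B = 500); differential-abundance recovery
uses 20 full-size cohorts with 39-genus families; clock checks use 30
cohorts. The acceptance suite documents each check in its docstring.

## Known limitations

- The robust-fit covariance is the weighted-normal-equations form with a
  Gaussian consistency correction; it is accurate under near-Gaussian
  errors with sporadic outliers but is not a full sandwich estimator.
- The empirical-null scale is a median/MAD estimator, not the original
  Bayesian formulation; both estimate the null scale but can differ in
  small samples.
- The differential-abundance model shares ANCOM-BC2's estimand, not its
  inference machinery; strong structural zeros or taxon-specific biases
  are outside its assumptions.
- A planted 2-percentage-point Beta difference with M-scale noise SD 0.3
  is an ~2 SE effect at n = 372: it is estimable without bias but not
  detectable at genome-wide thresholds, and the corresponding power
  check in the acceptance suite records this fact.
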