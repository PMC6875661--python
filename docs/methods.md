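# Methods

`invadapt` implements the statistical chain used to ask whether an invasive
population's success reflects niche conservatism or post-introduction
adaptation: niche-overlap statistics in a reduced environmental space,
ensemble distribution models with map-agreement niche-change metrics, dual
genotype–environment outlier detection, generalized dissimilarity modelling
(GDM) of per-locus allelic turnover, and landmark-based wing morphometrics.
This note records the models, the defaults and why they were chosen, what
the synthetic-data generators do and do not emulate, and the numerical
choices that matter.

## Synthetic data

All analyses are exercised on generated data with planted ground truth.

**Environmental stacks.** Layers are Gaussian white noise smoothed with a
Gaussian kernel of width `spatial_range` (in cells, default 6–8), then mixed
through the matrix square root of a target inter-layer correlation matrix.
Fields are standardized to mean 0, SD 1, so regression coefficients on
layers are per-SD effects. Six layers named PRJ, PRS, MTP, ISO, NPP, HF by
default, matching the winter-precipitation / seasonality / cold-temperature
/ isothermality / productivity / human-footprint predictor set typical of
mosquito distribution work.

**Occurrences.** Presence points are drawn from a logistic suitability
surface `expit(b0 + Σ b_i · layer_i)`, with cell probability proportional to
suitability; points sit at cell centres and carry extracted values. There is
no sampling bias, spatial clustering beyond the surface itself, or
positional error — detection of those artefacts is outside what these tests
can show.

**Genotypes.** Biallelic SNPs under a hierarchical island model: ancestral
frequencies `p0 ~ U(0.1, 0.9)`; each of K=3 ancestries draws its frequency
from a Balding–Nichols Beta distribution around `p0` with divergence
parameter `baseline_fst` (default 0.10). Populations (default 90 × 6
individuals, the study scale) are assigned wholly to one ancestry
round-robin, so ancestry is asymptotically uncorrelated with the
environment, and by default share their ancestry's frequency — all
structure lives at the K-group level, which is the regime a K-factor model
can fully absorb. A `within_fst` parameter adds optional nested
population-level divergence beyond what K factors can capture; it defaults
to 0 because the one-level model is the stated design. Causal loci shift
population frequencies on the logit scale by `cline_strength ×`
standardized predictor at the population's cell, clamped to [0.01, 0.99].
Genotypes are Binomial(2, frequency); missingness (default 18.5%, the
study's rate) is completely at random. Monomorphic SNPs are redrawn with a
retry cap. SNPs are grouped into parent RAD loci of random size (mean 2) at
random positions on a 110-bp sequence. Not emulated: linkage
disequilibrium, coalescent genealogical noise, allele-frequency spectra
under selection, or informative missingness — conclusions about those
features do not follow from passing tests.

**Landmarks.** Twenty 2-D landmarks on a wing-like template; individuals are
the template plus a per-group mean displacement plus isotropic Gaussian
landmark noise, scaled by a per-group size effect with log-normal
individual jitter, randomly rotated and translated. No semilandmarks, no
digitizing error model, no allometry beyond the size scalar.

## Niche overlap

Environmental variables are filtered greedily in input order, keeping a
variable iff |Pearson r| < 0.50 against everything already kept. The kept
variables are standardized and decomposed by PCA of the occurrence values;
background cells are projected with the occurrence centering/scaling.

Occupancy densities are computed on an R×R grid (default R=100) of the
first two axes: occurrence and background points are binned and smoothed
with a Gaussian kernel (Silverman's rule per axis by default). The occupancy
density is corrected by background prevalence, `z = o/e` where `e > 0` and 0
elsewhere, then normalized — the standard availability correction; the
uncorrected variant is available via `corrected=False` since sources differ
on which was used. Overlap is Schoener's `D = 1 − 0.5 Σ|z1 − z2|`.

The equivalency test pools the two occurrence sets and reassigns labels
preserving sample sizes; `p = (1 + #{null_D ≤ observed_D})/(n_perm + 1)`,
small when the niches are less interchangeable than chance. The similarity
test holds the reference niche fixed and translates the shifted niche's
occurrence cloud so its centroid lands on a random background point;
translations that push more than 5% of points outside the analysis extent
are resampled (capped, with an error if no admissible shift exists);
`p = (1 + #{null_D ≥ observed_D})/(n_perm + 1)`. The add-one estimator keeps
p in (0, 1]. One degenerate regime is worth knowing: when the shifted niche
fills its whole background, admissible translations are confined near the
original centroid and the null collapses onto the observed D; because any
nonzero translation clips some density, the observed value is the null's
supremum and p is small rather than large — the test is uninformative, not
anticonservative, there. Calibration was verified by simulation: generating
the shifted niche by the test's own relocation process (on a fixed analysis
extent, so observed and permuted draws are exchangeable) yields uniform
p-values.

Niche centroid displacements are reported as raw vectors without a test.

## Ensemble distribution models

Occurrences are thinned to one per raster cell. Pseudo-absences come from
outside a surface range envelope: the per-variable [q, 1−q] interval
(q = 0.025) of presence values; candidate cells fall outside it in at least
one variable, and several independent sets are drawn (defaults 5 × 5,000 at
study scale; smaller in tests). Five model families sit behind a shared
fit/predict-probability contract: a logistic GLM, a cubic-spline additive
logistic model (GAM-like), gradient-boosted trees, an L1-pruned
piecewise-linear hinge logistic model (MARS-like adaptive splines), and a
random forest. Each learner × pseudo-absence set × repeat is fit on a
stratified random 70% and scored by TSS and ROC-AUC on the held-out 30%;
the TSS-maximizing threshold is recorded from held-out scores. Stratification
avoids single-class folds; learner failures are logged and skipped.

Variable importance is `1 − mean Pearson r` between predictions and
predictions after permuting that variable's column. The ensemble is the
TSS-weighted mean of member probability maps over members with TSS ≥ 0.4
(a common convention; the inclusion cutoff and weighting rule are
configurable), binarized at the ensemble's TSS-maximizing threshold on its
calibration data. Projection "into the invaded range" means applying
source-calibrated members to the invaded stack and binarizing with the
source model's own threshold. Map agreement within an optional region mask:
stability = |A∩B|/|A|, expansion = |A∖B|/|A|, unfilling = |B∖A|/|B| with A
the invaded-model cells and B the source-model cells; stability + expansion
= 1 by construction.

## Genotype–environment association

SNPs are filtered at ≤30% missing data and minor allele count ≥40 (both
rules floors, per the upstream bioinformatic convention; tests use smaller
MAC floors at their smaller sample sizes). Missing calls are imputed with
the per-SNP mean; the mask is retained.

**Latent factor model.** For one standardized environmental variable x and
the centered genotype matrix Y, each repeat runs a two-stage fit from a
random initialization:

1. *Flag pass.* Factors are estimated by alternating least squares jointly
   with the environmental effect (rank-K decomposition of the
   effect-residual). This statistic has full power but its null is
   structure-inflated, because the factor subspace omits the component of
   population structure aligned with x; its z-scores are therefore GIF
   recalibrated and used only to flag candidate SNPs at p < 1e-3.
2. *Calibrated pass.* Factors are re-estimated from the genotype matrix
   with the flagged SNPs' columns excluded. With three ancestries the
   centered structure has rank 2, so a K=3 factor basis has a spare
   dimension that would otherwise capture a strong environmental response
   itself; excluding flagged SNPs keeps the factors on population
   structure. The final z for every SNP is the t-statistic of the
   environmental coefficient in the joint regression on [1, x, U] — the
   joint fit partials the factors out of x, which is what keeps null
   z-scores calibrated (GIF ≈ 1).

z-scores are median-combined across repeats (default 5); the genomic
inflation factor is `λ = median(z²)/median(χ²₁)` (median of χ²₁ ≈ 0.4549)
and adjusted p-values come from `z²/λ` against χ²₁. In simulation the null
λ lies within 1 ± 0.1 at 2,000 SNPs and planted clines (strength 3, 20 of
2,000 causal) are recovered with sensitivity ≈ 1.

**Partial RDA.** Genotypes (centered, not scaled — the field convention)
and the six predictors are residualized on [1, Q without one column] (one
ancestry column dropped against the sum-to-one singularity); predictors
fully absorbed by the conditioning are removed rather than letting their
numerically-zero residuals project noise. The multivariate fitted values
are decomposed by SVD; each SNP's loadings on the constrained axes give a
robust Mahalanobis distance (median centre, 1.4826×MAD scale per axis —
axes are orthogonal so a diagonal scatter suffices), GIF-calibrated against
χ² with the axis count as degrees of freedom.

**FDR and intersection.** Storey q-values with smoother-estimated π₀
(spline over the λ-grid 0.05…0.95, read off at 0.95, clipped to
[1/m, 1]). Outliers are SNPs with q < 0.05 in *both* detectors; loci are
summarized by parent-locus grouping with per-method hit counts.

## Allelic turnover (F_ST + GDM)

Pairwise Weir–Cockerham θ is computed per locus between populations, with
multi-SNP loci combined by ratio of sums of the variance components across
the locus's SNPs. A population enters a locus's roster when its mean
genotyped-individual count over the locus's SNPs is ≥5 (per-SNP pairs with
fewer than 2 genotyped individuals are dropped from the sums — the
components are undefined there). Negative estimates are floored at 0, then
the off-diagonal values are min–max rescaled to [0, 1] per locus. The
rescaling choice is per locus, not global; it makes turnovers comparable
across loci at the cost of amplifying pure noise at uninformative loci,
which is exactly why classification must follow a screen (below).

GDM: `d_ij = 1 − exp(−η_ij)`, `η_ij = α + Σ_p Σ_k β_pk |I_pk(x_pi) −
I_pk(x_pj)|` with all coefficients ≥ 0. Each predictor gets three monotone
I-spline basis functions — normalized antiderivatives of degree-1 B-splines
with knots at the 0/50/100th percentiles — each rising 0→1 over the
observed gradient, so a predictor's partial turnover (the fitted function's
total height, the predicted ΔF_ST across the gradient) is simply the sum of
its coefficients. Geographic distance enters as a special predictor whose
I-splines apply to the pairwise Euclidean distance itself. Fitting is
iteratively reweighted non-negative least squares on the link scale
(binomial-type deviance, exponential link), with step-halving when a step
fails to reduce the deviance (the plain IRLS can 2-cycle on noisy loci);
convergence at 1e-10 relative change, error after 200 iterations.
%GDM = 100·(null deviance − deviance)/null deviance, with the null the
intercept-only fit (μ = mean dissimilarity).

A reference group of 200 randomly sampled SNPs, fitted identically, gives
the null level of %GDM and turnover. Candidate classification applies three
criteria to a locus's model: (C1) %GDM above the reference's; (C2) the
environmental predictor with the largest turnover exceeds both the
reference's turnover for that predictor and the locus's geography turnover
(a locus whose largest turnover belongs to geography is a false positive);
(C3) refitting with the winning predictor alone retains ≥40% of the full
model's %GDM — the single-predictor-refit operationalization of "that
predictor explains ≥40% of the deviance", chosen because per-predictor
deviance attribution is not otherwise identified under non-negative
coefficients. A locus is a candidate iff all three hold.

The three criteria are intentionally permissive on arbitrary loci: a
single locus's rescaled F_ST always spans [0, 1], so its noisy %GDM and
turnover routinely exceed the precise 200-SNP reference floor (in null
simulation ~60–70% of unscreened loci pass). The procedure is therefore
defined — here as in the originating workflow — as GEA screen first, GDM
classification second (`discover_candidates`); at that level the null
candidate rate over loci is ≈0 and planted cline loci are recovered with
the correct predictor.

Turnover maps evaluate a fitted predictor transform over a raster, clamping
out-of-gradient cells (count reported), with per-population observed
allele frequencies available as an overlay table.

## Morphometrics

TPS files are parsed strictly (landmark-count and malformed-line errors
name the record/line). Generalized Procrustes alignment centres each
configuration, scales to unit centroid size and iteratively rotates onto
the running consensus until it moves < 1e-10; rotations are constrained to
det +1 (all wings come from the same side, so reflections are excluded).
The reported consensus is the arithmetic mean of the aligned set. Shape PCA
operates on flattened Procrustes coordinates.

Group tests: Pillai's trace MANOVA on the leading principal components
capturing 95% of shape variance (Procrustes coordinates have 2·20−4 = 36
free dimensions and often exceed the observation count; the dimension used
is reported and additionally capped at n − groups − 1); type II ANOVA on
log centroid size, with pairwise comparisons restricted to groups of ≥5.
With a single factor, type II sums of squares coincide with the sequential
decomposition — multi-factor designs should be checked against their
coding. The environment-conditioned RDA residualizes shape (or log size)
and predictors on [1, population-averaged ancestry coefficients minus one
column] and tests the constrained variance fraction by permuting rows of
the residualized response under the reduced model (999 permutations by
default; 99–199 in tests).

## Problem sizes and numerical notes

Tests and the acceptance script run the GEA chain at the study scale
(90 populations × 6 individuals, 2,000 SNPs, 20 causal) and scale replicate
counts — not effect sizes, rates or thresholds — to keep the suite quick:
150 replicate datasets for permutation-test calibration (n_perm = 99),
20 seeds for GEA power and SDM importance ranking, 50 replicates for GDM
parameter recovery, 20–30 replicates for morphometric calibration and
power. Degenerate inputs are errors rather than silent results: all-zero
suitability surfaces, non-PSD correlation targets, rank-deficient predictor
matrices, single-class labels, all-missing SNPs, degenerate (coincident)
landmark configurations, and dissimilarities outside [0, 1] all raise with
a diagnostic. Ties and floors are explicit: frequency clamps at 0.01/0.99,
F_ST floored at 0 before rescaling, q-values clipped to (0, 1], robust MAD
scales replaced by 1 when zero.

## Known limitations

The latent-factor solver is a deterministic least-squares formulation, not
the original Gibbs sampler; repeat-to-repeat variation comes from random
initialization only. The MARS-like and GAM-like learners are spline-basis
logistic models, not the reference implementations of those families.
Geography in the GDM is straight-line distance; no resistance or
least-cost surfaces. The similarity test's translation-only null cannot
reshape niches. Synthetic data lack LD, sampling bias and informative
missingness, so power and calibration results transfer to real data only to
the extent those features are negligible.
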