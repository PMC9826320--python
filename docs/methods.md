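# Methods

## Scope and data model

The package analyses paired urban/non-urban comparisons of three avian
life-history traits — laying date (day-of-year, 1 January = 1), clutch size
and number of fledglings — each comparison summarised per habitat arm by a
mean, an SD and a sample size, optionally per breeding season. Records that
cannot support an effect size are removed in a fixed rule order (missing n,
missing SD, n = 1, SD = 0); a record failing several rules is tallied once
under the first, so the exclusion log is an unambiguous sequential account.
Summary-statistic conversions accept standard errors (SD = SE√n) and
three-number summaries {q1, median, q3}, the latter through the optimally
weighted median/quartile mean estimator and the normal-quantile IQR SD
estimator. Both quartile estimators assume approximate normality of the
underlying sample; a degenerate summary yields SD = 0 and is then excluded.

## Effect sizes

Four paired measures are implemented, always with the urban arm in the
numerator so positive values mean "urban larger":

* lnRR — the plain log-ratio of means with its delta-method variance.
  No small-sample bias correction is applied to the point estimate; this
  matches the convention of the standard effect-size tooling in this
  literature, which keeps results comparable with published analyses.
* lnCVR and lnVR — with the 1/(2(n−1)) bias corrections in both the
  estimate and the variance; the lnCVR variance treats the sampling
  correlation between mean and SD as zero (exact for normal data).
* SMDH — a standardized mean difference for unequal arm variances, with the
  exact Gamma-function small-sample correction and its large-sample
  heteroscedastic variance.

All four were verified to full printed precision against an independent
reference implementation; the verified values are frozen in the test suite.
Per-arm (ln SD, ln mean) rows carry sampling variance 1/(2(n−1)) into the
arm-based model. Back-transformation to percent differences uses
100·(exp(|y|) − 1); the magnitude convention (absolute value before
exponentiation) reproduces the percent interpretations usually quoted for
both positive and negative log-ratios. The effective sample size of a
comparison is 4·n_u·n_c/(n_u + n_c).

## Season pooling

Among-season means are sample-size-weighted means of per-season means;
among-season variances are the weighted within-season variance plus the
weighted dispersion of season means around the pooled mean. With population
variances (denominator n) this equals the variance of the concatenated raw
samples exactly — the property the tests exploit — while with the sample
variances reported in the literature it is the standard approximation. The
pooled record re-enters the pipeline with SD = √(pooled variance) and
n = Σnᵢ, the weight implied by the pooled-mean formula. The inter-annual
dataset consists of source-reported multi-season records plus pooled
versions of groups observed in ≥ 2 seasons; groups observed in a single
season only carry no among-season information and are dropped (this choice
reproduces the qualitative structure of the literature dataset, whose
among-season subset is several times smaller than its within-season subset).

## Phylogeny

Trees are read from Newick (rooted; polytomies allowed). Grafen heights —
(number of descendant tips − 1)^ρ, scaled to root height 1, with ρ = 1 —
give an ultrametric tree without requiring dated branch lengths. The species
correlation matrix A sets A[i,j] to the shared fraction of the root-to-tip
path (root-to-MRCA depth over total depth), giving a symmetric PSD matrix
with unit diagonal that enters the meta-models as the correlation structure
of the phylogenetic species effects.

## The multilevel meta-analytic engine

The marginal covariance of the effect-size vector sums: a study-by-trait
block T expanded over same-study pairs; population-pair, phylogenetic
(through A) and non-phylogenetic species intercept variances; per-trait (or
single) observation-level variances; and the known sampling variances vi.
Five structures constrain T: a single variance with zero covariances (1
parameter), compound symmetry (2), heteroscedastic compound symmetry (4),
diagonal (3) and unstructured (6). Parameterisation keeps every structure
valid throughout optimisation: variances on the log scale, the CS
correlation through a logistic map onto (−1/(t−1), 1) (the PSD range for a
t×t CS matrix), and the unstructured block through its Cholesky factor
(log-diagonal plus free sub-diagonal).

Likelihoods (ML or REML) are evaluated by one Cholesky factorisation of the
dense k×k covariance; gradients use the mixed-model identity
∂ℓ/∂θ = −½[tr(Q ∂V) − r′V⁻¹ ∂V V⁻¹ r] with Q the REML projection matrix,
where ∂V is assembled per parameter (for the structured block, by
differencing the small t×t parameterisation only). The restricted
likelihood includes the +½log|X′X| constant so values are directly
comparable with the common reporting convention. Optimisation is L-BFGS-B
with box bounds (−30, 10) on transformed parameters (keeping exp() finite),
relative function tolerance 1e−12, and up to five dispersed starts before a
fit is flagged — never silently — as non-converged. Structure comparison
fits all five T structures by ML and ranks them by AIC (ΔAIC to the best;
ties below 1e−6 resolved toward fewer parameters); the four non-diagonal
structures are warm-started from the fitted diagonal model, which protects
the nested-likelihood ordering (unstructured ≥ any constrained) from local
optima. AIC counts free covariance parameters plus, under ML only, the fixed
effects; REML AICs are comparable only across a common fixed part, so final
reported fits use REML while structure comparison uses ML.

Confidence intervals default to Wald z (the convention behind published
symmetric intervals). Two small-sample options exist: "t-contain" swaps z
for t quantiles with containment degrees of freedom — the number of levels
of the coarsest grouping factor (typically species) minus the number of
fixed effects — and "adjusted" inflates the coefficient
covariance Kenward-Roger-style, Φ_A = Φ + 2Φ[Σ W_ij (Q_ij − A_iΦA_j)]Φ,
propagating the sampling covariance W of the variance components, and pairs
it with per-coefficient Satterthwaite degrees of freedom
df_j = 2Φ_A[j,j]²/var(Φ[j,j]) (available for correlation-free structures,
where V is linear in the components). The recovery experiments use
"adjusted": with ~35 species the phylogenetic variance is weakly
identified, its estimate frequently shrinks to the boundary, and plain z
intervals then run narrow; the adjustment widens intervals adaptively —
most in exactly the replicates where the component uncertainty is largest —
and restores near-nominal coverage in the package's own calibration
experiments.

Heterogeneity is decomposed as multilevel I²: each component variance over
the total of components plus the typical sampling variance
σ̄²ₘ = (k−1)Σw / ((Σw)² − Σw²), w = 1/vi. Marginal R² for moderator models
is var(Xβ̂)/(var(Xβ̂) + Σσ²ᵤ). Publication bias is probed by two
uni-moderator multilevel models: √(1/effective n) for small-study effects
and mean-centred publication year for decline effects.

The arm-based model regresses ln SD on habitat and centred ln mean (the
mean–variance, Taylor's-law slope), with population, species and
phylogenetic intercepts plus a study-level effect whose entries within a
study share an estimated correlation (compound symmetry within study,
correlation through a tanh transform); sampling variances are 1/(2(n−1)).

## Spatial moderators

Land-cover input is any single-band categorical grid in ESRI ASCII format
with a planar (metre) or geographic (degree) georeference. A buffer counts
pixels whose centres fall within the radius — the inclusion rule is
validated against brute-force containment — with per-pixel great-circle
distances (sphere radius 6371.0088 km) in geographic mode, avoiding any
projection choice. From the counts: the urban index (share of pixels in the
configured urban categories) and landscape heterogeneity as the effective
number of land covers, exp of the Shannon–Wiener index (Hill number of
order 1), which equals 1 for a single category and the richness for a
uniform mixture. Profiles are taken at 250–5000 m in 250 m steps; per-pair
moderators are urban-minus-nonurban differences at each shared radius plus
the great-circle pair distance. The paired urban-index contrast is tested
with an intercept-only linear model (one-sample mean with SE = sd/√n).

## Synthetic data generator

The generator mirrors the estimation model in the generative direction. Per
study it draws a species (from a simulated pure-birth tree), one or two
population pairs, one to three traits, and one season or several (about a
third of studies are multi-season, 2–8 seasons). For each record a true
lnRR and lnCVR compose the trait-level mean plus study-by-trait,
population, phylogenetic (MVN(0, σ²ₐA)), species and observation-level
normal deviations. Truth is imposed exactly on the estimands: the non-urban
arm keeps the baseline mean and CV (laying date 110 d, CV 0.08; clutch size
6, CV 0.25; fledglings 4, CV 0.45), the urban mean is baseline·exp(lnRR)
and the urban CV baseline·exp(lnCVR). Individuals are normal within arms
(laying dates clipped to [1, 366]); per-arm n is lognormal (median ≈ 30,
clipped to [8, 300]), resembling typical field-study samples. All draws flow
from a single seeded PCG64 generator, so a fixed seed gives byte-identical
output.

Default magnitudes are the study conditions of the literature this package
targets: 35 species, 68 studies (≈ 400 comparisons after composition), true
trait-level effects lnRR = (−0.048, −0.066, −0.070) and lnCVR = (0.176,
0.055, 0.037) for laying date, clutch size and fledglings, and variance
components calibrated so the implied heterogeneity decomposition matches
the reported shares (lnRR: I²total ≈ 98% with ≈ 2% phylogeny, ≈ 16%
species, ≈ 8% study; lnCVR: I²total ≈ 74% with ≈ 6% phylogeny, ≈ 3%
species, ≈ 0% study).

What the generator does **not** emulate: non-normal phenotype
distributions (real clutch sizes are small counts), reporting and rounding
error in extracted summaries, correlated trait reporting within studies
(trait-level deviations are independent unless a study-level correlation is
switched on), literature search bias (beyond the optional funnel-asymmetry
injection used by the publication-bias tests), and real landscape structure
(land cover is smoothed categorical noise with an urban core). Passing
recovery tests therefore demonstrate estimator correctness under the
model's own assumptions at realistic sizes, not robustness to real-data
violations of those assumptions.

The recovery experiment (simulate → effect sizes → trivariate REML fit with
the generating structure) at 200 replicates and k ≈ 400 measures bias, RMSE
and CI coverage of the trait-level fixed effects; these sizes keep the full
experiment within minutes on one CPU while making the Monte-Carlo error of
the bias estimate (≈ 0.005) small against the tolerance used in tests.

## Numerical notes and limitations

* Variance components truly at zero are estimated at the log-scale lower
  bound (exp(−30) ≈ 1e−13), i.e. effectively zero, never negative.
* The likelihood is exact-dense; beyond a few thousand effect sizes the
  O(k³) factorisation would dominate and a sparse or profiled
  implementation would be preferable.
* Wald z intervals undercover moderately (≈ 88–90% observed for a nominal
  95%) when the phylogenetic component dominates replicate-level
  uncertainty; the "adjusted" (Kenward-Roger-style) option restores
  near-nominal coverage, at the cost of one extra O(k³) pass per fit and a
  restriction to correlation-free covariance structures.
* REML-based AIC comparison across different fixed parts is refused by
  construction (the restricted likelihoods are not comparable).
* The raster reader supports ESRI ASCII grids only; GeoTIFF ingestion would
  require a geospatial I/O dependency and is out of scope.
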