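# Methods

## Synthetic multisite data

Each site is a multivariate normal over P features (default P = 273,
mimicking regional grey-matter volumes over a whole-brain parcellation),
with 3 sites of 1,000 subjects by default.  Because the per-site moments of
the motivating real dataset are not published, site heterogeneity is
parametric and mirrors ComBat's own model form, which makes parameter
recovery testable:

* site mean: `mu_i = base_mu + a_i`, with `a_i` drawn per feature with SD
  `additive_shift_scale × sqrt(diag(base_sigma))` (default scale 1.0);
* site covariance: `sigma_i = m_i² × base_sigma`, `m_i` uniform on
  `multiplicative_scale_range` (default [0.7, 1.5]).

The base covariance is a one-factor ("hub") correlation matrix scaled by
per-feature SDs (uniform [0.5, 2], volume-like units; means uniform
[5, 15]).  The hub feature — by default index 186, named "IDP-187" in
1-based user-facing labels — carries factor loading `hub_strength` (default
0.9) while other features load uniformly on [0.2, 0.7], so the hub
correlates appreciably with every feature.  This realizes, as a tunable
knob, the qualitative property that the representative feature is
correlated with many others; no quantitative criterion for that choice
exists, so the loading ranges are package defaults.

The behavioral variable is the per-site z-score (sample SD, ddof = 1) of
the hub feature plus Gaussian noise of variance 0.04, giving an analytic
within-site correlation `1/sqrt(1.04) ≈ 0.9806` with the hub and no site
effect in behavior itself.

For the harmonization-effectiveness demonstrations the generator is run in
a *strong-heterogeneity* regime, `additive_shift_scale = 8`: between-site
mean offsets of ~8 within-site SDs produce nearly disjoint per-site
clusters, the regime in which pooled ("mega-analysis") correlations collapse
while within-site correlations are intact.  The default (1.0) regime keeps
sites overlapping and is used for the outlier sweeps, where the readout is
the distortion caused by outliers rather than by site separation.

What the generator does **not** emulate: non-Gaussian marginals, site
differences in correlation *structure* (only scale), covariate effects
(age, sex), or realistic artifact physics behind outliers.  Passing tests
therefore demonstrate the statistical mechanics of ComBat under
contamination, not claims about any specific real dataset.

## Outlier model

Quartiles use linear interpolation between order statistics (the common
"type 7" estimator); this choice is load-bearing because fences and scores
are defined from Q1/Q3/IQR, and it is fixed and documented here.  Fences are
Tukey's with k = 3 and the comparison is inclusive (a value exactly at the
fence is an outlier).  The outlier score `min(|x − Q1|, |x − Q3|)/IQR` is
clamped to 0 inside [Q1, Q3]; score ≥ 3 is equivalent to the fence rule.
Scores below 3 are rejected at validation — such a value would not be an
outlier by definition.

Injection appends `n_out = round(fraction × site size)` rows per
contaminated site, drawn MVN around `Q3 + score·IQR` (upper) or
`Q1 − score·IQR` (lower) with covariance `0.003² × R` (R = the site's
normal-data correlation matrix; the small cloud SD keeps the realized score
within a few thousandths of the nominal one).  `quantity_fraction` means the
**total** count per affected site; bilateral scenarios split it across sides
(upper side takes the extra row on odd counts).  This keeps the
contamination level comparable across scenarios on a common axis; a
`per_side=True` mode adds the full count on each side instead.  The
"one-site different" scenario pins the upper side at score 40 and sweeps
the lower-side score.

Balancing: every non-contaminated site gains the same number of fresh
normal rows drawn from its generating model.  All appended rows (outlier
and normal) receive behavior from the normal mechanism — a normal
target-feature value z-scored against the site's *pre-injection* statistics
plus noise; for outlier rows that value is a fresh draw (their own
target-feature value is extreme and must not leak into behavior), for
appended normal rows it is the row's own drawn value.  The behavioral
variable therefore never contains Tukey-flagged values.

Subject-level semantics: a subject counts as an outlier if flagged on at
least one feature; the robust pipeline excludes whole subjects (per-value
masking is not used because the location-scale fit is row-wise).

## ComBat estimation

* Identification: `sum_i n_i γ_iv = 0` (sample-size weighted), which makes
  α_v the weighted grand mean over all subjects.
* `σ̂_v²` pools squared residuals with maximum-likelihood denominator N by
  default; `ml_variance=False` switches to N − rank(design).  At n = 1,000
  per site the two differ negligibly.
* Raw site effects on the standardized scale: per-site mean of Z (γ̂) and
  per-site variance with ddof = 1 (δ̂²), matching the reference
  implementation.
* Hyperpriors by method of moments: `γ̄_i, τ̂_i²` are the across-feature
  mean/variance of γ̂; `λ_i = m²/s² + 2`, `θ_i = m(λ_i − 1)` invert the
  inverse-gamma mean m and variance s² of δ̂².  If s² is 0 the variance
  shrinkage for that site is disabled (flagged, not fatal).
* Conditional-posterior-mean updates iterate until the maximum relative
  change drops below 1e-4 or 100 iterations (non-convergence is recorded,
  not fatal).  The full pipeline agrees with Bioconductor `sva::ComBat`
  to ~1e-13 on shared fixtures.
* Covariates default to none; the simulated behavioral variable is never
  passed as a covariate and is never harmonized.
* Robust mode: with `exclude_mask`, *every* fitted quantity —
  standardization, raw effects, hyperpriors, posteriors — is estimated on
  unflagged rows only; the fitted affine transform is then applied to all
  rows, including the outliers.  Each site must retain ≥ 2 unflagged rows.

Idempotence: exact re-application identity holds for the EB-off,
unbiased-denominator configuration.  With EB enabled a second pass
re-estimates the hyperpriors from the shrinkage residuals and shrinks
again — repetition contracts (second-pass changes are < 5% of the first)
but is not a fixed point to machine precision; the ML denominator likewise
rescales by `sqrt(N/(N−S))` on a refit.  This is a property of the standard
formulation (the reference implementation behaves identically), documented
rather than "fixed".

## Evaluation battery

* PCA embeddings use column-centered, unscaled data; the largest-magnitude
  loading of each component is made positive for a deterministic sign.
* Correlations: Pearson and Spearman (average ranks on ties — injected
  clouds can tie at low spread) per site and pooled over all subjects (the
  "combined site", i.e. mega-analysis pooling of raw rows, not averaged
  per-site statistics).
* ICC: two-way random-effects, absolute-agreement, single-measure
  (ICC(2,1)) from ANOVA mean squares, extended to k > 2 raters;
  consistency-type ICC(3,1) by flag.  Absolute agreement is the default
  because the analyses compare the *values* of correlation vectors across
  sites, where constant offsets are real disagreement.  Bands: ≥ 0.80 high,
  [0.60, 0.80) moderate, [0.40, 0.60) good, [0.10, 0.40) poor, < 0.10 none.
* Normal-sample moments (mean, ddof-1 variance of the target feature over
  rows whose ground-truth flag is false) are the core distortion readout.
  The *direction* of the outlier-induced mean shift is assessed against the
  outlier-free harmonized level (the ground-truth-excluded robust fit on the
  same rows), because comparing to the raw pre-harmonization mean confounds
  the shift with ordinary site alignment.
* Scenario-consistency tables compare the grid-ordered correlation vectors
  (35 cells under the default grids) between the one-site scenario pair
  and among the two-site scenario triple, per contaminated site and for the
  combined site, before and after harmonization; the "one-site different"
  scenario is excluded since it differs in score, not only placement.

## Pipeline and reproducibility

One normal dataset per master seed; each grid cell derives a stable
sub-seed from SHA-256 of (master seed, scenario, quantity index, score
index), so single cells can be re-run in isolation and reproduce their
report rows exactly.  Failed cells are recorded with a reason code and never
abort a sweep.  Dataset CSVs are written with `%.17g` floats and read with
round-trip parsing, so write-then-read is exact.  Figures are optional and
off by default.

## Problem sizes

The default design (3 × 1,000 × 273, 210 grid cells, naive + robust per
cell) is the full study.  The test suite and the acceptance script run the
sweep at a reduced size — 300 subjects/site, 30 features, hub at index
15 — chosen so the whole battery completes in minutes on a single CPU while
every qualitative contrast (attenuation, squeeze/stretch, Pearson-vs-
Spearman, rescue) remains comfortably detectable; the full-size
configuration is exercised once in the outlier-free effectiveness check.

## Known limitations

* Parametric EB only; the nonparametric prior variant is out of scope.
* Feature-wise location-scale harmonization only — no covariance
  harmonization, no longitudinal extension.
* Exact ICC magnitudes from the motivating study are functions of
  unpublished real-data covariance structure and are not reproduction
  targets; the package reproduces the qualitative pattern (band
  transitions, directions, invariances) and its own numbers are
  seed-stable.
* Recovery of the generating EB hyperparameters is subject to the model's
  identifiability constraints (weighted-zero location effects, unit
  weighted-mean scale effects per feature); tests generate
  constraint-consistent effects, and λ̂/θ̂ carry a known small-sample bias
  (~7% at n = 500) from the sampling noise of per-site variances.
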