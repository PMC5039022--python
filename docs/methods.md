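# Methods

This note records the statistical models implemented in `rangetrends`, the
defaults and why they were chosen, the numerical details that matter for
reproducing results, and the known limits of what the synthetic tests show.

## Design-based estimation

Jolly's Method 2 for transects of unequal lengths is a ratio estimator with
a finite-population-corrected variance. Sample moments use n−1 denominators
(the standard convention for this estimator). The estimator is exactly
design-unbiased under equal-area units — verified by exhaustive enumeration
of all samples of tiny populations in the tests. Two edge cases are defined
rather than exceptional: a complete census (n = N) and counts exactly
proportional to areas both give SE = 0. A negative variance, which the
formula can produce in finite samples, is clamped to zero with a logged
warning and flagged on the returned estimate. With n = 1 the point estimate
is returned with an undefined (NaN) SE. Species are estimated independently;
no between-species covariance is computed.

## The trend model

Per county, the log mean of the survey estimates is a sum of species fixed
effects, a common-trend P-spline, a species-specific P-spline and a fixed
offset `log(mean estimate of the species in the county)`. The response is
the survey estimate rounded to the nearest integer for the NB likelihood
(raw values are preserved in the observation grid). Estimate-level SEs from
the survey stage are *not* propagated into the trend likelihood — a known
limitation: years estimated with very different precision carry equal
weight.

### Spline construction

`m = 20` equally spaced interior knots, degree `d = 3`, penalty order
`r = 3` by default, giving `K = m+d+1 = 24` basis functions. The boundary
knots are stacked to multiplicity `d+1` (the endpoint plus `d` additional
knots at the start and `max{1, d}` at the end), i.e. a clamped basis; this
is the only multiplicity that yields exactly `K = m+d+1` columns and a
partition of unity on the closed domain, and it reproduces all the
reference dimensions (`ds1 = 21`, `ds2 = 21p`). The generalized inverse in
`Z = Ũ(QᵀQ)⁻Qᵀ` is the Moore–Penrose pseudo-inverse: unique and stable.
Survey dates are mapped to decimal years; predictions for unsurveyed years
are placed at mid-June, encoded as year + 0.45.

### Fixed effects and the penalty null space

The reparameterization puts the r-dimensional null space of the difference
penalty (index-polynomials of degree < r) *outside* the random-effect span.
Consequently a model whose only fixed effects are species intercepts cannot
represent a monotone trend: every fit shrinks to a species mean. This was
confirmed empirically (a simulated 67% decline fitted as ~0%). The default
fixed design therefore contains species intercepts *and* per-species linear
time slopes — the parametric species × time interaction, p + p columns —
which restores the drift directions species by species and makes a smooth
exponential decline exactly representable. A configuration switch
(`fixed_species_slopes=False`) retains the intercepts-only variant for
sensitivity analysis. The remaining quadratic null direction is left out
deliberately: with 21 penalized basis directions per smooth its practical
effect is a mild attenuation of strongly curved trends, visible only in the
logistic (saturating) scenarios.

### Fitting: residual PQL

The fitter alternates three updates until the maximum relative parameter
change falls below 1e−6 (at most 100 iterations; non-convergence raises an
error carrying the last iterate and the per-iteration trace):

1. working variate `e = η + (y−μ)/μ` on the log link with weights
   `w = μ/(1+μ/k)`;
2. REML estimation of (σ²ᵤ₁, σ²ᵤ₂) for the linear mixed model of `e`
   (Nelder–Mead on the log-variance scale, warm-started between outer
   iterations), then a Henderson mixed-model-equation solve for (β, u);
3. a moment-matching update of the NB shape: `k` solves
   Σ(y−μ)²/(μ(1+μ/k)) = n − p (Pearson statistic equal to its degrees of
   freedom), bracketed on [1e−4, 1e8] and clamped with a warning at the
   bounds (the upper bound is the Poisson limit).

Alternating the k update with the variance-component update was chosen over
joint profiling for robustness and transparency of the trace. Variance
components are floored at 1e−10. Initialization: η₀ = log(y + 0.5), k₀ = 1,
σ² = 0.1. The relative-change criterion floors its denominator at 1e−4 so
spline coefficients that are numerically zero cannot stall convergence.
The pseudo-likelihood objective is monitored across iterations; decreases
are logged, not fatal.

In the limit where both spline variances are pinned at zero and k is fixed,
the PQL iteration is exactly IRLS for the NB GLM; the tests verify
coefficient agreement with an independent GLM implementation to 1e−6.

### Prediction

Point predictions are `exp(η̂)` at observed survey dates (averaged within a
calendar year afterwards, consistent with the aggregation stage) and at
mid-June for unsurveyed years. Pointwise 95% bands use the normal quantile
1.96 on the link scale with SE from the inverse mixed-model-equation
coefficient matrix — the prediction variance of (β̂, û − u) — so the bands
account for spline-coefficient uncertainty. Extrapolation outside the
spline domain is refused. On data simulated from the model itself (dense
yearly surveys, weak overdispersion) the empirical pointwise coverage over
200 replicates falls in the low-to-mid 90s, inside the 90–99% acceptance
band.

## Aggregation conventions

Years with multiple surveys are averaged after model fitting; excluded
outliers (an explicit input list — there is no automatic outlier rule, by
design, to keep reruns reproducible) are dropped before averaging but kept
in tables for plotting. National sums refuse silent gaps: every county must
contribute a value for every species-year, model-predicted where
unsurveyed. Reference periods carry per-county end-year overrides (a
2011–2013 window extended to 2014/2015/2016 for counties surveyed later).
The default baseline period starts in 1977; a 1978 variant is a
configuration choice. Ratios and percents are reported at one decimal but
computed on unrounded values. Biomass unit weights ship with the package as
a clearly non-canonical synthetic default table (`DEFAULT_UNIT_WEIGHTS`);
real analyses must supply their own.

## Covariate analyses

- Intercensal interpolation assumes exponential growth between anchors;
  it is exact at both anchors and multiplicatively consistent when chained.
- Climate trend tests are OLS slopes on year with two-sided t-tests (the
  choice of test was open; OLS is the simplest defensible default, and its
  type-I error is verified by simulation).
- Univariate density curves are plain NB2 maximum-likelihood regressions
  with a log county-area offset (no random term by default, because no
  grouping structure is implied; a county-level random intercept can be
  approximated by fitting per-county subsets). AICc counts the NB shape as
  a parameter: q = mean parameters + 1.
- The "constant variance" curve is least squares on an exp-polynomial mean,
  chosen to match the NB log-link mean function so the two fits are
  directly comparable.
- Forward selection standardizes the main effects internally (centered,
  scaled) and searches mains, squares and pairwise interactions under
  strong hierarchy: a square needs its main effect, an interaction both.
  Ties break by larger criterion improvement, then alphabetically, making
  the trace deterministic. Coefficients are expanded back to the original
  covariate scale; the round-trip is exact to numerical precision.
  Outputs describe associations ("most strongly correlated"), not causes.

## The synthetic-data generator

The generator emulates the monitoring design: 5 km × 5 km units
(configurable), ~5.7% sampling intensity, survey calendars with gap years,
NB2 counts at both the unit level (for survey-estimation tests) and the
estimate level (for trend-model tests), and county covariate histories —
exponential human population growth (~4.8-fold over 1962–2009), linear
warming of 0.013–0.035 °C/yr plus Gaussian noise, rainfall with a weak
negative trend. The default wildlife decline rate is 0.0288/yr (a ~67.5%
decline over 39 years); shoats rise logistically toward twice their initial
abundance; cattle decline gently. The unit-level NB shape defaults to
k = 5, a realistic level of aerial-count overdispersion (the survey
literature does not pin a value); at the estimate level the same k gives a
one-survey CV near 45%. All randomness flows through named substreams of
one seed, so stages regenerate independently and byte-identically.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: spatially explicit animal
distributions, rainfall quasi-periodicity, seasonal migratory/resident
switching (one population per species-county; season-split analyses are
supported by partitioning the input), observer undercount bias, and
changes in strip width or unit size across surveys.

## Problem sizes in the test suite

Simulation-based checks are sized for a single CPU: the decline-recovery
suite uses 200 replicates of a one-county, four-species scenario with
m = 10 knots; the coverage suite 200 replicates of a two-species dense
design; selection-recovery 30 replicates at n = 1000; the climate type-I
suite 500 replicates. These sizes are the package's own test design; the
underlying operations scale unchanged to the full 21-county, 18-species
configuration (the reference 540-row, 273-random-dimension design is
assembled and checked exactly).

## Known limitations

- PQL is approximate for strongly overdispersed, small-count data; no
  quadrature or MCMC alternative is provided.
- The common variance σ²ᵤ₂ is shared across all species-specific smooths;
  species with genuinely different roughness are averaged over.
- Survey-level SEs are ignored by the trend likelihood (see above).
- The radial-basis fallback smoother with k-d-tree knots, used elsewhere
  for counties where the P-spline model fails to converge, is a documented
  non-goal and is not implemented; non-convergence here raises with a
  diagnostic trace instead.
- GIS/mapping, raster climate extraction and photographic count correction
  are out of scope.
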