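# Methods

This package implements a functional-data-analysis pipeline for daily
physical-activity profiles measured by accelerometer, together with a
synthetic-data generator that provides ground truth for validating every
stage. This note records the statistical model, the defaults and why they
were chosen, the numerical decisions, and what the synthetic validation
does and does not demonstrate.

## Data model and preprocessing

The raw unit is the *epoch*: a 15-second bin over which the device sums
dimensionless activity counts. All clock times are minutes since
midnight, intervals are half-open `[start, end)`, and a minute is
labelled by its start time. The preprocessing contract is:

1. **Minute aggregation.** 15-s counts are summed into minutes; a minute
   counts as observed only when *all* of its sub-epochs are present.
   There is no accepted partial-minute convention, and summing partial
   minutes would bias counts downward unevenly, so incomplete minutes are
   treated as missing.
2. **Wear-time filter.** A day is retained when at least 600 worn minutes
   start within `[07:00, 22:00)` (900 possible minutes). Nonwear
   detection itself (consecutive-zero rules and the like) is out of
   scope: missingness is simply absent rows, and a nonwear classifier can
   be plugged in upstream.
3. **Common window.** Retained days are standardised to `[08:30, 19:30)`,
   exactly 660 one-minute epochs. Functional analysis needs a common
   grid with no missing values, so a day missing any in-window minute is
   rejected (a reported outcome, not an error). Counts outside the
   window still count toward wear time.
4. **One day per child.** To avoid modelling within-child dependence,
   one eligible day is sampled uniformly per child, from a dedicated RNG
   stream so the choice is reproducible independently of simulation.

## Smoothing: quasi-likelihood B-splines

Each profile `y_i` (660 counts) is represented as a smooth latent
function `y_i(t) = φ(t)ᵀ c_i` in an order-4 (cubic) B-spline basis of
dimension `k` with `k − 4` equally spaced interior knots on
`[510, 1170]` minutes — equal spacing is the standard default of
spline-basis constructors and nothing in the problem suggests adaptive
knots. Coefficients are fitted by a quasi-likelihood GLM with identity
link and variance linear in the mean (`V(μ) = φ·μ`), the classic working
model for overdispersed counts: only the first two moments are assumed.
Fitting is iteratively reweighted least squares with weights
`1/max(μ̂, floor)`.

Numerical choices:

- **Start and floor.** IRLS starts at `μ̂⁰ = max(y, floor)` with
  `floor = 1` count/min. Identity link with `V(μ) = μ` is undefined at
  zero and zero minutes are common, so the floor applies *inside the
  variance weights only*; negative fitted values are otherwise permitted
  (the identity link makes no positivity guarantee).
- **Convergence.** Relative change of the Pearson chi-square below
  `1e-8`, at most 100 iterations; non-convergence flags the result
  rather than raising.
- **Dispersion.** Estimated per profile as Pearson `X²/(660 − k)`.

The basis dimension is global — one `k` for the whole cohort — and chosen
by minimising the mean over profiles of the GCV score

    GCV = n · Σ_m (y_m − μ̂_m)² / max(μ̂_m, floor) / (n − k)²,

with `n = 660`. The dispersion is omitted from the GCV weights: at fixed
weights-from-means it is a constant factor and cannot change the argmin
over `k`. Ties within 0.1% relative score go to the smaller `k`. The
default candidate grid `{9, 19, 39, 59, 99, 149, 199, 299}` log-spaces
the range appropriate to 660-point profiles; smoothness is controlled
through `k` only (no roughness penalty).

## Functional ANOVA

Smoothed profiles are decomposed as

    y_{i,g}(t) = α₀(t) + α_g(t) + ε_{i,g}(t),

where `α₀` is the reference-category profile function and each `α_g` is a
time-specific contrast of a non-reference level, extended additively to
several categorical covariates with reference coding and no interactions.
Because responses and coefficient functions share one basis and the model
is linear, estimation is a single weighted least-squares regression of
the child-level coefficient vectors on the design matrix. This is
exactly equivalent to a pointwise weighted regression at every grid
minute (both are linear in the same fitted values), an identity the test
suite asserts at `1e-8`. The decomposition identity
`C = X·B̂ + residuals` holds to machine precision by construction.

Inverse-probability weights (sampling × nonresponse) enter only here:
smoothing is within-child, while the weights correct between-child
selection. Weights are rescaled to mean 1 by the generator, which leaves
weighted least squares invariant and keeps effective sample sizes
interpretable.

**Permutation functional F test.** The pointwise statistic is the
weighted variance of fitted values over the weighted mean squared
residual; the test statistic is its maximum over the 660-point grid (an
integrated-F alternative is switchable). The null distribution permutes
whole covariate rows — weights travelling with their rows — against the
fixed profiles, preserving the joint covariate structure, with
`p = (1 + #{perm ≥ obs})/(1 + nperm)`. Univariable screens and the
multivariable model use the same fitting routine.

**Bootstrap bands.** Children are resampled with replacement (carrying
their weights) and the FANOVA refitted per replicate; bands are
*pointwise* percentile intervals (simultaneous bands are out of scope).
Rank-deficient replicates are redrawn, with failure if redraws exceed
half the replicates. Percentile bands are widened, where necessary, to
bracket the point estimate so the band invariant holds even at extreme
quantile configurations. Defaults `B = 199`, `nperm = 199`,
`level = 0.95`, seeds mandatory.

**Window averages.** A contrast is summarised over a clock window as its
*length-normalised* integral, computed exactly from the piecewise
polynomial (no quadrature). Normalisation keeps the summary in
counts/min, the scale on which localised deficits are naturally read; a
contrast constant over the window summarises to that constant. The four
reporting windows are 08:30–09:30, 09:30–12:00, 12:00–13:30 and
17:30–19:30, plus the full day.

## The synthetic generator

The generator emulates the structure of cohort accelerometry without
reproducing any real child's data:

- **Baseline mean.** 300 counts/min plus Gaussian bumps at 08:45
  (+250, σ 15 min), 10:30 (+150, σ 12), 12:30 (+200, σ 25) and 15:30
  (+250, σ 30): commute, break, lunch and after-school peaks with a
  mid-lesson trough, at magnitudes typical of hip-worn uniaxial devices
  in 7-year-olds.
- **Effects.** Smooth Gaussian bumps so window-averaged truths have
  closed forms (via erf). Defaults: girls average −70 counts/min over
  12:00–13:30 (bump centred 12:45, σ 20 min, height −128.8); children
  driven to school average −75 over 08:30–09:30 (centred 09:00, σ 18,
  height −110.3). Bump widths and the recovery-test basis dimension
  (k = 59, knot spacing ≈ 12 min ≪ bump σ) were fixed from a spline
  approximation-error argument: with `h ≈ 12` min the projection bias of
  a σ ≥ 18 min Gaussian onto the cubic spline space, `O(h⁴ f⁗/384)`, is
  an order of magnitude below the Monte-Carlo standard-error band used in
  the recovery test.
- **Noise.** Negative binomial with `Var = φ·μ` exactly (size
  `μ/(φ−1)`, success probability `1/φ`), default `φ = 5` at 15-s scale.
  This makes the smoother's working variance correctly specified, so
  recovery tests isolate estimation error. Since the success probability
  is mean-free, minute sums of 15-s draws are again NB with the same φ —
  the in-memory fast path draws minutes directly and is *exactly*
  distributed as the file path. Means are floored at 1 count/min before
  noise so the NB size parameter is never degenerate. Epochs are
  independent given the mean; real accelerometry has residual within-day
  autocorrelation that is not modelled, so test results speak to the
  estimators under the stated moment model, not to serial-dependence
  robustness.
- **Cohort structure.** Covariates are drawn from per-covariate
  frequency tables (defaults: sex 51/49, transport 60/40); weights are
  inverse logistic propensities (intercept 1.0, Female −0.3, Car −0.2 on
  the log-odds scale) rescaled to mean 1; each child contributes 2–7
  days; 15% of days lose a contiguous 1–8-hour block so the QC filters
  are exercised. The latent mean is piecewise constant within each
  minute, making the expected minute-aggregated curve equal baseline +
  effects exactly — an analytic structural identity used in tests.

## Validation design and problem sizes

The statistical checks run at sizes chosen to give stable Monte-Carlo
answers on a single CPU: algebraic equivalences at n = 50, k = 25 over
20 seeds (tolerance 1e-8); effect recovery at n = 400, φ = 5, k = 59
over 50 simulations (within 3 Monte-Carlo SEs of the analytic truth in
every contrast × window cell); permutation type-I error at n = 60,
k = 25, nperm = 99 over 200 null simulations (rejection rate in
[0.02, 0.09] at nominal 0.05); bootstrap pointwise coverage of a constant
−50 contrast at n = 300, B = 199 over 100 simulations (coverage in
[0.90, 0.99] at 12:45). The numbered analysis scripts use a 300-child
cohort through the full file-based path.

## Known limitations

- One profile per child: repeated days would need functional mixed
  models, deliberately not attempted.
- Pointwise (not simultaneous) bands; no propagation of basis-dimension
  uncertainty into intervals.
- Continuous functional covariates and covariate interactions are not
  supported.
- The GCV score is used exactly in the printed form above, whose net
  `(n−k)²` denominator equals the standard `n·WSSE/(n−k)²` normalisation;
  alternative normalisations would not change the selected `k` ranking
  materially but are not offered.
- Independence of epochs given the mean (see above); device-specific
  cleaning and nonwear classification are delegated to upstream tools.
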