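# Methods

## Model and assumptions

The model is a single-season, two-scale site-occupancy model with
imperfect detection.  Large 10 km × 10 km grids carry a tiger occupancy
state `Z_i`; their 2 km × 2 km subgrids carry prey-use and tiger-use
states `z^x_ij`, `z^y_ij`.  Prey use is modelled jointly with tiger use
because tiger use is allowed to depend on the prey-use indicator of the
same subgrid (coefficient `β1y`).  Sign detections are binomial over the
number of 100-m survey segments walked in a subgrid, with per-segment
detection probabilities that vary with NDVI and elevation.  Effort enters
only as the binomial size, never as a regression covariate: a subgrid
walked twice as far offers twice as many Bernoulli trials, which is the
mechanistically correct role for search effort in a segment-level
recording protocol.

Assumptions: closure of the latent states within the survey season;
independence of detections across segments given the latent state; no
spatial autocorrelation beyond what the covariates induce; covariates
measured without error and standardized (mean 0, sample sd 1) at their own
scale.

### Gating

The detection probability is multiplied by latent indicators ("gates"), so
detections are impossible where the relevant states are 0.  Which binomial
carries the grid-level `Z_i` is configurable:

* `tiger_gated` (default): tiger detections require `Z_i · z^y_ij`; prey
  detections require `z^x_ij` only.  This matches the stated design — two
  nested levels of occupancy *for tigers*, with subgrid "use" meaning use
  within an occupied home range — and makes prey a first-level process,
  since prey occupancy at the grid scale is summarized by the `Prey_i`
  covariate rather than modelled.
* `as_printed`: `Z_i` gates the prey binomial and not the tiger one.  Some
  published renderings of this model family attach the indicators this
  way; it is ecologically inverted (a tiger-occupancy state silencing prey
  detections) but preserved verbatim for exact replication.
* `both_gated`: `Z_i` gates both binomials; provided for sensitivity
  analysis.

Use-state priors are deliberately *not* conditioned on `Z_i`; gating acts
only through the detection layer.  This keeps every full conditional a
closed-form Bernoulli and matches the printed factorization.

## Covariate preparation

Human population density is floored at 11 persons/km² (the minimum
observed nonzero ward density; park cores are assigned zero population)
before a log₁₀ transform, at both scales.  Prey for grids that could not
be visited is imputed as the arithmetic mean of directly observed adjacent
grids; adjacency is supplied as an explicit table (conventionally
8-neighbour/queen, which maximizes donors for edge grids and keeps
geometry out of the core).  All covariates are then centred and scaled
with the sample (n−1) standard deviation, separately per scale, and the
scaling is stored so it can be inverted.  Pearson correlations between
prepared covariates are reported for screening only; nothing is dropped
automatically (the system this emulates retained all covariates despite a
−0.58 NDVI–HPD correlation).

## Inference

Metropolis-within-Gibbs with data augmentation:

1. **Latent sweep.**  Each of `z^x`, `z^y`, `Z` is drawn from its exact
   Bernoulli full conditional (vectorized over cells).  The prey-use
   conditional includes the tiger-use prior factor because `ψ^y` depends
   on `z^x`.  Cells with gated detections are forced to 1 automatically
   (the likelihood ratio is +∞); log-domain arithmetic is used throughout
   and impossible observations yield −∞, never NaN.
2. **Coefficient sweep.**  The twenty coefficients form five blocks (grid
   occupancy, prey use, tiger use, tiger detection, prey detection), each
   updated by symmetric random-walk Metropolis under independent uniform
   priors on [−10, 10] — on the logit scale this spans probabilities from
   ~4.5·10⁻⁵ to ~0.99995, i.e. effectively unbounded while keeping the
   posterior proper.  Proposals outside the bounds are rejected outright.
   Because the latent sweep is the expensive step, three coefficient
   sweeps are run per latent sweep (`metropolis_sweeps`, default 3).
3. **Adaptation (burn-in only).**  Per-block scalar step sizes adapt every
   50 iterations toward a 0.2–0.5 acceptance band, and from one fifth of
   burn-in onward the proposal is shaped by the empirical covariance of
   the recent burn-in history (Haario-style adaptive Metropolis, scaled by
   2.38/√d).  All adaptation freezes at the end of burn-in, so the
   post-burn-in kernel is a fixed, detailed-balance-preserving Metropolis
   kernel targeting the exact posterior.

Defaults mirror the standard generic-engine run: 10,000 iterations, 3
chains, burn-in 2,500 *within* the 10,000 (the first 2,500 discarded),
thinning 10 — hence 750 retained draws per chain.  Draws are retained at
burn_in + k·thin, which guarantees exactly ⌊(iterations − burn_in)/thin⌋
draws per chain for any configuration.  Chains are initialized from
N(0, 1.5) coefficient draws (overdispersed relative to the posterior,
inside the prior bounds) and latent states forced to 1 wherever gated
detections occurred, Bernoulli(0.5) elsewhere.  All randomness flows from
a single seed through `numpy` SeedSequence spawning, so runs are exactly
reproducible.

Convergence is the split-chain Gelman–Rubin potential scale reduction
factor (each chain halved, classic non-rank-normalized formulation),
threshold 1.1.  The implementation is cross-checked against arviz's
split-R-hat in the test suite.

### Validation against an enumeration oracle

For instances with ≤ 20 latent bits, the package enumerates all latent
configurations to compute the exact marginal likelihood and exact
posterior marginals `P(Z_i = 1 | data)` at fixed coefficients.  The test
suite verifies (a) every Gibbs full conditional against likelihood ratios
of the complete-data log-likelihood, and (b) the latent sampler's
marginal occupancy probabilities against the enumeration posterior within
three Monte-Carlo standard errors over 20 seeds.

## Synthetic-data generator

The generator emulates the survey design: `n_grids` (default 62) grids of
`subgrids_per_grid` (default 25) subgrids; independent standard-normal
subgrid covariates (an equicorrelation knob exists but defaults to 0,
whereas real covariates correlate up to ≈ −0.6); grid covariates are the
re-standardized means of member subgrids and grid prey is standard
normal; effort per subgrid is categorical with 35% mass at zero and a
geometric-style decay over 1–20 segments (mean ≈ 4.4 segments ≈ 0.44 km),
chosen so a 25-subgrid grid averages ≈ 11 km of trail — the same order as
the real campaign (808.5 km over 57 grids) — with a hard cap of 400
segments (40 km) per grid; a fraction 5/62 of grids is marked unsurveyed
(efforts zeroed, grid prey masked and later imputed from lattice
neighbours).  Detections are binomial with gated probabilities, so the
generator and the likelihood agree exactly.

The default coefficient preset places the generator in the regime reported
for this system: intercepts at logit(0.903) for grid occupancy,
logit(0.462) for tiger use, logit(0.80) for prey use, logit(0.342) and
logit(0.62) for tiger and prey detection; slope coefficients at the
reported point estimates (b1 = 1.42, b2 = −0.852, b3 = −0.841,
b4 = −0.784, β1y = 0.570, β2y = 0.583, β3y = −0.664, β4y = −1.264,
d1y = 0.15, d2y = 0.42, d1x = 0.43, d2x = −0.65) and, for the prey-use
slopes that are not reported numerically, a weak NDVI effect (0.10) with
clearly negative HPD and elevation effects (−0.50 each).  The preset is a
fixed study condition, not a tuning dial.

What passing recovery tests do **not** show about real data: the generator
has independent covariates, no spatial autocorrelation, no covariate
measurement error, and its effort distribution is an assumption (the real
effort frequencies are not published), so recovery under the generator
demonstrates internal consistency of model + sampler, not robustness to
the ways real surveys violate the model.

### Known limitation: grid-level coverage at 60 grids

In the 20-replicate recovery experiment (60 grids × 25 subgrids, reduced
sampler of 3 chains × 3,000, burn-in 1,000, thin 5) all replicates
converge (R-hat < 1.1) and the subgrid-scale use and detection blocks —
informed by ~1,500 subgrids — cover their true coefficients at 0.85–1.00.
The grid-occupancy block does not reach nominal coverage (0.65–0.80
across b0–b4).  This is a property of the estimand, not the sampler: the
block is a Bayesian logistic regression on only 60 Bernoulli outcomes
whose linear predictor has sd ≈ 2 on the logit scale, so realizations are
frequently near-separable and the flat U(−10, 10) prior lets posterior
mass spread toward large magnitudes, inflating posterior means (intercept
bias ≈ +1.5 *even when the latent states are fixed at truth*, where the
sampler demonstrably matches the maximum-likelihood fit).  Equal-tailed
intervals centred on the inflated posterior then miss the truth more than
5% of the time at this sample size.  Practical implication: grid-scale
coefficients from ~60 grids should be read as order-of-magnitude
statements with wide, right-skewed uncertainty — consistent with the wide
interval (0.77–0.99) reported for grid occupancy in the real analysis —
while subgrid-scale conclusions rest on far more data.

## Posterior summaries

Equal-tailed 95% credible intervals from pooled-chain empirical quantiles
(linear interpolation), matching the "estimate (CI: a, b)" convention;
highest-posterior-density intervals are not used.  "At mean covariates"
means all standardized covariates at 0, i.e. the inverse logit of the
intercept draws; because the prey-use indicator in the tiger-use predictor
is not a zero-mean covariate, tiger use is reported both with and without
prey use.  Use maps are means of the retained latent indicators, so cells
with gated detections map to exactly 1.

## Rescue-conflict analysis

Events are coded as *presence* of ≥ 1 rescue per subgrid (cells, not
rescue counts, populate the tables).  High/low classification is strict
`>` against the thresholds (values exactly at a cut are "low").  The
association test is the asymptotic one-sided Z-test on the log odds ratio
with SE = √(1/a + 1/b + 1/c + 1/d); zero cells require an explicit
Haldane–Anscombe 0.5 correction.  Homogeneity of odds ratios across
strata uses Woolf's inverse-variance chi-square by default — the natural
companion of the log-OR framework — with Breslow–Day available through
statsmodels.  The two methods give 6.13 and ≈ 8.7 respectively on the
packaged stratified tables; they bracket, but do not equal, the 7.785
sometimes quoted for these data, whose exact method is unidentified, so
the package treats homogeneity results as method-labelled statistics and
its tests assert structural properties (zero on identical strata,
stratum-order invariance, agreement with the direct formula) rather than
any single published value.  Statistics are keyed to table cells, never to
narrative labels, because published prose and tables occasionally swap
column labels.

The analysis window for rescues is a configuration value (default
2020-01-01 to 2024-08-31); published accounts of the same record system
give several slightly different windows.

## Seasonality

Rescues are totalled by calendar month across the window and fitted with
a single-harmonic sinusoid of fixed 12-month period by ordinary least
squares on the basis [1, sin(2πm/12), cos(2πm/12)] at month midpoints
m ∈ {0.5, …, 11.5} — the closed-form minimum-MSE fit over level,
amplitude and phase.  Midpoint coding makes "start/middle/end of month"
statements well defined.  Amplitude is √(a1² + a2²); peak and trough are
a0 ± amplitude, exactly six months apart; a (numerically) zero amplitude
is flagged degenerate and has no peak.  Fitting the 12 month-of-year
totals rather than the full monthly series was chosen because the
quantity of interest is the seasonal profile; with a fixed 12-month
period the two regressions have identical harmonic coefficients when the
series covers whole years.

## Numerical choices

Logistic link via `scipy.special.expit`; Bernoulli log-mass as
`z·η − log(1+e^η)`; binomial probabilities clipped to
[1e−300, 1 − 2⁻⁵³] before logs so gated-but-extreme probabilities never
produce NaN; −∞ is propagated explicitly for impossible states.  The
enumeration oracle is guarded at 20 latent bits (≈ 10⁶ configurations).
R-hat of identical constant chains is defined as 1, of distinct constant
chains as +∞.

## Problem sizes used in the shipped experiments

The test suite validates the sampler against enumeration on 10-latent-bit
instances (20 seeds × 1,500 iterations) and runs the recovery experiment
at 20 replicates of 60 × 25 with the reduced sampler above; the
acceptance script fits one 62 × 25 landscape with 3 chains × 3,000
iterations.  These sizes were chosen to make the full battery run in
minutes on a single core while keeping every experiment at the study's
actual spatial scale.
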