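# Methods

`baybloom` implements an end-to-end analysis of a long (multi-decade) weekly
estuarine chlorophyll *a* record with substantial, structured missingness:
gap-filling by a Bayesian dynamic linear model (DLM), Monte-Carlo propagation
of the imputation uncertainty through a seasonal ARIMAX regression on
environmental drivers, Granger-causality screening at decadal resolution,
threshold-based bloom phenology, and long-term trend statistics. This note
records the models, the defaults and why they were chosen, the numerical
choices, and what the synthetic test bed does and does not establish.

## The weekly grid

All series live on a contiguous (year, week-of-year) grid with exactly 52
weeks per year: week = ceil(day-of-year / 7), capped at 52, so days 365/366
fold into week 52. A 52-week year keeps the calendar commensurate with the
period-52 seasonal models; the alternative (ISO weeks, occasionally 53) would
break the seasonal difference and shifts phenology weeks by at most one.
Multiple samples within one week are averaged, since the sampling design is
one visit per week. Units are carried as metadata only.

## Synthetic data generator

The generator emulates the statistical features the analysis must cope with,
without calibrating to any particular site:

* **Chlorophyll on the log scale.** Observed concentrations in records of
  this kind span several orders of magnitude, so noise is multiplicative:
  `log chl = mu + trend*t + seasonal(week) + sum_i beta_i z_i(t - l_i) + e_t`,
  with AR(1) errors `e_t` (phi = 0.5, innovation SD 0.55). The default trend
  (-0.018 per year on logs) produces roughly a halving of cumulative annual
  chlorophyll between the first and last decade of a 50-year record, and the
  default seasonal + noise mix gives mean annual coefficients of variation
  near 85-100% — the overdispersion regime typical of seasonal temperate
  estuaries.
* **Bimodal seasonality** as two circular Gaussian bumps (defaults: centers
  at weeks 8 and 32, widths 3.5 and 4.5 weeks, heights 1.2 and 0.9 on logs)
  rather than one sinusoid, reproducing a winter-spring and a summer-fall
  bloom. An optional `bump_drift_per_year` shifts both centers linearly for
  timing-trend recovery experiments; the default is no drift.
* **Drivers first, chlorophyll second.** Temperature, salinity, Secchi depth,
  light, precipitation, stratification and four nutrients are generated as
  baseline + sinusoidal season + trend + AR(1) noise (positive variables via
  exp), nutrients anti-phased with the blooms and slowly declining,
  temperature warming. Chlorophyll then depends on standardized driver
  anomalies through known lagged coefficients, so the causal direction is
  known and Granger power checks have a ground truth.
* **Missingness** mirrors a real monitoring record: Bernoulli point gaps
  (default 10%), stretches of every-other-week sampling in the early years,
  and whole multi-year block gaps (defaults: 1995-1998 and 2012). Masking
  never perturbs observed values.

What the generator does *not* emulate: regime shifts, spiky storm responses,
heteroskedastic measurement error, chl:carbon ratio drift, or spatial
structure. Tests passing on it therefore establish the correctness and
calibration of the machinery under the assumed data-generating class, not
fidelity to any real estuary.

## Gap-filling DLM

The observation model is `y_t = F' theta_t + v_t`, `theta_t = G theta_{t-1} +
w_t`, with a local-linear-trend block (level + slope) and a trigonometric
seasonal block (default 3 harmonics of period 52; the full 26-harmonic
seasonal is available). Chlorophyll is modeled on the log scale by default —
it is strictly positive and spans decades of magnitude — with a raw-scale
option; the transform is recorded in all outputs.

* **Observation variance** is unknown and handled conjugately
  (normal-inverse-gamma; prior df 1, scale 1), giving Student-t one-step
  forecasts and a posterior for V that the sampler draws from.
* **Evolution covariances** come from block-diagonal discounting:
  `W_t,block = P_t,block (1 - delta)/delta` with delta = 0.98 for both blocks
  by default. Discounting is applied per block with no cross-block noise,
  which keeps the implied W positive semidefinite; scaling the cross terms as
  well (the tempting one-matrix shortcut) injects spurious correlated noise
  into the trend when the two discounts differ, and measurably corrupts
  trend extraction.
* **Priors** default to weakly informative moments on the data scale (prior
  level = observed mean, prior covariance 25x the observed variance). A very
  diffuse fixed prior (1e6) combined with discounts near 1 makes the
  backward recursion ill-conditioned; the data-scaled prior keeps the
  smoother numerically stable while still letting a handful of observations
  dominate.
* **Filtering/smoothing** are the standard conjugate forward and backward
  recursions; missing weeks update through the evolution only; smoothed
  covariances are retrospectively rescaled by S_T/S_t.
* **FFBS** draws exact joint state paths: V is drawn per member from its
  inverse-gamma posterior, states are sampled backward with covariances
  scaled by V/S_t, and missing weeks emit a posterior-predictive observation
  (state draw + observation noise). Observed weeks are emitted verbatim —
  imputation only fills gaps. Multi-year block gaps are treated like any
  other gap; their wider intervals propagate naturally.
* **Panel imputation**: chlorophyll receives the full M-member ensemble
  (default M = 100); every driver is completed with its smoothed posterior
  mean (log scale whenever its observed values are strictly positive). Which
  treatment the original analyses of such records used is generally
  unstated; ensemble-imputing only the response keeps the Monte-Carlo
  dimension focused on the quantity of interest.

Calibration: on the default 50-year masked panel, the 95%
posterior-predictive intervals cover the held-out truth at ~0.96 across
~570 masked weeks (slightly conservative inside block gaps, slightly
anti-conservative at isolated gaps, because the AR(1) error is treated as
white observation noise).

## Seasonal ARIMAX Monte Carlo

Each ensemble member is fitted with a regression-with-SARIMA-errors model,
default order (2,0,1)x(0,1,1)_52, with lagged exogenous drivers (default:
ammonium lags 0-2, silicate 0-1, nitrate+nitrite 0-3, Secchi 0, temperature
0, salinity 0-2 — fourteen columns). Coefficients sit on the undifferenced
scale; seasonal differencing applies to response and regressors jointly
(the statsmodels SARIMAX convention). Per-parameter results are aggregated
into MC-mean, MC-SD and the count of members with two-sided Wald p < 0.05.

Numerical choices:

* `simple_differencing` is used whenever d or D > 0: differencing the data
  up front instead of carrying the integration in the state makes a
  period-52 fit on ~2,600 weeks take seconds-to-tens-of-seconds instead of
  minutes, at the usual cost of conditioning on the first season of data.
* Exogenous regressors are standardized internally and back-transformed, so
  reported coefficients are per unit of the input variable while the
  optimizer sees O(1) columns.
* L-BFGS with tightened tolerances; pure-regression models (no ARMA terms)
  use BFGS with statsmodels' complex-step score, which reaches the optimum
  to machine precision.
* Non-converged members are dropped with a logged count; more than 20%
  failures aborts with advice to revise the specification. Model selection
  among candidate orders uses AIC on the ensemble-mean series (the
  "best-fit" criterion is an assumption, logged as such), ties broken toward
  fewer parameters.

Recovery: simulating 2,600 weeks from (2,0,1)x(0,1,1)_52 with AR1 = 1.1,
AR2 = -0.2, MA1 = -0.7, SMA1 = -0.9 and one exogenous beta = 2, every
parameter lands within 3 reported SEs of truth in 20/20 seeded replicates,
and a pure-noise exogenous column is "significant" in well under 15% of 100
member fits.

## Granger screening

Bivariate only: x Granger-causes y if lags of x improve an autoregression of
y (F-test on the x-lag block). The lag order is selected by AIC on the
*restricted* model (y's own lags), never looking at x, which preserves the
test's nominal size under the null (empirically 0.047 at alpha = 0.05 over
1,000 null simulations). For decadal-scale screening the default
preprocessing takes annual means of the completed series and
first-differences them, removing shared long-term trends that would
otherwise manufacture spurious causality; a weekly-resolution mode exists
(default max lags: 4 annual, 8 weekly). p-values are reported per pair with
no multiplicity adjustment, matching the reporting convention of this kind
of screen.

## Bloom phenology

A year's bloom threshold is 1.05x its median weekly chlorophyll (the ">5%
above the annual median" convention; the factor is configurable). A bloom is
a maximal run of consecutive weeks strictly above threshold; minimum length
one week, no gap-merging (weekly data already smooth sub-weekly structure).
The peak is the argmax within the event, earliest week on ties. Events are
labeled by the window containing their start week — winter-spring weeks
1-16, summer-fall weeks 22-38, otherwise "other" (counting toward annual
frequency only). Per season and year: start = earliest event start in the
window, peak = week of the highest concentration among the window's events,
duration = duration of the event containing that peak. Where the window's
highest week is below threshold the event-based rule governs (the seasonal
argmax alternative was rejected: a "bloom maximum" should belong to a
detected bloom). Because the threshold scales with the median, every metric
is invariant to rescaling a year's chlorophyll.

Metrics are computed per ensemble member and summarized as across-member
median ± SD per year; a single-series mode exists for speed. Timing trends
are quantified two ways: a Poisson GLM (log link, IRLS) of week numbers on
covariates, and an OLS rate converted to days per decade (slope in
weeks/year x 70).

## Trend statistics

Annual summaries (cumulative, mean, sample SD, CV = 100·SD/mean, max, min)
are computed on complete (imputed) years; partial years are excluded, and
years falling inside multi-year observation gaps are ordinary imputed years
whose uncertainty lives in the ensemble spread. Decade comparisons use
Welch's t by default (a pooled-variance option exists) — the unequal-variance
form is the safer default when decadal variances differ. Trend fits are OLS
of ln(value) on calendar year; slope sign and R² are the portable facts (the
intercept depends on the x-origin convention).

The k-sample Anderson-Darling test is the rank-based Scholz-Stephens
statistic with midrank tie handling, standardized by the exact finite-sample
null SD. Two p-value routes:

* **Asymptotic:** A² converges in law to `sum_j chi2_{k-1,j} / (j(j+1))`.
  The tail probability is computed by Imhof's characteristic-function
  inversion (2,000 weight terms, truncated tail folded in as its mean) and
  the observed standardized statistic is mapped onto the standardized limit.
  Unlike critical-value interpolation, this gives a continuous p across
  (0, 1) instead of clipping at the tabulated 0.25/0.001 range.
* **Permutation:** seeded reshuffles of the pooled sample, p = (1 + #{T* >=
  T})/(B + 1), B >= 2,000. This is the reference at small samples; across
  20 null datasets (k = 5, n = 52) the asymptotic p agrees with a
  5,000-permutation oracle to within 0.02.

Degenerate input (all pooled values identical) returns p = 1 without
division by zero. Pairwise decade comparisons report the unadjusted
symmetric p-value matrix.

## Pipeline and reproducibility

`run_pipeline` executes synth/load → impute → SARIMAX-MC → Granger →
phenology → trends, writing every intermediate as plain CSV plus a JSON
manifest (config echo, stage seeds, timings, warnings). Stage seeds derive
from the master seed by hashing the stage name (blake2s, mod 2^31), so adding
a stage never perturbs earlier stages' randomness; reruns with the same
config and seed are byte-identical. The SARIMAX stage consumes the ensemble
on the log scale by default — on synthetic data the generating model is
log-linear; a raw-scale flag mirrors analyses that fit concentrations
directly.

## Problem sizes used in the shipped experiments

The acceptance script and test suite run: a 50-year panel (2,600 weeks) with
the default missingness (~570 masked chlorophyll weeks); a 100-member
imputation ensemble; SARIMAX Monte Carlo on a 12-member subsample (a
period-52 fit on 2,600 weeks costs roughly half a minute, and 12 members
already pin the MC means to a few percent); 20 replicates of the full
parameter-recovery simulation; 1,000 null simulations for the Granger size
check; and 20 null datasets x 5,000 permutations for the AD agreement check.

## Known limitations

* The DLM treats the AR(1) error of the generator as white observation
  noise; interval calibration is good marginally but joint (multi-week)
  predictive statements would be mildly miscalibrated.
* No hyperparameter MCMC: discounts and harmonics are fixed, not learned.
* Granger screening is bivariate; conditional (multivariate) causality and
  frequency-domain variants are out of scope.
* The SARIMAX Monte Carlo treats the completed drivers as fixed; driver
  imputation uncertainty is not propagated.
* Asymptotic AD p-values at very small n (< ~20 per sample) should be
  replaced by the permutation route.
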