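# baybloom

Long-term analysis of weekly estuarine chlorophyll *a* records with
structured missingness. The package is aimed at plankton-time-series
analysts who need to (1) gap-fill a decades-long weekly record — including
multi-year holes — while keeping track of the imputation uncertainty, and
(2) push that uncertainty through everything downstream: driver regressions,
causality screens, bloom phenology, and trend tests.

## The method

**Gap filling.** Chlorophyll (on the log scale) follows a Bayesian dynamic
linear model

    y_t      = F' θ_t + v_t,    v_t ~ N(0, V)
    θ_t      = G θ_{t-1} + w_t, w_t ~ N(0, W_t)

with a local-linear-trend block and a trigonometric seasonal block
(harmonics of period 52), unknown observation variance handled conjugately,
and discount-factor evolution noise. Forward-filtering backward-sampling
(FFBS) draws M = 100 complete sequences from the posterior predictive:
observed weeks are kept verbatim, gaps get state + observation-noise draws.

**Uncertainty propagation.** A seasonal ARIMAX — regression with
SARIMA(2,0,1)×(0,1,1)₅₂ errors and lagged environmental regressors
(nutrients, Secchi depth, temperature, salinity at 0–3 week lags) — is fit
to *each* ensemble member. Coefficients are reported as Monte-Carlo mean,
MC-SD, and the number of members in which the parameter was significant
(p < 0.05), so every reported effect carries the imputation uncertainty.

**Decadal screening and phenology.** Bivariate Granger tests (F-test on
lagged-x blocks, lag order by AIC on the restricted model) run on annual,
first-differenced series. Blooms are maximal runs of weeks above 1.05× the
annual median; per-season start/peak/duration/frequency are computed per
ensemble member and summarized as median ± SD. Long-term trends use Welch
t-tests between the first and last decade, log-linear OLS fits of annual
extremes, and the k-sample Anderson–Darling test (midrank statistic;
asymptotic p by Imhof inversion of the limiting law, or seeded
permutations) on decadal weekly climatologies.

A seeded synthetic generator reproduces the study conditions — bimodal
seasonality, ~88% annual CV overdispersion, long-term decline, warming,
nutrient anti-phasing, point/biweekly/block-gap missingness — with full
ground truth, so every stage has parameter-recovery and calibration tests.

## Worked example

```sh
python analysis/01_simulate_panel.py --seed 1     # 50-y masked weekly panel
python analysis/02_impute_chlorophyll.py --seed 1 # 100-member DLM ensemble
python analysis/03_fit_sarimax_mc.py              # SARIMAX Monte Carlo
python analysis/04_granger_screen.py              # annual Granger screen
python analysis/05_bloom_phenology.py             # bloom timing metrics
python analysis/06_longterm_trends.py             # decadal trend statistics
```

Outputs land under `results/`. With `--seed 1` the run prints, among other
lines:

```
panel: 2600 weeks x 11 variables, 21.8% of chlorophyll weeks masked
95% posterior-predictive coverage at masked weeks: 0.947
mean annual CV: 91%
cumulative: -51% (Welch t = 6.48, p = 5.3e-05)
winter-spring bloom: mean start week 1.5 +/- 0.9, mean peak week 7.9
median annual bloom count: 8
```

Read: the DLM's 95% intervals cover the held-out truth at the masked weeks
at very nearly the nominal rate; annual chlorophyll is strongly
overdispersed (CV ≈ 91%); cumulative annual chlorophyll fell by about half
between the first and last decade (a real decline, not an imputation
artifact — the Welch test is on per-year totals of the gap-filled series);
and the winter-spring bloom peaks near week 8 with about eight
above-threshold events per year (the 1.05×-median threshold is deliberately
permissive, so bloom *starts* sit very early in the window and event counts
run high on noisy weekly data). The equivalent one-shot pipeline is
`baybloom run --seed 1 --outdir results/pipeline` (console script installed
with the package), which also writes a JSON manifest with per-stage seeds
and timings; reruns are byte-identical.

Each member of `results/ensemble.csv` is a complete plausible chlorophyll
history; `results/mc_summary.csv` is the coefficient table with MC means,
SDs and significance frequencies; `results/ad_matrix.csv` holds the pairwise
decadal comparisons.

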