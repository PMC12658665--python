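# Methods

## The estimand and the two-stage design

For one stratum — an exposure zone × care setting × cause category — let
*yₜ* be the observed daily visit count and *μₜ* the counts that would have
occurred without the event. The quantity of interest over a post-event
window W is the excess Σ_W (yₜ − μₜ) and its normalized form
100·Σ_W (yₜ − μₜ) / Σ_W μₜ (percent excess). Since *μₜ* is unobservable
after the event, stage 1 learns a counterfactual predictor *ŷₜ* from
pre-event data only, and stage 2 treats Σ_W (yₜ − ŷₜ) as the excess
estimate, with uncertainty obtained by Monte Carlo perturbation of *ŷ*.
Each stratum is modeled independently; no information flows between strata.

## Stage 1: counterfactual model

**Base learner.** The default `structural_seasonal` learner is a Poisson
GLM (log link) with: intercept; linear trend in years, optionally extended
by truncated-linear spline knots (`trend_flexibility` = number of interior
knots, default 0; knots are equally spaced over the pre-period and the
spline extrapolates linearly); day-of-week indicators; annual Fourier
harmonics up to `fourier_order_annual` (default 3; 0 disables annual
terms); a holiday indicator (US federal holidays plus Dec 24–Jan 1); and,
when `covariates_in_base` is on (default), the z-scored exogenous
covariates as log-linear terms. The log-linear covariate terms matter:
background drivers such as wastewater virus levels act multiplicatively on
visit rates, and leaving them only to the tree-based corrector left a
window-specific model error that the corrector, trained on ~800 noisy
residuals, could not reliably remove. A `seasonal_regression` alternative
fits the same design by least squares on the count scale (predictions
clipped at zero).

**Residual corrector.** Optionally, gradient boosting (xgboost) is trained
on the base learner's residuals with features: day of week, holiday flag,
first-order day-of-year harmonics, and the z-scored covariates.
`gb_rounds=0` is allowed and yields a null corrector. Because residual
signals are weak relative to count noise, the booster carries fixed
regularization (`subsample=0.8`, `colsample_bytree=0.8`,
`min_child_weight=5`, `reg_lambda=1`). The corrector never sees lagged
observed counts — only exogenous and calendar inputs — so predictions into
the post-period cannot absorb the effect being estimated; mutating
post-period observations provably changes nothing about the fit.

**Covariates.** Daily max/min temperature (°C), max/min relative humidity
(%), wind speed (m/s), downward shortwave radiation (W/m²), and weekly
wastewater concentrations for influenza, RSV and SARS-CoV-2 (held constant
within ISO weeks). Covariates are standardized by their pre-period mean and
SD. They are treated as exogenous: the event is assumed not to act on the
counterfactual through them.

**Model selection.** Candidates compete on mean RMSE over rolling-origin
cross-validation folds. The default scheme uses 5 folds × 28 validation
days, zero gap: the validation windows are the last five 28-day blocks of
the pre-period, each fold training only on earlier dates, with at least 365
training days required for the earliest fold. Ties break toward the earlier
candidate in the list. The selected configuration is refit on the full
pre-period.

## Stage 2: Monte Carlo empirical CIs

Each of `n_iter` (default 1000) iterations forms a perturbed counterfactual
ŷ\*ₜ = max(0, ŷₜ + σ(ŷₜ)·εₜ) over the window, recomputes the (percent)
excess against the fixed observations, and the 95% CI is the 2.5th/97.5th
percentile of the iterates (percentile method, no bias correction). The
perturbations εₜ are circular moving-block bootstrap draws (default block
7 days) from the selected model's **cross-validation residuals**,
standardized on the negative-binomial Pearson scale
σ(μ) = √(μ + μ²/k̂), with k̂ estimated by moments from those residuals.
Three choices deserve explanation:

- *CV rather than in-sample residuals.* In-sample residuals understate
  forecast error — severely so for the boosted corrector — and produced
  intervals covering a known injected effect well below their nominal
  level in replicate experiments. The rolling-origin validation residuals
  are genuine forecasts at horizons comparable to the analysis window.
- *Pearson scaling.* Overdispersed counts have variance growing with the
  mean. The analysis window often sits at a seasonal peak (a January event
  coincides with the respiratory-season maximum), where raw-scale residual
  resampling is too narrow; meanwhile percent-scale uncertainty must widen
  on low-count days (weekends), which pure relative scaling would erase.
  √(μ + μ²/k) interpolates correctly between both regimes.
- *Blocks of 7 days.* Model misfit is persistent within a week (weekly
  covariate shocks, level errors), and a block the length of the analysis
  window preserves that common component in the resampled sums.

Daily and cumulative estimates share the same draws, so per-iteration daily
excesses sum exactly to the cumulative excess. A refit-per-iteration mode
(`mode="refit"`) re-estimates the selected configuration on a
residual-perturbed pre-period each iteration; it adds parameter uncertainty
at substantial cost and is off by default. When all residuals are zero the
interval degenerates to the point estimate and the result carries a
`degenerate` flag.

Replicate experiments at the default study conditions (baseline 80
visits/day, NB dispersion k = 40, injected 1.40× over the 7-day window)
show ~85–90% coverage of the true +40% by the nominal 95% interval and a
5–8% false-exclusion rate under the null. The residual anticonservatism is
inherent to prediction-side resampling: the observation noise of the window
itself, inflated under a genuine effect, is represented only at
null-period scale.

## Exposure zoning

Tracts are represented by a single point (a representative point or
centroid; tract polygons are not modeled). Distance to a burn zone is the
minimum great-circle distance (haversine, sphere radius 6371.0088 km) from
that point to the polygon boundary — zero inside the polygon — where edges
are straight segments in longitude/latitude (GeoJSON semantics) and the
per-edge minimum is found by bounded scalar minimization after a coarse
scan. Multiple fires are handled by taking the minimum distance over
polygons, which equals the distance to their union. Classification:
*high* strictly within the buffer (a tract at exactly the buffer distance
is not high); otherwise *moderate* inside LA County, *minimal* outside.
At sub-100 km scales the spherical treatment is accurate to well under 1%.

## Cause categorization

Only the three-character ICD-10 root decides membership, compared
lexicographically against inclusive range bounds — so T50 ∈ \[S00, T88\] —
and subcodes never change the category. F00 falls outside \[F01, F99\] by
construction. An encounter listing codes in several ranges increments each
matched category once and all-cause once; the all-cause series therefore
conserves encounters. Whether multi-diagnosis encounters should count per
diagnosis instead is a genuine ambiguity in this kind of analysis; counting
per encounter was chosen because the modeled unit is the visit.

## Synthetic data generator

The generator emulates what the analysis assumes about real EHR-derived
series: for each zone × setting × cause cell the daily mean is

max(0, base + trend·t) · weekly(dow) · annual(t) · holiday(t) · exp(Σ βⱼ zⱼ(t)) · m(t)

with negative-binomial noise (variance μ + μ²/k; k = ∞ gives Poisson) and
m(t) the injected multiplier when the cell/date matches a configured
effect. Defaults: baseline 80 visits/day per cell; trend +2 visits/day/yr;
weekend suppression stronger for outpatient (day-of-week factors down to
0.35) than virtual care (0.75); winter-peaking annual cycle of relative
amplitude 0.15 (peak around Jan 10); holiday multiplier 0.6; covariate
coefficients −0.02 (tmax) and +0.04…0.06 (the three wastewater signals) per
SD; dispersion k = 40 (variance ≈ 3× Poisson at the default baseline, a
realistic degree of overdispersion for daily acute-care counts — the
marginal law of real daily counts is not known, and negative binomial is
this module's assumption). Weather follows sinusoidal annual cycles with
Gaussian noise; wastewater is log-scale winter-peaking, drawn once per ISO
week and shared across zones like a county-wide surveillance signal.
Members get uniform ages on \[0, 85) years (median ≈ 42 with a wide IQR)
and configurable sex and race/ethnicity mixes.

Randomness derives from one master seed through fixed-role child streams
(members / covariates / visits), with one grandchild stream per visit cell —
so outputs are byte-identical under a repeated seed, and injecting an
effect into one cell cannot perturb any other cell's draws.

What the generator does **not** emulate: encounter-level timestamps and
codes (counts are generated directly at the aggregate), spatially resolved
smoke exposure, autocorrelated epidemic waves beyond the smooth seasonal +
weekly-shock structure, care-seeking displacement between settings, and
reporting artifacts (backfill, closures beyond the holiday list). Passing
recovery tests therefore demonstrates that the pipeline recovers effects
under the structure it assumes, not that a real series satisfies that
structure.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at desk scale: ~26 months
of daily data per stratum, two candidate configurations (GLM with
covariates, ± a depth-2/100-round boosted corrector), 5 × 28-day CV, and
1000 Monte Carlo iterations; replicate studies use 20–50 replicates.
Predictions are floored at zero (clip counts logged); fitted values below
0.5 visits/day are floored in the Pearson variance function, since counts
that small carry no scale information; GLM fitting is IRLS with up to 200
iterations; percent excess is undefined (NaN) when the predicted window
total is zero, while the count excess is still reported.

## Known limitations

- The empirical CI quantifies prediction uncertainty around the selected
  model; model-selection uncertainty enters only through the CV residuals,
  and the percentile method slightly shortens the lower arm for
  right-skewed percent iterates.
- Percent-excess CIs aggregate across zones only on the count scale;
  a percent CI for a multi-zone total is not defined by this scheme.
- Exposure is distance-based only; smoke and burn-zone exposure are not
  separated, and tract points ignore tract shape.
- The extrapolation treats zone coverage fractions as known constants, so
  extrapolated CIs inherit no uncertainty from them.
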