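# fireits

Estimating excess acute-care visits after an abrupt environmental disaster
with a two-stage interrupted time series (ITS).

When a wildfire (or comparable disruption) hits a metropolitan area, health
systems see shifts in outpatient and virtual care-seeking within days. The
question — *how many visits happened that would not have happened without
the event?* — cannot be answered by a before/after comparison, because daily
visit counts carry trend, weekly and annual seasonality, holiday dips, and
background respiratory-virus waves. `fireits` implements the full analysis
pipeline for this problem, aimed at epidemiologists and health-services
researchers working with EHR-derived daily count series:

1. **Exposure zoning** — census tracts classified *high / moderate /
   minimal* by great-circle distance from the union of burn-zone polygons
   (default buffer 20 km, with a 10 km sensitivity definition).
2. **Cause categorization** — ICD-10 codes mapped to all-cause,
   cardiovascular (I00–I99), injury (S00–T88), neuropsychiatric (F01–F99)
   and respiratory (J00–J99), then aggregated to a dense daily
   zone × setting × cause series.
3. **Stage 1 — counterfactual model.** For each stratum, candidate hybrid
   models (structural seasonal-trend Poisson base learner, optionally a
   gradient-boosted residual corrector on exogenous covariates and calendar
   features) compete on mean RMSE over rolling-origin cross-validation
   folds; the winner is refit on the full pre-event period. Post-event
   observations never enter the fit.
4. **Stage 2 — excess inference.** For a post-event window
   \[t₀, t₁\], with observed counts *yₜ* and counterfactual predictions
   *ŷₜ*,

   excess = Σₜ (yₜ − ŷₜ),  % excess = 100 · excess / Σₜ ŷₜ,

   with 95% empirical CIs from 1000 Monte Carlo iterations: each iteration
   perturbs *ŷ* with circular moving-block bootstrap samples of the
   model's cross-validation residuals (standardized on the
   negative-binomial Pearson scale) and recomputes the excess.
5. **Reporting** — stratified cohort characteristics tables and
   market-share extrapolation (cohort excess / coverage fraction) to the
   full insured population.
6. **Synthetic EHR generator** — members, tracts, daily weather and weekly
   wastewater covariates, and overdispersed daily visit counts with a
   *known* injected multiplicative post-event effect, so the whole pipeline
   is validated end-to-end by parameter recovery.

## Worked example

`examples/04_counterfactual_excess.py` simulates the default study
conditions — daily counts from November 2022 through January 2025, an event
on 2025-01-07, and a 1.40× effect (40% excess) injected into high-zone
virtual respiratory visits for the first post-event week — then runs both
stages:

```
selected model: residual_learner=gradient_boosting, CV RMSE 15.27 visits/day
week excess: +378 visits (+41.2%; 95% empirical CI +26.9% to +60.2%) — injected truth +40%
  2025-01-07  obs   217  pred  146.4  excess  +48.2%  [  +8.8%, +107.8%]
  2025-01-08  obs   250  pred  146.6  excess  +70.5%  [ +29.7%, +133.9%]
  ...
  2025-01-13  obs   190  pred  131.3  excess  +44.7%  [  +5.9%, +104.0%]
```

The weekly estimate (+41.2%, CI 26.9–60.2%) recovers the injected +40%
truth; the daily profile shows wider CIs on the low-count weekend days
(Jan 11–12), as expected when percent uncertainty scales with 1/√count.
The other examples cover simulation (`01`), zoning (`02`), ICD-10
aggregation (`03`) and cohort tables with population extrapolation (`05`).

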