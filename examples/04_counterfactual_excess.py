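"""The full 2-stage interrupted time series on one stratum.

Stage 1 fits candidate counterfactual models on pre-event data only and
selects by rolling-origin cross-validated RMSE; stage 2 compares observed
post-event counts with the counterfactual prediction and attaches 95%
empirical CIs from 1000 Monte Carlo iterations. The injected truth here is
a 1.40x multiplier (40% excess), so the printed estimate can be judged
against it.
"""

import datetime as dt
from pathlib import Path

from fireits import (
    InjectedEffect,
    ModelConfig,
    SyntheticScenario,
    daily_excess_profile,
    fit_counterfactual,
    generate_covariates,
    generate_visits,
    plot_excess_profile,
    stratum_series,
)

WINDOW = (dt.date(2025, 1, 7), dt.date(2025, 1, 13))
COVS = ("tmax_c", "ww_flu", "ww_rsv", "ww_cov")

scenario = SyntheticScenario(
    injected_effects=[
        InjectedEffect("high", "virtual", "respiratory", *WINDOW, 1.40)
    ],
    seed=1,
)
covariates = generate_covariates(scenario)
series = stratum_series(
    generate_visits(scenario, covariates), "high", "virtual", "respiratory"
)

configs = [
    ModelConfig(covariate_names=COVS),
    ModelConfig(
        residual_learner="gradient_boosting", gb_depth=2, gb_rounds=100,
        covariate_names=COVS,
    ),
]
fit = fit_counterfactual(
    series,
    covariates[covariates["zone"] == "high"],
    scenario.event_date,
    configs,
    seed=1,
    stratum=("high", "virtual", "respiratory"),
)
print(f"selected model: residual_learner={fit.config.residual_learner}, "
      f"CV RMSE {fit.cv_rmse:.2f} visits/day")

daily, week = daily_excess_profile(fit, series, WINDOW, n_iter=1000, seed=1)
print(
    f"week excess: {week.excess:+.0f} visits "
    f"({week.pct_excess:+.1f}%; 95% empirical CI "
    f"{week.ci_low:+.1f}% to {week.ci_high:+.1f}%) — injected truth +40%"
)
for d in daily:
    print(
        f"  {d.window[0]}  obs {d.observed:5.0f}  pred {d.predicted:6.1f}  "
        f"excess {d.pct_excess:+6.1f}%  [{d.ci_low:+6.1f}%, {d.ci_high:+6.1f}%]"
    )

Path("scratch").mkdir(exist_ok=True)
plot_excess_profile(daily, week, "high / virtual / respiratory",
                    path="scratch/excess_profile.png")
print("Daily whisker plot written to scratch/excess_profile.png")
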