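import datetime as dt
import math

import pytest

from fireits import InjectedEffect, SyntheticScenario

#: Covariates used by candidate models throughout the tests.
COVS = ("tmax_c", "ww_flu", "ww_rsv", "ww_cov")

WINDOW = (dt.date(2025, 1, 7), dt.date(2025, 1, 13))


@pytest.fixture
def flat_scenario():
    """Structureless Poisson world: constant mean 100, no seasonality/trend."""
    return SyntheticScenario(
        n_tracts_per_zone={"high": 1},
        baseline_rate=100.0,
        trend_slope=0.0,
        weekly_amplitude=0.0,
        annual_amplitude=0.0,
        holiday_effect=1.0,
        covariate_betas={},
        dispersion=math.inf,
        seed=42,
    )


def make_study(multiplier: float, seed: int) -> SyntheticScenario:
    """Default study conditions with an optional injected post-event effect
    on high-zone virtual respiratory visits over the first post-event week."""
    effects = []
    if multiplier != 1.0:
        effects = [
            InjectedEffect(
                "high", "virtual", "respiratory", WINDOW[0], WINDOW[1], multiplier
            )
        ]
    return SyntheticScenario(injected_effects=effects, seed=seed)
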