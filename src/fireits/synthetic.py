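"""Synthetic EHR generator: members, daily covariates and daily visit counts.

Emulates the statistical structure an interrupted time-series analysis of
acute-care utilization assumes: a ~26-month daily count series per
zone x care-setting x cause cell with secular trend, weekly and annual
seasonality, holiday dips, exogenous covariate dependence, overdispersed
count noise and a configurable multiplicative post-event excess confined to
chosen cells.

All randomness flows from the scenario's master seed through fixed-role
child streams (members / covariates / visits; one grandchild stream per
visit cell), so identical scenarios are byte-identical and injecting an
effect in one cell never perturbs draws in any other cell.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .scenario import (
    CAUSES,
    COVARIATE_COLUMNS,
    RACE_LEVELS,
    SETTINGS,
    SEX_LEVELS,
    SyntheticScenario,
    holiday_dates,
)

# Stream tags for child seed derivation; never reorder (would break replay).
_STREAM_MEMBERS = 1
_STREAM_COVARIATES = 2
_STREAM_VISITS = 3

# Day-of-week base profiles (Mon..Sun), deviation scaled by weekly_amplitude.
# Acute outpatient care collapses on weekends; virtual care is less suppressed.
_DOW_PROFILE = {
    "outpatient": np.array([1.08, 1.06, 1.02, 1.00, 0.96, 0.45, 0.35]),
    "virtual": np.array([1.05, 1.03, 1.01, 1.00, 0.98, 0.80, 0.75]),
}

# Default demographic mix, loosely matching a large Southern-California
# insured population (female-majority, plurality Hispanic).
DEFAULT_DEMOGRAPHIC_MIX: dict[str, dict[str, float]] = {
    "sex": {"female": 0.522, "male": 0.4778, "other": 0.0001, "unknown": 0.0001},
    "race_ethnicity": {
        "hispanic": 0.438,
        "nh_asian": 0.115,
        "nh_black": 0.078,
        "nh_white": 0.290,
        "unknown": 0.047,
        "other": 0.032,
    },
}

_LEVELS = {"sex": SEX_LEVELS, "race_ethnicity": RACE_LEVELS}


def _rng(scenario: SyntheticScenario, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, *stream]))


def generate_members(
    scenario: SyntheticScenario,
    n_members: int,
    demographic_mix: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Draw a synthetic member roster.

    Members are assigned uniformly to the scenario's tracts; sex and
    race/ethnicity follow ``demographic_mix`` (probabilities per attribute
    must sum to 1 within 1e-9). Ages at the event date are uniform on
    [0, 85) years, which yields a median near 42 with a wide IQR.
    """
    if n_members < 0:
        raise ValueError("n_members must be >= 0")
    mix = {k: dict(v) for k, v in (demographic_mix or DEFAULT_DEMOGRAPHIC_MIX).items()}
    for attr, probs in mix.items():
        if attr not in _LEVELS:
            raise ValueError(f"unknown demographic attribute {attr!r}")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"probabilities for attribute {attr!r} sum to {total!r}, not 1"
            )
    rng = _rng(scenario, _STREAM_MEMBERS)
    tracts = scenario.tracts()["tract_id"].to_numpy()
    columns: dict[str, np.ndarray] = {
        "member_id": np.array([f"M{i:07d}" for i in range(n_members)]),
        "tract_id": rng.choice(tracts, size=n_members),
    }
    event = pd.Timestamp(scenario.event_date)
    age_days = rng.uniform(0.0, 85.0 * 365.25, size=n_members)
    columns["birth_date"] = (event - pd.to_timedelta(age_days, unit="D")).normalize()
    for attr in ("sex", "race_ethnicity"):
        levels = [lv for lv in _LEVELS[attr] if lv in mix[attr]]
        p = np.array([mix[attr][lv] for lv in levels], dtype=float)
        columns[attr] = rng.choice(np.array(levels), size=n_members, p=p / p.sum())
    return pd.DataFrame(columns)


def _annual_cos(doy: np.ndarray, peak_doy: float) -> np.ndarray:
    return np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def generate_covariates(
    scenario: SyntheticScenario, noise_scale: float = 1.0
) -> pd.DataFrame:
    """Daily covariate panel, one row per date x zone.

    Weather follows sinusoidal annual cycles (summer-peaking temperature and
    shortwave radiation) with additive Gaussian noise; wastewater levels for
    the three respiratory viruses follow a winter-peaking annual cycle on the
    log scale, drawn once per ISO week and held constant across the week and
    across zones (a county-wide surveillance signal). ``noise_scale=0`` gives
    the deterministic seasonal curves.
    """
    rng = _rng(scenario, _STREAM_COVARIATES)
    dates = scenario.dates
    doy = dates.dayofyear.to_numpy(dtype=float)
    n = len(dates)
    frames = []
    for zone in scenario.zones:
        tmax = 23.0 + 7.5 * _annual_cos(doy, 200.0) + noise_scale * rng.normal(0, 2.0, n)
        diurnal = np.maximum(0.0, 10.0 + noise_scale * rng.normal(0, 2.0, n))
        tmin = tmax - diurnal
        rhmin = np.clip(35.0 - 8.0 * _annual_cos(doy, 200.0) + noise_scale * rng.normal(0, 6.0, n), 0, 100)
        rhmax = np.clip(rhmin + np.maximum(0.0, 35.0 + noise_scale * rng.normal(0, 8.0, n)), 0, 100)
        wind = np.abs(3.0 + noise_scale * rng.normal(0, 1.2, n))
        srad = np.maximum(0.0, 230.0 + 90.0 * _annual_cos(doy, 172.0) + noise_scale * rng.normal(0, 25.0, n))
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "zone": zone,
                    "tmax_c": tmax,
                    "tmin_c": tmin,
                    "rhmax_pct": rhmax,
                    "rhmin_pct": rhmin,
                    "wind_ms": wind,
                    "srad_wm2": srad,
                }
            )
        )
    panel = pd.concat(frames, ignore_index=True)

    # Weekly wastewater signal, shared across zones, constant within ISO week.
    iso = dates.isocalendar()
    week_key = list(zip(iso["year"].to_numpy(), iso["week"].to_numpy()))
    unique_weeks = list(dict.fromkeys(week_key))
    week_mid_doy = {}
    for wk in unique_weeks:
        member_doys = [d for d, k in zip(doy, week_key) if k == wk]
        week_mid_doy[wk] = float(np.mean(member_doys))
    ww_levels = {}
    for virus, (base, amp, sd) in {
        "ww_flu": (2.0, 1.5, 0.35),
        "ww_rsv": (1.5, 1.2, 0.35),
        "ww_cov": (3.0, 0.8, 0.30),
    }.items():
        per_week = {
            wk: math.exp(base + amp * math.cos(2 * math.pi * (week_mid_doy[wk] - 15.0) / 365.25)
                         + noise_scale * rng.normal(0, sd))
            for wk in unique_weeks
        }
        ww_levels[virus] = np.array([per_week[k] for k in week_key])
    for virus, values in ww_levels.items():
        panel[virus] = np.tile(values, len(scenario.zones))
    return panel


def _check_covariate_coverage(scenario: SyntheticScenario, covariates: pd.DataFrame) -> None:
    have = pd.DatetimeIndex(pd.to_datetime(covariates["date"]).unique())
    missing = scenario.dates.difference(have)
    if len(missing) > 0:
        shown = ", ".join(d.date().isoformat() for d in missing[:5])
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        raise ValueError(f"covariates missing dates: {shown}{more}")


def generate_visits(
    scenario: SyntheticScenario, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Daily visit counts per zone x setting x cause cell.

    The generative mean for a cell on day t is::

        max(0, base + trend_slope * years(t))
          * weekly(dow; setting) * annual(t) * holiday(t)
          * exp(sum_c beta_c * z_c(t))
          * injected multiplier (if the cell/date matches an injected effect)

    with z-scored covariates standardized over the pre-event period of the
    cell's zone. Counts are negative binomial with dispersion ``k``
    (``inf`` -> Poisson). Each cell draws from its own child random stream,
    so effects injected elsewhere leave a cell's counts bit-identical.
    """
    _check_covariate_coverage(scenario, covariates)
    dates = scenario.dates
    n = len(dates)
    years = (dates - pd.Timestamp(scenario.study_start)).days.to_numpy() / 365.25
    dow = dates.dayofweek.to_numpy()
    doy = dates.dayofyear.to_numpy(dtype=float)
    annual = 1.0 + scenario.annual_amplitude * _annual_cos(doy, 10.0)
    holidays = holiday_dates(scenario.study_start, scenario.study_end)
    holiday = np.where(dates.isin(holidays), scenario.holiday_effect, 1.0)

    cov = covariates.copy()
    cov["date"] = pd.to_datetime(cov["date"])
    log_cov_effect: dict[str, np.ndarray] = {}
    for zone in scenario.zones:
        zcov = cov[cov["zone"] == zone].set_index("date").reindex(dates)
        effect = np.zeros(n)
        pre = zcov.index < pd.Timestamp(scenario.event_date)
        for name, beta in scenario.covariate_betas.items():
            x = zcov[name].to_numpy(dtype=float)
            mu, sd = np.nanmean(x[pre]), np.nanstd(x[pre])
            z = (x - mu) / sd if sd > 0 else np.zeros(n)
            effect += beta * z
        log_cov_effect[zone] = effect

    frames = []
    for zi, zone in enumerate(scenario.zones):
        for si, setting in enumerate(SETTINGS):
            weekly = 1.0 + scenario.weekly_amplitude * (_DOW_PROFILE[setting][dow] - 1.0)
            weekly = np.maximum(weekly, 0.0)
            for ci, cause in enumerate(CAUSES):
                base = scenario.cell_baseline(zone, setting, cause)
                mean = (
                    np.maximum(0.0, base + scenario.trend_slope * years)
                    * weekly
                    * annual
                    * holiday
                    * np.exp(log_cov_effect[zone])
                )
                mult = np.ones(n)
                for e in scenario.injected_effects:
                    if e.matches(zone, setting, cause):
                        window = (dates >= pd.Timestamp(e.start)) & (
                            dates <= pd.Timestamp(e.end)
                        )
                        mult = np.where(window, mult * e.multiplier, mult)
                mean = mean * mult
                cell_rng = _rng(scenario, _STREAM_VISITS, zi, si, ci)
                if math.isinf(scenario.dispersion):
                    counts = cell_rng.poisson(mean)
                else:
                    k = scenario.dispersion
                    p = k / (k + mean)
                    counts = np.where(
                        mean > 0, cell_rng.negative_binomial(k, np.where(mean > 0, p, 1.0)), 0
                    )
                frames.append(
                    pd.DataFrame(
                        {
                            "date": dates,
                            "zone": zone,
                            "setting": setting,
                            "cause": cause,
                            "count": counts.astype(np.int64),
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def expected_mean(
    scenario: SyntheticScenario,
    covariates: pd.DataFrame,
    zone: str,
    setting: str,
    cause: str,
) -> pd.Series:
    """Closed-form generative mean for one cell (oracle for recovery tests)."""
    _check_covariate_coverage(scenario, covariates)
    dates = scenario.dates
    years = (dates - pd.Timestamp(scenario.study_start)).days.to_numpy() / 365.25
    dow = dates.dayofweek.to_numpy()
    doy = dates.dayofyear.to_numpy(dtype=float)
    annual = 1.0 + scenario.annual_amplitude * _annual_cos(doy, 10.0)
    holidays = holiday_dates(scenario.study_start, scenario.study_end)
    holiday = np.where(dates.isin(holidays), scenario.holiday_effect, 1.0)
    weekly = np.maximum(
        1.0 + scenario.weekly_amplitude * (_DOW_PROFILE[setting][dow] - 1.0), 0.0
    )
    cov = covariates.copy()
    cov["date"] = pd.to_datetime(cov["date"])
    zcov = cov[cov["zone"] == zone].set_index("date").reindex(dates)
    effect = np.zeros(len(dates))
    pre = zcov.index < pd.Timestamp(scenario.event_date)
    for name, beta in scenario.covariate_betas.items():
        x = zcov[name].to_numpy(dtype=float)
        mu, sd = np.nanmean(x[pre]), np.nanstd(x[pre])
        z = (x - mu) / sd if sd > 0 else np.zeros(len(dates))
        effect += beta * z
    base = scenario.cell_baseline(zone, setting, cause)
    mean = (
        np.maximum(0.0, base + scenario.trend_slope * years)
        * weekly * annual * holiday * np.exp(effect)
    )
    for e in scenario.injected_effects:
        if e.matches(zone, setting, cause):
            window = (dates >= pd.Timestamp(e.start)) & (dates <= pd.Timestamp(e.end))
            mean = np.where(window, mean * e.multiplier, mean)
    return pd.Series(mean, index=dates, name="mean")
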