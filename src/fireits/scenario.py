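"""Study-design parameters for the synthetic acute-care visit generator.

A :class:`SyntheticScenario` bundles every knob of the generative model:
study window, event date, baseline visit rates, trend, weekly/annual
seasonality, holiday dips, covariate coefficients, count dispersion and the
injected post-event effects whose recovery the pipeline is tested on.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import pandas as pd
import yaml
from pandas.tseries.holiday import USFederalHolidayCalendar

ZONES: tuple[str, ...] = ("high", "moderate", "minimal")
SETTINGS: tuple[str, ...] = ("outpatient", "virtual")
CAUSES: tuple[str, ...] = (
    "all_cause",
    "cardiovascular",
    "injury",
    "neuropsychiatric",
    "respiratory",
)

SEX_LEVELS: tuple[str, ...] = ("female", "male", "other", "unknown")
RACE_LEVELS: tuple[str, ...] = (
    "hispanic",
    "nh_asian",
    "nh_black",
    "nh_white",
    "other",
    "unknown",
)

#: Covariate columns of the daily panel (weather daily, wastewater weekly).
COVARIATE_COLUMNS: tuple[str, ...] = (
    "tmax_c",
    "tmin_c",
    "rhmax_pct",
    "rhmin_pct",
    "wind_ms",
    "srad_wm2",
    "ww_flu",
    "ww_rsv",
    "ww_cov",
)


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class InjectedEffect:
    """A multiplicative excess applied to one stratum over a date window."""

    zone: str
    setting: str
    cause: str
    start: dt.date
    end: dt.date  # inclusive
    multiplier: float

    def matches(self, zone: str, setting: str, cause: str) -> bool:
        return (self.zone, self.setting, self.cause) == (zone, setting, cause)


@dataclass
class SyntheticScenario:
    """Full generative parameter set for one synthetic study.

    Defaults reproduce the study conditions of the motivating analysis:
    a ~26-month daily series beginning 2022-11-01, an abrupt event on
    2025-01-07 and data through 2025-01-21.

    Parameters
    ----------
    baseline_rate
        Expected visits/day for a zone x setting x cause cell, before
        trend/seasonality/covariates. Either a scalar applied to every cell
        or a mapping ``(zone, setting, cause) -> rate`` with an optional
        ``"default"`` key for unlisted cells.
    trend_slope
        Secular drift in visits/day per year, applied additively to the
        cell baseline before the multiplicative terms.
    weekly_amplitude
        Scales the deviation of the day-of-week profile from 1; 0 removes
        weekly structure entirely.
    annual_amplitude
        Relative amplitude of the winter-peaking annual cycle (must keep the
        multiplier non-negative, so <= 1).
    holiday_effect
        Multiplier applied on US federal holidays and Dec 24 - Jan 1.
    covariate_betas
        Log-rate coefficients per standardized (pre-period z-scored)
        covariate unit, applied uniformly across cells.
    dispersion
        Negative-binomial dispersion k (variance = mu + mu^2/k);
        ``math.inf`` switches to Poisson noise.
    """

    study_start: dt.date = dt.date(2022, 11, 1)
    study_end: dt.date = dt.date(2025, 1, 21)
    event_date: dt.date = dt.date(2025, 1, 7)
    n_tracts_per_zone: Mapping[str, int] = field(
        default_factory=lambda: {"high": 40, "moderate": 120, "minimal": 160}
    )
    baseline_rate: float | Mapping = 80.0
    trend_slope: float = 2.0
    weekly_amplitude: float = 1.0
    annual_amplitude: float = 0.15
    holiday_effect: float = 0.6
    covariate_betas: Mapping[str, float] = field(
        default_factory=lambda: {
            "tmax_c": -0.02,
            "ww_flu": 0.06,
            "ww_rsv": 0.04,
            "ww_cov": 0.05,
        }
    )
    dispersion: float = 40.0
    injected_effects: Sequence[InjectedEffect] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        self.study_start = _as_date(self.study_start)
        self.study_end = _as_date(self.study_end)
        self.event_date = _as_date(self.event_date)
        effects = []
        for e in self.injected_effects:
            if not isinstance(e, InjectedEffect):
                e = InjectedEffect(
                    zone=e["zone"],
                    setting=e["setting"],
                    cause=e["cause"],
                    start=_as_date(e["start"]),
                    end=_as_date(e["end"]),
                    multiplier=float(e["multiplier"]),
                )
            else:
                e = InjectedEffect(
                    e.zone, e.setting, e.cause, _as_date(e.start), _as_date(e.end), e.multiplier
                )
            effects.append(e)
        self.injected_effects = tuple(effects)
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if not (self.study_start < self.event_date <= self.study_end):
            raise ValueError(
                "require study_start < event_date <= study_end, got "
                f"{self.study_start} / {self.event_date} / {self.study_end}"
            )
        for zone, n in self.n_tracts_per_zone.items():
            if zone not in ZONES:
                raise ValueError(f"unknown zone {zone!r}")
            if int(n) <= 0:
                raise ValueError(f"n_tracts_per_zone[{zone!r}] must be positive")
        for cell in self._iter_cells():
            if self.cell_baseline(*cell) < 0:
                raise ValueError(f"negative baseline rate for cell {cell}")
        if not (0 < self.holiday_effect <= 2):
            raise ValueError("holiday_effect must lie in (0, 2]")
        if self.weekly_amplitude < 0 or self.annual_amplitude < 0:
            raise ValueError("seasonal amplitudes must be >= 0")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0 (use math.inf for Poisson)")
        for name in self.covariate_betas:
            if name not in COVARIATE_COLUMNS:
                raise ValueError(f"unknown covariate in betas: {name!r}")
        for e in self.injected_effects:
            if e.multiplier <= 0:
                raise ValueError("injected multiplier must be > 0")
            if not (self.event_date <= e.start <= e.end <= self.study_end):
                raise ValueError(
                    f"injected-effect window {e.start}..{e.end} must lie within "
                    f"[{self.event_date}, {self.study_end}]"
                )
            if e.zone not in ZONES or e.setting not in SETTINGS or e.cause not in CAUSES:
                raise ValueError(f"injected effect targets unknown stratum {e}")

    # -- derived structure ----------------------------------------------
    def _iter_cells(self):
        for zone in self.zones:
            for setting in SETTINGS:
                for cause in CAUSES:
                    yield zone, setting, cause

    @property
    def zones(self) -> tuple[str, ...]:
        return tuple(z for z in ZONES if z in self.n_tracts_per_zone)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.study_start, self.study_end, freq="D")

    def cell_baseline(self, zone: str, setting: str, cause: str) -> float:
        if isinstance(self.baseline_rate, Mapping):
            key = (zone, setting, cause)
            if key in self.baseline_rate:
                return float(self.baseline_rate[key])
            return float(self.baseline_rate.get("default", 0.0))
        return float(self.baseline_rate)

    def tracts(self) -> pd.DataFrame:
        """Synthetic tract roster: one row per tract with its true zone."""
        rows = []
        for zone in self.zones:
            for i in range(int(self.n_tracts_per_zone[zone])):
                rows.append({"tract_id": f"T-{zone}-{i:04d}", "zone": zone})
        return pd.DataFrame(rows)

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["study_start"] = self.study_start.isoformat()
        doc["study_end"] = self.study_end.isoformat()
        doc["event_date"] = self.event_date.isoformat()
        doc["n_tracts_per_zone"] = dict(self.n_tracts_per_zone)
        doc["covariate_betas"] = dict(self.covariate_betas)
        if isinstance(self.baseline_rate, Mapping):
            doc["baseline_rate"] = {
                ("default" if k == "default" else "|".join(k)): float(v)
                for k, v in self.baseline_rate.items()
            }
        doc["injected_effects"] = [
            {
                "zone": e.zone,
                "setting": e.setting,
                "cause": e.cause,
                "start": e.start.isoformat(),
                "end": e.end.isoformat(),
                "multiplier": e.multiplier,
            }
            for e in self.injected_effects
        ]
        if math.isinf(self.dispersion):
            doc["dispersion"] = "inf"
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if isinstance(doc.get("baseline_rate"), Mapping):
            doc["baseline_rate"] = {
                ("default" if k == "default" else tuple(k.split("|"))): v
                for k, v in doc["baseline_rate"].items()
            }
        if doc.get("dispersion") == "inf":
            doc["dispersion"] = math.inf
        return cls(**doc)


def holiday_dates(start: dt.date, end: dt.date) -> pd.DatetimeIndex:
    """US federal holidays plus the Dec 24 - Jan 1 block, inclusive of ends."""
    cal = USFederalHolidayCalendar()
    fed = cal.holidays(start=pd.Timestamp(start), end=pd.Timestamp(end))
    extra = []
    for year in range(start.year - 1, end.year + 1):
        block = pd.date_range(dt.date(year, 12, 24), dt.date(year + 1, 1, 1), freq="D")
        extra.append(block)
    days = fed.union(extra[0])
    for block in extra[1:]:
        days = days.union(block)
    return days[(days >= pd.Timestamp(start)) & (days <= pd.Timestamp(end))]
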