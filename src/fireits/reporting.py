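"""Cohort characteristics tables and insured-population extrapolation.

The cohort table summarizes a member roster by exposure stratum (total /
high / moderate / minimal): counts with percents per demographic level and
median (IQR) age at a reference date. Market-share extrapolation scales a
cohort-level excess estimate to the full insured population by dividing by
the cohort's coverage fraction in each zone; the CI bounds scale by the same
factor (the coverage fraction is treated as a known constant).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .excess import ExcessEstimate
from .scenario import RACE_LEVELS, SEX_LEVELS
from .zoning import ExposureZone

_COLUMNS = ("total", "high", "moderate", "minimal")


def cohort_percent(level_count: int, column_total: int) -> str:
    """Format a table percent: half-up to 1 decimal; '<0.1' below 0.05%."""
    if column_total <= 0:
        raise ValueError("column_total must be > 0")
    if not (0 <= level_count <= column_total):
        raise ValueError("level_count must lie in [0, column_total]")
    pct = 100.0 * level_count / column_total
    if 0 < pct < 0.05:
        return "<0.1"
    return str(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class CohortTable:
    frame: pd.DataFrame  # formatted cells, index = row label, columns = strata
    counts: pd.DataFrame  # raw level counts

    def to_markdown(self) -> str:
        return self.frame.to_markdown()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


def _median_iqr(ages: np.ndarray) -> str:
    if len(ages) == 0:
        return "—"
    med, q1, q3 = np.percentile(ages, [50, 25, 75])  # linear interpolation
    return f"{med:.0f} ({q1:.0f}-{q3:.0f})"


def cohort_table(
    members: pd.DataFrame,
    zoning: Iterable[ExposureZone],
    reference_date: dt.date,
) -> CohortTable:
    """Build the stratified cohort characteristics table.

    ``members`` needs columns member_id, tract_id, birth_date, sex,
    race_ethnicity. Every member's tract must appear in ``zoning``. Age is
    computed at ``reference_date``. Unknown demographic levels are reported,
    never dropped; an empty stratum renders "0 (—)".
    """
    zone_of = {z.tract_id: z.zone for z in zoning}
    m = members.copy()
    unzoned = set(m["tract_id"].astype(str)) - set(zone_of)
    if unzoned:
        raise ValueError(f"members in unzoned tracts: {sorted(unzoned)[:5]}")
    m["zone"] = m["tract_id"].astype(str).map(zone_of)
    ref = pd.Timestamp(reference_date)
    m["age_years"] = (ref - pd.to_datetime(m["birth_date"])).dt.days / 365.25

    def column_mask(col: str) -> pd.Series:
        return m["zone"].notna() if col == "total" else m["zone"] == col

    rows: dict[str, dict[str, str]] = {}
    counts: dict[str, dict[str, int]] = {}
    rows["N"] = {c: str(int(column_mask(c).sum())) for c in _COLUMNS}
    rows["Age, median (IQR), y"] = {
        c: _median_iqr(m.loc[column_mask(c), "age_years"].to_numpy()) for c in _COLUMNS
    }
    for attr, levels, title in (
        ("sex", SEX_LEVELS, "Sex"),
        ("race_ethnicity", RACE_LEVELS, "Race and ethnicity"),
    ):
        for level in levels:
            label = f"{title}: {level}"
            cell: dict[str, str] = {}
            cnt: dict[str, int] = {}
            for col in _COLUMNS:
                sub = m.loc[column_mask(col)]
                n = int((sub[attr] == level).sum())
                total = len(sub)
                cnt[col] = n
                cell[col] = f"{n} ({cohort_percent(n, total)})" if total > 0 else "0 (—)"
            rows[label] = cell
            counts[label] = cnt
    frame = pd.DataFrame(rows).T[list(_COLUMNS)]
    return CohortTable(frame=frame, counts=pd.DataFrame(counts).T)


def extrapolate(
    estimate: ExcessEstimate | Sequence[ExcessEstimate],
    coverage: Mapping[str, float],
) -> ExcessEstimate:
    """Scale cohort-level excess to the insured population by market share.

    Each zone-level estimate is divided by that zone's coverage fraction
    (cohort members / insured residents, in (0, 1]); point estimate and CI
    bounds scale identically. A list of same-window estimates across zones
    is scaled per zone and then summed (counts and count CIs add; percent
    excess is recomputed from the summed totals).
    """
    singles = [estimate] if isinstance(estimate, ExcessEstimate) else list(estimate)
    scaled = []
    for est in singles:
        zone = est.stratum[0] if est.stratum else None
        if zone not in coverage:
            raise ValueError(f"no coverage fraction for zone {zone!r}")
        f = float(coverage[zone])
        if not (0 < f <= 1):
            raise ValueError(f"coverage fraction for {zone!r} must be in (0, 1]")
        scaled.append(
            dataclasses.replace(
                est,
                observed=est.observed / f,
                predicted=est.predicted / f,
                excess=est.excess / f,
                excess_ci_low=est.excess_ci_low / f,
                excess_ci_high=est.excess_ci_high / f,
            )
        )
    if len(scaled) == 1:
        return scaled[0]
    windows = {s.window for s in scaled}
    if len(windows) != 1:
        raise ValueError("cannot sum estimates over different windows")
    obs = sum(s.observed for s in scaled)
    pred = sum(s.predicted for s in scaled)
    ex = obs - pred
    return ExcessEstimate(
        stratum=None,
        window=scaled[0].window,
        observed=obs,
        predicted=pred,
        excess=ex,
        pct_excess=100.0 * ex / pred if pred > 0 else float("nan"),
        ci_low=float("nan"),  # percent CI does not aggregate across zones
        ci_high=float("nan"),
        excess_ci_low=sum(s.excess_ci_low for s in scaled),
        excess_ci_high=sum(s.excess_ci_high for s in scaled),
        n_iterations=scaled[0].n_iterations,
    )
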