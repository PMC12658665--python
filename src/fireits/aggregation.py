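"""ICD-10 cause categorization and aggregation to the daily visit series.

Five cause categories drive the analysis: all-cause plus four specific
ICD-10 chapter ranges (cardiovascular I00-I99, injury S00-T88,
neuropsychiatric F01-F99, respiratory J00-J99). Membership is decided by
the 3-character code root alone, compared lexicographically against the
inclusive range bounds; subcodes after the dot never change the category.

An encounter listing codes in two ranges increments both specific-cause
counts but contributes exactly once to all-cause, so the all-cause series
conserves the number of encounters.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import pandas as pd

from .scenario import CAUSES, SETTINGS
from .zoning import ExposureZone

#: Inclusive 3-character root ranges per specific cause category.
CAUSE_RANGES: dict[str, tuple[str, str]] = {
    "cardiovascular": ("I00", "I99"),
    "injury": ("S00", "T88"),
    "neuropsychiatric": ("F01", "F99"),
    "respiratory": ("J00", "J99"),
}

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.[A-Za-z0-9]+)?$")


def classify_icd10(code: str) -> frozenset[str]:
    """Map an ICD-10 code to the cause categories it belongs to.

    Always contains ``all_cause``; adds every specific category whose
    inclusive root range covers the code's first three characters.

    >>> sorted(classify_icd10("J45.901"))
    ['all_cause', 'respiratory']
    """
    code = str(code).strip()
    if not _CODE_RE.match(code):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    root = code[:3]
    cats = {"all_cause"}
    for name, (lo, hi) in CAUSE_RANGES.items():
        if lo <= root <= hi:
            cats.add(name)
    return frozenset(cats)


def dense_grid(
    dates: pd.DatetimeIndex,
    zones: Sequence[str],
    settings: Sequence[str] = SETTINGS,
    causes: Sequence[str] = CAUSES,
) -> pd.DataFrame:
    """All-zero dense visit grid over dates x zones x settings x causes."""
    idx = pd.MultiIndex.from_product(
        [dates, list(zones), list(settings), list(causes)],
        names=["date", "zone", "setting", "cause"],
    )
    return idx.to_frame(index=False).assign(count=0)


def aggregate(
    encounters: pd.DataFrame,
    zoning: Iterable[ExposureZone],
    dates: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """Aggregate encounter records to the daily zone x setting x cause series.

    Parameters
    ----------
    encounters
        Table with columns ``date``, ``tract_id``, ``setting`` and ``icd10``
        (semicolon-separated when an encounter lists several diagnoses).
    zoning
        Tract exposure assignments; every encounter tract must be zoned.
    dates
        Calendar to densify over; defaults to the encounter date span.

    Returns a dense grid with explicit zero rows so downstream models see
    every calendar day.
    """
    zone_of = {z.tract_id: z.zone for z in zoning}
    zones = sorted(set(zone_of.values()), key=["high", "moderate", "minimal"].index)

    enc = encounters.copy()
    enc["date"] = pd.to_datetime(enc["date"]).dt.normalize()
    unknown = set(enc["tract_id"].astype(str)) - set(zone_of)
    if unknown:
        raise ValueError(f"encounters reference unzoned tracts: {sorted(unknown)[:5]}")
    bad_setting = set(enc["setting"]) - set(SETTINGS)
    if bad_setting:
        raise ValueError(f"unknown care settings: {sorted(bad_setting)}")

    if dates is None:
        if len(enc) == 0:
            raise ValueError("no encounters and no explicit date range")
        dates = pd.date_range(enc["date"].min(), enc["date"].max(), freq="D")

    grid = dense_grid(dates, zones).set_index(["date", "zone", "setting", "cause"])
    if len(enc) > 0:
        records = []
        for row in enc.itertuples(index=False):
            cats: set[str] = set()
            for code in str(row.icd10).split(";"):
                code = code.strip()
                if code:
                    cats |= classify_icd10(code)
            zone = zone_of[str(row.tract_id)]
            records.extend((row.date, zone, row.setting, c) for c in cats)
        tallies = (
            pd.DataFrame(records, columns=["date", "zone", "setting", "cause"])
            .value_counts()
            .rename("count")
        )
        grid["count"] = grid["count"].add(tallies, fill_value=0).astype(int)
    return grid.reset_index()


def stratum_series(
    visits: pd.DataFrame, zone: str, setting: str, cause: str
) -> pd.Series:
    """Extract one stratum's daily count series, indexed by date."""
    sel = visits[
        (visits["zone"] == zone)
        & (visits["setting"] == setting)
        & (visits["cause"] == cause)
    ]
    s = sel.set_index(pd.to_datetime(sel["date"]))["count"].sort_index()
    s.index.name = "date"
    return s
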