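"""Distance-buffer exposure zoning of census tracts around wildfire burn zones.

Tracts are classified by the great-circle distance from their representative
point to the nearest point on the union of burn-zone polygon boundaries:

* ``high``     — distance < buffer (default 20 km),
* ``moderate`` — at/beyond the buffer but inside LA County,
* ``minimal``  — at/beyond the buffer outside LA County.

Polygon edges are treated as straight segments in longitude/latitude space
(GeoJSON semantics); the point-to-edge distance is found by bounded scalar
minimization of the haversine distance along each edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from shapely.geometry import Point, Polygon, shape

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class TractGeometry:
    tract_id: str
    lon: float
    lat: float
    county: str = ""
    in_la_county: bool = True


@dataclass(frozen=True)
class BurnZone:
    fire_name: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if len(self.polygon.exterior.coords) < 4:  # closed ring: >=3 distinct
            raise ValueError(f"burn zone {self.fire_name!r} needs >= 3 vertices")
        if not self.polygon.is_valid:
            raise ValueError(f"burn zone {self.fire_name!r} polygon is invalid")


@dataclass(frozen=True)
class ExposureZone:
    tract_id: str
    zone: str
    distance_km: float
    buffer_km: float


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _segment_min_km(lon, lat, a, b) -> float:
    """Min haversine distance from (lon, lat) to the lon/lat-linear segment a-b."""
    ax, ay = a
    bx, by = b

    def f(t: float) -> float:
        return float(haversine_km(lon, lat, ax + t * (bx - ax), ay + t * (by - ay)))

    # Coarse scan guards against flat/multimodal profiles before refinement.
    ts = np.linspace(0.0, 1.0, 17)
    vals = [f(t) for t in ts]
    i = int(np.argmin(vals))
    lo, hi = ts[max(i - 1, 0)], ts[min(i + 1, len(ts) - 1)]
    res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    return min(float(res.fun), vals[i])


def distance_to_burn_zones(lon: float, lat: float, zones: Sequence[BurnZone]) -> float:
    """Distance (km) from a point to the nearest burn-zone boundary; 0 inside."""
    if not zones:
        raise ValueError("at least one burn zone is required")
    pt = Point(lon, lat)
    best = np.inf
    for z in zones:
        if z.polygon.covers(pt):
            return 0.0
        coords = list(z.polygon.exterior.coords)
        for a, b in zip(coords[:-1], coords[1:]):
            best = min(best, _segment_min_km(lon, lat, a, b))
    return float(best)


def classify_tracts(
    tracts: Iterable[TractGeometry],
    zones: Sequence[BurnZone],
    buffer_km: float = 20.0,
) -> list[ExposureZone]:
    """Assign each tract to high/moderate/minimal exposure.

    A tract at exactly the buffer distance is *not* high (the high zone is the
    strict-interior "within" of the buffer). Output order matches input order.
    """
    if buffer_km <= 0:
        raise ValueError("buffer_km must be > 0")
    out = []
    for t in tracts:
        if not (-180 <= t.lon <= 180 and -90 <= t.lat <= 90):
            raise ValueError(f"tract {t.tract_id!r} has invalid coordinates ({t.lon}, {t.lat})")
        d = distance_to_burn_zones(t.lon, t.lat, zones)
        if d < buffer_km:
            zone = "high"
        elif t.in_la_county:
            zone = "moderate"
        else:
            zone = "minimal"
        out.append(ExposureZone(t.tract_id, zone, d, buffer_km))
    return out


# -- I/O helpers ---------------------------------------------------------

def load_burn_zones(path) -> list[BurnZone]:
    """Read burn-zone polygons from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        doc = json.load(fh)
    zones = []
    for feat in doc["features"]:
        geom = shape(feat["geometry"])
        name = feat.get("properties", {}).get("fire_name", "unnamed")
        if geom.geom_type == "Polygon":
            zones.append(BurnZone(name, geom))
        elif geom.geom_type == "MultiPolygon":
            zones.extend(BurnZone(name, p) for p in geom.geoms)
        else:
            raise ValueError(f"feature {name!r} is not a polygon")
    return zones


def tracts_from_frame(frame: pd.DataFrame) -> list[TractGeometry]:
    """Build tract geometries from a table (tract_id, lon, lat, county, in_la_county)."""
    return [
        TractGeometry(
            tract_id=str(r.tract_id),
            lon=float(r.lon),
            lat=float(r.lat),
            county=str(getattr(r, "county", "")),
            in_la_county=bool(getattr(r, "in_la_county", True)),
        )
        for r in frame.itertuples(index=False)
    ]


def zoning_frame(zoning: Sequence[ExposureZone]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tract_id": [z.tract_id for z in zoning],
            "zone": [z.zone for z in zoning],
            "distance_km": [z.distance_km for z in zoning],
            "buffer_km": [z.buffer_km for z in zoning],
        }
    )
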