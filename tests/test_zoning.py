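"""Exposure zoning: great-circle distances, buffer rules, partition laws."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from fireits import (
    BurnZone,
    TractGeometry,
    classify_tracts,
    distance_to_burn_zones,
    haversine_km,
    load_burn_zones,
)

KM_PER_DEG_LAT = math.pi / 180.0 * 6371.0088  # ~111.195 km


def square(lon0, lat0, half_deg, name="test-fire"):
    return BurnZone(
        name,
        Polygon(
            [
                (lon0 - half_deg, lat0 - half_deg),
                (lon0 + half_deg, lat0 - half_deg),
                (lon0 + half_deg, lat0 + half_deg),
                (lon0 - half_deg, lat0 + half_deg),
                (lon0 - half_deg, lat0 - half_deg),
            ]
        ),
    )


def dense_boundary_distance(lon, lat, zone: BurnZone, per_edge=600) -> float:
    """Independent oracle: min haversine over densely sampled boundary points."""
    coords = list(zone.polygon.exterior.coords)
    best = np.inf
    for (ax, ay), (bx, by) in zip(coords[:-1], coords[1:]):
        t = np.linspace(0.0, 1.0, per_edge)
        d = haversine_km(lon, lat, ax + t * (bx - ax), ay + t * (by - ay))
        best = min(best, float(np.min(d)))
    return best


class TestDistance:
    def test_point_inside_polygon_is_zero(self):
        z = square(-118.5, 34.1, 0.2)
        assert distance_to_burn_zones(-118.5, 34.1, [z]) == 0.0

    def test_one_degree_of_latitude_due_south(self):
        # point 1 degree south of the southern edge vertex, same meridian
        z = square(-118.5, 34.1, 0.2)
        d = distance_to_burn_zones(-118.7, 34.1 - 0.2 - 1.0, [z])
        assert d == pytest.approx(KM_PER_DEG_LAT, rel=1e-4)

    def test_min_decomposes_over_zones(self):
        z1 = square(-118.5, 34.1, 0.1)
        z2 = square(-117.5, 33.5, 0.1)
        lon, lat = -118.0, 33.0
        both = distance_to_burn_zones(lon, lat, [z1, z2])
        single = min(
            distance_to_burn_zones(lon, lat, [z1]),
            distance_to_burn_zones(lon, lat, [z2]),
        )
        assert both == pytest.approx(single, abs=1e-9)

    def test_empty_zone_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            distance_to_burn_zones(0.0, 0.0, [])

    def test_agrees_with_dense_boundary_oracle(self):
        # irregular polygons with <= 20 vertices, points 10-80 km away
        rng = np.random.default_rng(17)
        for _ in range(6):
            n_vert = int(rng.integers(5, 20))
            ang = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
            rad = rng.uniform(0.05, 0.25, n_vert)
            ring = [
                (-118.5 + r * np.cos(a), 34.1 + r * np.sin(a))
                for a, r in zip(ang, rad)
            ]
            ring.append(ring[0])
            poly = Polygon(ring)
            if not poly.is_valid:
                continue
            zone = BurnZone("rand", poly)
            bearing = rng.uniform(0, 2 * np.pi)
            dist_deg = rng.uniform(0.3, 0.7)
            lon = -118.5 + dist_deg * np.cos(bearing)
            lat = 34.1 + dist_deg * np.sin(bearing)
            got = distance_to_burn_zones(lon, lat, [zone])
            want = dense_boundary_distance(lon, lat, zone)
            assert got == pytest.approx(want, rel=1e-3)


class TestClassification:
    def tract_at_km(self, km_south, tract_id="t", in_la=True):
        z = square(-118.5, 34.5, 0.2)
        lat = 34.5 - 0.2 - km_south / KM_PER_DEG_LAT
        return TractGeometry(tract_id, -118.5, lat, in_la_county=in_la), z

    def test_within_buffer_is_high(self):
        tract, z = self.tract_at_km(5.0)
        assert classify_tracts([tract], [z], 20.0)[0].zone == "high"

    def test_sensitivity_buffer_flips_to_moderate(self):
        tract, z = self.tract_at_km(15.0)
        assert classify_tracts([tract], [z], 20.0)[0].zone == "high"
        assert classify_tracts([tract], [z], 10.0)[0].zone == "moderate"

    def test_exact_buffer_distance_is_not_high(self):
        tract, z = self.tract_at_km(12.0)
        d = classify_tracts([tract], [z], 20.0)[0].distance_km
        out = classify_tracts([tract], [z], buffer_km=d)
        assert out[0].zone != "high"

    def test_outside_buffer_outside_la_is_minimal(self):
        tract, z = self.tract_at_km(30.0, in_la=False)
        assert classify_tracts([tract], [z], 20.0)[0].zone == "minimal"

    def test_invalid_coordinates_name_the_tract(self):
        z = square(-118.5, 34.5, 0.2)
        bad = TractGeometry("bad-tract", -200.0, 34.0)
        with pytest.raises(ValueError, match="bad-tract"):
            classify_tracts([bad], [z])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        lon=st.floats(-119.5, -117.5),
        lat=st.floats(33.0, 35.5),
        in_la=st.booleans(),
        buffer_km=st.floats(5.0, 30.0),
    )
    def test_partition_single_label(self, lon, lat, in_la, buffer_km):
        z = square(-118.5, 34.5, 0.2)
        tract = TractGeometry("t", lon, lat, in_la_county=in_la)
        out = classify_tracts([tract], [z], buffer_km)
        assert len(out) == 1
        e = out[0]
        assert e.zone in ("high", "moderate", "minimal")
        assert (e.zone == "high") == (e.distance_km < buffer_km)
        if e.zone == "moderate":
            assert in_la
        if e.zone == "minimal":
            assert not in_la

    def test_high_set_monotone_in_buffer(self):
        z = square(-118.5, 34.5, 0.2)
        rng = np.random.default_rng(4)
        tracts = [
            TractGeometry(f"t{i}", -118.5 + rng.uniform(-1, 1), 34.5 + rng.uniform(-1, 1))
            for i in range(40)
        ]
        previous: set[str] = set()
        for buffer_km in (5, 10, 15, 20, 25, 30):
            high = {
                e.tract_id
                for e in classify_tracts(tracts, [z], buffer_km)
                if e.zone == "high"
            }
            assert previous <= high
            previous = high


def test_geojson_loader(tmp_path):
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"fire_name": "Eaton"},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[-118.2, 34.2], [-118.0, 34.2], [-118.0, 34.3],
                         [-118.2, 34.3], [-118.2, 34.2]]
                    ],
                },
            }
        ],
    }
    path = tmp_path / "burns.geojson"
    path.write_text(json.dumps(doc))
    zones = load_burn_zones(path)
    assert len(zones) == 1 and zones[0].fire_name == "Eaton"
    assert distance_to_burn_zones(-118.1, 34.25, zones) == 0.0
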