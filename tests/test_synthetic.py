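"""Generator behavior: determinism, mean structure, invariants, injections."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from fireits import (
    InjectedEffect,
    SyntheticScenario,
    expected_mean,
    generate_covariates,
    generate_members,
    generate_visits,
    holiday_dates,
    stratum_series,
)


def tiny_scenario(**kw):
    base = dict(
        study_start=dt.date(2022, 11, 1),
        study_end=dt.date(2022, 11, 10),
        event_date=dt.date(2022, 11, 9),
        n_tracts_per_zone={"high": 1},
        seed=1,
    )
    base.update(kw)
    return SyntheticScenario(**base)


class TestScenario:
    def test_date_ordering_enforced(self):
        with pytest.raises(ValueError, match="study_start"):
            SyntheticScenario(event_date=dt.date(2022, 10, 1))

    def test_injected_window_must_be_post_event(self):
        with pytest.raises(ValueError, match="window"):
            SyntheticScenario(
                injected_effects=[
                    InjectedEffect(
                        "high", "virtual", "respiratory",
                        dt.date(2024, 12, 1), dt.date(2025, 1, 10), 1.5,
                    )
                ]
            )

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            SyntheticScenario(baseline_rate=-1.0)

    def test_yaml_round_trip(self, tmp_path):
        sc = SyntheticScenario(
            baseline_rate={("high", "virtual", "respiratory"): 55.0, "default": 20.0},
            dispersion=math.inf,
            injected_effects=[
                InjectedEffect(
                    "high", "virtual", "respiratory",
                    dt.date(2025, 1, 7), dt.date(2025, 1, 13), 1.4,
                )
            ],
            seed=9,
        )
        path = tmp_path / "scenario.yaml"
        sc.to_yaml(path)
        back = SyntheticScenario.from_yaml(path)
        assert back == sc

    def test_holiday_calendar_covers_winter_block_and_fourth_of_july(self):
        days = holiday_dates(dt.date(2023, 1, 1), dt.date(2023, 12, 31))
        assert pd.Timestamp("2023-07-04") in days
        for d in pd.date_range("2023-12-24", "2023-12-31"):
            assert d in days
        assert pd.Timestamp("2023-03-15") not in days


class TestMembers:
    def test_empty_roster(self, flat_scenario):
        assert len(generate_members(flat_scenario, 0)) == 0

    def test_deterministic_given_seed(self, flat_scenario):
        a = generate_members(flat_scenario, 500)
        b = generate_members(flat_scenario, 500)
        pd.testing.assert_frame_equal(a, b)

    def test_female_fraction_within_binomial_error(self, flat_scenario):
        # binomial oracle: SE = sqrt(p(1-p)/n)
        n, p = 10_000, 0.522
        members = generate_members(flat_scenario, n)
        se = math.sqrt(p * (1 - p) / n)
        observed = (members["sex"] == "female").mean()
        assert abs(observed - p) < 3 * se

    def test_unnormalized_mix_names_attribute(self, flat_scenario):
        mix = {"sex": {"female": 0.6, "male": 0.6}}
        with pytest.raises(ValueError, match="sex"):
            generate_members(flat_scenario, 10, demographic_mix=mix)


class TestCovariates:
    def test_one_row_per_date_and_zone(self):
        panel = generate_covariates(tiny_scenario())
        assert len(panel) == 10
        assert panel["zone"].unique().tolist() == ["high"]

    def test_noise_free_limit_matches_seasonal_curve(self):
        sc = tiny_scenario()
        panel = generate_covariates(sc, noise_scale=0.0)
        doy = pd.to_datetime(panel["date"]).dt.dayofyear.to_numpy(dtype=float)
        curve = 23.0 + 7.5 * np.cos(2 * np.pi * (doy - 200.0) / 365.25)
        np.testing.assert_allclose(panel["tmax_c"].to_numpy(), curve, rtol=0, atol=1e-12)

    def test_physical_invariants_hold(self):
        sc = SyntheticScenario(seed=3)
        panel = generate_covariates(sc)
        assert (panel["tmax_c"] >= panel["tmin_c"]).all()
        assert (panel["rhmax_pct"] >= panel["rhmin_pct"]).all()
        assert panel["rhmax_pct"].between(0, 100).all()
        assert (panel["wind_ms"] >= 0).all()
        assert (panel["srad_wm2"] >= 0).all()

    def test_wastewater_constant_within_iso_week(self):
        sc = SyntheticScenario(n_tracts_per_zone={"high": 1}, seed=5)
        panel = generate_covariates(sc)
        iso = pd.to_datetime(panel["date"]).dt.isocalendar()
        grouped = panel.groupby([iso["year"], iso["week"]])
        for virus in ("ww_flu", "ww_rsv", "ww_cov"):
            assert (grouped[virus].nunique() == 1).all()


class TestVisits:
    def test_poisson_mean_oracle(self, flat_scenario):
        cov = generate_covariates(flat_scenario)
        visits = generate_visits(flat_scenario, cov)
        s = stratum_series(visits, "high", "virtual", "respiratory")
        n_days = len(s)
        se = math.sqrt(100.0 / n_days)
        assert abs(s.mean() - 100.0) < 3 * se

    def test_injected_multiplier_shifts_only_the_window(self, flat_scenario):
        import dataclasses

        window = (dt.date(2025, 1, 7), dt.date(2025, 1, 13))
        sc = dataclasses.replace(
            flat_scenario,
            injected_effects=[
                InjectedEffect("high", "virtual", "respiratory", *window, 1.4)
            ],
        )
        cov = generate_covariates(sc)
        s = stratum_series(generate_visits(sc, cov), "high", "virtual", "respiratory")
        in_window = s[pd.Timestamp(window[0]): pd.Timestamp(window[1])]
        se = math.sqrt(140.0 / len(in_window))
        assert abs(in_window.mean() - 140.0) < 3 * se

    def test_zero_baseline_gives_zero_counts(self, flat_scenario):
        import dataclasses

        sc = dataclasses.replace(flat_scenario, baseline_rate=0.0)
        visits = generate_visits(sc, generate_covariates(sc))
        assert (visits["count"] == 0).all()

    def test_byte_identical_given_seed(self):
        sc = SyntheticScenario(n_tracts_per_zone={"high": 1, "moderate": 1}, seed=11)
        cov1, cov2 = generate_covariates(sc), generate_covariates(sc)
        pd.testing.assert_frame_equal(cov1, cov2)
        pd.testing.assert_frame_equal(generate_visits(sc, cov1), generate_visits(sc, cov2))

    def test_injection_elsewhere_leaves_cell_untouched(self):
        base = SyntheticScenario(n_tracts_per_zone={"high": 1, "moderate": 1}, seed=13)
        injected = SyntheticScenario(
            n_tracts_per_zone={"high": 1, "moderate": 1},
            injected_effects=[
                InjectedEffect(
                    "high", "virtual", "respiratory",
                    dt.date(2025, 1, 7), dt.date(2025, 1, 13), 2.0,
                )
            ],
            seed=13,
        )
        cov = generate_covariates(base)
        v0 = generate_visits(base, cov)
        v1 = generate_visits(injected, cov)
        untouched0 = stratum_series(v0, "moderate", "outpatient", "cardiovascular")
        untouched1 = stratum_series(v1, "moderate", "outpatient", "cardiovascular")
        pd.testing.assert_series_equal(untouched0, untouched1)
        # and the targeted cell did change inside the window
        t0 = stratum_series(v0, "high", "virtual", "respiratory")
        t1 = stratum_series(v1, "high", "virtual", "respiratory")
        assert (t1["2025-01-07":"2025-01-13"] != t0["2025-01-07":"2025-01-13"]).any()

    def test_covariate_gap_rejected_with_dates(self, flat_scenario):
        cov = generate_covariates(flat_scenario)
        gap = cov[pd.to_datetime(cov["date"]) != pd.Timestamp("2023-05-05")]
        with pytest.raises(ValueError, match="2023-05-05"):
            generate_visits(flat_scenario, gap)

    def test_closed_form_mean_tracks_empirical_mean(self):
        sc = SyntheticScenario(n_tracts_per_zone={"high": 1}, dispersion=math.inf, seed=21)
        cov = generate_covariates(sc)
        s = stratum_series(generate_visits(sc, cov), "high", "outpatient", "all_cause")
        mu = expected_mean(sc, cov, "high", "outpatient", "all_cause")
        # standardized daily deviations should behave like unit-variance noise
        z = (s - mu) / np.sqrt(mu)
        assert abs(z.mean()) < 3 / math.sqrt(len(z))
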