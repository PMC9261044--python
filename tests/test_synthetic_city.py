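"""Synthetic city, cohort, wear-day, census, weather generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import Point

from actigeo import synthetic_city as sc
from actigeo.exposures import classify_gentrification
from actigeo.sensor_processing import ChoiParams, CutPoints, classify_intensity, compute_counts, detect_nonwear


class TestCity:
    def test_forced_2x2_grid_and_tract_sizes(self):
        city = sc.generate_city(4, das_per_tract=2, seed=0)
        assert city.n_da == 4 and city.nx == 2 and city.ny == 2
        tracts = pd.Series(city.tract_membership)
        assert sorted(tracts.value_counts().tolist()) == [2, 2]

    def test_zero_density_empties_every_layer(self):
        density = {k: 0.0 for k in sc.DEFAULT_AMENITY_DENSITY}
        city = sc.generate_city(9, 3, amenity_density=density, seed=1)
        assert all(len(p) == 0 for p in city.amenity_layers.values())

    def test_poisson_count_within_99pct_interval(self):
        city = sc.generate_city(100, 4, amenity_density={"transit_stops": 50.0}, seed=7)
        lam = 50.0 * city.extent_area_km2
        lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
        assert lo <= len(city.amenity_layers["transit_stops"]) <= hi

    def test_polygons_tile_without_overlap(self):
        city = sc.generate_city(16, 4, seed=0)
        polys = list(city.da_polygons().values())
        total = sum(p.area for p in polys)
        from shapely.ops import unary_union

        assert abs(unary_union(polys).area - total) < 1e-6

    def test_every_da_has_exactly_one_tract(self):
        city = sc.generate_city(10, 3, seed=0)
        assert set(city.tract_membership) == set(city.da_ids)
        assert all(len(v) > 0 for v in pd.Series(city.tract_membership).value_counts().items())

    def test_determinism(self):
        a = sc.generate_city(25, 5, seed=9)
        b = sc.generate_city(25, 5, seed=9)
        for k in a.amenity_layers:
            np.testing.assert_array_equal(a.amenity_layers[k], b.amenity_layers[k])
        assert a.tract_membership == b.tract_membership

    def test_config_errors(self):
        with pytest.raises(sc.ConfigurationError):
            sc.generate_city(2, 1)
        with pytest.raises(sc.ConfigurationError):
            sc.generate_city(9, 3, amenity_density={"dwellings": -1.0})


class TestCohort:
    def test_single_category_distributions_are_constant(self, small_city):
        demo = {k: {list(v)[0]: 1.0} for k, v in sc.DEFAULT_DEMOGRAPHICS.items()}
        roster = sc.generate_cohort(10, small_city, demographics=demo, seed=0)
        for col in demo:
            assert roster[col].nunique() == 1

    def test_concentrated_home_weights(self, small_city):
        w = {d: 0.0 for d in small_city.da_ids}
        w["DA0003"] = 1.0
        roster = sc.generate_cohort(10, small_city, home_da_weights=w, seed=0)
        assert (roster["home_da"] == "DA0003").all()

    def test_uniform_homes_pass_chi_square_gof(self):
        city = sc.generate_city(100, 4, seed=2)
        roster = sc.generate_cohort(1000, city, seed=2)
        observed = roster["home_da"].value_counts().reindex(city.da_ids, fill_value=0)
        chi2 = ((observed - 10.0) ** 2 / 10.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=99)

    def test_bad_probabilities_rejected(self, small_city):
        demo = dict(sc.DEFAULT_DEMOGRAPHICS)
        demo["age_group"] = {"18-24": 0.5, "25-44": 0.2}
        with pytest.raises(sc.ConfigurationError, match="sum"):
            sc.generate_cohort(5, small_city, demographics=demo)


def _one_day(city, truth, config, seed=0, roster_seed=0):
    roster = sc.generate_cohort(1, city, seed=roster_seed)
    exposure_da, tm = sc.generate_exposure_table(city, seed=1)
    da_cov = sc._da_covariate_frame(city, exposure_da, tm)
    weather = sc.generate_weather([pd.Timestamp("2018-06-04")], seed=1)
    re = sc.participant_random_effects(truth, 1, seed)
    rng = np.random.default_rng(seed)
    plan = sc.plan_day(
        roster.iloc[0], pd.Timestamp("2018-06-04"), 1, 1, city, truth, da_cov,
        weather.set_index("date").iloc[0], re[0], config, rng,
    )
    return roster, plan


class TestWearDay:
    def test_home_share_one_keeps_all_fixes_in_home_da(self, small_city):
        truth = sc.SyntheticTruth(home_dwell_share=1.0)
        config = sc.MobilityConfig(wear_minutes=60)
        roster, plan = _one_day(small_city, truth, config)
        mc, gps, _ = sc.materialize_counts_day(plan, small_city, config, np.random.default_rng(1))
        home_poly = small_city.da_polygon(roster.loc[0, "home_da"], wgs84=True)
        assert all(
            home_poly.covers(Point(x, y)) for x, y in zip(gps["lon"], gps["lat"])
        )

    def test_day_starts_and_ends_at_home(self, small_city):
        truth = sc.SyntheticTruth()
        config = sc.MobilityConfig(wear_minutes=200, n_destinations=2, dest_dwell_min=30)
        roster, plan = _one_day(small_city, truth, config)
        home = roster.loc[0, "home_da"]
        assert plan.episodes[0][0] == home and plan.episodes[-1][0] == home
        assert len({d for d, _ in plan.episodes}) == 3

    def test_all_fixes_within_city_extent(self, small_city):
        truth = sc.SyntheticTruth()
        config = sc.MobilityConfig(wear_minutes=120)
        _, plan = _one_day(small_city, truth, config)
        _, gps, _ = sc.materialize_counts_day(plan, small_city, config, np.random.default_rng(2))
        x, y = small_city.crs.to_planar(gps["lon"].to_numpy(), gps["lat"].to_numpy())
        assert (x >= 0).all() and (y >= 0).all()
        assert (x <= small_city.nx * small_city.cell_size_m).all()
        assert (y <= small_city.ny * small_city.cell_size_m).all()

    def test_constant_speed_travel_traces_the_transition(self, small_city):
        """With a travel speed set, the first fixes of a new episode move in a
        straight line from the previous anchor instead of jumping."""
        truth = sc.SyntheticTruth()
        snap = sc.MobilityConfig(wear_minutes=120, n_destinations=1, dest_dwell_min=30)
        travel = sc.MobilityConfig(
            wear_minutes=120, n_destinations=1, dest_dwell_min=30, travel_speed_m_s=15.0
        )
        _, plan = _one_day(small_city, truth, travel)
        _, gps, _ = sc.materialize_counts_day(plan, small_city, travel, np.random.default_rng(8))
        x, y = small_city.crs.to_planar(gps["lon"].to_numpy(), gps["lat"].to_numpy())
        # steps across the first episode boundary stay near the travel speed
        s0 = plan.episodes[0][1] * 60  # first fix of episode 2
        step = np.hypot(np.diff(x), np.diff(y))
        window = step[s0 - 1 : s0 + 30]
        assert window.max() <= 15.0 + 8 * travel.gps_noise_m
        # the minute-snapped counterpart jumps across the same boundary
        _, gps2, _ = sc.materialize_counts_day(plan, small_city, snap, np.random.default_rng(8))
        x2, y2 = small_city.crs.to_planar(gps2["lon"].to_numpy(), gps2["lat"].to_numpy())
        step2 = np.hypot(np.diff(x2), np.diff(y2))
        assert step2[s0 - 1] > window.max()

    def test_planted_nonwear_gap_recovered_exactly(self, small_city):
        truth = sc.SyntheticTruth()
        config = sc.MobilityConfig(wear_minutes=180, nonwear_gap_min=120)
        _, plan = _one_day(small_city, truth, config)
        mc, _, nonwear_truth = sc.materialize_counts_day(
            plan, small_city, config, np.random.default_rng(3)
        )
        assert len(nonwear_truth) == 1
        start, end = nonwear_truth[0]
        assert (end - start) == pd.Timedelta(minutes=119)
        wear = detect_nonwear(mc.set_index("minute_start")["counts"], ChoiParams())
        assert not wear[:120].any() and wear[120:].all()

    def test_row_truth_identities(self, small_city):
        truth = sc.SyntheticTruth()
        config = sc.MobilityConfig(wear_minutes=300)
        _, plan = _one_day(small_city, truth, config)
        rows = plan.rows()
        assert rows["minutes_total"].sum() == 300
        assert (
            rows["pa_minutes"]
            == rows["minutes_light"] + rows["minutes_moderate"] + rows["minutes_vigorous"]
        ).all()

    def test_unknown_home_da_rejected(self, small_city):
        truth = sc.SyntheticTruth()
        bad = pd.Series({"participant_id": "PX", "home_da": "DA9999"})
        exposure_da, tm = sc.generate_exposure_table(small_city, seed=1)
        da_cov = sc._da_covariate_frame(small_city, exposure_da, tm)
        weather = sc.generate_weather([pd.Timestamp("2018-06-04")], seed=1)
        with pytest.raises(sc.ConfigurationError, match="not in city"):
            sc.plan_day(
                bad, pd.Timestamp("2018-06-04"), 1, 1, small_city, truth, da_cov,
                weather.set_index("date").iloc[0], np.zeros(2), sc.MobilityConfig(),
                np.random.default_rng(0),
            )


class TestSignalFidelity:
    def test_signal_mode_reproduces_intended_classes(self, small_city):
        """Counts derived from the 50 Hz stream land in the planted band for
        >= 99% of worn minutes (band edges tolerate filter leakage)."""
        truth = sc.SyntheticTruth()
        config = sc.MobilityConfig(wear_minutes=60, n_destinations=1, dest_dwell_min=15)
        _, plan = _one_day(small_city, truth, config, seed=4)
        rng = np.random.default_rng(4)
        sig, _, _ = sc.materialize_signal_day(plan, small_city, config, rng)
        # planted per-minute classes from the shared count draw
        mc, _, _ = sc.materialize_counts_day(plan, small_city, config, np.random.default_rng(4))
        planted = classify_intensity(
            mc["counts"].to_numpy(), np.ones(len(mc), dtype=bool), CutPoints()
        )
        derived_counts = compute_counts(sig)["y"].to_numpy()
        derived = classify_intensity(
            derived_counts, np.ones(len(derived_counts), dtype=bool), CutPoints()
        )
        n = min(len(planted), len(derived))
        agree = (planted[:n] == derived[:n]).mean()
        assert agree >= 0.99


class TestCensusPanel:
    def test_classifier_recovers_constructed_labels(self, small_city):
        panel, metro, truth = sc.generate_census_panel(
            small_city, gentrify_fraction=0.5, high_ses_fraction=0.25, seed=5
        )
        got = classify_gentrification(panel, metro)
        pd.testing.assert_series_equal(got.sort_index(), truth.sort_index(), check_names=False)

    def test_gentrified_count_matches_fraction(self, small_city):
        n_tracts = len(set(small_city.tract_membership.values()))
        panel, metro, truth = sc.generate_census_panel(
            small_city, gentrify_fraction=1.0, high_ses_fraction=0.5, seed=6
        )
        got = classify_gentrification(panel, metro)
        eligible = n_tracts - int(round(0.5 * n_tracts))
        assert (got == "gentrified").sum() == eligible

    def test_zero_gentrify_all_high_ses(self, small_city):
        panel, metro, truth = sc.generate_census_panel(
            small_city, gentrify_fraction=0.0, high_ses_fraction=1.0, seed=7
        )
        assert (classify_gentrification(panel, metro) == "high_ses").all()

    def test_bad_fraction_rejected(self, small_city):
        with pytest.raises(sc.ConfigurationError):
            sc.generate_census_panel(small_city, gentrify_fraction=1.5)


class TestWeather:
    def test_deterministic_and_nonnegative(self):
        dates = pd.date_range("2018-01-01", periods=365)
        a = sc.generate_weather(dates, seed=11)
        b = sc.generate_weather(dates, seed=11)
        pd.testing.assert_frame_equal(a, b)
        assert (a["precipitation_mm"] >= 0).all()

    def test_zero_variance_config_constant(self):
        cfg = sc.WeatherConfig(p_wet=0.0, temp_seasonal_amp_c=0.0, temp_noise_sd_c=0.0)
        w = sc.generate_weather(pd.date_range("2018-01-01", periods=30), seed=1, config=cfg)
        assert (w["precipitation_mm"] == 0).all()
        assert w["temperature_c"].nunique() == 1


class TestTablePathConsistency:
    def test_direct_table_matches_pipeline_row_truth(self, small_cohort_inputs):
        """The cohort-scale table path and the minute-level path share draws."""
        from actigeo.validation import cohort_minutes_pipeline

        city, roster, exposure_da, tm, weather = small_cohort_inputs
        truth = sc.SyntheticTruth()
        table = sc.simulate_cohort_table(
            city, roster, truth, exposure_da, tm, weather, n_days=3, seed=3
        )
        agg, row_truth = cohort_minutes_pipeline(
            city, roster, truth, exposure_da, tm, weather, 3, sc.MobilityConfig(), seed=3
        )
        key = ["participant_id", "date", "da_id"]
        a = table[key + ["pa_minutes", "minutes_total"]].sort_values(key).reset_index(drop=True)
        b = row_truth[key + ["pa_minutes", "minutes_total"]].sort_values(key).reset_index(drop=True)
        a["date"] = pd.to_datetime(a["date"])
        b["date"] = pd.to_datetime(b["date"])
        pd.testing.assert_frame_equal(a, b)
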