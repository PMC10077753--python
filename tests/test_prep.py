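"""Screening filters, reproductive labelling and availability sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reprorsf.grids import Grid, Landscape
from reprorsf.prep import (
    availability_radius,
    correlation_screen,
    extract_and_standardize,
    fix_rate_filter,
    generate_available,
    label_reproduction,
    remove_2d,
    subsample_daily,
    tradeoff_regressions,
)


def make_fixes(animal_id, n, start="2016-02-01 06:00", freq="4h", x=500.0, y=500.0):
    ts = pd.date_range(start, periods=n, freq=freq)
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "year": 2016,
            "timestamp": ts,
            "x": x,
            "y": y,
            "fix_dim": "3D",
        }
    )


class TestFixRateFilter:
    @pytest.mark.parametrize(
        "achieved,kept", [(95, True), (90, False), (100, True), (91, True)]
    )
    def test_strict_90_percent_threshold(self, achieved, kept):
        fixes = make_fixes("A", achieved)
        out, rep = fix_rate_filter(fixes, scheduled=100)
        assert ("A" in out["animal_id"].values) is kept
        assert rep["animals"]["A"]["rate"] == achieved / 100

    def test_zero_scheduled_flagged_and_removed(self):
        fixes = make_fixes("A", 10)
        out, rep = fix_rate_filter(fixes, scheduled={"A": 0})
        assert len(out) == 0
        assert "A" in rep["removed_animals"]

    def test_counts_reconcile(self):
        fixes = pd.concat([make_fixes("A", 95), make_fixes("B", 50)], ignore_index=True)
        out, rep = fix_rate_filter(fixes, scheduled=100)
        assert rep["n_in"] == rep["n_out"] + rep["n_removed"] == 145
        assert set(out["animal_id"]) == {"A"}


class TestRemove2d:
    def test_conservation_over_mixed_table(self):
        fixes = make_fixes("A", 20)
        fixes.loc[::3, "fix_dim"] = "2D"
        out, rep = remove_2d(fixes)
        assert rep["n_in"] == rep["n_out"] + rep["n_2d_removed"]
        assert (out["fix_dim"] == "3D").all()

    def test_all_3d_identity_and_all_2d_empty(self):
        fixes = make_fixes("A", 10)
        out, _ = remove_2d(fixes)
        assert len(out) == 10
        fixes["fix_dim"] = "2D"
        out, rep = remove_2d(fixes)
        assert len(out) == 0 and rep["n_2d_removed"] == 10

    def test_missing_dim_counted(self):
        fixes = make_fixes("A", 5)
        fixes.loc[2, "fix_dim"] = None
        out, rep = remove_2d(fixes)
        assert rep["n_missing_dim"] == 1 and len(out) == 4


class TestSubsampleDaily:
    def test_six_slot_schedule_keeps_four(self):
        # the simulated schedule: 02,06,09,14,18,21 -> 2 morning + first 2 evening
        ts = [pd.Timestamp(f"2016-03-01 {h:02d}:00") for h in (2, 6, 9, 14, 18, 21)]
        fixes = pd.DataFrame(
            {"animal_id": "A", "year": 2016, "timestamp": ts, "x": 0.0, "y": 0.0,
             "fix_dim": "3D"}
        )
        out, rep = subsample_daily(fixes)
        hours = sorted(out["timestamp"].dt.hour)
        assert hours == [6, 9, 14, 18]
        assert rep["n_in"] == rep["n_out"] + rep["n_removed"]

    def test_outside_both_windows_gives_empty(self):
        ts = [pd.Timestamp("2016-03-01 11:30")] * 4
        fixes = pd.DataFrame(
            {"animal_id": "A", "year": 2016, "timestamp": ts, "x": 0.0, "y": 0.0,
             "fix_dim": "3D"}
        )
        out, _ = subsample_daily(fixes)
        assert len(out) == 0

    def test_first_rule_deterministic_and_random_rule_seeded(self):
        fixes = make_fixes("A", 60, freq="1h")
        a, _ = subsample_daily(fixes, rule="first")
        b, _ = subsample_daily(fixes, rule="first")
        pd.testing.assert_frame_equal(a, b)
        c, _ = subsample_daily(fixes, rule="random", seed=3)
        d, _ = subsample_daily(fixes, rule="random", seed=3)
        pd.testing.assert_frame_equal(c, d)

    def test_malformed_windows_rejected(self):
        fixes = make_fixes("A", 5)
        with pytest.raises(ValueError):
            subsample_daily(fixes, windows=((10.0, 4.0),))
        with pytest.raises(ValueError):
            subsample_daily(fixes, windows=((4.0, 14.0), (13.0, 22.0)))


@pytest.fixture()
def timelines():
    return pd.DataFrame(
        {
            "animal_id": ["A", "B", "C", "D"],
            "year": [2016] * 4,
            "pregnant": [True, True, True, False],
            "part_doy": pd.array([100, 100, 100, pd.NA], dtype="Int64"),
            # A survives, B dies day 10 (early loss), C dies day 35 (late loss)
            "death_day": pd.array([pd.NA, 10, 35, pd.NA], dtype="Int64"),
        }
    )


def fixes_on_days(animal, days, year=2016):
    ts = [pd.Timestamp(year, 1, 1) + pd.Timedelta(days=d - 1, hours=6) for d in days]
    return pd.DataFrame(
        {"animal_id": animal, "year": year, "timestamp": ts, "x": 1.0, "y": 1.0,
         "fix_dim": "3D"}
    )


class TestLabelReproduction:
    def test_day_before_parturition_is_preparturition(self, timelines):
        d1, d2, _ = label_reproduction(fixes_on_days("A", [99]), timelines)
        assert len(d1) == 1 and d1.iloc[0]["lamb"] == 0 and d1.iloc[0]["state"] == "pre"

    def test_provisioning_capped_at_120_days(self, timelines):
        d1, d2, rep = label_reproduction(fixes_on_days("A", [220, 221]), timelines)
        # day 220 = part + 120 still provisioning; 221 is past weaning
        assert len(d1) == 1 and d1.iloc[0]["lamb"] == 1 and d1.iloc[0]["part"] == 120
        assert rep["n_post_wean_excluded"] == 1

    def test_early_loss_female_feeds_dataset2(self, timelines):
        d1, d2, _ = label_reproduction(fixes_on_days("B", [105, 115]), timelines)
        # day 105 = part+5 provisioning (death day 10); 115 = post-mortality
        assert len(d1) == 1 and d1.iloc[0]["lamb"] == 1
        assert len(d2) == 1 and d2.iloc[0]["state"] == "ad" and d2.iloc[0]["lamb"] == 0

    def test_late_loss_female_contributes_no_dataset2_rows(self, timelines):
        d1, d2, rep = label_reproduction(fixes_on_days("C", [105, 140]), timelines)
        assert len(d2) == 0
        assert rep["n_late_loss_excluded"] == 1
        assert len(d1) == 1  # the provisioning row remains in dataset1

    def test_nonpregnant_females_excluded(self, timelines):
        d1, d2, rep = label_reproduction(fixes_on_days("D", [50, 120]), timelines)
        assert len(d1) == 0 and len(d2) == 0
        assert rep["n_nonpregnant_excluded"] == 2


class TestAvailabilityRadius:
    def test_two_step_direct_formula(self):
        fixes = pd.DataFrame(
            {
                "animal_id": "A",
                "timestamp": pd.date_range("2016-01-01", periods=3, freq="4h"),
                "x": [0.0, 100.0, 400.0],
                "y": 0.0,
            }
        )
        # steps 100 and 300
        want = 2.58 * np.std([100.0, 300.0], ddof=1)
        assert availability_radius(fixes) == pytest.approx(want)

    def test_normal_steps_approach_258(self, rng):
        n = 10_000
        steps = rng.normal(300, 100, n)
        x = np.concatenate([[0.0], np.cumsum(steps)])
        fixes = pd.DataFrame(
            {
                "animal_id": "A",
                "timestamp": pd.date_range("2016-01-01", periods=n + 1, freq="1h"),
                "x": x,
                "y": 0.0,
            }
        )
        assert availability_radius(fixes) == pytest.approx(258.0, rel=0.05)

    def test_degenerate_steps_rejected(self):
        fixes = pd.DataFrame(
            {
                "animal_id": "A",
                "timestamp": pd.date_range("2016-01-01", periods=4, freq="4h"),
                "x": [0.0, 50.0, 100.0, 150.0],
                "y": 0.0,
            }
        )
        with pytest.raises(ValueError):
            availability_radius(fixes)  # all steps identical -> SD 0


@pytest.fixture(scope="module")
def flat_landscape():
    return Landscape({"z": Grid(np.zeros((100, 100)), cell_size=10.0)})


class TestGenerateAvailable:
    def test_exact_ratio_bookkeeping(self, flat_landscape):
        used = pd.DataFrame({"x": np.full(37, 500.0), "y": np.full(37, 500.0)})
        out = generate_available(used, 50.0, flat_landscape, ratio=10, seed=1)
        assert len(out) == 370
        assert (out.groupby("stratum").size() == 10).all()

    def test_per_point_mode_containment(self, flat_landscape, rng):
        used = pd.DataFrame(
            {"x": rng.uniform(200, 800, 50), "y": rng.uniform(200, 800, 50)}
        )
        out = generate_available(used, 80.0, flat_landscape, ratio=10, seed=2,
                                 mode="per_point")
        d = np.hypot(
            out["x"] - used["x"].to_numpy().repeat(10),
            out["y"] - used["y"].to_numpy().repeat(10),
        )
        assert (d <= 80.0 + 1e-9).all()

    def test_per_point_radial_law(self, flat_landscape):
        """Radial CDF of uniform-disc draws is r^2/R^2 (KS test)."""
        used = pd.DataFrame({"x": [500.0], "y": [500.0]})
        out = generate_available(used, 100.0, flat_landscape, ratio=4000, seed=3,
                                 mode="per_point")
        r = np.hypot(out["x"] - 500.0, out["y"] - 500.0)
        p = stats.kstest(r, lambda v: (v / 100.0) ** 2).pvalue
        assert p > 0.01

    def test_pooled_mode_stays_in_buffered_domain(self, flat_landscape):
        used = pd.DataFrame({"x": [300.0, 700.0], "y": [300.0, 700.0]})
        out = generate_available(used, 120.0, flat_landscape, ratio=500, seed=4)
        d = np.minimum(
            np.hypot(out["x"] - 300.0, out["y"] - 300.0),
            np.hypot(out["x"] - 700.0, out["y"] - 700.0),
        )
        # cell-resolution rasterization can exceed the radius by a cell diagonal
        assert (d <= 120.0 + 15.0).all()

    def test_bad_inputs_rejected(self, flat_landscape):
        used = pd.DataFrame({"x": [5000.0], "y": [500.0]})
        with pytest.raises(ValueError):
            generate_available(used, 50.0, flat_landscape)
        with pytest.raises(ValueError):
            generate_available(pd.DataFrame({"x": [5.0], "y": [5.0]}), -1.0, flat_landscape)


class TestExtractAndStandardize:
    def test_known_scaler_formula_and_round_trip(self, landscape64):
        rng = np.random.default_rng(0)
        xmin, xmax, ymin, ymax = landscape64.extent
        pts = pd.DataFrame(
            {"x": rng.uniform(xmin, xmax, 400), "y": rng.uniform(ymin, ymax, 400)}
        )
        out, scalers, rep = extract_and_standardize(pts, landscape64, ["elevation"])
        mu, sd = scalers["elevation"]
        raw = landscape64["elevation"].sample(out["x"], out["y"])
        np.testing.assert_allclose(out["elevation"], (raw - mu) / sd, atol=1e-12)
        # de-standardisation round-trips to machine precision
        np.testing.assert_allclose(out["elevation"] * sd + mu, raw, atol=1e-9)
        assert abs(out["elevation"].mean()) < 1e-10 and out["elevation"].std(ddof=0) == pytest.approx(1.0)

    def test_constant_covariate_rejected(self, flat_landscape):
        pts = pd.DataFrame({"x": [50.0, 150.0], "y": [50.0, 150.0]})
        with pytest.raises(ValueError):
            extract_and_standardize(pts, flat_landscape, ["z"])

    def test_nodata_rows_dropped_with_count(self):
        vals = np.ones((10, 10))
        vals[0, :] = np.nan
        vals[5, 5] = 4.0
        L = Landscape({"v": Grid(vals, cell_size=10.0)})
        # first point hits the NaN row; the others hit cells valued 1 and 4
        pts = pd.DataFrame({"x": [55.0, 15.0, 55.0], "y": [95.0, 15.0, 45.0]})
        out, _, rep = extract_and_standardize(pts, L, ["v"])
        assert rep["n_nodata_dropped"] == 1 and len(out) == 2


class TestCorrelationScreen:
    def test_duplicated_column_dropped(self, rng):
        x = rng.normal(size=500)
        t = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=500)})
        retained, rep = correlation_screen(t, ["a", "b", "c"])
        assert len(retained) == 2 and "c" in retained
        assert len(rep["dropped"]) == 1

    def test_independent_columns_all_retained(self, rng):
        t = pd.DataFrame(rng.normal(size=(800, 4)), columns=list("abcd"))
        retained, _ = correlation_screen(t, list("abcd"))
        assert retained == list("abcd")

    def test_vacuous_threshold_retains_all(self, rng):
        x = rng.normal(size=100)
        t = pd.DataFrame({"a": x, "b": x})
        retained, _ = correlation_screen(t, ["a", "b"], threshold=1.01)
        assert retained == ["a", "b"]


class TestTradeoffRegressions:
    def test_perfect_line_gives_unit_r_squared(self):
        x = np.linspace(0, 10, 50)
        t = pd.DataFrame({"prone": x, "averse": x})
        rep = tradeoff_regressions(t, ["prone"], ["averse"])
        assert rep.iloc[0]["r_squared"] == pytest.approx(1.0)
        assert rep.iloc[0]["slope"] == pytest.approx(1.0)

    def test_independent_noise_r_squared_near_zero(self, rng):
        t = pd.DataFrame({"p": rng.normal(size=2000), "a": rng.normal(size=2000)})
        rep = tradeoff_regressions(t, ["p"], ["a"])
        assert rep.iloc[0]["r_squared"] < 0.01

    def test_known_variance_ratio(self, rng):
        n = 20_000
        x = rng.normal(size=n)
        eps = rng.normal(scale=2.0, size=n)
        t = pd.DataFrame({"p": 2.0 * x + eps, "a": x})
        rep = tradeoff_regressions(t, ["p"], ["a"])
        want = 4.0 / (4.0 + 4.0)  # var(2x) / var(y)
        assert rep.iloc[0]["r_squared"] == pytest.approx(want, abs=0.02)
        assert rep.iloc[0]["slope"] == pytest.approx(2.0, abs=0.05)

    def test_zero_variance_regressor_skipped(self):
        t = pd.DataFrame({"p": [1.0, 2.0, 3.0], "a": [5.0, 5.0, 5.0]})
        rep = tradeoff_regressions(t, ["p"], ["a"])
        assert rep.iloc[0]["note"] == "zero-variance regressor"
        assert np.isnan(rep.iloc[0]["r_squared"])
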