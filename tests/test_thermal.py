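"""Aerobic-scope curve, occupancy scoring and energetic-cost calculations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import upriver as u
from upriver.thermal import _frac_time_below


class TestCurve:
    def test_peak_equals_scalar_maximum(self, calibrated_curve):
        assert u.aas_value(calibrated_curve, 17.6) == pytest.approx(1.0)

    def test_window_bounds_retain_ninety_percent(self, calibrated_curve):
        assert u.aas_value(calibrated_curve, 12.8) == pytest.approx(0.9, abs=1e-9)
        assert u.aas_value(calibrated_curve, 20.8) == pytest.approx(0.9, abs=1e-9)

    @pytest.mark.parametrize(
        "T, expected", [(15.0, 0.9696), (25.0, 0.4652)],
    )
    def test_hand_evaluated_values(self, calibrated_curve, T, expected):
        # direct evaluation of the two-part formula with sigma=7.3938,
        # T_crit_max=27.719
        assert u.aas_value(calibrated_curve, T) == pytest.approx(expected, abs=5e-5)

    def test_calibration_closed_form(self, calibrated_curve):
        assert calibrated_curve.sigma == pytest.approx(7.3938, abs=1e-4)
        assert calibrated_curve.T_crit_max == pytest.approx(27.719, abs=1e-3)

    def test_floored_at_zero_above_critical(self, calibrated_curve):
        assert u.aas_value(calibrated_curve, 35.0) == 0.0

    def test_continuous_and_peaked_at_optimum(self, calibrated_curve):
        grid = np.arange(5.0, 30.0, 0.001)
        vals = u.aas_value(calibrated_curve, grid)
        assert np.max(np.abs(np.diff(vals))) < 1e-3  # no jumps at T_opt
        assert grid[np.argmax(vals)] == pytest.approx(17.6, abs=1e-3)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            u.calibrate_curve(17.6, 12.8, 20.8, q=1.0 - 1e-15)
        with pytest.raises(ValueError):
            u.calibrate_curve(17.6, 18.0, 20.8, q=0.9)

    def test_retention_window_limits(self, calibrated_curve):
        near_one = u.retention_window(calibrated_curve, 0.9999)
        assert near_one.lower == pytest.approx(17.6, abs=0.2)
        assert near_one.upper == pytest.approx(17.6, abs=0.2)
        q0 = u.retention_window(calibrated_curve, 0.0)
        assert q0.upper == pytest.approx(27.719, abs=1e-3)

    @given(
        T_opt=st.floats(5.0, 25.0),
        below=st.floats(0.5, 10.0),
        above=st.floats(0.5, 10.0),
        q=st.floats(0.2, 0.98),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_calibrate_retention_round_trip(self, T_opt, below, above, q):
        curve = u.calibrate_curve(T_opt, T_opt - below, T_opt + above, q)
        win = u.retention_window(curve, q)
        assert win.lower == pytest.approx(T_opt - below, abs=1e-9)
        assert win.upper == pytest.approx(T_opt + above, abs=1e-9)


class TestExposure:
    def test_constant_series_reproduced(self, calibrated_curve):
        idx = pd.date_range("2021-10-01", periods=400, freq="h")
        temps = pd.Series(15.0, index=idx)
        exp = u.reconstruct_exposure(temps, "2021-10-02", 3.0)
        assert len(exp) == 72 and (exp == 15.0).all()

    def test_ten_day_window_has_240_hours(self, temps):
        exp = u.reconstruct_exposure(temps, "2021-10-01", 10.0)
        assert len(exp) == 240

    def test_short_gap_interpolated_long_gap_rejected(self):
        idx = pd.date_range("2021-10-01", periods=48, freq="h")
        temps = pd.Series(np.linspace(14.0, 16.0, 48), index=idx)
        one_gap = temps.drop(idx[10])
        exp = u.reconstruct_exposure(one_gap, idx[0], 2.0)
        assert exp.iloc[10] == pytest.approx((temps.iloc[9] + temps.iloc[11]) / 2.0)
        big_gap = temps.drop(idx[10:14])
        with pytest.raises(ValueError, match="gap"):
            u.reconstruct_exposure(big_gap, idx[0], 2.0)

    def test_constant_exposure_summary(self, calibrated_curve):
        summ = u.exposure_summary([15.0] * 24, calibrated_curve)
        assert summ.prop_in_window == pytest.approx(1.0)
        assert summ.prop_below_topt_in_window == pytest.approx(1.0)
        assert summ.prop_above_topt_in_window == pytest.approx(0.0)

    def test_proportions_partition_unity(self, calibrated_curve):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.normal(16.0, 4.0, size=rng.integers(2, 200))
            s = u.exposure_summary(vals, calibrated_curve)
            total = s.prop_below_window + s.prop_in_window + s.prop_above_window
            assert total == pytest.approx(1.0, abs=1e-12)
            split = s.prop_below_topt_in_window + s.prop_above_topt_in_window
            assert split == pytest.approx(s.prop_in_window, abs=1e-12)

    def test_warming_never_increases_cold_occupancy(self, calibrated_curve):
        rng = np.random.default_rng(6)
        vals = rng.normal(13.0, 3.0, 500)
        base = u.exposure_summary(vals, calibrated_curve)
        warm = u.exposure_summary(vals + 1.5, calibrated_curve)
        assert warm.prop_below_window <= base.prop_below_window + 1e-12

    def test_downsample_hourly_mean(self):
        idx = pd.date_range("2021-10-01", periods=120, freq="min")
        s = pd.Series(np.arange(120.0), index=idx)
        hourly = u.downsample_hourly(s)
        assert hourly.iloc[0] == pytest.approx(np.mean(np.arange(60.0)))


class TestCost:
    def test_identity_temperatures(self):
        cm = u.cost_metrics(u.RMRModel(), 15.0, 15.0)
        assert cm.ratio_percent == pytest.approx(100.0)
        assert cm.daily_diff_kj == pytest.approx(0.0)

    def test_ratio_invariant_to_scale_diff_linear(self):
        base = u.cost_metrics(u.RMRModel(a=0.707), 12.8, 20.8)
        scaled = u.cost_metrics(u.RMRModel(a=1.414), 12.8, 20.8)
        assert scaled.ratio_percent == pytest.approx(base.ratio_percent)
        assert scaled.daily_diff_kj == pytest.approx(2.0 * base.daily_diff_kj)
        oxy = u.cost_metrics(u.RMRModel(a=0.707, oxycal=28.2), 12.8, 20.8)
        assert oxy.daily_diff_kj == pytest.approx(2.0 * base.daily_diff_kj)

    @pytest.mark.parametrize("delta, expected", [(2.0, 19.2), (4.0, 42.2)])
    def test_warming_rmr_increase_closed_form(self, delta, expected):
        # 100 * (exp(0.088 * delta) - 1)
        got = 100.0 * (math.exp(0.088 * delta) - 1.0)
        assert got == pytest.approx(expected, abs=0.05)


class TestScenarios:
    def test_zero_delta_reproduces_baseline(self, temps, calibrated_curve):
        grid = u.scenario_grid(temps, ["10-01", "10-06"], 10.0, calibrated_curve,
                               deltas=[0.0])
        direct = u.exposure_summary(
            u.reconstruct_exposure(temps, "2021-10-01", 10.0), calibrated_curve
        )
        row = grid[(grid["departure"] == "10-01")].iloc[0]
        assert row["prop_in_window"] == pytest.approx(direct.prop_in_window)
        assert row["rmr_increase_percent"] == pytest.approx(0.0)

    def test_warming_scenario_uniform_shift(self, temps):
        shifted = u.warming_scenario(temps, 2.0)
        assert np.allclose(shifted.to_numpy() - temps.to_numpy(), 2.0)


class TestLoggerComparison:
    def test_identical_series(self, temps):
        cmp = u.compare_logger_vs_river(temps, temps)
        assert cmp.mean_diff == 0.0 and cmp.sd_diff == 0.0 and cmp.n == len(temps)

    def test_single_shared_hour_sd_undefined(self, temps):
        with pytest.warns(UserWarning, match="single shared hour"):
            cmp = u.compare_logger_vs_river(temps.iloc[:1], temps)
        assert math.isnan(cmp.sd_diff) and cmp.n == 1

    def test_disjoint_series_rejected(self, temps):
        other = temps.copy()
        other.index = other.index + pd.Timedelta(days=365)
        with pytest.raises(ValueError):
            u.compare_logger_vs_river(other, temps)


def test_occupancy_interpolation_beats_point_counting():
    """Piecewise-linear occupancy tracks a continuous path through a band
    boundary better than sample counting when the crossing is mid-segment."""
    vals = np.array([10.0, 20.0])
    assert _frac_time_below(vals, 15.0, "interpolate") == pytest.approx(0.5)
    assert _frac_time_below(vals, 15.0, "sample") == pytest.approx(0.5)
    assert _frac_time_below(vals, 12.5, "interpolate") == pytest.approx(0.25)
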