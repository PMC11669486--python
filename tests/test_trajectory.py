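"""Filtering rules and the hierarchical spline + AR(1) trajectory model."""

import numpy as np
import pandas as pd
import pytest

import upriver as u
from .conftest import simulate_mixed_linear


def simple_tracks(rows):
    return pd.DataFrame(rows, columns=["fish_id", "day", "chainage_km"])


class TestFilter:
    def test_gap_longer_than_three_days_truncates(self):
        tracks = simple_tracks(
            [("A", d, c) for d, c in zip([0, 1, 2, 6], [0, 10, 20, 55])]
        )
        data = u.filter_tracking_data(tracks)
        sub = data.frame[data.frame.fish_id == "A"]
        dropped = sub[~sub.retained]
        assert list(dropped.reason) == ["long_gap"]
        assert len(data.retained) == 3

    def test_initial_stay_dropped_and_time_rebased(self):
        days = [0, 1, 2, 3, 4, 5, 6]
        chain = [0.0, 0.2, 0.1, 0.3, 6.0, 12.0, 18.0]
        data = u.filter_tracking_data(simple_tracks([("B", d, c) for d, c in zip(days, chain)]))
        sub = data.frame[data.frame.fish_id == "B"]
        assert (sub[~sub.retained].reason == "initial_stay").all()
        kept = sub[sub.retained]
        # the last stationary fix anchors t=0; earlier stay fixes are dropped
        assert kept["t"].iloc[0] == 0.0
        assert len(kept) == 4
        assert kept["d"].iloc[0] == 0.0

    def test_two_point_fish_excluded(self):
        data = u.filter_tracking_data(simple_tracks([("C", 0, 0.0), ("C", 1, 9.0)]))
        assert data.retained.empty
        assert set(data.frame.reason) == {"too_few_points"}

    def test_lower_basin_spawner_excluded(self):
        tracks = simple_tracks(
            [("D", d, c) for d, c in zip(range(7), [0, 8, 15, 20, 20.2, 20.1, 19.9])]
        )
        fate = u.classify_fate(tracks)
        assert fate.category == "located" and fate.last_chainage_km < 30
        data = u.filter_tracking_data(tracks, {"D": fate})
        assert data.retained.empty
        assert "lower_basin_spawner" in set(data.frame.reason)

    def test_not_located_fish_excluded(self, projected, fate_records):
        data = u.filter_tracking_data(projected, fate_records)
        not_located = {r.fish_id for r in fate_records if r.category == "not_located"}
        assert not (set(data.retained.fish_id) & not_located)

    def test_station_keeping_tail_removed(self):
        days = list(range(12))
        chain = [0, 10, 20, 30, 40, 50, 55, 55.4, 54.8, 55.2, 55.0, 55.3]
        data = u.filter_tracking_data(simple_tracks([("E", d, c) for d, c in zip(days, chain)]))
        kept = data.retained
        assert kept["t"].max() <= 6.0


class TestModelFit:
    def test_linear_truth_independent_noise(self):
        # phi carries a finite-sample bias of order -1/T from the per-fish
        # effects absorbing noise, so the check uses series long enough for
        # that to be negligible and the median of a few fits
        rng = np.random.default_rng(30)
        phis = []
        for _ in range(5):
            df = simulate_mixed_linear(rng, phi=0.0, n_t=25, sd_resid=0.005,
                                       sd_intercept=0.005, sd_slope=0.5,
                                       mean_fn=lambda t: 12.0 * t)
            res = u.fit_trajectory_model(df)
            phis.append(res.phi)
            grid = np.linspace(0.0, 24.0, 80)
            pred = res.predict(grid)
            # fitted smooth collapses to the linear truth
            line = np.polyval(np.polyfit(grid, pred, 1), grid)
            assert np.max(np.abs(pred - line)) < 1e-3
        assert abs(float(np.median(phis))) <= 0.05

    def test_infinite_penalty_collapses_to_line(self):
        rng = np.random.default_rng(31)
        df = simulate_mixed_linear(rng, phi=0.0, sd_resid=0.5)
        res = u.TrajectoryModel(df).fit(fix_phi=0.0, fixed_ratios={"smooth": 1e-10})
        grid = np.linspace(0.0, 9.0, 40)
        pred = res.predict(grid)
        line = np.polyval(np.polyfit(grid, pred, 1), grid)
        assert np.max(np.abs(pred - line)) < 1e-6

    def test_random_intercept_sd_recovery(self):
        # truth SD 5 km; median estimate over seeds within +-40% relative
        estimates = []
        for seed in range(15):
            rng = np.random.default_rng(1000 + seed)
            df = simulate_mixed_linear(rng, sd_intercept=5.0, sd_slope=1.0,
                                       sd_resid=0.5, phi=0.0)
            res = u.fit_trajectory_model(df)
            estimates.append(res.sd_intercept)
        med = float(np.median(estimates))
        assert 3.0 <= med <= 7.0

    def test_prewhitening_removes_lag1_autocorrelation(self):
        rng = np.random.default_rng(32)
        df = simulate_mixed_linear(rng, phi=0.6, sd_resid=0.8, n_fish=20, n_t=12)
        res = u.fit_trajectory_model(df)
        model = res.model
        coefs = np.concatenate([res.beta, res.u_smooth])
        fitted = model._mean_design(model.t) @ coefs + model.Zf @ np.concatenate(
            [res.blups[["intercept", "slope"]].to_numpy().ravel()]
        )
        e = model.y - fitted
        num = den = 0.0
        for idx in model._fish_slices.values():
            ei = e[idx]
            w = ei[1:] - res.phi * ei[:-1]  # AR(1) prewhitening
            num += float(w[1:] @ w[:-1])
            den += float(w[:-1] @ w[:-1])
        assert abs(num / den) < 0.15

    def test_invariant_to_fish_relabelling(self):
        rng = np.random.default_rng(33)
        df = simulate_mixed_linear(rng, phi=0.3, sd_resid=0.5)
        res1 = u.fit_trajectory_model(df)
        relabel = {f: f"Z{np.random.default_rng(i).integers(1e6)}" for i, f in
                   enumerate(df.fish_id.unique())}
        df2 = df.assign(fish_id=df.fish_id.map(relabel))
        res2 = u.fit_trajectory_model(df2)
        assert res2.phi == pytest.approx(res1.phi, abs=1e-4)
        grid = np.linspace(0, 9, 10)
        assert np.allclose(res1.predict(grid), res2.predict(grid), atol=1e-4)

    def test_precondition_checks(self):
        df = simulate_mixed_linear(np.random.default_rng(34), n_fish=3)
        with pytest.raises(ValueError, match="5 fish"):
            u.TrajectoryModel(df)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(35)
    df = simulate_mixed_linear(rng, phi=0.3, sd_resid=0.5,
                               mean_fn=lambda t: 14.0 * t - 0.5 * t**2)
    return u.fit_trajectory_model(df)


class TestPrediction:

    def test_prediction_at_zero_is_intercept(self, fitted):
        pred0 = fitted.predict(0.0)
        assert pred0 == pytest.approx(0.0, abs=1.5)

    def test_interval_widens_beyond_data(self, fitted):
        _, lo_in, hi_in = fitted.predict(5.0, with_ci=True)
        _, lo_out, hi_out = fitted.predict(12.5, with_ci=True)
        assert (hi_out - lo_out) > (hi_in - lo_in)

    def test_extrapolation_limit_enforced(self, fitted):
        with pytest.raises(ValueError, match="predictable range"):
            fitted.predict(100.0)
        with pytest.raises(ValueError):
            fitted.predict(-1.0)

    def test_isotonic_projection_monotone(self, fitted):
        grid = np.linspace(0.0, fitted.model.t_hi, 300)
        pred = fitted.predict(grid, isotonic=True)
        assert np.all(np.diff(pred) >= -1e-12)

    def test_time_to_chainage_boundaries(self, fitted):
        assert fitted.time_to_chainage(0.0) == 0.0
        t50 = fitted.time_to_chainage(50.0)
        assert fitted.predict(t50, isotonic=False) >= 50.0 - 0.5
        with pytest.raises(ValueError, match="never reached"):
            fitted.time_to_chainage(1e6)

    def test_individual_predictions_use_blups(self, fitted):
        fid = fitted.blups.fish_id.iloc[0]
        ind = fitted.predict_fish(fid, [2.0])
        pop = fitted.predict(np.array([2.0]))
        row = fitted.blups.set_index("fish_id").loc[fid]
        assert ind[0] == pytest.approx(pop[0] + row.intercept + 2.0 * row.slope)


class TestARComparison:
    def test_ar1_preferred_when_noise_is_autocorrelated(self):
        rng = np.random.default_rng(36)
        df = simulate_mixed_linear(rng, phi=0.6, sd_resid=1.0, n_fish=20, n_t=12)
        comp = u.compare_ar_structures(df)
        ar1 = comp[comp.structure == "AR1"].iloc[0]
        indep = comp[comp.structure == "independent"].iloc[0]
        assert ar1.aic < indep.aic
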