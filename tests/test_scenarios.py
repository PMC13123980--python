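"""Future grids, climatology scenarios and recursive projection."""

import numpy as np
import pandas as pd
import pytest

from heatrisk.modeling import ModelSpec, chronological_split, fit
from heatrisk.scenarios import (
    ScenarioSpec,
    apply_scenario,
    build_future_grid,
    empirical_interval,
    interval_calibration,
    monthly_climatology,
    recursive_project,
)


class TestFutureGrid:
    def test_four_year_horizon_count(self):
        grid = build_future_grid("2024-01-01", "2027-12-31")
        assert len(grid) == 11_688  # 1,461 days x 8, incl. the 2024 leap day

    def test_single_day(self):
        assert len(build_future_grid("2025-06-01", "2025-06-01")) == 8

    def test_july_is_summer(self):
        grid = build_future_grid("2025-07-01", "2025-07-02")
        assert (grid["season_summer"] == 1).all()
        assert (grid[["season_winter", "season_spring", "season_autumn"]]
                .to_numpy() == 0).all()

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            build_future_grid("2025-01-02", "2025-01-01")


class TestClimatology:
    def test_constant_series(self, short_series):
        const = short_series.copy()
        const["temperature_c"] = 25.0
        const["relative_humidity_pct"] = 70.0
        clim = monthly_climatology(const)
        assert (clim["temperature_c"] == 25.0).all()
        assert len(clim) == 12

    def test_recovers_configured_monthly_means(self, short_series):
        clim = monthly_climatology(short_series)
        for month in (1, 7):
            observed = short_series.loc[
                short_series.index.month == month, "temperature_c"
            ].mean()
            assert clim.loc[month, "temperature_c"] == pytest.approx(observed)

    def test_missing_month_rejected(self, short_series):
        partial = short_series[short_series.index.month != 2]
        with pytest.raises(ValueError, match="2"):
            monthly_climatology(partial)


class TestApplyScenario:
    @pytest.fixture()
    def clim(self, short_series):
        return monthly_climatology(short_series)

    def test_zero_noise_repeats_climatology(self, clim):
        grid = build_future_grid("2022-01-01", "2022-12-31")
        spec = ScenarioSpec("moderate-deterministic")
        future = apply_scenario(clim, grid, spec)
        months = grid["month"].to_numpy()
        np.testing.assert_allclose(
            future["temperature_c"],
            clim["temperature_c"].reindex(months).to_numpy(),
        )

    def test_optimistic_shift_is_exactly_minus_half_degree(self, clim):
        grid = build_future_grid("2022-01-01", "2022-03-31")
        base = apply_scenario(clim, grid, ScenarioSpec("m"))
        opt = apply_scenario(
            clim, grid, ScenarioSpec("o", delta_t=-0.5, delta_rh=-2.0)
        )
        np.testing.assert_allclose(
            opt["temperature_c"] - base["temperature_c"], -0.5
        )

    def test_pessimistic_humidity_shift_clipped(self, clim):
        grid = build_future_grid("2022-01-01", "2022-03-31")
        pess = apply_scenario(clim, grid, ScenarioSpec("p", delta_t=1.0,
                                                       delta_rh=3.0))
        months = grid["month"].to_numpy()
        expected = np.clip(
            clim["relative_humidity_pct"].reindex(months).to_numpy() + 3.0,
            0.0, 100.0,
        )
        np.testing.assert_allclose(pess["relative_humidity_pct"], expected)

    def test_preset_deltas(self):
        o = ScenarioSpec.preset("optimistic")
        m = ScenarioSpec.preset("moderate")
        p = ScenarioSpec.preset("pessimistic")
        assert (o.delta_t, o.delta_rh) == (-0.5, -2.0)
        assert (m.delta_t, m.delta_rh) == (0.0, 0.0)
        assert (p.delta_t, p.delta_rh) == (1.0, 3.0)
        with pytest.raises(ValueError):
            ScenarioSpec.preset("catastrophic")

    def test_seeded_noise_reproducible(self, clim):
        grid = build_future_grid("2022-01-01", "2022-06-30")
        spec = ScenarioSpec.preset("moderate", seed=99)
        a = apply_scenario(clim, grid, spec)
        b = apply_scenario(clim, grid, spec)
        pd.testing.assert_frame_equal(a, b)


class _StubModel:
    """Minimal FittedModel returning one designated feature."""

    def __init__(self, feature_names, pick):
        self.feature_names = list(feature_names)
        self._idx = self.feature_names.index(pick)
        self.spec = ModelSpec("naive")

    def predict_single(self, row):
        return float(row[self._idx])


def _future(clim_value=25.0, n_days=5):
    grid = build_future_grid("2024-01-01", f"2024-01-{n_days:02d}")
    future = grid.copy()
    future.insert(0, "temperature_c", np.linspace(20, 30, len(grid)))
    future.insert(1, "relative_humidity_pct", 70.0)
    return future


FEATURES = ["temperature_c", "relative_humidity_pct", "hour", "day", "month",
            "season_winter", "season_spring", "season_summer", "season_autumn",
            "hi_lag1", "hi_lag3", "hi_lag6"]


class TestRecursion:
    def test_lag1_stub_holds_last_initializer(self):
        future = _future()
        model = _StubModel(FEATURES, "hi_lag1")
        out = recursive_project(model, future, np.arange(6.0), "s")
        np.testing.assert_allclose(out["point"], 5.0)

    def test_lag6_bookkeeping(self):
        future = _future()
        model = _StubModel(FEATURES, "hi_lag6")
        init = np.array([10.0, 11, 12, 13, 14, 15])
        out = recursive_project(model, future, init, "s")
        # the first 6 steps replay the initializers; from step 7 onward the
        # lag-6 feature is the prediction made 6 steps before
        np.testing.assert_allclose(out["point"].iloc[:6], init)
        np.testing.assert_allclose(
            out["point"].iloc[6:].to_numpy(),
            out["point"].iloc[:-6].to_numpy(),
        )

    def test_temperature_pass_through(self):
        future = _future()
        model = _StubModel(FEATURES, "temperature_c")
        out = recursive_project(model, future, np.zeros(6), "s")
        np.testing.assert_allclose(out["point"], future["temperature_c"])

    def test_wrong_init_length(self):
        with pytest.raises(ValueError):
            recursive_project(_StubModel(FEATURES, "hi_lag1"), _future(),
                              np.zeros(5), "s")

    def test_gap_in_future_grid(self):
        future = _future().drop(pd.Timestamp("2024-01-02 06:00"))
        with pytest.raises(ValueError, match="gap"):
            recursive_project(_StubModel(FEATURES, "hi_lag1"), future,
                              np.zeros(6), "s")

    def test_forest_projection_bounds_bracket_point(self, feature_matrix):
        train, _ = chronological_split(feature_matrix, "2021-10-01")
        model = fit(ModelSpec("rfr", {"n_estimators": 50}, seed=3), train)
        future = _future()
        out = recursive_project(model, future, np.full(6, 25.0), "s")
        assert (out["lower"] <= out["point"] + 1e-9).all()
        assert (out["point"] <= out["upper"] + 1e-9).all()

    def test_projection_deterministic(self, feature_matrix):
        train, _ = chronological_split(feature_matrix, "2021-10-01")
        model = fit(ModelSpec("rfr", {"n_estimators": 40}, seed=3), train)
        future = _future()
        a = recursive_project(model, future, np.full(6, 25.0), "s")
        b = recursive_project(model, future, np.full(6, 25.0), "s")
        pd.testing.assert_frame_equal(a, b)


class TestEmpiricalInterval:
    def test_degenerate_ensemble(self):
        mean, lo, hi = empirical_interval(np.full(100, 3.25))
        assert (mean, lo, hi) == (3.25, 3.25, 3.25)

    def test_order_statistic_oracle(self):
        preds = np.arange(1.0, 101.0)
        mean, lo, hi = empirical_interval(preds)
        # brute-force linear interpolation of order statistics
        def pct(q):
            rank = q / 100 * (len(preds) - 1)
            low = int(np.floor(rank))
            return preds[low] + (rank - low) * (preds[low + 1] - preds[low])
        assert mean == pytest.approx(50.5)
        assert lo == pytest.approx(pct(2.5))
        assert hi == pytest.approx(pct(97.5))

    def test_matrix_input(self):
        preds = np.vstack([np.arange(1.0, 101.0), np.full(100, 2.0)])
        mean, lo, hi = empirical_interval(preds)
        np.testing.assert_allclose(mean, [50.5, 2.0])

    def test_too_few_members(self):
        with pytest.raises(ValueError):
            empirical_interval(np.array([1.0]))


class TestCalibration:
    def test_unit_band(self):
        y = np.linspace(0, 10, 50)
        cov, width = interval_calibration(y - 1, y + 1, y)
        assert cov == 100.0
        assert width == pytest.approx(2.0)

    def test_exclusive_band(self):
        y = np.zeros(20)
        cov, _ = interval_calibration(y + 1, y + 2, y)
        assert cov == 0.0

    def test_misaligned_series_rejected(self):
        y = pd.Series([1.0, 2.0], index=[0, 1])
        lo = pd.Series([0.0, 0.0], index=[5, 6])
        with pytest.raises(ValueError, match="misaligned"):
            interval_calibration(lo, lo + 2, y)
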