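"""Feature construction, chronological splitting and the model registry."""

import numpy as np
import pandas as pd
import pytest

from heatrisk.modeling import (
    ModelSpec,
    build_features,
    chronological_split,
    derive_seed,
    expanding_window_cv,
    fit,
    grid_search,
)


def _toy_hi_frame(n, hi, start="2021-01-01"):
    idx = pd.date_range(start, periods=n, freq="3h")
    return pd.DataFrame(
        {
            "temperature_c": np.linspace(20, 25, n),
            "relative_humidity_pct": 60.0 + np.arange(n) % 5,
            "hi_c": np.asarray(hi, dtype=float),
        },
        index=idx,
    )


class TestBuildFeatures:
    def test_row_count_after_lag_burn_in(self):
        frame = _toy_hi_frame(10, np.arange(10))
        assert len(build_features(frame)) == 4  # 10 - max lag 6

    def test_lag_values_are_strictly_past(self):
        frame = _toy_hi_frame(20, np.arange(20))
        feats = build_features(frame)
        # lag-3 at timestamp t equals the value observed 9 hours earlier
        assert (feats["hi_lag3"] == feats.index.map(
            lambda t: frame.loc[t - pd.Timedelta(hours=9), "hi_c"]
        )).all()
        assert (feats["hi_lag1"] == np.arange(5, 19)).all()

    def test_future_permutation_leaves_past_rows_unchanged(self):
        frame = _toy_hi_frame(30, np.arange(30))
        feats = build_features(frame)
        mutated = frame.copy()
        mutated.iloc[20:, mutated.columns.get_loc("hi_c")] = 999.0
        feats2 = build_features(mutated)
        cut = frame.index[20 - 0]
        pd.testing.assert_frame_equal(
            feats.loc[: frame.index[19]], feats2.loc[: frame.index[19]]
        )
        assert not feats2.loc[cut:].equals(feats.loc[cut:])

    def test_gap_rejected(self):
        frame = _toy_hi_frame(12, np.arange(12)).drop(
            pd.Timestamp("2021-01-01 09:00")
        )
        with pytest.raises(ValueError, match="gap"):
            build_features(frame)

    def test_season_one_hot_columns_fixed_order(self, feature_matrix):
        cols = [c for c in feature_matrix.columns if c.startswith("season_")]
        assert cols == ["season_winter", "season_spring", "season_summer",
                        "season_autumn"]
        assert (feature_matrix[cols].sum(axis=1) == 1).all()


class TestSplit:
    def test_partition(self, feature_matrix):
        train, test = chronological_split(feature_matrix, "2021-07-01")
        assert len(train) + len(test) == len(feature_matrix)
        assert train.index.max() < pd.Timestamp("2021-07-01") <= test.index.min()
        assert train.index.intersection(test.index).empty

    def test_boundary_outside_range(self, feature_matrix):
        with pytest.raises(ValueError):
            chronological_split(feature_matrix, "2010-01-01")
        with pytest.raises(ValueError):
            chronological_split(feature_matrix, "2030-01-01")


class TestRegistry:
    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec("lstm")

    def test_naive_returns_lag1(self, feature_matrix):
        model = fit(ModelSpec("naive"), feature_matrix)
        np.testing.assert_array_equal(
            model.predict(feature_matrix), feature_matrix["hi_lag1"].to_numpy()
        )

    def test_forest_interpolates_deterministic_target(self):
        # hi is an exact function of the features and there is no noise:
        # the forest should essentially memorise the training set
        rng = np.random.default_rng(3)
        n = 600
        frame = _toy_hi_frame(n, rng.normal(size=n))
        frame["hi_c"] = 0.8 * frame["temperature_c"] + 0.05 * frame[
            "relative_humidity_pct"
        ]
        feats = build_features(frame)
        model = fit(ModelSpec("rfr", {"n_estimators": 100}, seed=0), feats)
        pred = model.predict(feats)
        ss_res = np.sum((feats["hi"] - pred) ** 2)
        ss_tot = np.sum((feats["hi"] - feats["hi"].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_same_spec_and_seed_reproduces_predictions(self, feature_matrix):
        train, test = chronological_split(feature_matrix, "2021-10-01")
        spec = ModelSpec("rfr", {"n_estimators": 60}, seed=derive_seed(5, "m"))
        a = fit(spec, train).predict(test)
        b = fit(spec, train).predict(test)
        np.testing.assert_array_equal(a, b)

    def test_forest_tree_mean_equals_point_prediction(self, feature_matrix):
        train, test = chronological_split(feature_matrix, "2021-10-01")
        model = fit(ModelSpec("rfr", {"n_estimators": 50}, seed=1), train)
        trees = model.tree_predictions(test.iloc[:50])
        assert trees.shape == (50, 50)
        np.testing.assert_allclose(
            trees.mean(axis=1), model.predict(test.iloc[:50]), atol=1e-9
        )

    def test_leakage_mutation_does_not_change_fit(self, feature_matrix):
        train, test = chronological_split(feature_matrix, "2021-10-01")
        spec = ModelSpec("rfr", {"n_estimators": 40}, seed=2)
        baseline = fit(spec, train).predict(train.iloc[:100])
        mutated_test = test.copy()
        mutated_test.loc[:, "hi"] = 999.0
        mutated_test.loc[:, "temperature_c"] = -50.0
        again = fit(spec, train).predict(train.iloc[:100])
        np.testing.assert_array_equal(baseline, again)

    def test_linear_adapter_one_step_ahead(self, feature_matrix):
        train, test = chronological_split(feature_matrix, "2021-11-01")
        model = fit(ModelSpec("arimax", {"maxiter": 25}), train)
        pred = model.predict(test)
        assert pred.shape == (len(test),)
        rmse = np.sqrt(np.mean((test["hi"].to_numpy() - pred) ** 2))
        naive_rmse = np.sqrt(np.mean(np.diff(test["hi"].to_numpy()) ** 2))
        assert rmse < naive_rmse  # beats persistence on the same block


class TestCrossValidation:
    def test_expanding_training_sizes(self, feature_matrix):
        cv = expanding_window_cv(ModelSpec("naive"), feature_matrix, folds=5)
        sizes = cv["fold_train_sizes"]
        assert len(sizes) == 5
        assert all(a < b for a, b in zip(sizes, sizes[1:]))

    def test_persistence_cv_rmse_matches_innovation_sd(self):
        # on a random walk the one-step persistence error IS the innovation
        rng = np.random.default_rng(8)
        sigma = 0.7
        hi = np.cumsum(rng.normal(0, sigma, size=4000))
        frame = _toy_hi_frame(4000, hi)
        feats = build_features(frame)
        cv = expanding_window_cv(ModelSpec("naive"), feats, folds=5)
        assert cv["mean_rmse"] == pytest.approx(sigma, rel=0.05)

    def test_too_few_rows(self, feature_matrix):
        with pytest.raises(ValueError):
            expanding_window_cv(ModelSpec("naive"), feature_matrix.iloc[:8], 5)


class TestGridSearch:
    def test_single_point_grid(self, feature_matrix):
        best, records = grid_search(
            "rfr", [{"n_estimators": 20}], feature_matrix.iloc[:500], folds=3
        )
        assert best.hyperparameters == {"n_estimators": 20}
        assert len(records) == 1

    def test_tie_broken_by_declaration_order(self, feature_matrix):
        # two identical grid points: the first declared must win
        grid = [{"n_estimators": 20, "max_features": 1.0},
                {"n_estimators": 20, "max_features": 1.0}]
        best, records = grid_search("rfr", grid, feature_matrix.iloc[:400],
                                    folds=3, seed=4)
        assert records[0]["mean_rmse"] == records[1]["mean_rmse"]
        assert best.hyperparameters is not grid[1]
        assert best.hyperparameters == grid[0]

    def test_empty_grid(self, feature_matrix):
        with pytest.raises(ValueError):
            grid_search("rfr", [], feature_matrix)


def test_derived_seeds_are_stable_and_distinct():
    assert derive_seed(1, "a") == derive_seed(1, "a")
    assert derive_seed(1, "a") != derive_seed(1, "b")
    assert 0 <= derive_seed(123456, "model:rfr") < 2**31
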