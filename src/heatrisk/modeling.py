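"""Leakage-safe feature construction and the conditional-estimation registry.

The Heat Index at 3-hourly resolution is modelled conditionally on
contemporaneous meteorology (temperature, humidity), calendar structure
(hour, day of month, month, one-hot season) and short autoregressive memory
(HI lagged 1, 3 and 6 steps, i.e. 3, 9 and 18 hours).  All lag features are
built strictly from past observations; rows without full lag history are
dropped rather than imputed.

Registry models:

``naive``
    persistence baseline — the previous 3-hourly HI value.
``arimax`` / ``sarimax``
    linear state-space adapters over statsmodels' SARIMAX, fitted on the raw
    (unscaled) target with raw exogenous regressors (temperature, humidity,
    season one-hots).  Evaluation on a held-out block is one-step-ahead via
    Kalman filtering with the training parameters held fixed.
``rfr`` / ``gboost``
    tree ensembles (scikit-learn random forest, XGBoost) on min-max-scaled
    features including the lag block.  The forest adapter additionally
    exposes per-tree predictions, the basis for empirical prediction
    intervals.

Model selection uses expanding-window time-series cross-validation: the
training span is cut into ``folds + 1`` contiguous blocks; fold *k*
validates on block *k + 1* after training on all earlier blocks, so
training sets strictly grow and no fold ever sees its own future.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import SEASONS, assign_season

__all__ = [
    "LAGS_DEFAULT",
    "ModelSpec",
    "derive_seed",
    "encode_calendar",
    "build_features",
    "chronological_split",
    "fit",
    "expanding_window_cv",
    "grid_search",
    "NaiveLagModel",
    "SarimaxAdapter",
    "ForestAdapter",
    "XGBoostAdapter",
]

LAGS_DEFAULT: tuple[int, ...] = (1, 3, 6)
STEP = pd.Timedelta(hours=3)

MODEL_NAMES = ("naive", "arimax", "sarimax", "rfr", "gboost")


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-component seed derived from the pipeline master seed."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass
class ModelSpec:
    """Named model with hyperparameter overrides and a seed."""

    name: str
    hyperparameters: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; known: {MODEL_NAMES}")


def encode_calendar(index: pd.DatetimeIndex) -> pd.DataFrame:
    """Hour/day/month integers plus fixed-order one-hot season columns."""
    month = index.month
    frame = pd.DataFrame(
        {
            "hour": index.hour.astype(int),
            "day": index.day.astype(int),
            "month": month.astype(int),
        },
        index=index,
    )
    season = np.array([assign_season(m) for m in month])
    for s in SEASONS:
        frame[f"season_{s}"] = (season == s).astype(int)
    return frame


def _check_gapfree(index: pd.DatetimeIndex) -> None:
    if len(index) > 1:
        deltas = np.diff(index.to_numpy())
        if not np.all(deltas == np.timedelta64(3, "h")):
            raise ValueError("series has gaps or irregular spacing; lags undefined")


def build_features(
    series: pd.DataFrame, lags: Sequence[int] = LAGS_DEFAULT
) -> pd.DataFrame:
    """Feature matrix with target column ``hi`` from a Heat-Index series.

    ``series`` must be a gap-free 3-hourly frame carrying ``temperature_c``,
    ``relative_humidity_pct`` and ``hi_c``.  Each ``hi_lag{k}`` value is the
    HI observed exactly k steps (3k hours) earlier; the first ``max(lags)``
    rows lack full history and are dropped.
    """
    _check_gapfree(series.index)
    out = encode_calendar(series.index)
    out.insert(0, "temperature_c", series["temperature_c"].to_numpy())
    out.insert(1, "relative_humidity_pct", series["relative_humidity_pct"].to_numpy())
    for k in sorted(lags):
        out[f"hi_lag{k}"] = series["hi_c"].shift(k)
    out["hi"] = series["hi_c"].to_numpy()
    return out.iloc[max(lags):].copy()


def chronological_split(
    matrix: pd.DataFrame, boundary
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows into (before boundary, from boundary on), preserving order."""
    boundary = pd.Timestamp(boundary)
    if boundary <= matrix.index.min() or boundary > matrix.index.max():
        raise ValueError("split boundary outside the data range")
    train = matrix.loc[matrix.index < boundary]
    test = matrix.loc[matrix.index >= boundary]
    return train, test


def _feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c != "hi"]


# ---------------------------------------------------------------------------
# Adapters
# ---------------------------------------------------------------------------


class FittedModel:
    """Common surface of fitted adapters: ``predict`` plus metadata."""

    spec: ModelSpec
    feature_names: list[str]

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def predict_single(self, row: np.ndarray) -> float:
        """Prediction for one raw feature row ordered as ``feature_names``."""
        frame = pd.DataFrame([row], columns=self.feature_names)
        return float(self.predict(frame)[0])


class NaiveLagModel(FittedModel):
    """Persistence baseline: HI at t equals HI observed at t − 1 step."""

    def __init__(self, spec: ModelSpec, train: pd.DataFrame):
        self.spec = spec
        self.feature_names = _feature_columns(train)
        if "hi_lag1" not in self.feature_names:
            raise ValueError("persistence baseline requires an hi_lag1 feature")

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        return matrix["hi_lag1"].to_numpy(dtype=float)

    def predict_single(self, row: np.ndarray) -> float:
        return float(row[self.feature_names.index("hi_lag1")])


class _FeatureScaler:
    """Min-max scaling of the continuous feature columns with ranges frozen
    on the training block.

    Binary season indicators are already in [0, 1] and pass through
    untouched.  A column that happens to be constant within a (short)
    training block — e.g. ``month`` inside one cross-validation fold —
    carries no information there and is mapped to 0 rather than rejected.
    """

    def __init__(self, train: pd.DataFrame, feature_names: list[str]):
        self.feature_names = feature_names
        mins = np.zeros(len(feature_names))
        ranges = np.ones(len(feature_names))
        for j, col in enumerate(feature_names):
            if col.startswith("season_"):
                continue
            lo = float(train[col].min())
            hi = float(train[col].max())
            mins[j] = lo
            ranges[j] = (hi - lo) if hi > lo else 1.0
        self.mins_vec = mins          # aligned with feature_names
        self.ranges_vec = ranges

    def transform(self, matrix: pd.DataFrame) -> np.ndarray:
        out = matrix[self.feature_names].to_numpy(dtype=float)
        return (out - self.mins_vec) / self.ranges_vec

    def transform_row(self, row: np.ndarray) -> np.ndarray:
        return (np.asarray(row, dtype=float) - self.mins_vec) / self.ranges_vec


_LINEAR_EXOG = [
    "temperature_c",
    "relative_humidity_pct",
    *(f"season_{s}" for s in SEASONS),
]


class SarimaxAdapter(FittedModel):
    """Linear state-space adapter (covers both ARIMAX and seasonal ARIMAX).

    Fitted on the raw target with raw exogenous regressors; the four season
    indicators sum to one and double as the intercept.  ``predict`` on a
    block immediately following the training span performs one-step-ahead
    Kalman prediction with parameters frozen at their training estimates
    (the observed test target enters only through the filter state, exactly
    as the persistence baseline uses the observed previous value).
    """

    def __init__(self, spec: ModelSpec, train: pd.DataFrame):
        import statsmodels.api as sm

        self.spec = spec
        self.feature_names = _feature_columns(train)
        hp = dict(spec.hyperparameters)
        if spec.name == "sarimax":
            order = tuple(hp.pop("order", (1, 0, 1)))
            seasonal_order = tuple(hp.pop("seasonal_order", (1, 0, 1, 8)))
        else:
            order = tuple(hp.pop("order", (2, 0, 2)))
            seasonal_order = tuple(hp.pop("seasonal_order", (0, 0, 0, 0)))
        self._maxiter = int(hp.pop("maxiter", 50))
        if hp:
            raise ValueError(f"unknown hyperparameters for {spec.name}: {list(hp)}")
        model = sm.tsa.SARIMAX(
            train["hi"].to_numpy(dtype=float),
            exog=train[_LINEAR_EXOG].to_numpy(dtype=float),
            order=order,
            seasonal_order=seasonal_order,
        )
        self._results = model.fit(disp=0, maxiter=self._maxiter)
        self.converged = bool(self._results.mle_retvals.get("converged", True))
        self.params = np.asarray(self._results.params)

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        extended = self._results.extend(
            matrix["hi"].to_numpy(dtype=float)
            if "hi" in matrix
            else np.full(len(matrix), np.nan),
            exog=matrix[_LINEAR_EXOG].to_numpy(dtype=float),
        )
        return np.asarray(extended.fittedvalues)

    def forecast_path(self, future_exog: pd.DataFrame) -> np.ndarray:
        """Multi-step mean forecast over a future horizon (no observed HI)."""
        return np.asarray(
            self._results.forecast(
                steps=len(future_exog),
                exog=future_exog[_LINEAR_EXOG].to_numpy(dtype=float),
            )
        )


class ForestAdapter(FittedModel):
    """Random-forest regressor with per-tree prediction access.

    The ensemble point prediction is the arithmetic mean over the per-tree
    predictions; ``tree_predictions`` exposes the full tree-level
    distribution so callers can form empirical prediction intervals from its
    percentiles.  Inputs are min-max scaled with ranges frozen on the
    training block.
    """

    def __init__(self, spec: ModelSpec, train: pd.DataFrame):
        from sklearn.ensemble import RandomForestRegressor

        self.spec = spec
        self.feature_names = _feature_columns(train)
        hp = {
            "n_estimators": 300,
            "max_features": "sqrt",
            "max_depth": None,
            **spec.hyperparameters,
        }
        self.scaler = _FeatureScaler(train, self.feature_names)
        self.model = RandomForestRegressor(
            random_state=spec.seed, n_jobs=1, **hp
        )
        self.model.fit(
            self.scaler.transform(train).astype(np.float32),
            train["hi"].to_numpy(dtype=float),
        )
        self._trees = [est.tree_ for est in self.model.estimators_]
        self._leaf_values = [t.value[:, 0, 0] for t in self._trees]

    @property
    def n_trees(self) -> int:
        return len(self._trees)

    def _scaled(self, matrix: pd.DataFrame) -> np.ndarray:
        return self.scaler.transform(matrix).astype(np.float32)

    def tree_predictions(self, matrix: pd.DataFrame) -> np.ndarray:
        """(n_rows, n_trees) matrix of individual tree predictions."""
        x = self._scaled(matrix)
        cols = [lv[t.apply(x)] for t, lv in zip(self._trees, self._leaf_values)]
        return np.column_stack(cols)

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        return self.tree_predictions(matrix).mean(axis=1)

    def tree_predictions_single(self, row: np.ndarray) -> np.ndarray:
        """Per-tree predictions for one raw feature row (fast path used by
        the recursive projector)."""
        x = self.scaler.transform_row(row).reshape(1, -1).astype(np.float32)
        return np.array(
            [lv[t.apply(x)[0]] for t, lv in zip(self._trees, self._leaf_values)]
        )

    def predict_single(self, row: np.ndarray) -> float:
        return float(self.tree_predictions_single(row).mean())


class XGBoostAdapter(FittedModel):
    """Gradient-boosting adapter (XGBoost) with early stopping.

    The final tenth of the training block, chronologically, serves as the
    early-stopping validation slice; inputs are min-max scaled with ranges
    frozen on the training block.
    """

    def __init__(self, spec: ModelSpec, train: pd.DataFrame):
        from xgboost import XGBRegressor

        self.spec = spec
        self.feature_names = _feature_columns(train)
        hp = {
            "n_estimators": 500,
            "learning_rate": 0.05,
            "early_stopping_rounds": 50,
            **spec.hyperparameters,
        }
        early = hp.pop("early_stopping_rounds")
        self.scaler = _FeatureScaler(train, self.feature_names)
        x = self.scaler.transform(train).astype(np.float32)
        y = train["hi"].to_numpy(dtype=float)
        n_val = max(1, len(train) // 10)
        self.model = XGBRegressor(
            random_state=spec.seed,
            n_jobs=1,
            early_stopping_rounds=early,
            **hp,
        )
        self.model.fit(
            x[:-n_val],
            y[:-n_val],
            eval_set=[(x[-n_val:], y[-n_val:])],
            verbose=False,
        )

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        x = self.scaler.transform(matrix).astype(np.float32)
        return self.model.predict(x).astype(float)


_ADAPTERS = {
    "naive": NaiveLagModel,
    "arimax": SarimaxAdapter,
    "sarimax": SarimaxAdapter,
    "rfr": ForestAdapter,
    "gboost": XGBoostAdapter,
}


def fit(spec: ModelSpec, train: pd.DataFrame) -> FittedModel:
    """Fit the adapter named by ``spec`` on a training feature matrix."""
    if len(train) == 0:
        raise ValueError("training matrix is empty")
    return _ADAPTERS[spec.name](spec, train)


# ---------------------------------------------------------------------------
# Expanding-window cross-validation and grid search
# ---------------------------------------------------------------------------


def expanding_window_cv(
    spec: ModelSpec, train: pd.DataFrame, folds: int = 5
) -> dict:
    """Expanding-window CV: fold k trains on everything before validation
    block k; the ``folds`` contiguous validation blocks are equal slices of
    the span after an initial burn-in block of the same size.

    Returns per-fold RMSEs with their mean and standard deviation.
    """
    n = len(train)
    if n < (folds + 1) * 2:
        raise ValueError("too few rows for the requested number of folds")
    edges = np.linspace(0, n, folds + 2).astype(int)  # burn-in + `folds` blocks
    rmses = []
    fold_sizes = []
    for k in range(1, folds + 1):
        fit_block = train.iloc[: edges[k]]
        val_block = train.iloc[edges[k]: edges[k + 1]]
        model = fit(spec, fit_block)
        err = val_block["hi"].to_numpy(dtype=float) - model.predict(val_block)
        rmses.append(float(np.sqrt(np.mean(err**2))))
        fold_sizes.append(len(fit_block))
    return {
        "fold_rmse": rmses,
        "fold_train_sizes": fold_sizes,
        "mean_rmse": float(np.mean(rmses)),
        "sd_rmse": float(np.std(rmses, ddof=1)),
    }


def grid_search(
    name: str,
    grid: Sequence[dict],
    train: pd.DataFrame,
    folds: int = 5,
    seed: int = 0,
) -> tuple[ModelSpec, list[dict]]:
    """Select the hyperparameter set minimising mean CV RMSE.

    Ties break in declaration order (the first grid point wins); the test
    partition is never consulted.  Returns the winning spec and the CV
    record of every grid point.
    """
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    records = []
    best = None
    for hp in grid:
        spec = ModelSpec(name=name, hyperparameters=dict(hp), seed=seed)
        cv = expanding_window_cv(spec, train, folds)
        records.append({"hyperparameters": dict(hp), **cv})
        if best is None or cv["mean_rmse"] < best[0]:
            best = (cv["mean_rmse"], spec)
    return best[1], records
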