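"""Climatological scenarios and recursive multi-year Heat Index projection.

Future meteorology is approximated by monthly climatology: per-calendar-month
mean temperature and humidity from the historical record, expanded as
constants within each month of a future 3-hourly grid.  Three named
scenarios perturb this baseline with a deterministic shift plus independent
Gaussian noise (seeded once per scenario):

================  ============  ============  ===========
scenario          ΔT (°C)       ΔRH (pp)      noise level
================  ============  ============  ===========
optimistic        −0.5          −2            low
moderate           0.0           0            moderate
pessimistic       +1.0          +3            elevated
================  ============  ============  ===========

Projection is recursive 3-hour-ahead estimation: lagged HI features are
drawn from the concatenation of the last six observed HI values and the
model's own earlier predictions, so each step feeds the next.  For forest
models the per-tree prediction spread at each step yields empirical 95 %
prediction intervals (2.5th/97.5th percentiles of the tree distribution,
linear interpolation of order statistics).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .heat_index import categorize
from .modeling import FittedModel, ForestAdapter, encode_calendar

__all__ = [
    "NOISE_SDS",
    "SCENARIO_PRESETS",
    "ScenarioSpec",
    "build_future_grid",
    "monthly_climatology",
    "apply_scenario",
    "recursive_project",
    "empirical_interval",
    "interval_calibration",
]

#: (temperature SD °C, humidity SD pp) for the named noise levels.
NOISE_SDS: dict[str, tuple[float, float]] = {
    "low": (0.5, 2.0),
    "moderate": (1.0, 4.0),
    "elevated": (1.5, 6.0),
}

#: (ΔT °C, ΔRH pp, noise level) of the three named scenarios.
SCENARIO_PRESETS: dict[str, tuple[float, float, str]] = {
    "optimistic": (-0.5, -2.0, "low"),
    "moderate": (0.0, 0.0, "moderate"),
    "pessimistic": (1.0, 3.0, "elevated"),
}


@dataclasses.dataclass
class ScenarioSpec:
    """A named or custom climatological scenario."""

    name: str
    delta_t: float = 0.0        # °C shift applied to monthly mean temperature
    delta_rh: float = 0.0       # pp shift applied to monthly mean humidity
    noise_sd_t: float = 0.0     # °C
    noise_sd_rh: float = 0.0    # pp
    seed: int = 0

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "ScenarioSpec":
        if name not in SCENARIO_PRESETS:
            raise ValueError(
                f"unknown scenario {name!r}; presets: {list(SCENARIO_PRESETS)}"
            )
        delta_t, delta_rh, level = SCENARIO_PRESETS[name]
        sd_t, sd_rh = NOISE_SDS[level]
        return cls(
            name=name,
            delta_t=delta_t,
            delta_rh=delta_rh,
            noise_sd_t=sd_t,
            noise_sd_rh=sd_rh,
            seed=seed,
        )


def build_future_grid(start, end) -> pd.DataFrame:
    """Complete 3-hourly future grid with calendar features.

    Columns: hour, day, month and the four fixed-order season indicators,
    encoded exactly as in the training feature matrix.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end < start:
        raise ValueError("end must not precede start")
    idx = pd.date_range(
        start.normalize(),
        end.normalize() + pd.Timedelta(hours=21),
        freq="3h",
        name="timestamp",
    )
    return encode_calendar(idx)


def monthly_climatology(series: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-month mean temperature and humidity.

    Every month 1–12 must be represented in the historical record.
    """
    grouped = series.groupby(series.index.month)[
        ["temperature_c", "relative_humidity_pct"]
    ].mean()
    missing = sorted(set(range(1, 13)) - set(grouped.index))
    if missing:
        raise ValueError(f"months absent from historical series: {missing}")
    grouped.index.name = "month"
    return grouped


def apply_scenario(
    climatology: pd.DataFrame, grid: pd.DataFrame, spec: ScenarioSpec
) -> pd.DataFrame:
    """Future climate series: shifted monthly climatology plus seeded noise.

    Monthly means are expanded as constants within each month (no synthetic
    diurnal cycle); noise is independent across timesteps; humidity is
    clipped to [0, 100] after shift and noise.
    """
    rng = np.random.default_rng(spec.seed)
    months = grid["month"].to_numpy()
    base_t = climatology["temperature_c"].reindex(months).to_numpy()
    base_rh = climatology["relative_humidity_pct"].reindex(months).to_numpy()
    n = len(grid)
    temp = base_t + spec.delta_t + rng.normal(0.0, spec.noise_sd_t, n)
    rh = base_rh + spec.delta_rh + rng.normal(0.0, spec.noise_sd_rh, n)
    return pd.DataFrame(
        {
            "temperature_c": temp,
            "relative_humidity_pct": np.clip(rh, 0.0, 100.0),
        },
        index=grid.index,
    )


def recursive_project(
    model: FittedModel,
    future: pd.DataFrame,
    init_hi: np.ndarray,
    scenario_name: str = "custom",
    lags: tuple[int, ...] = (1, 3, 6),
) -> pd.DataFrame:
    """Recursive 3-hour-ahead projection over a future climate series.

    ``future`` must combine the scenario climate columns with the calendar
    features of :func:`build_future_grid` on a gap-free 3-hourly grid;
    ``init_hi`` holds the last ``max(lags)`` observed HI values in
    chronological order and seeds the lag features.  At step *t* the lag-*k*
    feature is the value predicted at step *t − k* (or an initializer while
    *t < k*); the point prediction feeds the recursion.

    Returns a frame with ``point`` and, for forest models, ``lower``/``upper``
    empirical 95 % bounds from the per-tree spread at each step, plus the
    risk ``category`` of the point projection.
    """
    max_lag = max(lags)
    init_hi = np.asarray(init_hi, dtype=float)
    if init_hi.shape != (max_lag,):
        raise ValueError(f"init_hi must hold exactly {max_lag} values")
    if len(future) > 1:
        deltas = np.diff(future.index.to_numpy())
        if not np.all(deltas == np.timedelta64(3, "h")):
            raise ValueError("future grid has gaps or irregular spacing")

    feature_names = list(model.feature_names)
    lag_positions = {k: feature_names.index(f"hi_lag{k}") for k in lags}
    base = future[
        [c for c in feature_names if not c.startswith("hi_lag")]
    ]
    x = np.empty((len(future), len(feature_names)), dtype=float)
    for j, name in enumerate(feature_names):
        if not name.startswith("hi_lag"):
            x[:, j] = base[name].to_numpy(dtype=float)

    is_forest = isinstance(model, ForestAdapter)
    n = len(future)
    history = np.concatenate([init_hi, np.empty(n)])
    point = np.empty(n)
    lower = np.full(n, np.nan)
    upper = np.full(n, np.nan)
    for t in range(n):
        row = x[t]
        for k, j in lag_positions.items():
            row[j] = history[max_lag + t - k]
        if is_forest:
            trees = model.tree_predictions_single(row)
            point[t] = trees.mean()
            lower[t], upper[t] = np.percentile(trees, [2.5, 97.5])
        else:
            point[t] = model.predict_single(row)
        history[max_lag + t] = point[t]

    result = pd.DataFrame(
        {"point": point, "lower": lower, "upper": upper}, index=future.index
    )
    result["scenario"] = scenario_name
    result["category"] = categorize(point)
    result.attrs["init_hi"] = init_hi.tolist()
    result.attrs["model"] = model.spec.name
    return result


def empirical_interval(tree_predictions: np.ndarray) -> tuple:
    """Ensemble mean and empirical 95 % bounds from per-tree predictions.

    ``tree_predictions`` is either a vector (one timestamp) or an
    (n_timestamps, n_trees) matrix.  The mean is the arithmetic average over
    trees; bounds are the 2.5th and 97.5th percentiles of the tree
    distribution with linear interpolation of order statistics.
    """
    preds = np.asarray(tree_predictions, dtype=float)
    axis = preds.ndim - 1
    if preds.shape[axis] < 2:
        raise ValueError("need at least 2 ensemble members")
    mean = preds.mean(axis=axis)
    lower = np.percentile(preds, 2.5, axis=axis)
    upper = np.percentile(preds, 97.5, axis=axis)
    return mean, lower, upper


def interval_calibration(
    lower: np.ndarray, upper: np.ndarray, observed: np.ndarray
) -> tuple[float, float]:
    """Empirical coverage (%) and mean width (°C) of prediction intervals.

    Coverage counts observations with lower ≤ y ≤ upper, bounds inclusive.
    Pandas inputs must share an index; misalignment is an error rather than
    silently reindexed.
    """
    if isinstance(observed, pd.Series):
        for bound in (lower, upper):
            if isinstance(bound, pd.Series) and not bound.index.equals(observed.index):
                raise ValueError("interval bounds and observations are misaligned")
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    y = np.asarray(observed, dtype=float)
    if not (lo.shape == hi.shape == y.shape):
        raise ValueError("interval bounds and observations are misaligned")
    coverage = float(np.mean((y >= lo) & (y <= hi)) * 100.0)
    width = float(np.mean(hi - lo))
    return coverage, width
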