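"""Accuracy metrics, residual diagnostics and risk-category summaries.

Point accuracy is scored with MSE, RMSE, MAE, MAPE (in percent), MASE and
R².  MASE scales the model's mean absolute error by the in-sample mean
absolute error of the naive persistence benchmark — the forecast that HI at
time t equals its value one 3-hourly step earlier — so MASE < 1 means the
model beats persistence on the same series.  Residual diagnostics cover
serial correlation (Durbin–Watson) and heteroscedasticity (Breusch–Pagan).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.tools import add_constant

from .heat_index import RISK_CATEGORIES, categorize

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "naive_persistence",
    "durbin_watson",
    "breusch_pagan",
    "category_distribution",
]


@dataclasses.dataclass
class MetricsReport:
    """Point-accuracy summary for one model on one evaluation block."""

    mse: float          # °C²
    rmse: float         # °C
    mae: float          # °C
    mape: float | None  # %, absent when the target contains zeros
    mase: float         # unitless, persistence-scaled
    r2: float           # unitless, ≤ 1
    n: int              # observations scored
    m: int              # persistence lag (in 3-hourly steps)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_metrics(y, yhat, m: int = 1) -> MetricsReport:
    """Score predictions against observations.

    The MASE denominator is the in-sample mean absolute m-step naive error
    ``mean |y_j − y_{j−m}|`` over j = m+1 … n, with m = 1 by default (the
    3-hour persistence benchmark).  A constant target makes that denominator
    zero and is an error; zeros in the target suppress MAPE with a warning
    instead of dividing by zero.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    err = y - yhat
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(err)))
    if np.any(y == 0.0):
        warnings.warn("target contains zeros; MAPE not reported")
        mape = None
    else:
        mape = float(np.mean(np.abs(err / y)) * 100.0)
    denom = float(np.mean(np.abs(y[m:] - y[:-m])))
    if denom == 0.0:
        raise ValueError("constant target: MASE denominator is zero")
    mase = float(mae / denom)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / ss_tot) if ss_tot > 0 else float("nan")
    return MetricsReport(mse=mse, rmse=rmse, mae=mae, mape=mape, mase=mase,
                         r2=r2, n=n, m=m)


def naive_persistence(series) -> np.ndarray:
    """Persistence forecast: each value predicts the next step.

    Returns an array aligned with the input where position t holds the
    observation at t − 1; position 0 is NaN and must be excluded from
    scoring.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 2:
        raise ValueError("persistence needs at least 2 observations")
    out = np.empty_like(y)
    out[0] = np.nan
    out[1:] = y[:-1]
    return out


def durbin_watson(residuals) -> float:
    """Durbin–Watson statistic Σ(e_t − e_{t−1})² / Σe_t².

    ≈ 2 for white noise, → 0 under strong positive serial correlation
    (2(1 − ρ) for an AR(1) with coefficient ρ), → 4 under negative.
    """
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(np.sum(e**2))
    if denom == 0.0:
        raise ValueError("all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


def breusch_pagan(residuals, regressors) -> tuple[float, float]:
    """Breusch–Pagan LM test for heteroscedasticity.

    Regresses squared residuals on the given regressors (with an intercept);
    LM = n·R² is χ²(k)-distributed under homoscedasticity, k the number of
    regressors.  Returns (LM statistic, p-value).
    """
    e = np.asarray(residuals, dtype=float)
    x = np.asarray(regressors, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    if len(e) <= x.shape[1]:
        raise ValueError("need more observations than regressors")
    exog = add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("rank-deficient regressors")
    lm, lm_pvalue, _, _ = het_breuschpagan(e, exog)
    return float(lm), float(lm_pvalue)


def category_distribution(values) -> pd.Series:
    """Percentage share of each risk category over a set of records.

    Accepts HI values in °C (categorised on the fly) or pre-computed
    category labels; all five categories appear in the output, zeros
    included, and shares sum to 100 within rounding.
    """
    if isinstance(values, pd.DataFrame):
        values = values["category"] if "category" in values else values["hi_c"]
    arr = pd.Series(values).reset_index(drop=True)
    if len(arr) == 0:
        raise ValueError("empty input")
    if arr.dtype.kind in "fi":
        cats = pd.Series(categorize(arr.to_numpy()))
    else:
        cats = pd.Series(
            pd.Categorical(arr, categories=list(RISK_CATEGORIES), ordered=True)
        )
    shares = cats.value_counts(normalize=True, sort=False) * 100.0
    return shares.reindex(list(RISK_CATEGORIES), fill_value=0.0)
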