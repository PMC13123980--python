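"""NWS Heat Index (apparent temperature) and heat-health risk categories.

The Heat Index (HI) combines dry-bulb temperature and relative humidity into
a single apparent-temperature measure of physiological heat stress.  The
operational National Weather Service procedure is two-stage:

1. A simplified linear formula (Steadman-style) gives a preliminary estimate.
   If the preliminary value is below 80 °F the Heat Index equals that value.
2. Otherwise the full nine-term Rothfusz regression polynomial is evaluated,
   with two empirical corrections: a subtraction for very dry air
   (RH < 13 %, 80–112 °F) and an addition for very humid, moderately hot air
   (RH > 85 %, 80–87 °F).

All internal arithmetic is in °F (the polynomial's native units); the public
entry point :func:`heat_index_celsius` converts on the way in and out.

Two conventions exist for Stage 1 and both are supported via
``steadman_mode``:

* ``"paper"`` (default): the simple formula's output is averaged with the
  air temperature to form the preliminary estimate.
* ``"nws"``: the simple formula itself *is* the preliminary estimate (its
  constants already perform the averaging in the canonical NWS statement).

Risk categories follow the NWS bands expressed in °C: Normal (< 27),
Caution (27–32), Extreme Caution (32–41), Danger (41–54) and Extreme Danger
(≥ 54); bins are closed on the left.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ROTHFUSZ_COEFFICIENTS",
    "RISK_CATEGORIES",
    "CATEGORY_BOUNDS_C",
    "celsius_to_fahrenheit",
    "fahrenheit_to_celsius",
    "hi_simple",
    "preliminary_hi",
    "hi_rothfusz",
    "adjustment_low_humidity",
    "adjustment_high_humidity",
    "heat_index_fahrenheit",
    "heat_index_celsius",
    "categorize",
    "apply_heat_index",
]

#: The nine Rothfusz regression constants (°F-based polynomial).  These are
#: fixed at the published values and are deliberately not configurable.
ROTHFUSZ_COEFFICIENTS: tuple[float, ...] = (
    -42.379,
    2.04901523,
    10.14333127,
    -0.22475541,
    -0.00683783,
    -0.05481717,
    0.00122874,
    0.00085282,
    -0.00000199,
)

#: Ordered risk-category labels, coolest to hottest.
RISK_CATEGORIES: tuple[str, ...] = (
    "Normal",
    "Caution",
    "Extreme Caution",
    "Danger",
    "Extreme Danger",
)

#: Lower-inclusive category boundaries in °C between successive categories.
CATEGORY_BOUNDS_C: tuple[float, ...] = (27.0, 32.0, 41.0, 54.0)

_STEADMAN_MODES = ("paper", "nws")


def celsius_to_fahrenheit(t_c):
    return np.asarray(t_c, dtype=float) * 9.0 / 5.0 + 32.0


def fahrenheit_to_celsius(t_f):
    return (np.asarray(t_f, dtype=float) - 32.0) * 5.0 / 9.0


def _check_rh(rh) -> np.ndarray:
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    return rh


def hi_simple(t_f, rh):
    """Simplified Steadman-style Heat Index estimate in °F.

    ``0.5 * [T + 61.0 + (T - 68.0) * 1.2 + RH * 0.094]`` with T in °F.
    """
    t_f = np.asarray(t_f, dtype=float)
    rh = _check_rh(rh)
    return 0.5 * (t_f + 61.0 + (t_f - 68.0) * 1.2 + rh * 0.094)


def preliminary_hi(t_f, rh, steadman_mode: str = "paper"):
    """Stage-1 preliminary Heat Index in °F.

    In ``"paper"`` mode the simple estimate is averaged with the air
    temperature; in ``"nws"`` mode the simple estimate is used directly.
    """
    if steadman_mode not in _STEADMAN_MODES:
        raise ValueError(f"steadman_mode must be one of {_STEADMAN_MODES}")
    simple = hi_simple(t_f, rh)
    if steadman_mode == "paper":
        return (simple + np.asarray(t_f, dtype=float)) / 2.0
    return simple


def hi_rothfusz(t_f, rh):
    """Nine-term Rothfusz regression polynomial in °F.

    Intended for preliminary estimates ≥ 80 °F; the branch decision is the
    caller's responsibility.
    """
    t = np.asarray(t_f, dtype=float)
    r = np.asarray(rh, dtype=float)
    c = ROTHFUSZ_COEFFICIENTS
    return (
        c[0]
        + c[1] * t
        + c[2] * r
        + c[3] * t * r
        + c[4] * t * t
        + c[5] * r * r
        + c[6] * t * t * r
        + c[7] * t * r * r
        + c[8] * t * t * r * r
    )


def adjustment_low_humidity(t_f, rh):
    """Dry-air correction in °F, to be *subtracted* from the Rothfusz value.

    Non-zero only for RH < 13 % and 80 °F ≤ T ≤ 112 °F, where it equals
    ``((13 - RH) / 4) * sqrt((17 - |T - 95|) / 17)``.
    """
    t = np.asarray(t_f, dtype=float)
    r = np.asarray(rh, dtype=float)
    window = (r < 13.0) & (t >= 80.0) & (t <= 112.0)
    inner = np.clip((17.0 - np.abs(t - 95.0)) / 17.0, 0.0, None)
    adj = ((13.0 - r) / 4.0) * np.sqrt(inner)
    return np.where(window, adj, 0.0)


def adjustment_high_humidity(t_f, rh):
    """Humid-air correction in °F, to be *added* to the Rothfusz value.

    Non-zero only for RH > 85 % and 80 °F ≤ T ≤ 87 °F, where it equals
    ``((RH - 85) / 10) * ((87 - T) / 5)``.
    """
    t = np.asarray(t_f, dtype=float)
    r = np.asarray(rh, dtype=float)
    window = (r > 85.0) & (t >= 80.0) & (t <= 87.0)
    adj = ((r - 85.0) / 10.0) * ((87.0 - t) / 5.0)
    return np.where(window, adj, 0.0)


def heat_index_fahrenheit(t_f, rh, steadman_mode: str = "paper"):
    """Full two-stage Heat Index in °F (vectorized)."""
    t = np.asarray(t_f, dtype=float)
    rh = _check_rh(rh)
    prelim = preliminary_hi(t, rh, steadman_mode)
    full = (
        hi_rothfusz(t, rh)
        - adjustment_low_humidity(t, rh)
        + adjustment_high_humidity(t, rh)
    )
    return np.where(prelim < 80.0, prelim, full)


def heat_index_celsius(t_c, rh, steadman_mode: str = "paper"):
    """Heat Index in °C from temperature in °C and relative humidity in %.

    Temperature is converted to °F, the two-stage procedure applied, and the
    result converted back; no intermediate rounding is performed.
    """
    t_c = np.asarray(t_c, dtype=float)
    if not np.all(np.isfinite(t_c)):
        raise ValueError("temperature must be finite")
    t_f = celsius_to_fahrenheit(t_c)
    hi_f = heat_index_fahrenheit(t_f, rh, steadman_mode)
    return fahrenheit_to_celsius(hi_f)


def categorize(hi_c) -> pd.Categorical:
    """Map Heat Index values (°C) onto the five NWS risk categories.

    Bins are lower-inclusive: HI = 32 °C is Extreme Caution, HI = 41 °C is
    Danger.  Non-finite inputs are rejected.
    """
    hi = np.asarray(hi_c, dtype=float)
    if not np.all(np.isfinite(hi)):
        raise ValueError("Heat Index values must be finite")
    idx = np.digitize(hi, CATEGORY_BOUNDS_C, right=False)
    labels = np.take(RISK_CATEGORIES, idx)
    return pd.Categorical(labels, categories=list(RISK_CATEGORIES), ordered=True)


def apply_heat_index(series: pd.DataFrame, steadman_mode: str = "paper") -> pd.DataFrame:
    """Augment a climate series with ``hi_c`` and ``category`` columns.

    ``series`` must carry ``temperature_c`` and ``relative_humidity_pct``
    columns; a copy is returned, the input is never mutated.
    """
    out = series.copy()
    out["hi_c"] = heat_index_celsius(
        series["temperature_c"].to_numpy(),
        series["relative_humidity_pct"].to_numpy(),
        steadman_mode,
    )
    out["category"] = categorize(out["hi_c"].to_numpy())
    return out
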