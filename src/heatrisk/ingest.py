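"""Ingest and quality control of wide-format station tables.

Station archives deliver dry-bulb temperature and relative humidity as two
wide tables: one row per calendar day (Year/Month/Day keys) and one value
column per synoptic hour (00, 03, …, 21).  This module reshapes them to long
format, validates every calendar date strictly (February 30 is rejected, not
coerced), merges the two variables by multi-key matching, and runs the
descriptive quality-control steps: grid-continuity checking, IQR outlier
flagging (flagging only — extreme values are retained), season assignment,
min-max scaling with train-only ranges, and variance-inflation-factor
collinearity diagnostics.

QC is purely descriptive: no operation here ever mutates or removes a value.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools import add_constant

__all__ = [
    "HOUR_COLUMNS",
    "SEASON_BY_MONTH",
    "SEASONS",
    "QCReport",
    "read_wide_tables",
    "merge_long",
    "validate_continuity",
    "flag_outliers_iqr",
    "assign_season",
    "MinMaxScaler",
    "compute_vif",
    "qc_report",
]

#: Expected value columns of the wide dialect, in synoptic order.
HOUR_COLUMNS: tuple[str, ...] = ("00", "03", "06", "09", "12", "15", "18", "21")

#: Standard meteorological quarters.
SEASON_BY_MONTH: dict[int, str] = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

#: Fixed season ordering used for one-hot encodings.
SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "autumn")


@dataclasses.dataclass
class QCReport:
    """Descriptive quality-control summary; never used to alter data."""

    n_records: int = 0
    n_missing_timestamps: int = 0
    n_invalid_dates: int = 0
    missing_timestamps: list = dataclasses.field(default_factory=list)
    outlier_flags: list = dataclasses.field(default_factory=list)
    vif: dict = dataclasses.field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "n_records": self.n_records,
            "n_missing_timestamps": self.n_missing_timestamps,
            "n_invalid_dates": self.n_invalid_dates,
            "missing_timestamps": [str(t) for t in self.missing_timestamps],
            "outlier_flags": [(str(t), v) for t, v in self.outlier_flags],
            "vif": {k: float(v) for k, v in self.vif.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _wide_to_long(table: pd.DataFrame, source: str) -> pd.DataFrame:
    table = table.copy()
    table.columns = [str(c).strip() for c in table.columns]
    key_cols = ["Year", "Month", "Day"]
    missing_keys = [c for c in key_cols if c not in table.columns]
    if missing_keys:
        raise ValueError(f"{source}: missing key columns {missing_keys}")
    hour_cols = [c for c in HOUR_COLUMNS if c in table.columns]
    if len(hour_cols) != len(HOUR_COLUMNS):
        absent = sorted(set(HOUR_COLUMNS) - set(hour_cols))
        raise ValueError(f"{source}: missing hour columns {absent}")

    long = table.melt(
        id_vars=key_cols,
        value_vars=list(HOUR_COLUMNS),
        var_name="hour",
        value_name="value",
    )
    long = long.rename(columns={"Year": "year", "Month": "month", "Day": "day"})
    long["hour"] = long["hour"].astype(int)

    # Strict calendar validation: impossible dates are an error, not a NaT.
    parsed = pd.to_datetime(
        long[["year", "month", "day"]], errors="coerce"
    )
    bad = parsed.isna()
    if bad.any():
        first = long.loc[bad].iloc[0]
        raise ValueError(
            f"{source}: invalid calendar date "
            f"{int(first['year'])}-{int(first['month'])}-{int(first['day'])}"
        )
    return long[["year", "month", "day", "hour", "value"]]


def read_wide_tables(temp_path, rh_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the two wide tables into long (year, month, day, hour, value)
    frames, applying strict date parsing."""
    temp_long = _wide_to_long(_read_table(temp_path), f"temperature table {temp_path}")
    rh_long = _wide_to_long(_read_table(rh_path), f"humidity table {rh_path}")
    return temp_long, rh_long


def _key_frame(long: pd.DataFrame, name: str) -> pd.DataFrame:
    keys = ["year", "month", "day", "hour"]
    dup = long.duplicated(subset=keys)
    if dup.any():
        first = long.loc[dup, keys].iloc[0].to_dict()
        raise ValueError(f"duplicate key in {name} table: {first}")
    return long


def merge_long(temp_long: pd.DataFrame, rh_long: pd.DataFrame) -> pd.DataFrame:
    """Inner-join the two long tables on (year, month, day, hour).

    Returns a timestamp-indexed climate series with ``temperature_c`` and
    ``relative_humidity_pct``.  Keys present in only one table are excluded
    and recorded in ``result.attrs['unmatched_keys']``.  Duplicate keys or
    an empty overlap raise.
    """
    keys = ["year", "month", "day", "hour"]
    t = _key_frame(temp_long, "temperature").rename(columns={"value": "temperature_c"})
    r = _key_frame(rh_long, "humidity").rename(columns={"value": "relative_humidity_pct"})
    merged = t.merge(r, on=keys, how="outer", indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both", keys]
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    if len(merged) == 0:
        raise ValueError("temperature and humidity tables share no keys")

    ts = pd.to_datetime(merged[keys].assign(hour=merged["hour"]))
    series = pd.DataFrame(
        {
            "temperature_c": merged["temperature_c"].to_numpy(dtype=float),
            "relative_humidity_pct": merged["relative_humidity_pct"].to_numpy(dtype=float),
        },
        index=pd.DatetimeIndex(ts, name="timestamp"),
    ).sort_index()
    series.attrs["unmatched_keys"] = [tuple(row) for row in unmatched.to_numpy()]
    return series


def validate_continuity(series: pd.DataFrame) -> QCReport:
    """Report every expected-but-absent 3-hourly timestamp.

    The expected grid spans min to max observed timestamps at 3-hour spacing;
    the report is descriptive and the series is returned untouched.
    """
    idx = series.index
    report = QCReport(n_records=len(idx))
    if len(idx) == 0:
        return report
    expected = pd.date_range(idx.min(), idx.max(), freq="3h")
    missing = expected.difference(idx)
    report.n_missing_timestamps = len(missing)
    report.missing_timestamps = list(missing)
    return report


def flag_outliers_iqr(
    series: pd.DataFrame,
    columns: tuple[str, ...] = ("temperature_c", "relative_humidity_pct"),
    k: float = 1.5,
) -> list[tuple[pd.Timestamp, str]]:
    """Flag values outside [Q1 − k·IQR, Q3 + k·IQR], per variable.

    Quartiles use linear interpolation between order statistics.  Flags are
    reported only; nothing is removed (extremes in station records are
    typically genuine weather).
    """
    if len(series) < 4:
        raise ValueError("IQR flagging needs at least 4 records")
    flags: list[tuple[pd.Timestamp, str]] = []
    for col in columns:
        values = series[col]
        q1, q3 = values.quantile([0.25, 0.75])
        iqr = q3 - q1
        mask = (values < q1 - k * iqr) | (values > q3 + k * iqr)
        flags.extend((ts, col) for ts in series.index[mask])
    return flags


def assign_season(month: int) -> str:
    """Month number → meteorological season label."""
    month = int(month)
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return SEASON_BY_MONTH[month]


class MinMaxScaler:
    """Min-max scaling with ranges frozen on the training partition.

    Training values map into [0, 1]; values applied later may fall outside
    that interval (linear extrapolation), which is intentional: the scaler
    must never peek at post-training data.  Constant columns are rejected
    because their range is degenerate.
    """

    def __init__(self) -> None:
        self.mins: pd.Series | None = None
        self.maxs: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "MinMaxScaler":
        if len(train) == 0:
            raise ValueError("cannot fit scaler on an empty frame")
        self.mins = train.min()
        self.maxs = train.max()
        constant = self.maxs[self.maxs == self.mins]
        if len(constant) > 0:
            raise ValueError(f"constant column(s): {list(constant.index)}")
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if self.mins is None:
            raise RuntimeError("scaler is not fitted")
        cols = self.mins.index
        return (frame[cols] - self.mins) / (self.maxs - self.mins)

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)


def compute_vif(features: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per feature: VIF_j = 1 / (1 − R²_j) from
    regressing feature j on all others (with intercept).

    Perfectly collinear features yield very large or infinite VIFs rather
    than an error.
    """
    if features.shape[1] < 2:
        raise ValueError("VIF needs at least 2 features")
    if len(features) <= features.shape[1]:
        raise ValueError("VIF needs more rows than features")
    x = add_constant(features.astype(float), has_constant="add")
    with np.errstate(divide="ignore"):
        return {
            col: float(variance_inflation_factor(x.to_numpy(), i))
            for i, col in enumerate(x.columns)
            if col != "const"
        }


def qc_report(
    series: pd.DataFrame, vif_features: pd.DataFrame | None = None
) -> QCReport:
    """Assemble the full descriptive QC report for a merged climate series."""
    report = validate_continuity(series)
    if len(series) >= 4:
        report.outlier_flags = flag_outliers_iqr(series)
    if vif_features is not None:
        report.vif = compute_vif(vif_features)
    return report
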