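"""Synthetic 3-hourly tropical climate series with known ground truth.

The generator emulates the structure of synoptic-hour station records from a
monsoon-climate megacity: a gap-free 3-hourly grid (hours 00, 03, …, 21), an
annual temperature harmonic, a diurnal harmonic peaking in early afternoon,
short-memory AR(1) weather noise, and relative humidity that is negatively
coupled to the *de-seasonalized* temperature anomaly (hot afternoons are
dry) while optionally carrying its own seasonal harmonic (monsoon months are
humid).  Everything is deterministic for a fixed seed.

The module also writes fixtures in the wide station dialect (one row per
calendar day, one column per synoptic hour, separate files for temperature
and humidity) and can inject controlled defects for negative testing of the
ingest/QC stage.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "SYNOPTIC_HOURS",
    "SyntheticConfig",
    "generate_climate",
    "implied_trh_correlation",
    "solve_seasonal_cycle",
    "dhaka_like_config",
    "write_wide_fixtures",
    "series_to_long_tables",
    "inject_defects",
]

#: The eight synoptic observation hours of a 3-hourly station record.
SYNOPTIC_HOURS: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18, 21)

_DAYS_PER_YEAR = 365.25


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return dt.date.fromisoformat(str(d))


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic climate generator.

    Temperature model (°C)::

        T(t) = mean_temp
             + annual_amplitude  * cos(2π (doy(t) − annual_peak_doy) / 365.25)
             + annual_amplitude2 * cos(4π (doy(t) − annual_peak_doy) / 365.25)
             + diurnal_amplitude * cos(2π (hour(t) − diurnal_peak_hour) / 24)
             + z(t),   z AR(1) with coefficient ar_coefficient and
                       innovation SD noise_sd, started at stationarity.

    The optional phase-locked first overtone (``annual_amplitude2``, default
    0) shapes the annual cycle: a negative value flattens the hot season
    into a monsoon-style plateau while keeping the winter short and sharp —
    the characteristic annual profile of a tropical monsoon station.

    Relative humidity (%)::

        RH(t) = rh_baseline
              + rh_annual_amplitude * cos(2π (doy(t) − rh_peak_doy) / 365.25)
              + rh_coupling * (diurnal(t) + z(t))      # de-seasonalized anomaly
              + ε(t),  ε white noise with SD rh_noise_sd,

    clipped to [5, 100] %.  Coupling to the de-seasonalized anomaly (rather
    than the full anomaly) lets the generator reproduce the observed pattern
    of tropical stations where afternoons are dry relative to mornings while
    the hottest months are simultaneously the most humid.
    """

    start_date: dt.date = dt.date(2014, 1, 1)
    end_date: dt.date = dt.date(2023, 12, 31)
    mean_temp: float = 25.0          # °C
    annual_amplitude: float = 5.0    # °C
    diurnal_amplitude: float = 4.0   # °C
    ar_coefficient: float = 0.7      # unitless, in [0, 1)
    noise_sd: float = 1.0            # °C innovation SD
    rh_baseline: float = 75.0        # %
    rh_coupling: float = -1.5        # percentage points per °C of anomaly
    rh_noise_sd: float = 8.0         # percentage points
    seed: int = 0
    annual_peak_doy: float = 135.0   # mid-May by default
    annual_amplitude2: float = 0.0   # °C, phase-locked first overtone
    diurnal_peak_hour: float = 12.0  # early-afternoon peak
    rh_annual_amplitude: float = 0.0  # percentage points
    rh_peak_doy: float = 196.0       # mid-July (monsoon) by default

    def __post_init__(self) -> None:
        self.start_date = _as_date(self.start_date)
        self.end_date = _as_date(self.end_date)
        if self.end_date < self.start_date:
            raise ValueError("end_date must be on or after start_date")
        if self.noise_sd < 0 or self.rh_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")


def _grid(start: dt.date, end: dt.date) -> pd.DatetimeIndex:
    return pd.date_range(
        pd.Timestamp(start),
        pd.Timestamp(end) + pd.Timedelta(hours=21),
        freq="3h",
        name="timestamp",
    )


def _annual_phase(
    index: pd.DatetimeIndex, peak_doy: float, harmonic: int = 1
) -> np.ndarray:
    doy = index.dayofyear.to_numpy(dtype=float) + index.hour.to_numpy(dtype=float) / 24.0
    return np.cos(harmonic * 2.0 * np.pi * (doy - peak_doy) / _DAYS_PER_YEAR)


def generate_climate(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a gap-free 3-hourly climate series.

    Returns a DataFrame indexed by timestamp with columns ``temperature_c``
    and ``relative_humidity_pct``; byte-identical for identical config.
    """
    idx = _grid(config.start_date, config.end_date)
    n = len(idx)
    rng = np.random.default_rng(config.seed)

    annual = config.annual_amplitude * _annual_phase(
        idx, config.annual_peak_doy
    ) + config.annual_amplitude2 * _annual_phase(
        idx, config.annual_peak_doy, harmonic=2
    )
    hours = idx.hour.to_numpy(dtype=float)
    diurnal = config.diurnal_amplitude * np.cos(
        2.0 * np.pi * (hours - config.diurnal_peak_hour) / 24.0
    )

    phi = config.ar_coefficient
    innov = rng.normal(0.0, config.noise_sd, size=n)
    if config.noise_sd > 0:
        z0 = rng.normal(0.0, config.noise_sd / np.sqrt(1.0 - phi * phi))
    else:
        z0 = 0.0
    # AR(1) recursion z_t = phi z_{t-1} + e_t, seeded from the stationary law.
    z, _ = lfilter([1.0], [1.0, -phi], innov, zi=np.array([phi * z0]))

    temperature = config.mean_temp + annual + diurnal + z

    rh_seasonal = config.rh_annual_amplitude * _annual_phase(idx, config.rh_peak_doy)
    anomaly = diurnal + z
    rh = (
        config.rh_baseline
        + rh_seasonal
        + config.rh_coupling * anomaly
        + rng.normal(0.0, config.rh_noise_sd, size=n)
    )
    rh = np.clip(rh, 5.0, 100.0)

    return pd.DataFrame(
        {"temperature_c": temperature, "relative_humidity_pct": rh}, index=idx
    )


def implied_trh_correlation(config: SyntheticConfig) -> float:
    """Closed-form Pearson correlation between T and RH implied by the config.

    Derived from the variance decomposition of the generator (harmonics
    contribute half their squared amplitude; the AR(1) component contributes
    its stationary variance).  Humidity clipping is ignored, so the sample
    correlation of a generated series matches this value only approximately
    when clipping is active.
    """
    var_ar = (
        config.noise_sd**2 / (1.0 - config.ar_coefficient**2)
        if config.noise_sd > 0
        else 0.0
    )
    var_anom = config.diurnal_amplitude**2 / 2.0 + var_ar
    var_t = (
        config.annual_amplitude**2 / 2.0
        + config.annual_amplitude2**2 / 2.0
        + var_anom
    )
    phase_gap = 2.0 * np.pi * (config.annual_peak_doy - config.rh_peak_doy) / _DAYS_PER_YEAR
    cov_seasonal = 0.5 * config.annual_amplitude * config.rh_annual_amplitude * np.cos(phase_gap)
    cov = config.rh_coupling * var_anom + cov_seasonal
    var_rh = (
        config.rh_coupling**2 * var_anom
        + config.rh_annual_amplitude**2 / 2.0
        + config.rh_noise_sd**2
    )
    if var_t == 0.0 or var_rh == 0.0:
        return 0.0
    return float(cov / np.sqrt(var_t * var_rh))


def solve_seasonal_cycle(
    summer_mean: float,
    winter_mean: float,
    peak_doy: float,
    april_mean: float | None = None,
    start: dt.date = dt.date(2014, 1, 1),
    end: dt.date = dt.date(2023, 12, 31),
) -> tuple[float, float, float]:
    """Solve (mean, fundamental amplitude, overtone amplitude) from target
    seasonal temperature means.

    Summer is Jun–Aug, winter Dec–Feb (standard meteorological quarters).
    The seasonal means are linear in the harmonic coefficients; the
    season-window averages of the cosines are evaluated exactly on the
    requested grid and the linear system solved.  Diurnal and noise terms
    average to ~0 and do not enter.  Without an ``april_mean`` anchor the
    overtone amplitude is 0 (pure sinusoid); with it, a third equation pins
    the shoulder-month level, which shapes the flat-topped hot season of
    monsoon climates.
    """
    idx = _grid(start, end)
    phase1 = _annual_phase(idx, peak_doy)
    phase2 = _annual_phase(idx, peak_doy, harmonic=2)
    month = idx.month.to_numpy()
    windows = [np.isin(month, (6, 7, 8)), np.isin(month, (12, 1, 2))]
    targets = [summer_mean, winter_mean]
    if april_mean is not None:
        windows.append(month == 4)
        targets.append(april_mean)
        a = np.array([[1.0, phase1[w].mean(), phase2[w].mean()] for w in windows])
        mean, a1, a2 = np.linalg.solve(a, np.array(targets))
    else:
        a = np.array([[1.0, phase1[w].mean()] for w in windows])
        mean, a1 = np.linalg.solve(a, np.array(targets))
        a2 = 0.0
    return float(mean), float(a1), float(a2)


def dhaka_like_config(
    start_date: dt.date | str = dt.date(2014, 1, 1),
    end_date: dt.date | str = dt.date(2023, 12, 31),
    seed: int = 0,
) -> SyntheticConfig:
    """Calibrated preset emulating the 2014–2023 Dhaka station record.

    A synthetic stand-in, not real data.  The annual cycle peaks in
    mid-July and carries a flattening overtone; its mean and the two
    harmonic amplitudes are solved from the target seasonal means (summer
    29.5 °C, winter 20.7 °C) plus an April anchor of 28.0 °C that
    reproduces the monsoon-climate plateau in which the hot season extends
    from April through October while winter stays short and sharp.
    Humidity carries a monsoon harmonic and a strong negative diurnal
    coupling sized so the overall T–RH correlation is ≈ −0.36 despite hot
    months being humid.  Diurnal amplitude, AR parameters and noise SDs are
    set to typical magnitudes for a tropical synoptic record.
    """
    peak_doy = 197.0  # mid-July, centre of the Jun–Aug hot season
    mean_temp, annual_amplitude, annual_amplitude2 = solve_seasonal_cycle(
        29.5, 20.7, peak_doy, april_mean=28.4,
        start=_as_date(start_date), end=_as_date(end_date),
    )
    return SyntheticConfig(
        start_date=_as_date(start_date),
        end_date=_as_date(end_date),
        mean_temp=mean_temp,
        annual_amplitude=annual_amplitude,
        diurnal_amplitude=3.2,
        ar_coefficient=0.75,
        noise_sd=1.2,
        rh_baseline=81.0,
        rh_coupling=-5.2,
        rh_noise_sd=5.5,
        seed=seed,
        annual_peak_doy=peak_doy,
        annual_amplitude2=annual_amplitude2,
        diurnal_peak_hour=12.0,
        rh_annual_amplitude=7.0,
        rh_peak_doy=197.0,
    )


# ---------------------------------------------------------------------------
# Wide fixture dialect
# ---------------------------------------------------------------------------

_HOUR_LABELS = tuple(f"{h:02d}" for h in SYNOPTIC_HOURS)


def _to_wide(values: pd.Series) -> pd.DataFrame:
    idx = values.index
    frame = pd.DataFrame(
        {
            "Year": idx.year,
            "Month": idx.month,
            "Day": idx.day,
            "hour": [f"{h:02d}" for h in idx.hour],
            "value": values.to_numpy(),
        }
    )
    wide = frame.pivot_table(
        index=["Year", "Month", "Day"], columns="hour", values="value", sort=False
    ).reset_index()
    wide.columns.name = None
    return wide[["Year", "Month", "Day", *_HOUR_LABELS]]


def _write_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table.to_excel(path, index=False)
    else:
        table.to_csv(path, index=False)


def write_wide_fixtures(series: pd.DataFrame, temp_path, rh_path) -> None:
    """Write a climate series as two wide tables (CSV or XLSX by suffix).

    Each file has Year/Month/Day key columns followed by one value column per
    synoptic hour; the round trip through the ingest reader is lossless.
    """
    if len(series) == 0:
        raise ValueError("cannot write fixtures for an empty series")
    _write_table(_to_wide(series["temperature_c"]), temp_path)
    _write_table(_to_wide(series["relative_humidity_pct"]), rh_path)


def series_to_long_tables(series: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decompose a climate series into raw long (year, month, day, hour, value)
    tables, one for temperature and one for humidity."""
    idx = series.index
    keys = {
        "year": idx.year,
        "month": idx.month,
        "day": idx.day,
        "hour": idx.hour,
    }
    temp = pd.DataFrame({**keys, "value": series["temperature_c"].to_numpy()})
    rh = pd.DataFrame({**keys, "value": series["relative_humidity_pct"].to_numpy()})
    return temp, rh


def inject_defects(
    series: pd.DataFrame, kind: str, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return raw long tables with a named defect in the temperature table.

    Supported kinds: ``missing_row`` (one record deleted), ``duplicate_key``
    (one record repeated), ``invalid_date`` (one record moved to an
    impossible calendar date, e.g. February 30).  The defect position is
    seeded.  The humidity table is returned unmodified.
    """
    if len(series) == 0:
        raise ValueError("cannot inject defects into an empty series")
    temp, rh = series_to_long_tables(series)
    rng = np.random.default_rng(seed)
    pos = int(rng.integers(0, len(temp)))
    if kind == "missing_row":
        temp = temp.drop(index=pos).reset_index(drop=True)
    elif kind == "duplicate_key":
        temp = pd.concat([temp, temp.iloc[[pos]]], ignore_index=True)
    elif kind == "invalid_date":
        row = temp.iloc[pos].copy()
        year, month = int(row["year"]), int(row["month"])
        last_valid = calendar.monthrange(year, month)[1]
        if last_valid == 31:  # pick a month that can host an impossible day
            month = 2
        temp.loc[pos, "month"] = month
        temp.loc[pos, "day"] = calendar.monthrange(year, month)[1] + 1
    else:
        raise ValueError(f"unknown defect kind: {kind!r}")
    return temp, rh
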