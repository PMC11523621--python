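"""Hourly temperature series: interpolation, chamber schedules and chilling accounting.

Daily weather is a :class:`pandas.DataFrame` with columns ``date`` (ISO
dates), ``tmean``, ``tmax``, ``tmin`` in deg C.  Hourly series are
:class:`pandas.Series` of temperature (deg C) indexed by an hourly
:class:`pandas.DatetimeIndex` with 24 entries per covered day.

Chilling is counted on hours at or below an upper threshold (10 deg C by
default); the onset of chilling accumulation in autumn is the first day of
the first run of days whose daily *mean* is strictly below that threshold.
The strict/inclusive asymmetry between the two rules is deliberate and kept
as such throughout the package.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Union

import numpy as np
import pandas as pd

DateLike = Union[str, dt.date, dt.datetime, pd.Timestamp]

#: upper temperature threshold (deg C) below which chilling is effective
CHILL_THRESHOLD_C = 10.0

#: base temperature (deg C) for growing-degree-hour accumulation
BASE_TEMP_C = 5.0


@dataclasses.dataclass(frozen=True)
class ChamberRegime:
    """A periodic growth-chamber temperature schedule.

    Each 24-hour day consists of ``warm_hours`` at ``warm_temp_c`` followed
    by ``cool_hours`` at ``cool_temp_c``.  ``base_temp_c`` is the threshold
    for bud development used when accumulating growing degree hours.

    The default mirrors a common twig-forcing protocol: 25 deg C for 14 h
    (light) and 15 deg C for 10 h (dark), with a 5 deg C base.
    """

    warm_temp_c: float = 25.0
    warm_hours: int = 14
    cool_temp_c: float = 15.0
    cool_hours: int = 10
    base_temp_c: float = BASE_TEMP_C

    def __post_init__(self) -> None:
        if self.warm_hours + self.cool_hours != 24:
            raise ValueError(
                "chamber schedule must cover 24 h/day, got "
                f"{self.warm_hours} + {self.cool_hours}"
            )
        if self.warm_hours < 0 or self.cool_hours < 0:
            raise ValueError("block lengths must be non-negative")

    def daily_block(self) -> np.ndarray:
        """The 24 hourly temperatures of one chamber day."""
        return np.concatenate(
            [
                np.full(self.warm_hours, float(self.warm_temp_c)),
                np.full(self.cool_hours, float(self.cool_temp_c)),
            ]
        )


def _as_date(d: DateLike) -> pd.Timestamp:
    return pd.Timestamp(d).normalize()


def _check_daily(daily: pd.DataFrame) -> pd.DataFrame:
    required = {"date", "tmean", "tmax", "tmin"}
    missing = required - set(daily.columns)
    if missing:
        raise ValueError(f"daily weather missing columns: {sorted(missing)}")
    out = daily.copy().reset_index(drop=True)
    out["date"] = pd.to_datetime(out["date"]).dt.normalize()
    if len(out) == 0:
        raise ValueError("empty daily weather series")
    deltas = out["date"].diff().dropna()
    if (deltas <= pd.Timedelta(0)).any():
        raise ValueError("daily dates must be strictly increasing")
    gaps = deltas[deltas > pd.Timedelta(days=1)]
    if len(gaps):
        first_missing = out["date"].iloc[gaps.index[0] - 1] + pd.Timedelta(days=1)
        raise ValueError(f"gap in daily weather: missing {first_missing.date()}")
    bad = (out["tmin"] > out["tmean"]) | (out["tmean"] > out["tmax"])
    if bad.any():
        raise ValueError(
            f"tmin <= tmean <= tmax violated on {out.loc[bad, 'date'].iloc[0].date()}"
        )
    return out


def hourly_from_daily(daily: pd.DataFrame, h_min: int = 6) -> pd.Series:
    """Interpolate daily min/max temperatures to an hourly series.

    A single-harmonic diurnal cycle is used::

        T(h) = (tmax + tmin)/2 - (tmax - tmin)/2 * cos(2*pi*(h - h_min)/24)

    with the daily minimum at hour ``h_min`` (06:00 by default) and the
    maximum 12 h later.  Each day's 24 values are bounded by that day's
    [tmin, tmax] and attain both bounds.

    Parameters
    ----------
    daily:
        Contiguous daily records (columns ``date, tmean, tmax, tmin``).
    h_min:
        Hour of day (0-23) at which the minimum occurs.

    Returns
    -------
    pandas.Series
        Hourly temperature indexed by timestamp, 24 entries per day.
    """
    daily = _check_daily(daily)
    hours = np.arange(24)
    phase = -np.cos(2.0 * np.pi * (hours - h_min) / 24.0)  # -1 at h_min, +1 opposite
    mid = (daily["tmax"].to_numpy() + daily["tmin"].to_numpy()) / 2.0
    amp = (daily["tmax"].to_numpy() - daily["tmin"].to_numpy()) / 2.0
    temps = mid[:, None] + amp[:, None] * phase[None, :]
    stamps = (
        daily["date"].to_numpy()[:, None]
        + pd.to_timedelta(hours, unit="h").to_numpy()[None, :]
    ).ravel()
    return pd.Series(temps.ravel(), index=pd.DatetimeIndex(stamps), name="temp_c")


def chamber_series(regime: ChamberRegime, n_days: int, start: DateLike = "2000-01-01") -> pd.Series:
    """Realize a chamber schedule as an hourly temperature series.

    Parameters
    ----------
    regime:
        The periodic daily schedule.
    n_days:
        Number of repeated days (>= 1).
    start:
        Timestamp of the first hour (defaults to an arbitrary date; only the
        temperatures matter downstream).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    block = regime.daily_block()
    temps = np.tile(block, n_days)
    index = pd.date_range(_as_date(start), periods=24 * n_days, freq="h")
    return pd.Series(temps, index=index, name="temp_c")


def chilling_start_date(
    daily: pd.DataFrame,
    threshold: float = CHILL_THRESHOLD_C,
    run_length: int = 3,
) -> pd.Timestamp:
    """First day of the earliest run of cold days: chilling onset in autumn.

    Scans the daily means for the first run of ``run_length`` consecutive
    days with ``tmean`` strictly below ``threshold`` and returns the run's
    first day.

    Raises
    ------
    ValueError
        If no qualifying run exists in the series.
    """
    daily = _check_daily(daily)
    cold = (daily["tmean"].to_numpy() < threshold).astype(int)
    if len(cold) >= run_length:
        window = np.convolve(cold, np.ones(run_length, dtype=int), mode="valid")
        hits = np.nonzero(window == run_length)[0]
        if len(hits):
            return daily["date"].iloc[hits[0]]
    raise ValueError("no chilling onset found")


def _slice_hours(hourly: pd.Series, start: DateLike, end: DateLike) -> pd.Series:
    """Hours from start-date 00:00 through end-date 23:00, inclusive."""
    start_ts = _as_date(start)
    end_ts = _as_date(end) + pd.Timedelta(hours=23)
    if start_ts > end_ts:
        raise ValueError("start must not be after end")
    if start_ts < hourly.index[0] or end_ts > hourly.index[-1]:
        raise ValueError(
            f"window [{start_ts.date()}, {_as_date(end).date()}] outside series coverage"
        )
    return hourly.loc[start_ts:end_ts]


def chilling_hours_outside(
    hourly: pd.Series,
    start: DateLike,
    end: DateLike,
    threshold: float = CHILL_THRESHOLD_C,
) -> int:
    """Count hours at or below the chilling threshold in [start, end].

    Both end dates are inclusive (the window runs from ``start`` 00:00
    through ``end`` 23:00).  This is the outside chilling-hour total CH_O
    accrued between the chilling onset and a sampling date.
    """
    window = _slice_hours(hourly, start, end)
    return int((window.to_numpy() <= threshold).sum())


def forcing_outside(
    hourly: pd.Series,
    sampling_date: DateLike,
    season_jan1: DateLike,
    base_temp_c: float = BASE_TEMP_C,
) -> float:
    """Thermal time (deg C h) accrued outdoors between 1 January and sampling.

    Returns ``sum(max(T(t) - base, 0))`` over whole days from ``season_jan1``
    up to, but not including, ``sampling_date``; exactly 0 when the sampling
    date falls on or before 1 January.  This is the correction (Delta FR)
    subtracted from a twig's forcing requirement when it was sampled after
    forcing had already begun outdoors.
    """
    t_s = _as_date(sampling_date)
    t_1 = _as_date(season_jan1)
    if t_s <= t_1:
        return 0.0
    window = _slice_hours(hourly, t_1, t_s - pd.Timedelta(days=1))
    return float(np.maximum(window.to_numpy() - base_temp_c, 0.0).sum())


def read_daily_weather(path) -> pd.DataFrame:
    """Read a daily weather CSV (columns date, tmean, tmax, tmin)."""
    return _check_daily(pd.read_csv(path))


def write_hourly_series(hourly: pd.Series, path) -> None:
    """Write an hourly series as a two-column CSV (timestamp, temp_c)."""
    hourly.rename("temp_c").rename_axis("timestamp").to_csv(path)
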