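"""Synthetic twig experiments and weather with the assumed statistical structure.

The generator is the forward model of the analysis: a species is defined
by true curve parameters (a, b), a true normalized chilling function with
its scale k, and an additive Gaussian FR noise level.  An experiment
exposes twigs to a design of refrigerator temperatures and durations on
top of the outside chilling already received before collection, draws

    FR = a + b * exp(-c(T)/k * x) + noise,      x = CH_R + CH_O,

and converts FR to budburst dates through the chamber regime.  Weather is
a sinusoidal annual cycle with day-to-day noise and a fixed diurnal range,
emulating a continental temperate seasonal course (Beijing-like: annual
mean near 12 deg C, amplitude near 15 deg C, winter means below zero and
daily means dropping below 10 deg C in early November).

All randomness flows from explicit seeds; identical seeds give identical
tables.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from chillcurve.weather import ChamberRegime, DateLike, _as_date
from chillcurve.forcing import daily_gdh
from chillcurve.chilling_function import (
    ReferenceChillingFunction,
    TriangularChillingFunction,
)

#: default second-year-style design: five refrigerator temperatures ...
DEFAULT_TEMPS_C = (-10.0, -5.0, 0.0, 5.0, 10.0)
#: ... crossed with durations of 0-12 weeks
DEFAULT_DURATIONS_D = (0, 14, 28, 56, 84)

#: default outside chilling (h) accrued between autumn onset and collection
DEFAULT_CH_O_HOURS = 367.0

#: twigs not reaching budburst within this many chamber days are censored
CENSOR_DAYS = 90


def _triangle(t_op: float, c_low: float, c_high: float, k: float,
              t_low: float = -10.0, t_upper: float = 10.0) -> TriangularChillingFunction:
    """True triangular function through (t_low, c_low), apex 1, (t_upper, c_high)."""
    m1 = (1.0 - c_low) / (t_op - t_low)
    m2 = (c_high - 1.0) / (t_upper - t_op)
    return TriangularChillingFunction(
        m1=m1, n1=1.0 - m1 * t_op, m2=m2, n2=1.0 - m2 * t_op,
        t_op=t_op, t_upper=t_upper, k=k,
    )


@dataclasses.dataclass(frozen=True)
class SyntheticSpeciesSpec:
    """Ground-truth parameters of one simulated species.

    ``chilling_fn`` (with its scale ``k``) fixes the true decay rates via
    ``c0(T) = c(T)/k``; ``fr_noise_sd`` is additive Gaussian noise on the
    FR scale (deg C h) and ``log_noise_sd`` an optional multiplicative
    noise on the exponential term (used for type-I-error studies of the
    log-scale slope test).  Twigs whose noisy FR exceeds
    ``censor_days * daily_gdh`` are censored.
    """

    name: str
    a: float
    b: float
    chilling_fn: object
    fr_noise_sd: float = 300.0
    log_noise_sd: float = 0.0
    censor_days: float = CENSOR_DAYS

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if self.fr_noise_sd < 0 or self.log_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if getattr(self.chilling_fn, "k", None) in (None, 0):
            raise ValueError("chilling_fn must carry a positive scale k")

    def decay_rate(self, temp: float) -> float:
        """True c0 (per hour) at a chilling temperature."""
        return float(self.chilling_fn(temp)) / self.chilling_fn.k

    def true_fr(self, temp: float, x_hours) -> np.ndarray:
        """Noise-free FR after ``x_hours`` of chilling at ``temp``."""
        x = np.asarray(x_hours, float)
        return self.a + self.b * np.exp(-self.decay_rate(temp) * x)


def _consistent_params(
    c_min_ratio: float,
    b: float,
    x_min: float = DEFAULT_CH_O_HOURS,
    x_max: float = 24.0 * max(DEFAULT_DURATIONS_D) + DEFAULT_CH_O_HOURS,
) -> tuple[float, float]:
    """Solve (a, max c0) so the preset a/b rule is exact for the design.

    The curve-fitting stage presets ``a = 0.95 min(FR)`` and ``b = 1.1
    max(FR) - a`` from the pooled design points.  For the generating
    parameters to be recoverable, the truth must satisfy the same
    identities: with the fastest decay rate ``c0_max`` (attained at the
    apex temperature) and the slowest ``c0_min = c_min_ratio * c0_max``,
    the noise-free design extremes are ``min FR = a + b*exp(-c0_max *
    x_max)`` and ``max FR = a + b*exp(-c0_min * x_min)``, which reduce the
    two preset identities to::

        1.9*exp(-c0_max*x_max) + 1.1*exp(-c_min_ratio*c0_max*x_min) = 1
        a = 19 * b * exp(-c0_max*x_max)

    The first equation is monotone in ``c0_max`` and solved by bracketing.
    """
    from scipy.optimize import brentq

    def gap(c0_max: float) -> float:
        return (
            1.9 * np.exp(-c0_max * x_max)
            + 1.1 * np.exp(-c_min_ratio * c0_max * x_min)
            - 1.0
        )

    c0_max = float(brentq(gap, 1e-6, 1e-1, xtol=1e-14))
    a = 19.0 * b * np.exp(-c0_max * x_max)
    return a, c0_max


def default_species() -> list[SyntheticSpeciesSpec]:
    """Nine simulated temperate woody species.

    Early-season shrubs carry low forcing-requirement spans, late-season
    trees high ones; true apex temperatures sit at 0 or 5 deg C (within
    the tested grid) and one species departs from the rest with freezing
    temperatures markedly less effective.  Per species, the asymptote and
    the peak decay rate are derived from the preset-rule consistency
    conditions (see :func:`_consistent_params`) so that the generating
    parameters are exactly recoverable from noise-free data under the
    default design; peak rates come out at order 1e-3 per hour.
    """
    specs = []
    table = [
        # name, b, t_op, c(-10), c(10)
        ("sp01", 9000.0, 0.0, 0.35, 0.30),
        ("sp02", 11000.0, 0.0, 0.40, 0.25),
        ("sp03", 16000.0, 5.0, 0.30, 0.45),
        ("sp04", 8000.0, 0.0, 0.45, 0.35),
        ("sp05", 18000.0, 5.0, 0.28, 0.50),
        ("sp06", 12000.0, 0.0, 0.38, 0.30),
        ("sp07", 20000.0, 5.0, 0.25, 0.35),
        ("sp08", 10000.0, 5.0, 0.40, 0.42),
        # the odd one out: freezing temperatures much less effective
        ("sp09", 15000.0, 5.0, 0.10, 0.45),
    ]
    for name, b, t_op, c_low, c_high in table:
        a, c0_max = _consistent_params(min(c_low, c_high), b)
        fn = _triangle(t_op, c_low, c_high, k=1.0 / c0_max)
        specs.append(SyntheticSpeciesSpec(name=name, a=a, b=b, chilling_fn=fn))
    return specs


@dataclasses.dataclass(frozen=True)
class SyntheticWeatherSpec:
    """Sinusoidal annual temperature cycle with noise and diurnal range.

    Daily means follow ``annual_mean - amplitude * cos(2*pi*(doy -
    coldest_doy)/365.25)`` plus iid Gaussian noise; max/min are the mean
    plus/minus half the diurnal range.  Defaults emulate a Beijing-like
    continental temperate climate over one dormant season.
    """

    annual_mean_c: float = 12.0
    amplitude_c: float = 15.0
    diurnal_range_c: float = 8.0
    noise_sd_c: float = 2.0
    coldest_doy: int = 20
    start: DateLike = "2021-09-01"
    end: DateLike = "2022-06-30"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_c < 0 or self.noise_sd_c < 0 or self.diurnal_range_c < 0:
            raise ValueError("amplitude, noise sd and diurnal range must be >= 0")


def generate_weather(spec: SyntheticWeatherSpec) -> pd.DataFrame:
    """Daily weather table (date, tmean, tmax, tmin) from a weather spec.

    Raises
    ------
    ValueError
        If the generated series never sustains three consecutive days below
        10 deg C (no chilling onset would exist downstream).
    """
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(_as_date(spec.start), _as_date(spec.end), freq="D")
    doy = dates.dayofyear.to_numpy(float)
    cycle = spec.annual_mean_c - spec.amplitude_c * np.cos(
        2.0 * np.pi * (doy - spec.coldest_doy) / 365.25
    )
    tmean = cycle + rng.normal(0.0, spec.noise_sd_c, size=len(dates))
    half = spec.diurnal_range_c / 2.0
    daily = pd.DataFrame(
        {"date": dates, "tmean": tmean, "tmax": tmean + half, "tmin": tmean - half}
    )
    cold = (daily["tmean"].to_numpy() < 10.0).astype(int)
    runs = np.convolve(cold, np.ones(3, dtype=int), mode="valid") if len(cold) >= 3 else []
    if not np.any(np.asarray(runs) == 3):
        raise ValueError("weather spec admits no chilling onset (no sub-10 deg C run)")
    return daily


def generate_experiment(
    spec: SyntheticSpeciesSpec,
    temps_c: Sequence[float] = DEFAULT_TEMPS_C,
    durations_d: Sequence[float] = DEFAULT_DURATIONS_D,
    seed: int = 0,
    regime: Optional[ChamberRegime] = None,
    collection_date: DateLike = "2021-11-22",
    ch_o_hours: float = DEFAULT_CH_O_HOURS,
) -> pd.DataFrame:
    """Simulate one species' chilling-by-duration twig experiment.

    One row per design cell (refrigerator temperature x duration, the
    zero-duration cell carrying only the outside chilling).  FR is drawn
    from the exponential forward model at total chilling ``x = 24 *
    duration + ch_o_hours`` with additive Gaussian noise, then converted
    to a budburst timestamp via the chamber regime; cells exceeding the
    censoring horizon get an empty budburst date.

    Columns match the experiment-CSV dialect consumed by the fitting
    pipeline: species, year, chill_temp_c, chill_days_refrigerator,
    sampling_date, budburst_date, fr_true_gdh.
    """
    regime = regime or ChamberRegime()
    rng = np.random.default_rng(seed)
    t_collect = _as_date(collection_date)
    per_day = daily_gdh(regime)
    rows = []
    for dur in durations_d:
        for temp in temps_c:
            x = 24.0 * dur + ch_o_hours
            c0 = spec.decay_rate(temp)
            fr_true = spec.a + spec.b * np.exp(-c0 * x)
            fr = fr_true
            if spec.log_noise_sd > 0:
                fr = spec.a + (fr_true - spec.a) * np.exp(
                    rng.normal(0.0, spec.log_noise_sd)
                )
            if spec.fr_noise_sd > 0:
                fr = fr + rng.normal(0.0, spec.fr_noise_sd)
            fr = max(fr, 1.0)
            days = fr / per_day
            entry = t_collect + pd.Timedelta(days=float(dur))
            censored = days > spec.censor_days
            rows.append(
                {
                    "species": spec.name,
                    "year": t_collect.year,
                    "chill_temp_c": float(temp),
                    "chill_days_refrigerator": float(dur),
                    "sampling_date": t_collect.date().isoformat(),
                    "budburst_date": ""
                    if censored
                    else (entry + pd.Timedelta(days=days)).isoformat(),
                    "fr_true_gdh": fr_true,
                }
            )
    return pd.DataFrame(rows)


def treatment_points(
    experiment: pd.DataFrame,
    regime: Optional[ChamberRegime] = None,
    ch_o_hours: float = DEFAULT_CH_O_HOURS,
) -> pd.DataFrame:
    """Build the curve-fitting table (chill_temp_c, chill_hours, fr_gdh).

    Recovers FR from the recorded dates (chamber days times per-day GDH,
    entry to the chamber being the sampling date plus refrigerator days)
    and totals chilling as refrigerator plus outside hours.  Censored
    cells (empty budburst date) get NaN FR; rows without a refrigerator
    temperature (no-extra-chilling controls) are dropped.
    """
    regime = regime or ChamberRegime()
    exp = experiment.dropna(subset=["chill_temp_c"]).copy()
    t_s = pd.to_datetime(exp["sampling_date"])
    entry = t_s + pd.to_timedelta(exp["chill_days_refrigerator"], unit="D")
    t_f = pd.to_datetime(exp["budburst_date"], errors="coerce", format="ISO8601")
    days = (t_f - entry) / pd.Timedelta(days=1)
    return pd.DataFrame(
        {
            "species": exp["species"].to_numpy(),
            "chill_temp_c": exp["chill_temp_c"].astype(float).to_numpy(),
            "chill_hours": 24.0 * exp["chill_days_refrigerator"].to_numpy(float)
            + ch_o_hours,
            "fr_gdh": (days * daily_gdh(regime)).to_numpy(),
        }
    )
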