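"""Process-based budburst model: chilling accumulation to budburst prediction.

Chilling accumulation (CA) is the integral of the chilling function over
the hourly temperature series; the forcing requirement then follows the
negative exponential FR = a + b * exp(-CA/k).  In the chamber, predicted
FR converts to days to budburst by dividing by the per-day chamber GDH
total (after subtracting forcing already accrued outdoors after 1
January); in the field, the budburst date is the first day on which the
thermal time accumulated since 1 January reaches the current FR, examined
on a daily basis while CA keeps accruing.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from chillcurve.weather import (
    BASE_TEMP_C,
    ChamberRegime,
    DateLike,
    _as_date,
    _slice_hours,
    chilling_start_date,
    forcing_outside,
    hourly_from_daily,
)
from chillcurve.forcing import daily_gdh

#: default AICc parameter counts: (a, b, k) for the reference model,
#: plus (t_op, m1, m2) for the triangular model
N_PARAMS_REFERENCE = 3
N_PARAMS_TRIANGULAR = 6


def accumulate_ca(
    fn,
    hourly: pd.Series,
    t_start: Optional[DateLike] = None,
    t_end: Optional[DateLike] = None,
) -> float:
    """Chilling accumulation ``CA = sum(c(T(t)))`` over an hourly window.

    With ``t_start``/``t_end`` given, every hour from the first hour of
    ``t_start`` to the last hour of ``t_end`` counts (both dates
    inclusive); with both omitted the whole series counts.  For a
    constant-temperature series this reduces to ``c(T) * hours``.
    """
    if t_start is None and t_end is None:
        window = hourly
    else:
        window = _slice_hours(hourly, t_start, t_end)
    return float(np.asarray(fn(window.to_numpy())).sum())


@dataclasses.dataclass(frozen=True)
class PhenoModel:
    """Budburst model with parameters a, b (deg C h), k and a chilling function.

    ``chilling_fn`` is a triangular or reference function; ``k`` defaults
    to the function's own scale.  The chamber regime supplies the per-day
    GDH for converting FR to chamber days; ``onset_threshold_c`` and
    ``onset_run_days`` parameterize the autumn chilling-onset rule.
    """

    a: float
    b: float
    chilling_fn: object
    k: Optional[float] = None
    regime: ChamberRegime = ChamberRegime()
    onset_threshold_c: float = 10.0
    onset_run_days: int = 3
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if self.k is None:
            object.__setattr__(self, "k", getattr(self.chilling_fn, "k", None))
        if self.k is None or self.k <= 0:
            raise ValueError("model requires a positive scale k")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")

    def predicted_fr(self, ca) -> np.ndarray:
        """FR (deg C h) after chilling accumulation ``ca``: a + b*exp(-ca/k)."""
        ca = np.asarray(ca, float)
        if np.any(ca < 0):
            raise ValueError("chilling accumulation must be non-negative")
        return self.a + self.b * np.exp(-ca / self.k)

    def predict_days_to_budburst(
        self,
        chill_temp_c: Optional[float] = None,
        fridge_hours: float = 0.0,
        ca_outside: float = 0.0,
        delta_fr: float = 0.0,
    ) -> float:
        """Predicted chamber days to budburst for one experiment cell.

        CA is the refrigerator contribution ``c(T) * fridge_hours``
        (constant temperature) plus any ``ca_outside`` accumulated over the
        outdoor hourly series; ``delta_fr`` is forcing accrued outdoors
        after 1 January.  The result ``(FR - delta_fr) / daily_gdh`` is
        continuous and floored at zero (budburst due before forcing began).
        """
        ca = float(ca_outside)
        if chill_temp_c is not None:
            ca += float(self.chilling_fn(chill_temp_c)) * fridge_hours
        fr = float(self.predicted_fr(ca))
        per_day = daily_gdh(self.regime)
        if per_day == 0:
            raise ValueError("no forcing in chamber (daily GDH is zero)")
        return max((fr - delta_fr) / per_day, 0.0)

    def predict_cell(
        self,
        hourly: pd.Series,
        onset: DateLike,
        sampling_date: DateLike,
        chill_temp_c: Optional[float] = None,
        fridge_days: float = 0.0,
        season_jan1: Optional[DateLike] = None,
    ) -> float:
        """Predicted chamber days for a cell described by dates and weather.

        Outside CA accrues over [onset, sampling_date]; refrigerator CA is
        added at the set temperature; Delta FR is the outdoor forcing
        between 1 January (of the season's spring, inferred from the onset
        date unless given) and the sampling date.
        """
        onset = _as_date(onset)
        t_s = _as_date(sampling_date)
        if season_jan1 is None:
            season_jan1 = pd.Timestamp(year=onset.year + (1 if onset.month >= 7 else 0),
                                       month=1, day=1)
        ca_outside = accumulate_ca(self.chilling_fn, hourly, onset, t_s)
        delta_fr = forcing_outside(hourly, t_s, season_jan1,
                                   base_temp_c=self.regime.base_temp_c)
        return self.predict_days_to_budburst(
            chill_temp_c=chill_temp_c,
            fridge_hours=24.0 * fridge_days,
            ca_outside=ca_outside,
            delta_fr=delta_fr,
        )

    def predict_budburst_date(self, daily: pd.DataFrame) -> Optional[int]:
        """Predicted budburst day of year for one season of daily weather.

        Chilling starts at the autumn onset (first run of
        ``onset_run_days`` days with mean below ``onset_threshold_c``) and
        CA accrues daily thereafter, overlapping the forcing window.
        Forcing (GDH above the chamber base temperature) accumulates from
        1 January; the predicted budburst date is the first day whose
        cumulative forcing reaches that day's FR = a + b*exp(-CA/k).

        Returns None (censored) when forcing never catches up with FR
        before the series ends.
        """
        onset = chilling_start_date(
            daily, threshold=self.onset_threshold_c, run_length=self.onset_run_days
        )
        hourly = hourly_from_daily(daily)
        jan1 = pd.Timestamp(year=onset.year + (1 if onset.month >= 7 else 0),
                            month=1, day=1)

        temps = hourly.to_numpy()
        days = hourly.index.normalize()
        chill_daily = pd.Series(np.asarray(self.chilling_fn(temps)), index=days).groupby(level=0).sum()
        gdh_daily = pd.Series(
            np.maximum(temps - self.regime.base_temp_c, 0.0), index=days
        ).groupby(level=0).sum()

        span = chill_daily.index[(chill_daily.index >= jan1)]
        if len(span) == 0:
            return None
        ca_to_date = chill_daily.loc[onset:].cumsum().loc[span]
        fr_to_date = self.a + self.b * np.exp(-ca_to_date.to_numpy() / self.k)
        gdh_to_date = gdh_daily.loc[jan1:].cumsum().loc[span].to_numpy()
        reached = np.nonzero(gdh_to_date >= fr_to_date)[0]
        if len(reached) == 0:
            return None
        return int(span[reached[0]].dayofyear)


@dataclasses.dataclass(frozen=True)
class ValidationMetrics:
    """Goodness of fit between predicted and observed budburst timing."""

    r2: float
    rmse: float
    aicc: float  # NaN when n <= p + 1
    n: int
    n_params: int


def validate(observed, predicted, n_params: int) -> ValidationMetrics:
    """R-squared, RMSE and small-sample-corrected AIC of paired predictions.

    ``R2 = 1 - SSE/SST``; ``RMSE = sqrt(SSE/n)``;
    ``AICc = n*ln(SSE/n) + 2p + 2p(p+1)/(n-p-1)`` (Gaussian likelihood
    surrogate).  AICc is reported as NaN when ``n <= n_params + 1``.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have matching shapes")
    n = obs.size
    if n < 2:
        raise ValueError("need >= 2 paired values")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    rmse = float(np.sqrt(sse / n))
    p = n_params
    if n > p + 1:
        with np.errstate(divide="ignore"):
            aicc = n * np.log(sse / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)
    else:
        aicc = np.nan
    return ValidationMetrics(r2=r2, rmse=rmse, aicc=float(aicc), n=n, n_params=p)
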