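"""Growing-degree-hour forcing requirements in the growth chamber.

The forcing requirement (FR) of a twig is the total thermal time, in
growing degree hours (GDH, deg C h above a base temperature), accumulated
in the chamber between the sampling date and the budburst date.  Because
the chamber schedule is periodic, FR for whole days equals the number of
days times the per-day GDH total, and FR converts back to chamber days by
simple division.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Optional, Union

import numpy as np
import pandas as pd

from chillcurve.weather import ChamberRegime, DateLike, _as_date


@dataclasses.dataclass(frozen=True)
class ForcingOutcome:
    """Observed chamber response of one treatment cell.

    ``budburst_date`` is the mean over replicate twigs and may therefore be
    fractional; ``fr_gdh`` is None for censored treatments (no twig reached
    budburst within the observation window).
    """

    species: str
    sampling_date: pd.Timestamp
    budburst_days: Optional[float]  # mean days to budburst, None if censored
    fr_gdh: Optional[float]
    n_replicates: int = 5

    @property
    def censored(self) -> bool:
        return self.fr_gdh is None


def daily_gdh(regime: ChamberRegime) -> float:
    """Thermal time (deg C h) accumulated in the chamber per day.

    ``warm_hours * max(warm - base, 0) + cool_hours * max(cool - base, 0)``.
    The standard regime (25 deg C x 14 h, 15 deg C x 10 h, base 5 deg C)
    yields 380 deg C h per day.
    """
    warm = max(regime.warm_temp_c - regime.base_temp_c, 0.0)
    cool = max(regime.cool_temp_c - regime.base_temp_c, 0.0)
    return regime.warm_hours * warm + regime.cool_hours * cool


def _elapsed_days(t_s, t_f) -> float:
    """Elapsed chamber days between sampling and budburst (may be fractional)."""
    if isinstance(t_s, (int, float)) and isinstance(t_f, (int, float)):
        return float(t_f) - float(t_s)
    delta = pd.Timestamp(t_f) - pd.Timestamp(t_s)
    return delta / pd.Timedelta(days=1)


def forcing_requirement(
    regime: ChamberRegime,
    t_s: Union[DateLike, float],
    t_f: Union[DateLike, float],
) -> float:
    """Forcing requirement (deg C h) between sampling and budburst.

    GDH is summed hour by hour over the chamber schedule for whole elapsed
    days; a trailing fractional day (which arises when the budburst date is
    a mean over replicate twigs) contributes its fraction of the per-day
    total, keeping FR continuous in time.

    ``t_s`` and ``t_f`` may be dates/timestamps or plain day numbers.
    """
    elapsed = _elapsed_days(t_s, t_f)
    if elapsed < 0:
        raise ValueError(f"budburst date precedes sampling date ({elapsed:g} d)")
    whole = math.floor(elapsed)
    frac = elapsed - whole
    block_gdh = np.maximum(regime.daily_block() - regime.base_temp_c, 0.0)
    return float(whole * block_gdh.sum() + frac * block_gdh.sum())


def fr_to_days(fr: float, regime: ChamberRegime, delta_fr: float = 0.0) -> float:
    """Convert a forcing requirement to (continuous) chamber days.

    ``(fr - delta_fr) / daily_gdh(regime)``.  ``delta_fr`` is forcing already
    accrued outdoors before the twig entered the chamber.
    """
    if delta_fr < 0:
        raise ValueError("delta_fr must be non-negative")
    if fr < delta_fr:
        raise ValueError("fr must be >= delta_fr")
    per_day = daily_gdh(regime)
    if per_day == 0:
        raise ValueError("no forcing in chamber (daily GDH is zero)")
    return (fr - delta_fr) / per_day


def outcomes_from_experiment(
    table: pd.DataFrame, regime: ChamberRegime
) -> pd.DataFrame:
    """Annotate an experiment table with FR and days-to-budburst columns.

    Expects columns ``species, sampling_date, budburst_date`` (empty
    budburst_date = censored).  Adds ``days_to_budburst`` and ``fr_gdh``
    (NaN for censored rows).
    """
    out = table.copy()
    t_s = pd.to_datetime(out["sampling_date"])
    t_f = pd.to_datetime(out["budburst_date"], errors="coerce")
    days = (t_f - t_s) / pd.Timedelta(days=1)
    if (days.dropna() < 0).any():
        raise ValueError("budburst date precedes sampling date in experiment table")
    out["days_to_budburst"] = days
    out["fr_gdh"] = days * daily_gdh(regime)
    return out
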