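"""Exponential dormancy-release curves and the decay-rate contrast test.

For one species, the forcing requirement FR (deg C h) declines with total
chilling duration x (hours) as a negative exponential,

    FR = a + b * exp(-c0(T) * x),

with asymptote ``a`` and span ``b`` shared across chilling temperatures T
and a temperature-specific decay rate ``c0(T)`` (per hour) that measures
the rate of dormancy release at T.  ``a`` and ``b`` are preset from the
pooled FR range (a = 0.95 min FR, b = 1.1 max FR - a) so that every curve
shares the same asymptote and intercept; ``c0`` is then the single free
parameter per temperature, found by least squares.

Whether the rates differ between temperatures is tested on the log scale:
ln(FR - a) is linear in x with slope -c0(T), so an ordinary least-squares
fit of ln(FR - a) on x and the x-by-temperature interaction (temperature
categorical, coldest level as reference) yields per-temperature slope
offsets whose t-tests compare each c0(T) against the reference rate.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

#: upper bound (per hour) for the decay-rate search; generous relative to
#: observed dormancy-release rates (order 1e-4..1e-3 per hour)
C0_MAX = 0.05


@dataclasses.dataclass(frozen=True)
class ExpDecayFit:
    """Per-species exponential FR-vs-chilling fit with shared a and b."""

    a: float
    b: float
    rates: Dict[float, float]  # chilling temperature -> c0 (per hour)
    rmse: Dict[float, float]  # chilling temperature -> RMSE on the FR scale
    species: Optional[str] = None

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(list(self.rmse.values())))

    def predict(self, temp: float, x) -> np.ndarray:
        """FR predicted at chilling temperature ``temp`` after ``x`` hours."""
        return self.a + self.b * np.exp(-self.rates[temp] * np.asarray(x, float))


@dataclasses.dataclass(frozen=True)
class LfmResult:
    """Slope-contrast test of decay rates among chilling temperatures.

    ``reference_rate`` is c0 at the reference (coldest) temperature; the
    ``offsets`` table holds, per non-reference temperature, the rate
    difference c0(T) - c0(ref) with its standard error and p-value.
    Coefficients are reported on the decay-rate scale (the negated
    log-regression slopes), so positive offsets mean faster dormancy
    release than at the reference temperature.
    """

    intercept: float
    reference_temp: float
    reference_rate: float
    offsets: pd.DataFrame  # columns: temp, rate_offset, se, pvalue[, pvalue_holm]


def preset_ab(fr) -> tuple[float, float]:
    """Preset the shared asymptote and span from the pooled FR values.

    ``a = 0.95 * min(FR)``, ``b = 1.1 * max(FR) - a``, with the min/max
    taken over all chilling temperatures of the species.  This guarantees
    ``a`` below every observation, so ln(FR - a) is always defined.
    """
    fr = np.asarray(fr, float)
    fr = fr[~np.isnan(fr)]
    if fr.size == 0:
        raise ValueError("no FR values to preset a, b from")
    a = 0.95 * float(fr.min())
    b = 1.1 * float(fr.max()) - a
    return a, b


def fit_decay_rate(x, fr, a: float, b: float, c0_max: float = C0_MAX) -> tuple[float, float]:
    """Least-squares decay rate at one chilling temperature, a and b fixed.

    Minimizes ``sum((FR - a - b*exp(-c0*x))**2)`` over ``c0`` in
    ``[0, c0_max]`` by bounded scalar minimization (deterministic, no
    random starts; the SSE is smooth in c0 on this interval).

    Returns
    -------
    (c0, rmse):
        The decay rate (per hour) and the root-mean-square residual on the
        FR scale.
    """
    x = np.asarray(x, float)
    fr = np.asarray(fr, float)
    if x.shape != fr.shape:
        raise ValueError("x and fr must have matching shapes")
    if x.size < 2:
        raise ValueError("need >= 2 treatment points to fit a decay rate")

    def sse(c0: float) -> float:
        resid = fr - a - b * np.exp(-c0 * x)
        return float(resid @ resid)

    res = minimize_scalar(sse, bounds=(0.0, c0_max), method="bounded",
                          options={"xatol": 1e-12})
    if not res.success:
        raise RuntimeError(f"decay-rate optimization failed: {res.message}")
    # the bounded minimizer never probes the exact endpoints; snap to 0
    # when the boundary beats the interior solution (no-decay data)
    c0 = float(res.x)
    if sse(0.0) <= res.fun:
        c0 = 0.0
    rmse = float(np.sqrt(sse(c0) / x.size))
    return c0, rmse


def fit_species(points: pd.DataFrame, species: Optional[str] = None) -> ExpDecayFit:
    """Fit the full per-species curve family from a treatment-point table.

    ``points`` needs columns ``chill_temp_c``, ``chill_hours`` and
    ``fr_gdh`` (one row per treatment cell; censored cells, i.e. NaN FR,
    are dropped).  ``a`` and ``b`` are preset from the pooled FR values and
    one decay rate is fitted per chilling temperature.
    """
    pts = points.dropna(subset=["fr_gdh"])
    if len(pts) < 2:
        raise ValueError("need >= 2 uncensored treatment points")
    a, b = preset_ab(pts["fr_gdh"])
    rates: Dict[float, float] = {}
    rmse: Dict[float, float] = {}
    for temp, grp in pts.groupby("chill_temp_c", sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"chilling temperature {temp} has {len(grp)} point(s); need >= 2"
            )
        c0, err = fit_decay_rate(grp["chill_hours"], grp["fr_gdh"], a, b)
        rates[float(temp)] = c0
        rmse[float(temp)] = err
    return ExpDecayFit(a=a, b=b, rates=rates, rmse=rmse, species=species)


def lfm_slope_test(
    points: pd.DataFrame,
    a: float,
    reference_temp: Optional[float] = None,
    holm: bool = False,
) -> LfmResult:
    """Test whether decay rates differ among chilling temperatures.

    Ordinary least-squares fit of ``ln(FR - a) ~ x + x:C(T)`` with
    temperature categorical and the coldest temperature (or
    ``reference_temp``) as reference level.  Each interaction coefficient
    is the difference in log-scale slope between a temperature and the
    reference; a significant offset (t-test, P < 0.05) indicates a decay
    rate distinct from the reference temperature's.

    Set ``holm=True`` to append Holm-adjusted p-values across the
    per-temperature tests (not applied by default).
    """
    pts = points.dropna(subset=["fr_gdh"]).copy()
    temps = np.sort(pts["chill_temp_c"].unique())
    if len(temps) < 2:
        raise ValueError("need >= 2 chilling temperatures for a slope contrast")
    if (pts["fr_gdh"] <= a).any():
        raise ValueError("FR <= a for some point; log transform undefined")
    ref = float(temps[0]) if reference_temp is None else float(reference_temp)
    if ref not in temps:
        raise ValueError(f"reference temperature {ref} not among treatments")

    pts["fr_ln"] = np.log(pts["fr_gdh"] - a)
    pts["x"] = pts["chill_hours"].astype(float)
    pts["temp"] = pd.Categorical(
        pts["chill_temp_c"].astype(float),
        categories=[ref] + [float(t) for t in temps if float(t) != ref],
    )
    fit = smf.ols("fr_ln ~ x + x:temp", data=pts).fit()

    rows = []
    for name in fit.params.index:
        if name.startswith("x:temp"):
            level = float(name.split("[T.")[1].rstrip("]"))
            rows.append(
                {
                    "temp": level,
                    # negate: regression slopes are -c0, offsets reported on
                    # the decay-rate scale
                    "rate_offset": -float(fit.params[name]),
                    "se": float(fit.bse[name]),
                    "pvalue": float(fit.pvalues[name]),
                }
            )
    offsets = pd.DataFrame(rows).sort_values("temp").reset_index(drop=True)
    if holm:
        offsets["pvalue_holm"] = multipletests(offsets["pvalue"], method="holm")[1]
    return LfmResult(
        intercept=float(fit.params["Intercept"]),
        reference_temp=ref,
        reference_rate=-float(fit.params["x"]),
        offsets=offsets,
    )
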