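"""Normalized chilling functions: fitted triangular and flat reference.

The per-temperature decay rates c0(T) of the exponential dormancy-release
curves are normalized to a chilling function c(T) = k * c0(T) in [0, 1],
where k = 1/max(c0) so the most effective temperature scores one chilling
unit per hour.  Two continuous forms are supported:

* a *triangular* piecewise-linear function rising to an apex at T_op and
  falling to the upper threshold (10 deg C by default), fitted to the
  normalized samples by least squares under the apex constraint
  c(T_op) = 1 on both limbs;
* a *reference* function that scores every temperature at or below the
  upper threshold equally (c = 1), with k taken as the reciprocal of the
  mean decay rate.

Both evaluate to chilling units per hour, clipped to [0, 1] and to zero
above the upper threshold.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Optional

import numpy as np

#: default upper temperature threshold (deg C) for effective chilling
T_UPPER_DEFAULT = 10.0


@dataclasses.dataclass(frozen=True)
class TriangularChillingFunction:
    """Piecewise-linear chilling function with apex at ``t_op``.

    ``c(T) = m1*T + n1`` for T <= t_op, ``m2*T + n2`` for t_op < T <=
    t_upper and 0 above; both limbs meet at c(t_op) = 1.  Values are
    clipped to [0, 1] at evaluation.  ``k`` (deg C h per chilling unit,
    1/max c0) converts chilling units back to the decay-rate scale.
    """

    m1: float
    n1: float
    m2: float
    n2: float
    t_op: float
    t_upper: float = T_UPPER_DEFAULT
    k: Optional[float] = None

    def __post_init__(self) -> None:
        for limb in ((self.m1, self.n1), (self.m2, self.n2)):
            apex = limb[0] * self.t_op + limb[1]
            if abs(apex - 1.0) > 1e-8:
                raise ValueError(
                    f"apex constraint violated: limb value at t_op is {apex!r}"
                )

    def __call__(self, temp) -> np.ndarray:
        temp = np.asarray(temp, float)
        left = self.m1 * temp + self.n1
        right = self.m2 * temp + self.n2
        val = np.where(temp <= self.t_op, left, right)
        val = np.where(temp > self.t_upper, 0.0, val)
        return np.clip(val, 0.0, 1.0)


@dataclasses.dataclass(frozen=True)
class ReferenceChillingFunction:
    """Flat chilling function: 1 at or below ``t_upper``, 0 above.

    Encodes the assumption that every temperature below the upper
    threshold releases dormancy at the same rate.  ``k`` is the reciprocal
    of the mean decay rate across the tested temperatures.
    """

    t_upper: float = T_UPPER_DEFAULT
    k: Optional[float] = None

    def __call__(self, temp) -> np.ndarray:
        temp = np.asarray(temp, float)
        return np.where(temp <= self.t_upper, 1.0, 0.0)


def evaluate(fn, temp) -> np.ndarray:
    """Chilling units per hour at temperature(s) ``temp`` for either function."""
    return fn(temp)


def normalize_rates(rates: Dict[float, float]) -> tuple[float, Dict[float, float]]:
    """Normalize decay rates to chilling-unit samples.

    ``k = 1/max(c0)``; ``c(T) = k * c0(T)``, so the maximum sample equals
    1 exactly (ties share the maximum).

    Raises
    ------
    ValueError
        If every rate is zero (no dormancy release detected).
    """
    if not rates:
        raise ValueError("no decay rates given")
    c0_max = max(rates.values())
    if c0_max <= 0:
        raise ValueError("no dormancy release detected (all decay rates zero)")
    k = 1.0 / c0_max
    return k, {t: k * c0 for t, c0 in rates.items()}


def fit_triangular(
    c_samples: Dict[float, float],
    t_upper: float = T_UPPER_DEFAULT,
    k: Optional[float] = None,
    grid_step: float = 0.01,
) -> TriangularChillingFunction:
    """Least-squares triangular fit to normalized chilling-unit samples.

    The apex temperature is profiled on a fine grid (``grid_step`` deg C)
    over the sampled temperature range; at each candidate apex the two limb
    slopes have closed forms under the constraint c(T_op) = 1, so the
    profiled search attains the global least-squares optimum.  Ties prefer
    the lowest apex temperature.  Intercepts follow from the apex
    constraint; clipping to [0, 1] and to zero above ``t_upper`` applies at
    evaluation only, not during fitting.

    Warns (``UserWarning``) when the fitted shape is not a proper triangle
    (non-positive rising slope or non-negative falling slope), including
    the flat-top degenerate case of all samples equal, where the apex is
    placed at the middle sampled temperature.
    """
    if len(c_samples) < 3:
        raise ValueError("need >= 3 sampled temperatures to fit a triangle")
    temps = np.array(sorted(c_samples), float)
    c = np.array([c_samples[t] for t in temps], float)
    resid = c - 1.0

    if np.allclose(resid, 0.0, atol=1e-12):
        t_op = float(temps[len(temps) // 2])
        warnings.warn(
            "all chilling-unit samples equal 1: flat-top degenerate triangle, "
            "apex placed at the middle sampled temperature",
            UserWarning,
        )
        return TriangularChillingFunction(
            m1=0.0, n1=1.0, m2=0.0, n2=1.0, t_op=t_op, t_upper=t_upper, k=k
        )

    lo, hi = temps[0], min(temps[-1], t_upper)
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    def conditional_fit(t_op: float) -> tuple[float, float, float]:
        left = temps <= t_op
        sse = 0.0
        slopes = []
        for mask in (left, ~left):
            d = temps[mask] - t_op
            r = resid[mask]
            denom = float(d @ d)
            m = float(d @ r) / denom if denom > 0 else 0.0
            slopes.append(m)
            e = r - m * d
            sse += float(e @ e)
        return sse, slopes[0], slopes[1]

    best = min(
        ((conditional_fit(t), t) for t in grid),
        key=lambda item: (item[0][0], item[1]),
    )
    (sse, m1, m2), t_op = best
    t_op = float(t_op)
    if m1 <= 0 or m2 >= 0:
        warnings.warn(
            f"non-triangular shape: fitted slopes m1={m1:.4g}, m2={m2:.4g}",
            UserWarning,
        )
    return TriangularChillingFunction(
        m1=m1,
        n1=1.0 - m1 * t_op,
        m2=m2,
        n2=1.0 - m2 * t_op,
        t_op=t_op,
        t_upper=t_upper,
        k=k,
    )


def triangular_from_rates(
    rates: Dict[float, float], t_upper: float = T_UPPER_DEFAULT
) -> TriangularChillingFunction:
    """Normalize decay rates and fit the triangular function in one step."""
    k, c_samples = normalize_rates(rates)
    return fit_triangular(c_samples, t_upper=t_upper, k=k)


def reference_function(
    rates: Dict[float, float], t_upper: float = T_UPPER_DEFAULT
) -> ReferenceChillingFunction:
    """Flat reference function with k = 1 / mean(c0)."""
    if not rates:
        raise ValueError("no decay rates given")
    mean_c0 = float(np.mean(list(rates.values())))
    if mean_c0 <= 0:
        raise ValueError("no dormancy release detected (all decay rates zero)")
    return ReferenceChillingFunction(t_upper=t_upper, k=1.0 / mean_c0)
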