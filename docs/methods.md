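# Methods

## The model

`chillcurve` quantifies dormancy release of temperate woody species from
chilling–forcing twig experiments and turns the result into a process-based
budburst model.

**Forcing requirement.** The depth of dormancy of a twig sampled on date
`t_s` is measured as the forcing requirement (FR), the growing-degree-hour
(GDH) total accumulated in the growth chamber until budburst:

    FR = Σ_t max(T_g(t) − T_b, 0)        [°C·h, hourly]

with base temperature `T_b = 5 °C`. The standard chamber schedule — 25 °C
for 14 h (light) and 15 °C for 10 h (dark) — accumulates 380 °C·h per day,
so FR and chamber days interconvert by division. Budburst dates are
replicate means and may be fractional; the trailing partial day contributes
its fraction of the daily GDH total, keeping FR continuous.

**Dormancy-release curves.** For each species, FR declines with total
chilling duration `x` (hours at or below 10 °C, refrigerator plus outside
hours since the autumn onset) as a negative exponential per chilling
temperature `T`:

    FR = a + b·exp(−c₀(T)·x)

The asymptote `a` and span `b` are shared across temperatures and preset
from the pooled data (`a = 0.95·min FR`, `b = 1.1·max FR − a`), leaving the
decay rate `c₀(T)` — the rate of dormancy release at `T` — as the single
free parameter per temperature, found by bounded 1-D least squares
(Brent-style on `[0, 0.05 h⁻¹]`, `xatol = 1e-12`; deterministic). Fitting
is on the FR scale; the log scale is used only for inference.

**Rate contrasts.** Whether `c₀` differs among temperatures is tested by
OLS on `ln(FR − a) ~ x + x:T` with `T` categorical and the coldest
temperature as reference. Interaction slopes are reported negated, i.e. as
decay-rate offsets `c₀(T) − c₀(ref)`, with standard OLS t-tests. No
multiplicity correction is applied by default (a Holm option exists).

**Chilling functions.** Rates are normalized to chilling units,
`c(T) = k·c₀(T)` with `k = 1/max c₀`, and summarized by either

* a *triangular* piecewise-linear function with apex `T_op` (where
  `c = 1`), fitted by profiling `T_op` on a 0.01 °C grid with closed-form
  conditional limb slopes under the apex constraint — a global optimum for
  this tiny problem; ties take the lowest apex; evaluation clips to `[0,1]`
  and to 0 above the 10 °C upper threshold; or
* a flat *reference* function (`c = 1` at or below 10 °C, else 0) with
  `k = 1/mean c₀`, encoding equal effectiveness of all sub-threshold
  temperatures.

**Budburst model.** Chilling accumulation over arbitrary hourly series is
`CA = Σ c(T(t))`; at constant temperature this is `c(T)·x`. FR follows
`FR = a + b·exp(−CA/k)`. Chamber days to budburst are
`(FR − ΔFR)/380`, where ΔFR is forcing already accrued outdoors after
1 January (hours strictly before the sampling date), floored at zero.
Field budburst dates are found by a daily walk: CA accrues from the autumn
onset (first run of 3 days with mean below 10 °C, strict), GDH accrues from
1 January, and budburst is the first day whose cumulative GDH reaches that
day's FR; chilling and forcing windows overlap deliberately. Seasons where
forcing never catches FR return a censored (None) result.

**Hourly interpolation.** Daily min/max records become hourly series via a
single-harmonic diurnal cycle, minimum at 06:00 and maximum 12 h later
(phase configurable). Downstream quantities are threshold counts and sums,
insensitive to the exact phase. Note the deliberate asymmetry: the onset
rule uses *strictly below* 10 °C on daily means; hour counting uses *at or
below* 10 °C on hourly values.

**Validation metrics.** `R² = 1 − SSE/SST`, `RMSE = √(SSE/n)` (days), and
a Gaussian-surrogate `AICc = n·ln(SSE/n) + 2p + 2p(p+1)/(n−p−1)` with
default parameter counts `p = 3` for the reference model (a, b, k) and
`p = 6` for the triangular model (a, b, k, T_op, m₁, m₂). Absolute AICc
values depend on this surrogate; only orderings are meaningful. AICc is
undefined (NaN) for `n ≤ p + 1`.

## Synthetic data

The generator is the exact forward model of the analysis. A species is
defined by `(a, b)`, a true triangular chilling function with scale `k`,
and additive Gaussian FR noise (default sd 300 °C·h, roughly the replicate
-mean scatter of a five-twig treatment cell); an optional log-scale noise
mode supports calibration studies of the slope test. The default design
mirrors a two-year-style experiment: refrigerator temperatures
{−10, −5, 0, 5, 10} °C crossed with {0, 2, 4, 8, 12} weeks, on top of
367 h of outside chilling before collection (22 November). FR converts to
budburst timestamps through the chamber regime; cells exceeding 90 chamber
days are censored.

**Preset-consistent truth.** The preset rule ties `a` and `b` to the
design's extreme FRs. So that the generating parameters are exactly the
ones the estimator family can recover, each default species' asymptote and
peak rate are derived from the consistency conditions

    1.9·exp(−c0max·x_max) + 1.1·exp(−c0min·x_min) = 1,
    a = 19·b·exp(−c0max·x_max),

with `x_min = 367 h`, `x_max = 24·84 + 367 h`, and `c0min` fixed by the
triangle's edge values. With this construction the noise-free pipeline
(generate → FR → preset → rates → normalize → triangle/reference) returns
the truth to optimizer tolerance, and recovery error under noise is pure
variance, not preset bias. Two consequences, stated plainly: the default
triangles are peaked (edge values 0.1–0.45) rather than near-flat, and
apexes sit at tested temperatures (0 or 5 °C) so the apex — and hence `k`
— is identifiable from the sampled grid. Because the truth is peaked, the
triangular model also genuinely outperforms the flat reference on synthetic
internal validation; on field data of species with near-flat responses the
ordering can reverse once the AICc parameter penalty is applied.

Weather is a sinusoidal annual cycle (mean 12 °C, amplitude 15 °C, coldest
around 20 January) with iid daily noise (sd 2 °C) and an 8 °C diurnal
range — a continental temperate (Beijing-like) seasonal course with an
autumn onset in late October/November and winter means below zero. It does
not emulate synoptic autocorrelation, cold spells, or warming trends, so
passing tests demonstrate correctness of the accounting and fitting
machinery, not robustness to real weather structure.

All randomness flows from explicit integer seeds; identical seeds
reproduce tables bit-for-bit.

## Numerical choices and degenerate inputs

- Decay-rate SSE is smooth and unimodal on the search interval; the
  bounded minimizer result is snapped to 0 when the boundary beats the
  interior (no-decay data).
- All-equal normalized samples (`c ≡ 1`) are a flat-top degenerate
  triangle: slopes 0, apex at the middle sampled temperature, with a
  warning; the triangular and reference paths then coincide exactly,
  including `k`.
- Non-triangular fitted shapes (`m₁ ≤ 0` or `m₂ ≥ 0`) warn rather than
  fail.
- Window conventions: day windows are inclusive on both ends for chilling
  counts and CA; ΔFR excludes the sampling date; `x = CH_R + CH_O` treats
  outside chilling hours at the refrigerator temperature's rate, the same
  simplification the fitting stage assumes.
- Problem sizes in tests and the acceptance script (nine species × 25
  cells, 500-replicate calibration runs, 200-replicate bias studies) were
  chosen to estimate each quantity stably at interactive runtimes.

## Known limitations

- The upper chilling threshold (10 °C) and base temperature (5 °C) are
  assumptions carried from the experimental literature, configurable but
  not estimated.
- No photoperiod, humidity, or radiation effects; the chamber model is
  temperature-only.
- No bud-level survival or proportion-of-budburst modelling; censored
  treatments are flagged, never imputed.
- AICc parameter counts are conventions, not estimates of effective
  degrees of freedom.
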