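# Methods

This note records the model, the numerical choices, and the design decisions
behind pestrisk, in the spirit of a package methods appendix.

## Phenology model

The life cycle is egg → larva → pupa → adult (female/male), each stage a
`StageModel` of `FunctionSpec` curves drawn from a registry of
temperature-response families:

| role | families | form |
|---|---|---|
| development rate | `briere_1` | a·T·(T−T_L)·√(T_U−T) on (T_L, T_U), else 0 |
| | `sharpe_demichele_1` | Schoolfield biophysical rate with low/high-temperature enzyme inactivation (Kelvin internally, R = 1.987 cal mol⁻¹ K⁻¹) |
| daily mortality | `wang_mortality_1` | 1 − (1 − m_min)·exp(−(((T−T_opt)/B)²)^k), clipped to [0, 1] |
| development-time distribution | `cll_devtime`, `logit_devtime` | CDFs in a + b·ln x of normalized age x |
| mean fecundity | `taylor_fecundity_1` | F_max·exp(−½((T−T_opt)/σ)²) |
| cumulative fecundity | `exp_modified_cumfec_3` | C(x) = 1 − exp(−(x/γ)^θ) over normalized female age |
| adult senescence | `exp_simple_senescence` | a·e^{bT} (1/day) |

The registry isolates the one genuinely under-determined layer: the named
ILCYM function variants are documented in software manuals and earlier
modelling papers rather than in a single canonical reference, so each family
is an explicit, swappable entry with a fixed contract (rates and fecundities
≥ 0, mortalities and CDFs in [0, 1], boundary behaviour outside the
biological temperature domain: rate/fecundity 0, mortality 1). Two notes:

* The Wang-type mortality carries a shape exponent k (≥ 1). k = 1 is the
  plain Gaussian U; the synthetic generator uses k = 3 because a plain
  Gaussian cannot keep daily mortality low across a 20–25 °C optimal plateau
  *and* saturate at 10/35 °C thresholds — the two requirements the
  establishment index hinges on.
* Normalized age is physiological age (accumulated rate·time), making the
  development-time distribution temperature-invariant — the standard
  "same shape" assumption. CLL/logit intercepts of ln(ln 2)/0 put the median
  at normalized age 1, so the median duration at constant T is exactly
  1/rate(T).

Mortality here is a **daily** rate: per-step survival is
(1 − m(T))^(Δt/1 day), which collapses to 1 − m(T) over a constant-temperature
day. Interpreting the U-curve as stage-total mortality instead is a registry
swap plus a different aggregation; the daily reading keeps the cold-slows-
development-and-compounds-mortality mechanism that drives marginal-climate
unsuitability.

## Curve fitting

`fit_function` is bounded nonlinear least squares (scipy `least_squares`,
trust-region reflective) with five jittered starts from a family-specific
initial guess (fixed seed), because thermal curves have local optima.
Mortality predictions are clipped to [0, 1] inside the residual.
Non-convergence is flagged on the `FitResult`, never raised; fewer distinct
temperatures than free parameters is an argument error. Noiseless data are
recovered to machine precision (tested); 5% multiplicative noise at five
rearing temperatures with n = 100 recovers Brière and Taylor parameters
within 10%.

## Diurnal reconstruction and the daily steady-state regime

Monthly minima/maxima expand to 365 (min, max, next-day-min) triples
(non-leap calendar; the last day of each month takes the next month's
minimum, December wrapping to January). Each half-day is the cosine
interpolation at 48 fifteen-minute midpoints; the second half-day uses the
next day's minimum.

Each day is treated as a *steady-state regime*: the day's cycle is assumed to
persist for the cohort's whole life, and the per-day λ_i, Tc_i, R0_i entering
the indices come from that assumption. This is the only reading under which
per-day index summands are well defined, and it makes the simulation cheap:
under a repeating cycle a stage's physiological-age increment
a_s = mean_i rate(T_i) and daily survival p_s = Π_i (1−m(T_i))^{1/96} are
constants, so the cohort bookkeeping runs on a daily grid (entry-distribution
convolutions against stage-duration kernels p_s^k·ΔF(a_s·k)) while the 15-min
stepping enters through the within-day averages taken *through* the nonlinear
curves. Because those averages sample a smooth periodic function at equal
spacing, refining the step from 15 min to 1 min changes R0 only at the
10⁻¹⁵ level (tested); the 15-min resolution is retained as the pipeline's
convention, not as an accuracy compromise.

The life table is female-based: the cohort starts as one unit of female eggs,
and the sex ratio multiplies fecundity once (female eggs per female) in m_x.
Adults age at the mean senescence rate ρ; survival to normalized adult age x
follows the adult CLL distribution and eggs follow f_day·ΔC(x), with
f_day the cycle-mean Taylor fecundity. An `adult_male` stage is carried in
the model container for completeness but does not enter the female life
table.

Numerical choices: horizon 500 days with a truncation flag when development
cannot complete (never an exception; a fully lethal regime yields R0 = 0 with
the r = −∞ sentinel handled as λ = 0); duration kernels truncated where
1 − F < 10⁻¹²; Lotka–Euler solved by bracketing ([−2, 2], doubled as needed)
plus bisection to 10⁻¹⁰ — robust near flat schedules where Newton is not;
R0 = 1 gives r = 0, λ = 1, infinite doubling time, and Tc falls back to the
mean age of reproduction Σx·φ/R0.

## Risk indices

* **ERI** = (survivable days / 365) × net-reproduction factor. A day is
  survivable when every immature stage's daily survival under that day's
  cycle exceeds `survival_threshold` (default 0.01). The printed form of the
  index is dimensionally loose; the indicator reading keeps ERI ∈ [0, 1] and
  matches the "possibility for each immature stage to survive" semantics.
  The net-reproduction factor defaults to the indicator 1{mean annual
  R0 ≥ 1}; a `capped` alternative min(1, mean R0) is exposed for sensitivity
  runs.
* **GI** sums 365/Tc_i over days and divides by 365; days where the
  population cannot replace itself (R0 ≤ 1, or Tc undefined) contribute 0,
  keeping the index bounded and zero in deserts.
* **AI** = Σ log10 λ_i with λ floored at `lambda_floor` (default 10⁻⁶)
  before the log: the raw product is 0 (AI = −∞) if any single day is lethal,
  which would erase the finite negative values temperate zones should show.
  Without flooring, 10^AI equals Πλ_i exactly (tested to 10⁻⁹).

Classification uses half-open 0.2-wide bins with the top bin closed and
permanent establishment at ERI > 0.6 strictly (the 0.6 boundary cell itself
classifies as highly suitable but is not "permanent").

## Geospatial layer

ESRI ASCII grids only (6-line header, rows top-down, lower-left origin, cell
centers half a cell in); values are written with Python's shortest
round-trip float repr so write→read is bit-identical. Nodata is NaN in memory
and never enters statistics; a cell missing any of its 24 monthly values is
nodata in all outputs. Per-cell results are cached on the 24-value monthly
tuple rounded to 0.01 °C, and per-day regimes on the rounded
(min, max, next-min) triple shared across cells — real climate grids repeat
regimes massively, which is what makes raster-scale runs feasible.

Cell areas use a spherical Earth at 111.32 km/degree:
(cellsize·111.32)²·cos(lat_center), within 0.5% of closed-form spherical band
areas at 1° resolution (tested). Area tables carry per-region totals; an
explicit region-total override exists because published continental class
areas are rasterized and can fall slightly short of the published continent
total. Change maps are future − current with nodata if either side is
missing; area-change percentages are relative to the region's current total.

## Synthetic data: what it emulates and what it does not

The grid generator produces monthly means
T̄(lat, m) = T_eq − lapse·|lat| ± A·cos(2πm/12) (phase peaking mid-July north
of the equator, mid-January south), a fixed diurnal range, and i.i.d.
Gaussian noise on the monthly mean (so max ≥ min holds by construction).
Defaults — 20 × 20 cells over ±50° latitude, 28 °C equatorial mean,
0.35 °C/degree lapse, 6 °C seasonal amplitude, 10 °C diurnal range, 0.5 °C
noise — give a world whose suitable band sits at mid-latitudes for the
default insect. There is no spatial covariance, no continentality, no
elevation; passing tests show the pipeline's bookkeeping and monotonicities,
not fidelity to any real climate surface.

The default synthetic insect (thresholds 10/35 °C, optimum 22.5 °C, peak
daily egg rate 0.22 with larva/pupa at 0.45/0.7 of that, 120 eggs/female,
daily survival 0.98 at the optimum, ~18-day adult lifespan) is calibrated to
the reported biology of the tomato pinworm at the order-of-magnitude level:
at the 22.5 °C optimum it yields r ≈ 0.12/day (reported range 0.09–0.13),
R0 ≈ 36, and ≈ 12 generations per year. Observation noise is multiplicative
lognormal on development times and fecundities and binomial on survival
(mini-cohort size set so the sampling sd matches the requested noise at
p = 0.5), giving positivity and bounded proportions by construction.

## Problem sizes

The test suite and the acceptance script run desk-scale problems: 20 × 20
grids, 500-day cohort horizons, 365-day series per cell. A full
2.5-arcmin global grid is the same code path with more cells; the per-regime
cache is the quantity that matters there.

## Known limitations

Temperature is the only driver: no host plants, natural enemies, rainfall,
humidity, greenhouse microclimates, or overwintering diapause — the model
will call cold temperate zones unsuitable even where diapause lets real
populations persist. The steady-state-day convention ignores transient
carry-over between days. Male demography is not modelled. GeoTIFF input is
not supported; convert to ESRI ASCII first.
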