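"""Diurnal temperature reconstruction and stage-structured life-table simulation.

The pipeline reconstructs within-day temperatures from monthly minima and
maxima with the half-day cosine equation

    T_i = ((Max - Min) / 2) * cos(pi * (i - 0.5) / 48) + ((Max + Min) / 2),

evaluated at 48 fifteen-minute steps per half-day: the first half-day runs
from the day's maximum down using (Min, Max), the second half-day repeats the
equation with the *next* day's minimum. With monthly climate data the daily
extremes are the month's values; the next-day minimum at a month boundary
comes from the following month (December wraps to January).

Each calendar day's cycle is treated as a steady-state thermal regime: a
deterministic cohort of female eggs develops under that repeated cycle and its
l_x/m_x schedule yields the day's life-table parameters (GRR, R0, Tc, r,
lambda, doubling time). Because the regime repeats daily, development within a
stage accrues physiological age at a constant per-day increment
a_s = mean_i rate(T_i) and survives each day by p_s = prod_i (1-m(T_i))^(1/96),
so the cohort bookkeeping runs on a daily grid while the 15-min stepping enters
through those within-day averages (this is where "accounting for daily
temperature variability" bites: the averages are taken through the nonlinear
thermal curves, not of temperature itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .thermal import (PhenologyModel, devtime_cdf_grid,
                      evaluate_cumulative_fecundity, evaluate_fecundity,
                      evaluate_mortality, evaluate_rate, evaluate_senescence)

MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
DAYS_PER_YEAR = 365


# ---------------------------------------------------------------------------
# diurnal cycle
# ---------------------------------------------------------------------------

def halfday_temperature(t_min: float, t_max: float, i: int) -> float:
    """Temperature at 15-min step i (1..48) of a half-day cosine cycle."""
    if t_max < t_min:
        raise ValueError("t_max must be >= t_min")
    if not 1 <= i <= 48:
        raise ValueError(f"step index must be in 1..48, got {i}")
    return ((t_max - t_min) / 2.0) * math.cos(math.pi * (i - 0.5) / 48.0) \
        + (t_max + t_min) / 2.0


def _halfday_series(t_min: float, t_max: float, n_steps: int = 48):
    i = np.arange(1, n_steps + 1)
    return ((t_max - t_min) / 2.0) * np.cos(np.pi * (i - 0.5) / n_steps) \
        + (t_max + t_min) / 2.0


@dataclass(frozen=True)
class DiurnalCycle:
    """96 x 15-min temperatures: first half-day from (Min, Max), second from
    (next-day Min, Max)."""

    t_min: float
    t_max: float
    next_day_min: float
    steps: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.t_max < max(self.t_min, self.next_day_min):
            raise ValueError("t_max must be >= both minima")
        if self.steps is None:
            object.__setattr__(self, "steps", np.concatenate([
                _halfday_series(self.t_min, self.t_max),
                _halfday_series(self.next_day_min, self.t_max)]))


def build_diurnal_cycle(t_min: float, t_max: float,
                        next_day_min: float) -> DiurnalCycle:
    return DiurnalCycle(t_min, t_max, next_day_min)


def cycle_temperatures(t_min: float, t_max: float, next_day_min: float,
                       steps_per_halfday: int = 48):
    """One day's temperatures at arbitrary half-day resolution (engine/oracle)."""
    if t_max < max(t_min, next_day_min):
        raise ValueError("t_max must be >= both minima")
    return np.concatenate([
        _halfday_series(t_min, t_max, steps_per_halfday),
        _halfday_series(next_day_min, t_max, steps_per_halfday)])


def monthly_to_daily(tmin12: Sequence[float], tmax12: Sequence[float]):
    """Expand 12 monthly (min, max) pairs to 365 daily (min, max, next_min).

    Each day carries its month's extremes; the last day of a month takes the
    following month's minimum as next-day minimum (December wraps to January).
    Non-leap calendar throughout.
    """
    tmin12 = np.asarray(tmin12, dtype=float)
    tmax12 = np.asarray(tmax12, dtype=float)
    if tmin12.shape != (12,) or tmax12.shape != (12,):
        raise ValueError("expected 12 monthly minima and 12 monthly maxima")
    triples = []
    for m, ndays in enumerate(MONTH_LENGTHS):
        nxt = (m + 1) % 12
        for d in range(ndays):
            next_min = tmin12[m] if d < ndays - 1 else tmin12[nxt]
            triples.append((float(tmin12[m]), float(tmax12[m]), float(next_min)))
    return triples


# ---------------------------------------------------------------------------
# cohort simulation under one repeated daily cycle
# ---------------------------------------------------------------------------

@dataclass
class CohortSchedule:
    """Daily l_x / m_x schedule of one steady-state cohort.

    ``l_x`` is the proportion of the initial (female) egg cohort alive at age
    x days; ``m_x`` female eggs per surviving female per day; ``phi`` their
    product l_x * m_x (the Lotka-Euler kernel). ``stage_daily`` maps each stage
    to its per-day physiological-age increment and survival under the cycle.
    """

    ages: np.ndarray
    l_x: np.ndarray
    m_x: np.ndarray
    phi: np.ndarray
    immature_survival: float
    stage_daily: dict
    truncated: bool = False
    stage_entry: dict = field(default_factory=dict)

    @classmethod
    def from_lxmx(cls, l_x, m_x, ages=None) -> "CohortSchedule":
        l_x = np.asarray(l_x, dtype=float)
        m_x = np.asarray(m_x, dtype=float)
        if ages is None:
            ages = np.arange(l_x.size, dtype=float)
        phi = l_x * m_x
        return cls(np.asarray(ages, dtype=float), l_x, m_x, phi,
                   immature_survival=float("nan"), stage_daily={})


@dataclass
class LifeTableParams:
    """Daily steady-state life-table parameters.

    Consistency: lambda = e^r, Dt = ln 2 / r, Tc = ln(R0)/r (R0 > 0, r != 0).
    A regime where the cohort never reproduces carries R0 = 0 with the
    r = -inf sentinel handled as lambda = 0.
    """

    gross_repro: float
    net_repro: float
    gen_time: float
    intrinsic_rate: float
    finite_rate: float
    doubling_time: float
    immature_survival: float
    truncated: bool = False


def _stage_daily_aggregates(stage, temps, dt):
    """(phys-age increment per day, daily survival) for one immature stage."""
    rate = np.asarray(evaluate_rate(stage.dev_rate, temps), dtype=float)
    mort = np.asarray(evaluate_mortality(stage.mortality, temps), dtype=float)
    a = float(np.mean(rate))
    with np.errstate(divide="ignore"):
        logs = np.log1p(-np.clip(mort, 0.0, 1.0))
    p = float(np.exp(dt * np.sum(logs))) if np.all(np.isfinite(logs)) else 0.0
    return a, p


def simulate_cohort(model: PhenologyModel,
                    cycle: Union[DiurnalCycle, np.ndarray],
                    horizon: int = 500) -> CohortSchedule:
    """Deterministic cohort of female eggs under one repeated daily cycle.

    Stage-exit fractions follow the stage's normalized-age distribution
    evaluated at accumulated physiological age; survivorship multiplies the
    per-step survival (1 - m(T))^(dt/1 day). Adults age at the senescence rate
    and lay ``fecundity_mean`` eggs distributed over normalized adult age by
    the cumulative-fecundity curve; ``sex_ratio`` converts to female eggs.
    A regime where some stage cannot complete development within ``horizon``
    days is returned with the ``truncated`` flag set, never raised.
    """
    temps = cycle.steps if isinstance(cycle, DiurnalCycle) else np.asarray(cycle, float)
    dt = 1.0 / temps.size
    H = int(horizon)
    ages = np.arange(H + 1, dtype=float)

    entry = np.zeros(H + 1)
    entry[0] = 1.0
    alive = np.zeros(H + 1)
    truncated = False
    stage_daily = {}
    stage_entry = {}
    tol = 1e-12

    for stage in model.immatures:
        stage_entry[stage.stage] = entry
        a_s, p_s = _stage_daily_aggregates(stage, temps, dt)
        stage_daily[stage.stage] = (a_s, p_s)
        p_pow = p_s ** ages
        if a_s <= 0.0:
            # development stalled: cohort stays (and dies) in this stage
            alive += np.convolve(entry, p_pow)[:H + 1]
            entry = np.zeros(H + 1)
            truncated = True
            continue
        F = devtime_cdf_grid(stage.devtime_dist, a_s * ages)
        done = np.nonzero(1.0 - F < tol)[0]
        K = int(done[0]) if done.size else H
        if K == H and 1.0 - F[H] >= tol:
            truncated = True
        stay = p_pow[:K + 1] * (1.0 - F[:K + 1])
        exit_kernel = np.zeros(K + 1)
        exit_kernel[1:] = p_pow[1:K + 1] * np.diff(F[:K + 1])
        alive += np.convolve(entry, stay)[:H + 1]
        entry = np.convolve(entry, exit_kernel)[:H + 1]

    e_adult = entry
    stage_entry["adult_female"] = e_adult
    immature_survival = float(e_adult.sum())

    adult = model.adult_female
    rho = float(np.mean(np.asarray(
        evaluate_senescence(adult.senescence, temps), dtype=float)))
    f_day = float(np.mean(np.asarray(
        evaluate_fecundity(model.fecundity_mean, temps), dtype=float)))
    x_ad = rho * ages
    S_A = 1.0 - devtime_cdf_grid(adult.devtime_dist, x_ad)
    C = evaluate_cumulative_fecundity(model.fecundity_cum, x_ad)
    dC = np.diff(C, prepend=0.0)
    gone = np.nonzero(S_A < tol)[0]
    KA = int(gone[0]) if gone.size else H
    alive += np.convolve(e_adult, S_A[:KA + 1])[:H + 1]
    eggs = model.sex_ratio * f_day * np.convolve(
        e_adult, (S_A * dC)[:KA + 1])[:H + 1]

    l_x = alive
    m_x = np.divide(eggs, l_x, out=np.zeros_like(eggs), where=l_x > 1e-300)
    return CohortSchedule(ages=ages, l_x=l_x, m_x=m_x, phi=eggs,
                          immature_survival=immature_survival,
                          stage_daily=stage_daily, truncated=truncated,
                          stage_entry=stage_entry)


# ---------------------------------------------------------------------------
# Lotka-Euler life-table parameters
# ---------------------------------------------------------------------------

def _solve_lotka_euler(ages, phi, tol=1e-10):
    """Intrinsic rate r with sum(phi * exp(-r x)) = 1, bracketing + bisection."""

    support = phi > 0
    phi_s = phi[support]
    ages_s = ages[support]

    def g(r):
        # clip the exponent so phi * exp never produces 0 * inf -> NaN;
        # an overflowed (inf) sum still compares correctly against 1
        return float(np.sum(phi_s * np.exp(np.clip(-r * ages_s, -745.0, 709.0)))) - 1.0

    lo, hi = -2.0, 2.0
    # g is strictly decreasing in r; widen the bracket if needed
    for _ in range(60):
        if g(lo) > 0:
            break
        lo *= 2.0
    for _ in range(60):
        if g(hi) < 0:
            break
        hi *= 2.0
    if g(lo) <= 0 or g(hi) >= 0:  # pragma: no cover - pathological schedule
        raise ArithmeticError("could not bracket the intrinsic rate")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def lifetable_params(schedule: CohortSchedule, tol: float = 1e-10) -> LifeTableParams:
    """Life-table parameters from an l_x/m_x schedule.

    R0 = sum l_x m_x, GRR = sum m_x over the reproductive span, r solves the
    Lotka-Euler equation by bisection, lambda = e^r, Tc = ln(R0)/r,
    Dt = ln 2 / r. R0 = 0 yields the r = -inf sentinel with lambda = 0.
    """
    ages = schedule.ages
    phi = schedule.phi
    r0 = float(phi.sum())
    grr = float(schedule.m_x[phi > 0].sum()) if np.any(phi > 0) else 0.0
    surv = schedule.immature_survival
    if r0 <= 0.0:
        return LifeTableParams(grr, 0.0, math.nan, -math.inf, 0.0, math.nan,
                               surv, truncated=schedule.truncated)
    if abs(r0 - 1.0) < 1e-14:
        tc = float(np.sum(ages * phi) / r0)
        return LifeTableParams(grr, r0, tc, 0.0, 1.0, math.inf, surv,
                               truncated=schedule.truncated)
    r = _solve_lotka_euler(ages, phi, tol=tol)
    if r == 0.0:  # pragma: no cover - exactly replacement after bisection
        tc = float(np.sum(ages * phi) / r0)
        return LifeTableParams(grr, r0, tc, 0.0, 1.0, math.inf, surv,
                               truncated=schedule.truncated)
    return LifeTableParams(grr, r0, math.log(r0) / r, r, math.exp(r),
                           math.log(2.0) / r, surv,
                           truncated=schedule.truncated)


# ---------------------------------------------------------------------------
# daily series per grid cell
# ---------------------------------------------------------------------------

@dataclass
class DailySeries:
    """365 per-day life-table parameter sets for one location.

    ``min_immature_survival`` is, per day, the lowest daily survival among the
    immature stages under that day's cycle — the establishment indicator input.
    """

    params: list
    min_immature_survival: np.ndarray

    def __post_init__(self):
        if len(self.params) != DAYS_PER_YEAR or \
                len(self.min_immature_survival) != DAYS_PER_YEAR:
            raise ValueError("a daily series covers exactly 365 days")

    def __len__(self):
        return len(self.params)

    @classmethod
    def from_arrays(cls, finite_rate, net_repro=None, gen_time=None,
                    min_survival=None) -> "DailySeries":
        """Build a series from per-day arrays (testing / sensitivity runs).

        Missing pieces are filled consistently: r = ln(lambda), R0 = lambda
        unless given, Tc = ln(R0)/r where defined.
        """
        lam = np.asarray(finite_rate, dtype=float)
        n = lam.size
        r0 = np.asarray(net_repro, dtype=float) if net_repro is not None else lam.copy()
        tc = (np.asarray(gen_time, dtype=float) if gen_time is not None
              else np.full(n, np.nan))
        surv = (np.asarray(min_survival, dtype=float) if min_survival is not None
                else np.ones(n))
        params = []
        for i in range(n):
            lam_i = float(lam[i])
            r = math.log(lam_i) if lam_i > 0 else -math.inf
            tc_i = float(tc[i])
            if math.isnan(tc_i) and r0[i] > 0 and r not in (0.0, -math.inf):
                tc_i = math.log(r0[i]) / r if r0[i] != 1.0 else math.nan
            params.append(LifeTableParams(
                gross_repro=float(r0[i]), net_repro=float(r0[i]),
                gen_time=tc_i, intrinsic_rate=r, finite_rate=lam_i,
                doubling_time=math.log(2.0) / r if r not in (0.0, -math.inf)
                else math.inf, immature_survival=float(surv[i])))
        return cls(params, surv)

    @property
    def lambdas(self):
        return np.array([p.finite_rate for p in self.params])

    @property
    def net_repro(self):
        return np.array([p.net_repro for p in self.params])

    @property
    def gen_time(self):
        return np.array([p.gen_time for p in self.params])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "day": np.arange(1, DAYS_PER_YEAR + 1),
            "R0": self.net_repro,
            "GRR": [p.gross_repro for p in self.params],
            "Tc": self.gen_time,
            "r": [p.intrinsic_rate for p in self.params],
            "lambda": self.lambdas,
            "doubling_time": [p.doubling_time for p in self.params],
            "immature_survival": [p.immature_survival for p in self.params],
            "min_daily_survival": self.min_immature_survival,
        })


class CellSimulator:
    """Per-day steady-state life tables with caching over repeated regimes.

    With monthly climate inputs a cell has at most ~24 distinct
    (min, max, next-day-min) regimes per year; the cache is keyed on the
    triple rounded to ``cache_decimals`` and shared across cells, which makes
    raster-scale runs feasible.
    """

    def __init__(self, model: PhenologyModel, horizon: int = 500,
                 steps_per_halfday: int = 48, cache_decimals: int = 2):
        self.model = model
        self.horizon = horizon
        self.steps_per_halfday = steps_per_halfday
        self.cache_decimals = cache_decimals
        self._cache = {}

    def day_result(self, t_min: float, t_max: float, next_day_min: float):
        """(LifeTableParams, min immature daily survival) for one regime."""
        key = (round(min(t_min, t_max), self.cache_decimals),
               round(t_max, self.cache_decimals),
               round(min(next_day_min, t_max), self.cache_decimals))
        if key not in self._cache:
            temps = cycle_temperatures(*key, self.steps_per_halfday)
            sched = simulate_cohort(self.model, temps, horizon=self.horizon)
            params = lifetable_params(sched)
            if sched.stage_daily:
                min_surv = min(p for _, p in sched.stage_daily.values())
            else:  # pragma: no cover
                min_surv = 0.0
            self._cache[key] = (params, min_surv)
        return self._cache[key]

    def daily_series(self, tmin12, tmax12) -> DailySeries:
        triples = monthly_to_daily(tmin12, tmax12)
        params = []
        surv = np.empty(DAYS_PER_YEAR)
        for d, triple in enumerate(triples):
            p, s = self.day_result(*triple)
            params.append(p)
            surv[d] = s
        return DailySeries(params, surv)
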