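"""Diurnal reconstruction, cohort simulation and Lotka-Euler parameters."""

import math

import numpy as np
import pytest

import pestrisk as pr
from pestrisk.lifetable import MONTH_LENGTHS, cycle_temperatures
from pestrisk.thermal import FunctionSpec, StageModel, PhenologyModel


def make_simple_model(egg_rate_at_25=0.2):
    """Zero-mortality model with a known egg rate at 25 degC and CLL medians
    at normalized age 1, so median durations are exactly 1/rate."""
    a_briere = egg_rate_at_25 / (25.0 * (25.0 - 8.0) * math.sqrt(35.0 - 25.0))
    rate = FunctionSpec("briere_1", {"a": a_briere, "T_L": 8.0, "T_U": 35.0})
    no_mort = FunctionSpec("wang_mortality_1",
                           {"m_min": 0.0, "T_opt": 25.0, "B": 1e6, "k": 1.0})
    cll = FunctionSpec("cll_devtime", {"a": math.log(math.log(2.0)), "b": 12.0})
    stages = [StageModel(s, cll, dev_rate=rate, mortality=no_mort)
              for s in ("egg", "larva", "pupa")]
    sen = FunctionSpec("exp_simple_senescence", {"a": 0.05, "b": 0.0})
    stages += [StageModel(s, cll, senescence=sen)
               for s in ("adult_female", "adult_male")]
    return PhenologyModel(
        stages=tuple(stages),
        fecundity_mean=FunctionSpec("taylor_fecundity_1",
                                    {"F_max": 100.0, "T_opt": 25.0, "sigma": 5.0}),
        fecundity_cum=FunctionSpec("exp_modified_cumfec_3",
                                   {"gamma": 0.4, "theta": 2.0}),
        sex_ratio=0.5)


class TestHalfdayTemperature:
    @pytest.mark.parametrize("i", [1, 17, 48])
    def test_matches_printed_cosine_equation(self, i):
        expected = 10.0 * math.cos(math.pi * (i - 0.5) / 48.0) + 20.0
        assert pr.halfday_temperature(10.0, 30.0, i) == pytest.approx(
            expected, abs=1e-12)

    def test_zero_amplitude(self):
        assert all(pr.halfday_temperature(20.0, 20.0, i) == 20.0
                   for i in range(1, 49))

    def test_step_index_domain(self):
        for i in (0, 49, -3):
            with pytest.raises(ValueError):
                pr.halfday_temperature(10.0, 30.0, i)

    def test_inverted_extremes_rejected(self):
        with pytest.raises(ValueError):
            pr.halfday_temperature(30.0, 10.0, 5)


class TestDiurnalCycle:
    def test_symmetric_cycle_mean(self):
        cycle = pr.build_diurnal_cycle(10.0, 30.0, 10.0)
        assert cycle.steps.size == 96
        assert np.mean(cycle.steps) == pytest.approx(20.0, abs=1e-9)
        assert np.mean(cycle.steps[:48]) == pytest.approx(20.0, abs=1e-6)

    def test_second_halfday_uses_next_day_minimum(self):
        cycle = pr.build_diurnal_cycle(10.0, 30.0, 14.0)
        assert np.min(cycle.steps[48:]) >= 14.0 - 1e-9
        assert np.min(cycle.steps[:48]) < 14.0

    def test_steps_bounded_and_start_near_max(self):
        cycle = pr.build_diurnal_cycle(8.0, 27.0, 12.0)
        assert np.all(cycle.steps <= 27.0 + 1e-12)
        assert np.all(cycle.steps >= 8.0 - 1e-12)
        assert cycle.steps[0] == pytest.approx(27.0, abs=0.05)
        # each half-day decreases monotonically from Max toward Min
        assert np.all(np.diff(cycle.steps[:48]) < 0)
        assert np.all(np.diff(cycle.steps[48:]) < 0)

    def test_max_below_min_rejected(self):
        with pytest.raises(ValueError):
            pr.build_diurnal_cycle(20.0, 10.0, 5.0)


class TestMonthlyToDaily:
    def test_constant_climate(self):
        triples = pr.monthly_to_daily([10.0] * 12, [30.0] * 12)
        assert len(triples) == 365
        assert set(triples) == {(10.0, 30.0, 10.0)}

    def test_month_boundary_rule(self):
        tmin = [5.0, 10.0] + [0.0] * 10
        tmax = [15.0, 20.0] + [10.0] * 10
        triples = pr.monthly_to_daily(tmin, tmax)
        assert triples[30] == (5.0, 15.0, 10.0)  # Jan 31 looks at Feb
        assert triples[29] == (5.0, 15.0, 5.0)
        assert triples[364][2] == 5.0  # Dec 31 wraps to Jan

    def test_non_leap_calendar(self):
        triples = pr.monthly_to_daily(list(range(12)), [40.0] * 12)
        counts = [sum(1 for t in triples if t[0] == m) for m in range(12)]
        assert counts == list(MONTH_LENGTHS)


class TestCohortSimulation:
    def test_median_egg_duration_is_reciprocal_rate(self):
        model = make_simple_model(egg_rate_at_25=0.2)
        sched = pr.simulate_cohort(model, np.full(96, 25.0))
        entry = sched.stage_entry["larva"]
        cum = np.cumsum(entry)
        assert cum[4] < 0.5
        assert cum[5] == pytest.approx(0.5, abs=1e-9)

    def test_daily_survival_collapses_at_constant_temperature(self, model):
        T = 22.5
        sched = pr.simulate_cohort(model, np.full(96, T))
        for stage in model.immatures:
            expected = 1.0 - pr.evaluate_mortality(stage.mortality, T)
            assert sched.stage_daily[stage.stage][1] == pytest.approx(
                expected, abs=1e-9)

    def test_survivorship_non_increasing(self, model, optimal_cycle):
        sched = pr.simulate_cohort(model, optimal_cycle)
        assert np.all(np.diff(sched.l_x) <= 1e-12)
        assert sched.l_x[0] == pytest.approx(1.0)

    def test_lethal_regime_sets_truncation_flag(self, model):
        sched = pr.simulate_cohort(model, np.full(96, 5.0))  # below threshold
        assert sched.truncated
        assert sched.phi.sum() == 0.0

    def test_agrees_with_brute_force_subcohort_simulator(self, model):
        # independent bookkeeping (explicit sub-cohort dictionaries, python
        # loops) at 1-min resolution vs the convolution engine at 15-min
        temps_1min = cycle_temperatures(17.5, 27.5, 17.5, steps_per_halfday=720)
        lx_oracle, eggs_oracle = brute_force_schedule(model, temps_1min, 300)
        sched = pr.simulate_cohort(model, pr.build_diurnal_cycle(17.5, 27.5, 17.5),
                                   horizon=300)
        assert np.max(np.abs(sched.l_x - lx_oracle)) < 1e-3
        assert abs(sched.phi.sum() - eggs_oracle.sum()) < 1e-3


def brute_force_schedule(model, temps, horizon):
    """Reference cohort simulator: explicit sub-cohorts, no convolutions."""
    nt = len(temps)
    lx = np.zeros(horizon + 1)
    eggs = np.zeros(horizon + 1)
    cohorts = {0: 1.0}
    for stage in model.immatures:
        a = sum(float(pr.evaluate_rate(stage.dev_rate, t)) for t in temps) / nt
        p = 1.0
        for t in temps:
            p *= (1.0 - float(pr.evaluate_mortality(stage.mortality, t))) ** (1.0 / nt)
        nxt = {}
        for d0, mass in cohorts.items():
            f_prev = 0.0
            for k in range(0, horizon + 1 - d0):
                x = a * k
                F = float(pr.evaluate_devtime_cdf(stage.devtime_dist, x)) if x > 0 else 0.0
                lx[d0 + k] += mass * p ** k * (1.0 - F)
                if k > 0:
                    out = mass * p ** k * (F - f_prev)
                    if out > 0.0:
                        nxt[d0 + k] = nxt.get(d0 + k, 0.0) + out
                f_prev = F
                if 1.0 - F < 1e-12:
                    break
        cohorts = nxt
    adult = model.adult_female
    rho = sum(float(pr.evaluate_senescence(adult.senescence, t)) for t in temps) / nt
    f_day = sum(float(pr.evaluate_fecundity(model.fecundity_mean, t))
                for t in temps) / nt
    for d0, mass in cohorts.items():
        c_prev = 0.0
        for k in range(0, horizon + 1 - d0):
            x = rho * k
            S = 1.0 - (float(pr.evaluate_devtime_cdf(adult.devtime_dist, x))
                       if x > 0 else 0.0)
            C = float(pr.evaluate_cumulative_fecundity(model.fecundity_cum, x))
            lx[d0 + k] += mass * S
            eggs[d0 + k] += model.sex_ratio * f_day * mass * S * (C - c_prev)
            c_prev = C
            if S < 1e-12:
                break
    return lx, eggs


class TestLifeTableParams:
    def test_single_pulse_closed_form(self):
        for r0, age in ((5.0, 10), (0.25, 20), (2.0, 7)):
            l = np.zeros(60)
            m = np.zeros(60)
            l[age] = 1.0
            m[age] = r0
            p = pr.lifetable_params(pr.CohortSchedule.from_lxmx(l, m))
            assert p.intrinsic_rate == pytest.approx(math.log(r0) / age, abs=1e-8)
            assert p.net_repro == pytest.approx(r0)

    def test_replacement_rate(self):
        l = np.zeros(40)
        m = np.zeros(40)
        l[12] = 1.0
        m[12] = 1.0
        p = pr.lifetable_params(pr.CohortSchedule.from_lxmx(l, m))
        assert p.intrinsic_rate == 0.0
        assert p.finite_rate == 1.0
        assert math.isinf(p.doubling_time)
        assert p.gen_time == pytest.approx(12.0)

    def test_no_reproduction_sentinel(self):
        p = pr.lifetable_params(pr.CohortSchedule.from_lxmx(np.ones(30),
                                                            np.zeros(30)))
        assert p.net_repro == 0.0
        assert p.finite_rate == 0.0
        assert p.intrinsic_rate == -math.inf

    def test_internal_consistency_identities(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            l = np.cumprod(rng.uniform(0.85, 1.0, 50))
            m = rng.uniform(0, 3.0, 50) * (rng.uniform(size=50) < 0.4)
            m[0] = 0.0  # no reproduction at age 0
            p = pr.lifetable_params(pr.CohortSchedule.from_lxmx(l, m))
            if p.net_repro <= 0:
                continue
            assert p.finite_rate == pytest.approx(math.exp(p.intrinsic_rate),
                                                  rel=1e-8)
            if p.intrinsic_rate not in (0.0,):
                assert p.gen_time * p.intrinsic_rate == pytest.approx(
                    math.log(p.net_repro), abs=1e-8)
                assert p.doubling_time == pytest.approx(
                    math.log(2.0) / p.intrinsic_rate, rel=1e-10)

    def test_bisection_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            l = np.cumprod(rng.uniform(0.8, 1.0, 50))
            m = rng.uniform(0, 4.0, 50) * (rng.uniform(size=50) < 0.5)
            m[0] = 0.0  # no reproduction at age 0
            sched = pr.CohortSchedule.from_lxmx(l, m)
            p = pr.lifetable_params(sched)
            if not math.isfinite(p.intrinsic_rate):
                continue
            r_scan = grid_scan_r(sched.ages, sched.phi)
            assert p.intrinsic_rate == pytest.approx(r_scan, abs=1e-6)


def grid_scan_r(ages, phi, lo=-2.0, hi=2.0):
    """Progressively refined dense grid scan of the Lotka-Euler equation."""
    for step in (1e-2, 1e-4, 1e-6):
        grid = np.arange(lo, hi + step, step)
        vals = np.abs((np.exp(-np.outer(grid, ages)) * phi).sum(axis=1) - 1.0)
        best = grid[int(np.argmin(vals))]
        lo, hi = best - step, best + step
    return best


class TestDailySeries:
    def test_constant_climate_gives_identical_days(self, model):
        sim = pr.CellSimulator(model)
        series = sim.daily_series([17.5] * 12, [27.5] * 12)
        assert len(series) == 365
        assert np.unique(series.lambdas).size == 1
        assert np.unique(series.net_repro).size == 1

    def test_series_equals_expanded_monthly_computation(self, model):
        tmin = [12.0 + m for m in range(12)]
        tmax = [t + 10.0 for t in tmin]
        series = pr.CellSimulator(model).daily_series(tmin, tmax)
        fresh = pr.CellSimulator(model)
        for day, triple in enumerate(pr.monthly_to_daily(tmin, tmax)):
            params, _ = fresh.day_result(*triple)
            assert series.params[day].finite_rate == params.finite_rate

    def test_uniform_warming_below_optimum_raises_lambda(self, model):
        tmin = [13.0, 13.5, 14.0, 15.0, 15.5, 16.0, 16.0, 15.5, 15.0, 14.5,
                14.0, 13.0]
        tmax = [t + 10.0 for t in tmin]
        base = pr.CellSimulator(model).daily_series(tmin, tmax)
        warm = pr.CellSimulator(model).daily_series(
            [t + 2.0 for t in tmin], [t + 2.0 for t in tmax])
        assert np.all(warm.lambdas > base.lambdas)
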