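"""Synthetic temperature grids, phenology models and life-table observations.

These generators emulate the statistical structure the pipeline assumes so
every downstream stage runs without external downloads: monthly min/max
temperature grids with a latitudinal gradient, seasonality whose phase flips
between hemispheres and a fixed diurnal range; phenology parameter sets with
known thermal optima; and noisy constant-temperature life-table observations
of the kind collected in laboratory rearing studies (development times,
survival fractions and fecundities at a handful of constant temperatures).

All generators are deterministic under a fixed seed. The grid generator makes
no attempt to mimic real-climate spatial covariance — only plausible
gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import math
import numpy as np
import pandas as pd

from .geospatial import TemperatureGrid
from .thermal import (FunctionSpec, PhenologyModel, StageModel, evaluate_rate)

# CLL with a = ln(ln 2) has its median at normalized age 1, so the median
# development time at constant T is exactly 1 / rate(T)
_CLL_MEDIAN_AT_ONE = math.log(math.log(2.0))

# relative development speed of egg / larva / pupa at the optimum; roughly
# the pattern in tomato-pinworm rearing data (egg fastest, larva slowest)
_STAGE_SPEED = {"egg": 1.0, "larva": 0.45, "pupa": 0.7}


@dataclass(frozen=True)
class SyntheticGridSpec:
    """Parameters of the synthetic monthly min/max climate grid.

    Monthly mean at a cell = equator mean - lapse * |lat| + seasonal term,
    where the seasonal term is sinusoidal with amplitude ``seasonal_amplitude``
    peaking at mid-July north of the equator and mid-January south of it.
    ``diurnal_range`` fixes max - min; Gaussian noise (sd ``noise_sd``) is
    added to the monthly mean so the max >= min invariant holds by
    construction.
    """

    n_rows: int = 20
    n_cols: int = 20
    lat_range: tuple = (-50.0, 50.0)
    lon_range: tuple = (10.0, 30.0)
    mean_annual_temp_at_equator: float = 28.0
    lapse_per_degree_lat: float = 0.35
    seasonal_amplitude: float = 6.0
    diurnal_range: float = 10.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.lat_range[0] < self.lat_range[1]:
            raise ValueError("lat_range must be increasing")
        if not self.lon_range[0] < self.lon_range[1]:
            raise ValueError("lon_range must be increasing")


@dataclass(frozen=True)
class SyntheticPhenologySpec:
    """Thermal profile of the synthetic insect.

    ``survival_at_optimum`` is the daily immature survival at the optimum
    (mortality curves bottom out at 1 - survival_at_optimum); development and
    survival collapse outside [lower_threshold, upper_threshold].
    """

    lower_threshold: float = 10.0
    optimum: float = 22.5
    upper_threshold: float = 35.0
    peak_daily_rate: float = 0.22
    peak_fecundity: float = 120.0
    survival_at_optimum: float = 0.98
    seed: int = 0

    def validate(self):
        if not self.lower_threshold < self.optimum < self.upper_threshold:
            raise ValueError("thresholds must satisfy lower < optimum < upper")
        if not 0.0 < self.survival_at_optimum <= 1.0:
            raise ValueError("survival_at_optimum must be in (0, 1]")
        if self.peak_daily_rate <= 0 or self.peak_fecundity <= 0:
            raise ValueError("peak rate and fecundity must be positive")


def gen_temperature_grid(spec: SyntheticGridSpec) -> TemperatureGrid:
    """Generate 12 monthly min and 12 monthly max layers."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cellsize = (spec.lat_range[1] - spec.lat_range[0]) / spec.n_rows
    # array row 0 is the top (northernmost) row, per the raster convention
    lat = spec.lat_range[1] - (np.arange(spec.n_rows) + 0.5) * cellsize
    months = np.arange(12)
    # seasonal phase: peak at mid-July (month index 6) for lat >= 0, mid-January
    # (index 0) south of the equator; cos(2*pi*m/12) peaks at m=0, and
    # cos(2*pi*(m-6)/12) = -cos(2*pi*m/12)
    hemis = np.where(lat < 0.0, 1.0, -1.0)
    seasonal = (spec.seasonal_amplitude
                * hemis[None, :] * np.cos(2.0 * np.pi * months / 12.0)[:, None])
    base = (spec.mean_annual_temp_at_equator
            - spec.lapse_per_degree_lat * np.abs(lat))[None, :]
    mean = (base + seasonal)[:, :, None] * np.ones((1, 1, spec.n_cols))
    if spec.noise_sd > 0:
        mean = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    half = spec.diurnal_range / 2.0
    return TemperatureGrid(tmin=mean - half, tmax=mean + half,
                           xllcorner=spec.lon_range[0],
                           yllcorner=spec.lat_range[0],
                           cellsize=cellsize)


def _tuned_sharpe_rate(optimum: float, lower: float, upper: float,
                       peak_rate: float) -> FunctionSpec:
    """Sharpe-DeMichele spec whose rate peaks at ``optimum`` with value
    ``peak_rate``; the high-temperature inactivation midpoint is adjusted
    iteratively until the argmax lands on the optimum."""
    params = {"rho25": 0.1, "HA": 15000.0, "HL": -150000.0,
              "TL": lower + 273.15, "HH": 150000.0, "TH": optimum + 275.15}
    grid = np.arange(lower + 0.05, upper, 0.05)
    spec = None
    for _ in range(40):
        spec = FunctionSpec("sharpe_demichele_1", dict(params),
                            temp_domain=(lower, upper))
        vals = evaluate_rate(spec, grid)
        shift = optimum - grid[int(np.argmax(vals))]
        if abs(shift) < 0.02:
            break
        params["TH"] += shift
    peak = float(np.max(evaluate_rate(spec, grid)))
    params["rho25"] *= peak_rate / peak
    return FunctionSpec("sharpe_demichele_1", params, temp_domain=(lower, upper))


def gen_phenology_model(spec: SyntheticPhenologySpec) -> PhenologyModel:
    """Build a complete phenology model matching the requested thermal profile.

    Egg and larval development rates use the Sharpe-DeMichele family tuned to
    peak at the optimum; the pupal rate uses Briere-1 anchored at the two
    thresholds. Mortality is Wang-type U-shaped, minimal at the optimum,
    saturating at the thresholds. Development-time distributions are CLL
    (egg, pupa, adults) and logit (larva) with the median at normalized age 1.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    jitter = lambda: float(rng.lognormal(0.0, 0.02))
    lo, opt, hi = spec.lower_threshold, spec.optimum, spec.upper_threshold
    m_min = 1.0 - spec.survival_at_optimum
    # shape exponent 3 gives a flat survival plateau around the optimum with
    # steep walls; B places daily mortality at ~0.999 at the nearer threshold
    k_shape = 3.0
    b_width = min(opt - lo, hi - opt) / (math.log(1000.0) ** (1.0 / (2 * k_shape)))

    def mortality():
        return FunctionSpec("wang_mortality_1",
                            {"m_min": m_min, "T_opt": opt, "B": b_width,
                             "k": k_shape},
                            temp_domain=(lo, hi))

    def devtime(family):
        a = _CLL_MEDIAN_AT_ONE if family == "cll_devtime" else 0.0
        return FunctionSpec(family, {"a": a, "b": 10.0})

    stages = []
    for stage_name, dist_family in (("egg", "cll_devtime"),
                                    ("larva", "logit_devtime")):
        rate = _tuned_sharpe_rate(opt, lo, hi,
                                  spec.peak_daily_rate
                                  * _STAGE_SPEED[stage_name] * jitter())
        stages.append(StageModel(stage_name, devtime(dist_family),
                                 dev_rate=rate, mortality=mortality()))

    # Briere-1 peak rate at T* = (4 T_U + 3 T_L + sqrt((4T_U+3T_L)^2 - 40 T_L T_U)) / 10
    a0 = 1e-4
    briere = FunctionSpec("briere_1", {"a": a0, "T_L": lo, "T_U": hi},
                          temp_domain=(lo, hi))
    tgrid = np.arange(lo + 0.05, hi, 0.05)
    peak = float(np.max(evaluate_rate(briere, tgrid)))
    a_pupa = a0 * spec.peak_daily_rate * _STAGE_SPEED["pupa"] * jitter() / peak
    stages.append(StageModel(
        "pupa", devtime("cll_devtime"),
        dev_rate=FunctionSpec("briere_1", {"a": a_pupa, "T_L": lo, "T_U": hi},
                              temp_domain=(lo, hi)),
        mortality=mortality()))

    # adult senescence: mean longevity ~18 days at the optimum, shorter when warm
    b_sen = 0.07
    for adult in ("adult_female", "adult_male"):
        a_sen = (1.0 / (18.0 * jitter())) / math.exp(b_sen * opt)
        stages.append(StageModel(
            adult, devtime("cll_devtime"),
            senescence=FunctionSpec("exp_simple_senescence",
                                    {"a": a_sen, "b": b_sen})))

    return PhenologyModel(
        stages=tuple(stages),
        fecundity_mean=FunctionSpec(
            "taylor_fecundity_1",
            {"F_max": spec.peak_fecundity, "T_opt": opt,
             "sigma": (hi - lo) / 6.0}),
        fecundity_cum=FunctionSpec("exp_modified_cumfec_3",
                                   {"gamma": 0.4, "theta": 2.0}),
        sex_ratio=0.5)


def gen_lifetable_observations(model: PhenologyModel,
                               temperatures: Sequence[float],
                               n_per_temp: int = 30,
                               noise_sd: float = 0.05,
                               seed: int = 0) -> pd.DataFrame:
    """Noisy constant-temperature life-table observations around the model.

    Per temperature and immature stage: ``dev_time`` replicates (days,
    multiplicative lognormal noise around 1/rate; NaN where development is
    impossible), ``survival`` fractions (binomial sampling of the daily
    survival 1 - m(T), mini-cohort size chosen so the sampling sd matches
    ``noise_sd`` at p = 0.5) and, once per temperature, ``fecundity``
    replicates (lognormal around the Taylor mean). Columns: stage,
    temperature_C, trait, value, replicate.
    """
    from .thermal import evaluate_fecundity, evaluate_mortality
    temperatures = list(temperatures)
    if not temperatures:
        raise ValueError("need at least one temperature")
    if n_per_temp < 1:
        raise ValueError("n_per_temp must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    cohort = max(1, int(round(0.25 / noise_sd ** 2))) if noise_sd > 0 else None
    rows = []

    def emit(stage, T, trait, values):
        for k, v in enumerate(values):
            rows.append((stage, float(T), trait, float(v), k))

    for T in temperatures:
        for stage in model.immatures:
            rate = float(evaluate_rate(stage.dev_rate, T))
            if rate > 1e-9:
                true_dt = 1.0 / rate
                noise = (rng.lognormal(0.0, noise_sd, n_per_temp)
                         if noise_sd > 0 else np.ones(n_per_temp))
                emit(stage.stage, T, "dev_time", true_dt * noise)
            else:
                emit(stage.stage, T, "dev_time", [np.nan] * n_per_temp)
            s = 1.0 - float(evaluate_mortality(stage.mortality, T))
            if noise_sd > 0:
                surv = rng.binomial(cohort, s, n_per_temp) / cohort
            else:
                surv = np.full(n_per_temp, s)
            emit(stage.stage, T, "survival", surv)
        fec = float(evaluate_fecundity(model.fecundity_mean, T))
        noise = (rng.lognormal(0.0, noise_sd, n_per_temp)
                 if noise_sd > 0 else np.ones(n_per_temp))
        emit("adult_female", T, "fecundity", fec * noise)

    return pd.DataFrame(rows, columns=["stage", "temperature_C", "trait",
                                       "value", "replicate"])


def rate_observations(obs: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Development-rate observations (1/dev_time) for one stage, for fitting."""
    sel = obs[(obs["stage"] == stage) & (obs["trait"] == "dev_time")].copy()
    sel["value"] = 1.0 / sel["value"]
    return sel.dropna(subset=["value"])
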