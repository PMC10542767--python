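"""Temperature-response function families for insect phenology models.

A phenology model describes an insect's whole life cycle as a set of
temperature-response curves: a development-rate curve and a mortality curve per
immature stage (egg, larva, pupa), a distribution of normalized development
times shared across temperatures, adult senescence, and female fecundity (mean
total eggs and the cumulative oviposition profile over normalized female age).

Each curve is a :class:`FunctionSpec` naming one of the registered families.
The registry isolates the algebraic forms behind a stable contract so that
alternative parameterizations of the same named family can be swapped in
without touching the life-table engine:

``briere_1``
    rate(T) = a * T * (T - T_L) * sqrt(T_U - T) on (T_L, T_U), else 0.
``sharpe_demichele_1``
    Sharpe & DeMichele / Schoolfield biophysical rate with low- and
    high-temperature enzyme inactivation (temperatures in Kelvin internally).
``wang_mortality_1``
    symmetric U-shaped daily mortality
    m(T) = 1 - (1 - m_min) * exp(-(((T - T_opt) / B)^2)^k), clipped to [0, 1];
    the shape exponent k >= 1 flattens the survival plateau around the optimum
    while keeping steep walls toward the thermal limits.
``taylor_fecundity_1``
    Gaussian mean lifetime fecundity F_max * exp(-0.5 ((T - T_opt)/sigma)^2).
``exp_simple_senescence``
    adult senescence rate a * exp(b * T) (per day).
``cll_devtime`` / ``logit_devtime``
    complementary log-log and logistic CDFs on the log of normalized
    (physiological) age: F(x) = 1 - exp(-exp(a + b ln x)) and
    F(x) = 1 / (1 + exp(-(a + b ln x))).
``exp_modified_cumfec_3``
    cumulative fraction of lifetime fecundity laid by normalized female age x:
    C(x) = 1 - exp(-(x / gamma)^theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

GAS_CONSTANT = 1.987  # cal / (mol K), conventional in biophysical rate models

IMMATURE_STAGES = ("egg", "larva", "pupa")
ADULT_STAGES = ("adult_female", "adult_male")
STAGE_ORDER = IMMATURE_STAGES + ADULT_STAGES

RATE_FAMILIES = frozenset({"briere_1", "sharpe_demichele_1"})
MORTALITY_FAMILIES = frozenset({"wang_mortality_1"})
DEVTIME_FAMILIES = frozenset({"cll_devtime", "logit_devtime"})
FECUNDITY_FAMILIES = frozenset({"taylor_fecundity_1"})
CUMFEC_FAMILIES = frozenset({"exp_modified_cumfec_3"})
SENESCENCE_FAMILIES = frozenset({"exp_simple_senescence"})


# ---------------------------------------------------------------------------
# family registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Family:
    name: str
    param_names: tuple
    kind: str  # rate | mortality | devtime | fecundity | cumfec | senescence
    evaluate: Callable  # (params: dict, x: ndarray) -> ndarray
    bounds: Callable  # (x, y) -> (lower list, upper list)
    init: Callable  # (x, y) -> list


def _briere(p, T):
    T = np.asarray(T, dtype=float)
    a, tl, tu = p["a"], p["T_L"], p["T_U"]
    out = np.zeros_like(T)
    mask = (T > tl) & (T < tu)
    if np.any(mask):
        out[mask] = a * T[mask] * (T[mask] - tl) * np.sqrt(tu - T[mask])
    return np.maximum(out, 0.0)


def _sharpe_demichele(p, T):
    T = np.asarray(T, dtype=float)
    K = T + 273.15
    R = GAS_CONSTANT
    with np.errstate(over="ignore", divide="ignore"):
        num = p["rho25"] * (K / 298.15) * np.exp(
            np.clip(p["HA"] / R * (1.0 / 298.15 - 1.0 / K), -700, 700))
        den = (1.0
               + np.exp(np.clip(p["HL"] / R * (1.0 / p["TL"] - 1.0 / K), -700, 700))
               + np.exp(np.clip(p["HH"] / R * (1.0 / p["TH"] - 1.0 / K), -700, 700)))
        out = num / den
    return np.where(np.isfinite(out), np.maximum(out, 0.0), 0.0)


def _wang(p, T):
    T = np.asarray(T, dtype=float)
    z2 = ((T - p["T_opt"]) / p["B"]) ** 2
    m = 1.0 - (1.0 - p["m_min"]) * np.exp(-np.power(z2, p["k"]))
    return np.clip(m, 0.0, 1.0)


def _taylor(p, T):
    T = np.asarray(T, dtype=float)
    z = (T - p["T_opt"]) / p["sigma"]
    return p["F_max"] * np.exp(-0.5 * z * z)


def _exp_simple(p, T):
    T = np.asarray(T, dtype=float)
    return p["a"] * np.exp(p["b"] * T)


def _cll(p, x):
    x = np.asarray(x, dtype=float)
    return 1.0 - np.exp(-np.exp(p["a"] + p["b"] * np.log(x)))


def _logit(p, x):
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-(p["a"] + p["b"] * np.log(x))))


def _cumfec(p, x):
    x = np.asarray(x, dtype=float)
    return 1.0 - np.exp(-np.power(np.maximum(x, 0.0) / p["gamma"], p["theta"]))


def _briere_init(x, y):
    pos = x[np.asarray(y) > 0]
    tl = float(pos.min() - 2.0) if pos.size else float(np.min(x) - 2.0)
    tu = float(np.max(x) + 2.0)
    ypk = float(np.max(y))
    tpk = float(x[int(np.argmax(y))])
    denom = max(tpk * max(tpk - tl, 1.0) * np.sqrt(max(tu - tpk, 0.5)), 1e-9)
    return [max(ypk / denom, 1e-8), tl, tu]


def _taylor_init(x, y):
    return [max(float(np.max(y)), 1e-6), float(x[int(np.argmax(y))]),
            max(float(np.ptp(x)) / 4.0, 1.0)]


def _wang_init(x, y):
    return [min(max(float(np.min(y)), 0.0), 0.99), float(x[int(np.argmin(y))]),
            max(float(np.ptp(x)) / 4.0, 1.0), 1.0]


def _exp_simple_init(x, y):
    y = np.maximum(np.asarray(y, dtype=float), 1e-12)
    b, lna = np.polyfit(x, np.log(y), 1)
    return [float(np.exp(lna)), float(b)]


def _loglinear_cdf_init(x, y, link):
    y = np.clip(np.asarray(y, dtype=float), 1e-6, 1.0 - 1e-6)
    z = link(y)
    b, a = np.polyfit(np.log(np.asarray(x, dtype=float)), z, 1)
    return [float(a), max(float(b), 1e-2)]


def _sharpe_init(x, y):
    tpk = float(x[int(np.argmax(y))])
    return [max(float(np.max(y)), 1e-6), 15000.0,
            -150000.0, float(np.min(x)) + 273.15,
            150000.0, tpk + 274.65]


FAMILIES = {
    "briere_1": Family(
        "briere_1", ("a", "T_L", "T_U"), "rate", _briere,
        lambda x, y: ([1e-12, -30.0, 0.0], [1.0, 40.0, 80.0]), _briere_init),
    "sharpe_demichele_1": Family(
        "sharpe_demichele_1", ("rho25", "HA", "HL", "TL", "HH", "TH"), "rate",
        _sharpe_demichele,
        lambda x, y: ([1e-9, 1e3, -1e6, 240.0, 1e3, 270.0],
                      [10.0, 1e5, -1e3, 320.0, 1e6, 340.0]),
        _sharpe_init),
    "wang_mortality_1": Family(
        "wang_mortality_1", ("m_min", "T_opt", "B", "k"), "mortality", _wang,
        lambda x, y: ([0.0, -10.0, 0.5, 0.5], [1.0, 60.0, 60.0, 6.0]),
        _wang_init),
    "taylor_fecundity_1": Family(
        "taylor_fecundity_1", ("F_max", "T_opt", "sigma"), "fecundity", _taylor,
        lambda x, y: ([0.0, -10.0, 0.1], [10.0 * max(float(np.max(y)), 1.0), 60.0, 50.0]),
        _taylor_init),
    "exp_simple_senescence": Family(
        "exp_simple_senescence", ("a", "b"), "senescence", _exp_simple,
        lambda x, y: ([1e-12, -1.0], [10.0, 1.0]), _exp_simple_init),
    "cll_devtime": Family(
        "cll_devtime", ("a", "b"), "devtime", _cll,
        lambda x, y: ([-50.0, 1e-3], [50.0, 100.0]),
        lambda x, y: _loglinear_cdf_init(x, y, lambda q: np.log(-np.log(1.0 - q)))),
    "logit_devtime": Family(
        "logit_devtime", ("a", "b"), "devtime", _logit,
        lambda x, y: ([-50.0, 1e-3], [50.0, 100.0]),
        lambda x, y: _loglinear_cdf_init(x, y, lambda q: np.log(q / (1.0 - q)))),
    "exp_modified_cumfec_3": Family(
        "exp_modified_cumfec_3", ("gamma", "theta"), "cumfec", _cumfec,
        lambda x, y: ([1e-3, 0.1], [10.0, 20.0]),
        lambda x, y: [0.5, 2.0]),
}


# ---------------------------------------------------------------------------
# specs and models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunctionSpec:
    """One named temperature-response curve with its parameters.

    ``temp_domain`` bounds the biologically valid temperature interval; outside
    it evaluation returns the family's boundary behaviour (rate/fecundity 0,
    mortality 1, senescence clamped) rather than raising.
    """

    family: str
    params: dict
    temp_domain: Optional[tuple] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown function family {self.family!r}")
        fam = FAMILIES[self.family]
        missing = set(fam.param_names) - set(self.params)
        extra = set(self.params) - set(fam.param_names)
        if missing or extra:
            raise ValueError(
                f"{self.family} expects params {fam.param_names}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}")
        if self.temp_domain is not None:
            lo, hi = self.temp_domain
            if not lo < hi:
                raise ValueError("temp_domain must be an increasing interval")

    @property
    def kind(self):
        return FAMILIES[self.family].kind

    def _raw(self, x):
        return FAMILIES[self.family].evaluate(self.params, x)

    def to_dict(self):
        d = {"family": self.family,
             "params": {k: float(v) for k, v in self.params.items()}}
        if self.temp_domain is not None:
            d["temp_domain"] = [float(self.temp_domain[0]), float(self.temp_domain[1])]
        return d

    @classmethod
    def from_dict(cls, d):
        dom = d.get("temp_domain")
        return cls(d["family"], dict(d["params"]),
                   tuple(dom) if dom is not None else None)


def _check_kind(spec: FunctionSpec, kinds, what: str):
    if spec.kind not in kinds:
        raise ValueError(f"{spec.family} is not a {what} family")


def _domain_mask(spec, T):
    if spec.temp_domain is None:
        return np.ones(np.shape(T), dtype=bool)
    lo, hi = spec.temp_domain
    T = np.asarray(T, dtype=float)
    return (T > lo) & (T < hi)


def evaluate_rate(spec: FunctionSpec, T):
    """Development rate (1/day) at temperature T; 0 outside the temp domain."""
    _check_kind(spec, {"rate"}, "development-rate")
    T = np.asarray(T, dtype=float)
    out = np.where(_domain_mask(spec, T), spec._raw(T), 0.0)
    return out if out.ndim else float(out)


def evaluate_mortality(spec: FunctionSpec, T):
    """Daily mortality probability at temperature T; 1 outside the temp domain."""
    _check_kind(spec, {"mortality"}, "mortality")
    T = np.asarray(T, dtype=float)
    out = np.where(_domain_mask(spec, T), spec._raw(T), 1.0)
    return out if out.ndim else float(out)


def evaluate_devtime_cdf(spec: FunctionSpec, x):
    """CDF of normalized (physiological) development age x > 0."""
    _check_kind(spec, {"devtime"}, "development-time distribution")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("normalized age must be > 0")
    out = spec._raw(x)
    return out if out.ndim else float(out)


def devtime_cdf_grid(spec: FunctionSpec, x):
    """Like :func:`evaluate_devtime_cdf` but maps x <= 0 to 0 (engine helper)."""
    _check_kind(spec, {"devtime"}, "development-time distribution")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = spec._raw(x[pos])
    return out


def evaluate_fecundity(spec: FunctionSpec, T):
    """Mean lifetime fecundity (eggs/female) at temperature T."""
    _check_kind(spec, {"fecundity"}, "fecundity")
    T = np.asarray(T, dtype=float)
    out = np.where(_domain_mask(spec, T), spec._raw(T), 0.0)
    return out if out.ndim else float(out)


def evaluate_cumulative_fecundity(spec: FunctionSpec, x):
    """Cumulative fraction of lifetime eggs laid by normalized female age x."""
    _check_kind(spec, {"cumfec"}, "cumulative-fecundity")
    out = spec._raw(np.asarray(x, dtype=float))
    return out if out.ndim else float(out)


def evaluate_senescence(spec: FunctionSpec, T):
    """Adult senescence rate (1/day) at temperature T (clamped to the domain)."""
    _check_kind(spec, {"senescence"}, "senescence")
    if spec.params["a"] <= 0:
        raise ValueError("senescence scale a must be > 0")
    T = np.asarray(T, dtype=float)
    if spec.temp_domain is not None:
        T = np.clip(T, *spec.temp_domain)
    out = spec._raw(T)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class StageModel:
    """Per-stage curves: immatures carry dev_rate + mortality, adults senescence.

    Every stage carries a normalized development-time (or longevity)
    distribution, CLL or logit on log normalized age.
    """

    stage: str
    devtime_dist: FunctionSpec
    dev_rate: Optional[FunctionSpec] = None
    mortality: Optional[FunctionSpec] = None
    senescence: Optional[FunctionSpec] = None

    def __post_init__(self):
        if self.stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage!r}")
        _check_kind(self.devtime_dist, {"devtime"}, "development-time distribution")
        if self.stage in IMMATURE_STAGES:
            if self.dev_rate is None or self.mortality is None:
                raise ValueError(f"immature stage {self.stage} needs dev_rate and mortality")
            _check_kind(self.dev_rate, {"rate"}, "development-rate")
            _check_kind(self.mortality, {"mortality"}, "mortality")
        else:
            if self.senescence is None:
                raise ValueError(f"adult stage {self.stage} needs a senescence curve")
            _check_kind(self.senescence, {"senescence"}, "senescence")

    def to_dict(self):
        d = {"stage": self.stage, "devtime_dist": self.devtime_dist.to_dict()}
        for name in ("dev_rate", "mortality", "senescence"):
            spec = getattr(self, name)
            if spec is not None:
                d[name] = spec.to_dict()
        return d

    @classmethod
    def from_dict(cls, d):
        kw = {"stage": d["stage"],
              "devtime_dist": FunctionSpec.from_dict(d["devtime_dist"])}
        for name in ("dev_rate", "mortality", "senescence"):
            if name in d:
                kw[name] = FunctionSpec.from_dict(d[name])
        return cls(**kw)


@dataclass(frozen=True)
class PhenologyModel:
    """Complete life-cycle model: ordered stages plus fecundity curves."""

    stages: tuple
    fecundity_mean: FunctionSpec
    fecundity_cum: FunctionSpec
    sex_ratio: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError("sex_ratio must be in (0, 1)")
        names = [s.stage for s in self.stages]
        expected = [s for s in STAGE_ORDER if s in names]
        if names != expected or not set(IMMATURE_STAGES) <= set(names):
            raise ValueError(
                f"stages must follow the fixed order egg->larva->pupa->adults, got {names}")
        if "adult_female" not in names:
            raise ValueError("model needs an adult_female stage")
        _check_kind(self.fecundity_mean, {"fecundity"}, "fecundity")
        _check_kind(self.fecundity_cum, {"cumfec"}, "cumulative-fecundity")

    def stage(self, name: str) -> StageModel:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(name)

    @property
    def immatures(self):
        return tuple(s for s in self.stages if s.stage in IMMATURE_STAGES)

    @property
    def adult_female(self) -> StageModel:
        return self.stage("adult_female")

    def to_dict(self):
        return {"stages": [s.to_dict() for s in self.stages],
                "fecundity_mean": self.fecundity_mean.to_dict(),
                "fecundity_cum": self.fecundity_cum.to_dict(),
                "sex_ratio": float(self.sex_ratio)}

    @classmethod
    def from_dict(cls, d):
        return cls(stages=tuple(StageModel.from_dict(s) for s in d["stages"]),
                   fecundity_mean=FunctionSpec.from_dict(d["fecundity_mean"]),
                   fecundity_cum=FunctionSpec.from_dict(d["fecundity_cum"]),
                   sex_ratio=float(d.get("sex_ratio", 0.5)))

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    spec: FunctionSpec
    rss: float
    converged: bool
    n_obs: int
    message: str = ""


def fit_function(family: str, observations, init: Optional[Sequence] = None,
                 temp_domain: Optional[tuple] = None, n_starts: int = 5,
                 seed: int = 0) -> FitResult:
    """Bounded nonlinear least-squares fit of one family to observations.

    ``observations`` is a DataFrame with a ``value`` column and either a
    ``temperature_C`` column (thermal families) or an ``x`` column (normalized
    age families). Multi-start (jittered initial points, fixed seed) guards
    against the local optima thermal curves are prone to. Non-convergence is
    flagged on the result, never raised.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown function family {family!r}")
    fam = FAMILIES[family]
    xcol = "temperature_C" if "temperature_C" in observations else "x"
    data = observations[[xcol, "value"]].dropna()
    x = data[xcol].to_numpy(dtype=float)
    y = data["value"].to_numpy(dtype=float)
    n_params = len(fam.param_names)
    if np.unique(x).size < n_params:
        raise ValueError(
            f"need >= {n_params} distinct {xcol} values to fit {family}, "
            f"got {np.unique(x).size}")

    lo, hi = fam.bounds(x, y)
    lo, hi = np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)
    p0 = np.clip(np.asarray(init if init is not None else fam.init(x, y),
                            dtype=float), lo + 1e-12, hi - 1e-12)

    def residuals(theta):
        params = dict(zip(fam.param_names, theta))
        pred = fam.evaluate(params, x)
        if fam.kind == "mortality":
            pred = np.clip(pred, 0.0, 1.0)
        return pred - y

    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_starts)):
        start = p0 if k == 0 else np.clip(
            p0 * rng.lognormal(0.0, 0.15, size=p0.size)
            + rng.normal(0.0, 0.5, size=p0.size),
            lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(residuals, start, bounds=(lo, hi))
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        spec = FunctionSpec(family, dict(zip(fam.param_names, p0)), temp_domain)
        return FitResult(spec, float(np.sum(residuals(p0) ** 2)), False,
                         x.size, "all starts failed")
    params = dict(zip(fam.param_names, (float(v) for v in best.x)))
    spec = FunctionSpec(family, params, temp_domain)
    return FitResult(spec, float(2.0 * best.cost), bool(best.success),
                     x.size, best.message)
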