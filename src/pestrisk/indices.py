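"""The three mapped risk indices: establishment (ERI), generation (GI),
activity (AI).

From a year of per-day life-table parameters:

* ERI = (number of survivable days / 365) * net-reproduction factor. A day is
  survivable when every immature stage's daily survival under that day's
  cycle exceeds a threshold (default 0.01); the net-reproduction factor is by
  default the indicator that the mean annual R0 reaches replacement (>= 1),
  keeping ERI a probability in [0, 1]. ERI > 0.6 is read as permanent
  establishment.
* GI = (sum over days of 365 / Tc_i) / 365 — the mean number of generations
  completable per year. Days where the population cannot replace itself
  (R0 <= 1, or no defined generation time) contribute 0.
* AI = log10 of the product of the daily finite growth rates lambda_i; +1
  means tenfold yearly growth, 4 means a 10,000-fold yearly increase. Lethal
  days (lambda = 0) are floored at a configurable lambda before the log so a
  single lethal day yields a strongly negative, finite index rather than -inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifetable import DailySeries

DAYS_PER_YEAR = 365

ERI_CLASS_LABELS = ("unsuitable", "marginal", "suitable", "highly_suitable",
                    "optimal")
ERI_CLASS_BOUNDS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
PERMANENT_ESTABLISHMENT_THRESHOLD = 0.6


@dataclass(frozen=True)
class RiskIndices:
    eri: float
    gi: float
    ai: float


@dataclass(frozen=True)
class EriClassification:
    label: str
    code: int
    permanent_establishment: bool


def _check_series(series: DailySeries):
    if len(series) != DAYS_PER_YEAR:
        raise ValueError("risk indices need a full 365-day series")


def survivable_days(series: DailySeries, survival_threshold: float = 0.01):
    """Boolean mask of days where every immature stage can survive."""
    _check_series(series)
    return np.asarray(series.min_immature_survival) > survival_threshold


def compute_eri(series: DailySeries, survival_threshold: float = 0.01,
                reproduction_rule: str = "indicator") -> float:
    """Establishment risk index in [0, 1]."""
    _check_series(series)
    frac = float(survivable_days(series, survival_threshold).sum()) / DAYS_PER_YEAR
    mean_r0 = float(np.mean(series.net_repro))
    if reproduction_rule == "indicator":
        factor = 1.0 if mean_r0 >= 1.0 else 0.0
    elif reproduction_rule == "capped":
        factor = min(1.0, mean_r0)
    else:
        raise ValueError(f"unknown reproduction_rule {reproduction_rule!r}")
    return frac * factor


def compute_gi(series: DailySeries) -> float:
    """Generation index (mean generations per year)."""
    _check_series(series)
    tc = series.gen_time
    r0 = series.net_repro
    valid = (r0 > 1.0) & np.isfinite(tc) & (tc > 0.0)
    contrib = np.where(valid, DAYS_PER_YEAR / np.where(valid, tc, 1.0), 0.0)
    return float(contrib.sum()) / DAYS_PER_YEAR


def compute_ai(series: DailySeries, lambda_floor: float = 1e-6) -> float:
    """Activity index: log10 of the yearly product of daily growth rates."""
    _check_series(series)
    lam = series.lambdas
    if np.any(lam < 0):
        raise ValueError("finite rates of increase must be >= 0")
    return float(np.sum(np.log10(np.maximum(lam, lambda_floor))))


def compute_indices(series: DailySeries, survival_threshold: float = 0.01,
                    reproduction_rule: str = "indicator",
                    lambda_floor: float = 1e-6) -> RiskIndices:
    return RiskIndices(
        eri=compute_eri(series, survival_threshold, reproduction_rule),
        gi=compute_gi(series),
        ai=compute_ai(series, lambda_floor))


def classify_eri(eri: float) -> EriClassification:
    """Five-class suitability scheme on half-open bins, top bin closed.

    [0,0.2) unsuitable, [0.2,0.4) marginal, [0.4,0.6) suitable,
    [0.6,0.8) highly_suitable, [0.8,1.0] optimal; establishment is permanent
    when ERI > 0.6.
    """
    if not 0.0 <= eri <= 1.0:
        raise ValueError(f"ERI must lie in [0, 1], got {eri}")
    code = 0
    for k, lower in enumerate(ERI_CLASS_BOUNDS[1:-1], start=1):
        if eri >= lower:
            code = k
    return EriClassification(ERI_CLASS_LABELS[code], code,
                             eri > PERMANENT_ESTABLISHMENT_THRESHOLD)
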