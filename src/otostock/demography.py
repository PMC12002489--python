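"""Age at maturity and natural mortality estimators.

Age at 50% maturity (A50) comes from a binomial-logit GLM of maturity
state on fractional age: P(mature | t) = logistic(b0 + b1*t), with
A50 = -b0/b1 and a percentile bootstrap CI over resampled individuals.

Natural mortality M (year^-1) is estimated two ways:

* from maximum age:        M = 4.899 * t_max^-0.916
* from length at age:      ln M = 0.55 - 1.61*ln(FL) + 1.44*ln(L_inf) + ln(K)

where FL is the VBGM-predicted fork length at the given age.  The
length-at-age form yields an age-declining mortality schedule typical of
tropical fishes in which juvenile predation dominates M.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .growth import GrowthFit, vbgm_predict

__all__ = [
    "MaturityOgive",
    "fit_maturity",
    "mortality_from_tmax",
    "mortality_at_age",
    "mortality_table",
    "MortalityEstimate",
]


@dataclass
class MaturityOgive:
    """Fitted logistic maturity-at-age ogive for one group."""

    beta0: float
    beta1: float
    a50: float
    ci: Optional[tuple[float, float]] = None
    n: int = 0
    B: int = 0
    seed: Optional[int] = None
    group: str = ""
    separation: bool = False
    n_failed: int = 0

    def predict(self, age) -> np.ndarray:
        age = np.asarray(age, float)
        return 1.0 / (1.0 + np.exp(-(self.beta0 + self.beta1 * age)))


def _is_separated(ages: np.ndarray, mature: np.ndarray) -> bool:
    """Complete separation on a single covariate: the classes do not
    overlap in age, so the MLE diverges."""
    return (ages[mature == 0].max() < ages[mature == 1].min()
            or ages[mature == 1].max() < ages[mature == 0].min())


def _logit_a50(ages: np.ndarray, mature: np.ndarray) -> tuple[float, float, float, bool]:
    X = sm.add_constant(ages)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(mature, X, family=sm.families.Binomial()).fit(maxiter=100)
    b0, b1 = float(res.params[0]), float(res.params[1])
    separated = _is_separated(ages, mature) or not np.isfinite(res.bse).all()
    a50 = -b0 / b1 if b1 != 0 else float("nan")
    return b0, b1, a50, separated


def fit_maturity(ages: Sequence[float], mature: Sequence[int],
                 B: int = 999, seed: int = 0, group: str = "",
                 level: float = 0.95) -> MaturityOgive:
    """Binomial-logit maturity ogive with percentile bootstrap CI on A50.

    Resamples individuals (age, maturity) jointly; replicates where the
    GLM cannot be fitted (e.g. a single class drawn) are dropped and
    counted.  Raises when only one maturity class is present.
    """
    ages = np.asarray(ages, float)
    mature = np.asarray(mature, int)
    if ages.size < 10:
        raise ValueError("need at least 10 individuals")
    if mature.min() == mature.max():
        raise ValueError("single class: both immature and mature fish required")

    b0, b1, a50, separated = _logit_a50(ages, mature)
    if separated:
        # complete separation: report the boundary midpoint with a warning
        lo = ages[mature == 0].max()
        hi = ages[mature == 1].min()
        if lo < hi:
            a50 = (lo + hi) / 2.0
        warnings.warn("complete separation detected; A50 from boundary midpoint",
                      RuntimeWarning, stacklevel=2)

    rng = np.random.default_rng(seed)
    draws = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, ages.size, ages.size)
        m = mature[idx]
        if m.min() == m.max():
            n_failed += 1
            continue
        try:
            _, _, a50_b, sep_b = _logit_a50(ages[idx], m)
        except Exception:
            n_failed += 1
            continue
        if np.isfinite(a50_b) and not sep_b:
            draws.append(a50_b)
        else:
            n_failed += 1
    ci = None
    if draws:
        alpha = (1 - level) / 2
        lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
        ci = (float(lo), float(hi))
    return MaturityOgive(beta0=b0, beta1=b1, a50=float(a50), ci=ci,
                         n=int(ages.size), B=B, seed=seed, group=group,
                         separation=separated, n_failed=n_failed)


@dataclass
class MortalityEstimate:
    method: str       # "max_age" | "length_at_age"
    M: float          # year^-1
    inputs: dict = field(default_factory=dict)


def mortality_from_tmax(t_max: float) -> float:
    """Maximum-age natural mortality M = 4.899 * t_max^-0.916."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    return 4.899 * t_max ** -0.916


def mortality_at_age(age: float, fit: GrowthFit) -> float:
    """Length-at-age natural mortality at a given age.

    FL is the VBGM-predicted fork length at ``age``;
    M = exp(0.55 - 1.61*ln(FL) + 1.44*ln(L_inf) + ln(K)).  Strictly
    decreasing in age for a fixed fit.
    """
    fl = float(vbgm_predict(fit.linf, fit.k, fit.t0, age))
    if fl <= 0:
        raise ValueError(f"non-positive predicted fork length at age {age}")
    return math.exp(0.55 - 1.61 * math.log(fl)
                    + 1.44 * math.log(fit.linf) + math.log(fit.k))


def mortality_table(fit: GrowthFit, ages: Sequence[float]) -> pd.DataFrame:
    """Length-at-age mortality schedule over an age ladder."""
    rows = []
    for a in ages:
        fl = float(vbgm_predict(fit.linf, fit.k, fit.t0, a))
        if fl <= 0:
            continue
        rows.append({"group": fit.group, "age": float(a), "fl_cm": fl,
                     "M": mortality_at_age(a, fit)})
    return pd.DataFrame(rows)
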