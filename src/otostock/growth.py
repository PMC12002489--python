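"""Von Bertalanffy growth modelling and hierarchical group comparison.

The von Bertalanffy growth model (VBGM) describes mean length at age as

    E[L | t] = L_inf * (1 - exp(-K * (t - t0)))

with L_inf the asymptotic mean fork length (cm), K the rate at which the
asymptote is approached (year^-1) and t0 the hypothetical age at zero
length (the x-intercept).  Fits are nonlinear least squares with Gaussian
additive error of constant variance; the Gaussian log-likelihood with
profiled variance,

    logL = -(n/2) * (ln(2*pi) + ln(RSS/n) + 1),

makes nested models comparable by likelihood ratio.

Comparing g groups (sexes or fishing sites) uses the classical lattice of
up to eight curves: the coincident model (all three parameters shared,
3 parameters), three models letting one parameter differ, three letting
two differ, and the fully distinct model (3*g parameters).  Each nested
pair is tested with chi^2 = 2*(logL_full - logL_reduced) on df equal to
the parameter-count difference, walking hierarchically from the most
complex model toward the coincident curve and keeping the more
parsimonious model whenever the test is non-significant.

Derived quantities: growth performance PHI' = log10(K) + 2*log10(L_inf)
(comparable across populations of a species) and lifespan
t_max = 3/K + t0 (age at ~95% of L_inf).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "vbgm_predict",
    "GrowthFit",
    "FitError",
    "fit_vbgm",
    "gaussian_loglik",
    "bootstrap_ci",
    "GroupedFit",
    "ModelLattice",
    "compare_growth",
    "growth_performance",
    "lifespan",
    "LifeHistorySummary",
    "life_history_summary",
    "PARAMS",
]

PARAMS = ("linf", "k", "t0")


def vbgm_predict(linf: float, k: float, t0: float, age) -> np.ndarray | float:
    """Mean length at age under the VBGM; defined for all real ages.

    Negative predictions (ages far below t0) are returned as-is; callers
    that cannot accept them must check.
    """
    age = np.asarray(age, dtype=float)
    out = linf * (1.0 - np.exp(-k * (age - t0)))
    return out if out.ndim else float(out)


def gaussian_loglik(rss: float, n: int) -> float:
    """Gaussian log-likelihood with the variance profiled out at RSS/n."""
    if n <= 0 or rss <= 0:
        raise ValueError("need n > 0 and RSS > 0")
    return -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)


class FitError(RuntimeError):
    """Nonlinear fit failed after all restarts; carries diagnostics."""


@dataclass
class GrowthFit:
    """A fitted VBGM for one group of fish."""

    linf: float
    k: float
    t0: float
    n: int
    rss: float
    loglik: float
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)   # bootstrap percentile CIs
    group: str = ""
    converged: bool = True
    n_restarts: int = 0

    @property
    def df(self) -> int:
        return self.n - 3

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.linf, self.k, self.t0)

    def predict(self, age) -> np.ndarray | float:
        return vbgm_predict(self.linf, self.k, self.t0, age)


def _default_start(ages: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    return np.array([1.1 * lengths.max(), 0.2, -1.0])


def _residuals(theta: np.ndarray, ages: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    linf, k, t0 = theta
    return lengths - linf * (1.0 - np.exp(-k * (ages - t0)))


def _jac(theta: np.ndarray, ages: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    linf, k, t0 = theta
    e = np.exp(-k * (ages - t0))
    return -np.column_stack([1.0 - e, linf * (ages - t0) * e, -linf * k * e])


def fit_vbgm(ages: Sequence[float], lengths: Sequence[float],
             start: Optional[Sequence[float]] = None,
             group: str = "", max_restarts: int = 5,
             rng: Optional[np.random.Generator] = None) -> GrowthFit:
    """Least-squares VBGM fit with multi-start restarts.

    The VBGM surface is flat along the L_inf/K ridge, so a failed or
    degenerate first fit is retried from up to ``max_restarts`` jittered
    starting points before raising :class:`FitError`.  Default start:
    L_inf = 1.1 * max length, K = 0.2, t0 = -1.
    """
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    n = ages.size
    if n < 4:
        raise ValueError("need at least 4 (age, length) pairs")
    if np.unique(ages).size < 3:
        raise ValueError("degenerate design: need at least 3 distinct ages")
    rng = rng or np.random.default_rng(0)
    x0 = np.asarray(start, float) if start is not None else _default_start(ages, lengths)
    lb = np.array([1e-6, 1e-6, -np.inf])
    ub = np.array([np.inf, np.inf, np.inf])

    best = None
    last_err = None
    for attempt in range(max_restarts + 1):
        xa = x0 if attempt == 0 else x0 * np.exp(rng.normal(0, 0.2, 3))
        if attempt:
            xa[2] = x0[2] + rng.normal(0, 1.0)
        xa = np.clip(xa, lb + 1e-9, None)
        try:
            sol = optimize.least_squares(
                _residuals, xa, jac=_jac, args=(ages, lengths),
                bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as exc:  # pragma: no cover - scipy-internal failures
            last_err = exc
            continue
        if not sol.success:
            last_err = RuntimeError(sol.message)
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol, attempt)
            if attempt == 0:
                break  # first start converged; accept it

    if best is None:
        raise FitError(f"VBGM fit failed after {max_restarts} restarts: {last_err}")
    rss, sol, n_restarts = best
    linf, k, t0 = sol.x

    # asymptotic SEs from the Jacobian at the solution
    se = {}
    try:
        dof = n - 3
        if dof > 0 and rss > 0:
            JTJ = sol.jac.T @ sol.jac
            cov = np.linalg.inv(JTJ) * (rss / dof)
            sd = np.sqrt(np.clip(np.diag(cov), 0, None))
            se = dict(zip(PARAMS, map(float, sd)))
    except np.linalg.LinAlgError:
        pass

    loglik = gaussian_loglik(rss, n) if rss > 0 else float("inf")
    return GrowthFit(linf=float(linf), k=float(k), t0=float(t0), n=n,
                     rss=rss, loglik=loglik, se=se, group=group,
                     converged=True, n_restarts=n_restarts)


def bootstrap_ci(ages: Sequence[float], lengths: Sequence[float],
                 B: int = 9999, seed: int = 0, level: float = 0.95,
                 strict: bool = False, group: str = "") -> dict:
    """Percentile bootstrap CIs for the VBGM parameters.

    Resamples (age, length) pairs with replacement and refits; replicates
    that fail to converge are dropped and counted.  With ``strict`` a
    non-convergence fraction above 20% raises instead of warning.
    Deterministic for a fixed seed.
    """
    if B < 100:
        raise ValueError("need B >= 100 bootstrap iterations")
    ages = np.asarray(ages, float)
    lengths = np.asarray(lengths, float)
    n = ages.size
    rng = np.random.default_rng(seed)
    point = fit_vbgm(ages, lengths, group=group)
    draws = np.empty((B, 3))
    n_failed = 0
    start = np.array(point.params)
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            fb = fit_vbgm(ages[idx], lengths[idx], start=start, max_restarts=2,
                          rng=rng)
            draws[b] = fb.params
        except (FitError, ValueError):
            draws[b] = np.nan
            n_failed += 1
    frac_failed = n_failed / B
    if frac_failed > 0.20:
        msg = f"{frac_failed:.0%} of bootstrap replicates failed to converge"
        if strict:
            raise FitError(msg)
        import warnings
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    alpha = (1 - level) / 2
    lo, hi = np.nanpercentile(draws, [100 * alpha, 100 * (1 - alpha)], axis=0)
    cis = {p: (float(lo[i]), float(hi[i])) for i, p in enumerate(PARAMS)}
    return {"point": point, "ci": cis, "B": B, "n_failed": n_failed, "seed": seed}


# ---------------------------------------------------------------------------
# hierarchical comparison of growth curves across groups

#: the eight models, keyed by the frozenset of parameters that DIFFER
#: among groups; the empty set is the coincident curve.
MODEL_KEYS: tuple[frozenset, ...] = tuple(
    frozenset(c) for r in range(4) for c in itertools.combinations(PARAMS, r))


def _model_label(key: frozenset) -> str:
    if not key:
        return "coincident"
    return "{" + ",".join(p for p in PARAMS if p in key) + "} differ"


@dataclass
class GroupedFit:
    """One member of the model lattice: which parameters vary by group."""

    varying: frozenset
    params: dict            # group -> (linf, k, t0); coincident stores one entry "*"
    m: int                  # parameter count
    n: int
    rss: float
    loglik: float
    converged: bool = True

    @property
    def label(self) -> str:
        return _model_label(self.varying)


def _pack(shared: dict, per_group: dict, groups: Sequence[str],
          varying: frozenset) -> np.ndarray:
    vec = []
    for p in PARAMS:
        if p in varying:
            vec.extend(per_group[g][p] for g in groups)
        else:
            vec.append(shared[p])
    return np.asarray(vec, float)


def _unpack(theta: np.ndarray, groups: Sequence[str], varying: frozenset) -> dict:
    out = {g: {} for g in groups}
    i = 0
    for p in PARAMS:
        if p in varying:
            for g in groups:
                out[g][p] = theta[i]
                i += 1
        else:
            for g in groups:
                out[g][p] = theta[i]
            i += 1
    return out


def _fit_lattice_member(data: pd.DataFrame, groups: Sequence[str],
                        varying: frozenset, group_fits: dict,
                        pooled: GrowthFit) -> GroupedFit:
    """Fit one lattice member by shared-parameter least squares."""
    n = len(data)
    g = len(groups)
    m = sum(g if p in varying else 1 for p in PARAMS)

    if len(varying) == 3:
        # fully distinct model decomposes into independent per-group fits
        rss = sum(group_fits[gr].rss for gr in groups)
        params = {gr: dict(zip(PARAMS, group_fits[gr].params)) for gr in groups}
        return GroupedFit(varying=varying, params=params, m=m, n=n, rss=rss,
                          loglik=gaussian_loglik(rss, n))
    if not varying:
        params = {"*": dict(zip(PARAMS, pooled.params))}
        return GroupedFit(varying=varying, params=params, m=m, n=n,
                          rss=pooled.rss, loglik=pooled.loglik)

    shared0 = dict(zip(PARAMS, pooled.params))
    per0 = {gr: dict(zip(PARAMS, group_fits[gr].params)) for gr in groups}
    x0 = _pack(shared0, per0, groups, varying)

    ages = data["age"].to_numpy(float)
    lengths = data["length"].to_numpy(float)
    gidx = {gr: (data["group"] == gr).to_numpy() for gr in groups}

    def resid(theta):
        p = _unpack(theta, groups, varying)
        r = np.empty(n)
        for gr in groups:
            mask = gidx[gr]
            r[mask] = lengths[mask] - vbgm_predict(
                p[gr]["linf"], p[gr]["k"], p[gr]["t0"], ages[mask])
        return r

    sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
    rss = float(2 * sol.cost)
    params = {gr: {p: float(v) for p, v in d.items()}
              for gr, d in _unpack(sol.x, groups, varying).items()}
    return GroupedFit(varying=varying, params=params, m=m, n=n, rss=rss,
                      loglik=gaussian_loglik(rss, n), converged=bool(sol.success))


def _lrt(full: GroupedFit, reduced: GroupedFit) -> tuple[float, int, float]:
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.m - reduced.m
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return chi2, df, p


@dataclass
class ModelLattice:
    """The fitted model lattice plus the hierarchical selection walk."""

    fits: dict                   # frozenset -> GroupedFit
    comparisons: pd.DataFrame    # full label, reduced label, chi2, df, p
    selected: frozenset
    alpha: float
    partial: bool = False

    @property
    def selected_fit(self) -> GroupedFit:
        return self.fits[self.selected]

    def table(self) -> pd.DataFrame:
        rows = []
        for key in MODEL_KEYS:
            f = self.fits.get(key)
            if f is None:
                continue
            rows.append({"model": f.label, "m": f.m, "df": f.n - f.m,
                         "rss": f.rss, "loglik": f.loglik,
                         "selected": key == self.selected})
        return pd.DataFrame(rows)


def compare_growth(data: pd.DataFrame, factor: str = "group",
                   alpha: float = 0.05) -> ModelLattice:
    """Fit the 8-curve lattice over a grouping factor and select a model.

    ``data`` needs columns ``age``, ``length`` and the factor column.
    Selection walks hierarchically: the fully distinct model is first
    tested against the coincident curve; if distinguishable, it is
    compared with the three two-parameters-differ models, keeping the
    more parsimonious whenever P > alpha and breaking ties by highest
    log-likelihood; the walk then descends to the one-parameter models
    and finally confirms against the coincident curve.  The selection is
    invariant to group-label permutation.
    """
    df = data.rename(columns={factor: "group"})[["age", "length", "group"]].dropna()
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare growth curves")

    group_fits = {}
    partial = False
    for gr in groups:
        sub = df[df["group"] == gr]
        try:
            group_fits[gr] = fit_vbgm(sub["age"], sub["length"], group=str(gr))
        except (FitError, ValueError) as exc:
            partial = True
            raise FitError(f"group {gr!r} not fittable: {exc}") from exc
    pooled = fit_vbgm(df["age"], df["length"], group="pooled")

    fits = {key: _fit_lattice_member(df, groups, key, group_fits, pooled)
            for key in MODEL_KEYS}

    full_key = frozenset(PARAMS)
    comparisons = []

    def record(fk, rk):
        chi2, ddf, p = _lrt(fits[fk], fits[rk])
        comparisons.append({
            "full": fits[fk].label, "reduced": fits[rk].label,
            "chi2": chi2, "df": ddf, "p": p})
        return p

    # step 0: fully distinct vs coincident
    p0 = record(full_key, frozenset())
    if p0 > alpha:
        selected = frozenset()
    else:
        current = full_key
        while len(current) > 1:
            children = [k for k in MODEL_KEYS
                        if len(k) == len(current) - 1 and k < current]
            keep = []
            for child in children:
                p = record(current, child)
                if p > alpha:
                    keep.append(child)
            if not keep:
                break
            current = max(keep, key=lambda k: fits[k].loglik)
        selected = current
        if selected != full_key:
            # confirm the simplification against the coincident curve
            p_conf = record(selected, frozenset())
            if p_conf > alpha:
                selected = frozenset()

    return ModelLattice(fits=fits, comparisons=pd.DataFrame(comparisons),
                        selected=selected, alpha=alpha, partial=partial)


# ---------------------------------------------------------------------------
# derived growth quantities

def growth_performance(k: float, linf: float) -> float:
    """Growth performance index PHI' = log10(K) + 2*log10(L_inf)."""
    if k <= 0 or linf <= 0:
        raise ValueError("K and L_inf must be positive")
    return math.log10(k) + 2.0 * math.log10(linf)


def lifespan(k: float, t0: float) -> float:
    """Lifespan t_max = 3/K + t0, the age at ~95% of L_inf."""
    if k <= 0:
        raise ValueError("K must be positive")
    return 3.0 / k + t0


@dataclass
class LifeHistorySummary:
    group: str
    phi_prime: float
    t_max: float


def life_history_summary(fits: Sequence[GrowthFit]) -> pd.DataFrame:
    """PHI' and t_max per fitted group, unrounded."""
    rows = [{"group": f.group,
             "phi_prime": growth_performance(f.k, f.linf),
             "t_max": lifespan(f.k, f.t0)} for f in fits]
    return pd.DataFrame(rows)
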