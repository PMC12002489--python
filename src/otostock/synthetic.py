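"""Synthetic population generator emulating the study's individual-level data.

Generates linked fish records, otolith readings and shape tables with
the statistical structure the analysis assumes, so every pipeline stage
is testable without the original spreadsheet supplements:

* site-stratified age compositions shaped like the published age-length
  key margins;
* fork length at age from the per-site von Bertalanffy truth plus
  Gaussian noise (truncated positive);
* maturity as Bernoulli draws from a logistic ogive on age, per sex;
* annulus radii from a monotone saturating radius-at-age map, with the
  edge increment driven by time since the annual deposition window so
  the marginal-increment series bottoms out in that window;
* shape variables following power-law allometry a * FL^b with
  site-specific multipliers and multiplicative lognormal noise
  (percentage indices via a logistic-normal model).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    PERCENT_VARS,
    FishRecord,
    OtolithReading,
    ShapeTable,
)
from .growth import vbgm_predict

__all__ = [
    "ShapeVarModel",
    "SiteConfig",
    "PopulationConfig",
    "default_config",
    "generate_population",
    "SimPopulation",
    "fixture_from_age_length_key",
]

STUDY_WINDOW = (dt.date(2008, 1, 1), dt.date(2009, 12, 31))


@dataclass
class ShapeVarModel:
    """Allometric model for one shape variable: V = a * FL^b * site_mult * noise.

    Percentage indices instead follow a logistic-normal model around
    ``pct_mean`` with an optional log-length slope and site shifts on
    the logit scale.
    """

    a: float = 1.0
    b: float = 0.0
    site_mult: dict = field(default_factory=dict)   # site -> multiplier
    cv: float = 0.10
    factor: Optional[str] = None                    # latent factor name, if any
    loading: float = 0.0                            # log-scale loading on factor
    pct_mean: Optional[float] = None                # percent scale, for % indices
    pct_site_shift: dict = field(default_factory=dict)
    pct_fl_slope: float = 0.0
    pct_sd: float = 0.2


@dataclass
class SiteConfig:
    """Per-site truth: growth curve, age composition, sample size."""

    vbgm: tuple[float, float, float]    # (L_inf cm, K /yr, t0 yr)
    age_weights: np.ndarray             # over age classes 0..12
    n: int


@dataclass
class PopulationConfig:
    sites: dict                          # site name -> SiteConfig
    length_noise_sd: float = 1.5         # cm, additive Gaussian
    maturity: dict = field(default_factory=lambda: {
        # (beta0, beta1) on the logit scale; A50 = -beta0/beta1
        "female": (-4.55, 3.5),          # A50 = 1.3 yr
        "male": (-2.80, 3.5),            # A50 = 0.8 yr
    })
    deposition_window: tuple[int, ...] = (7, 8, 9)
    # otolith radius-at-age map R(t) = r_inf * (1 - exp(-kr*(t - t0r))), mm
    radius_model: tuple[float, float, float] = (4.0, 0.25, -1.0)
    shape_vars: dict = field(default_factory=dict)  # name -> ShapeVarModel
    factor_site_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _FACTOR_SITE_MEANS.items()})
    reader_disagree_rate: float = 0.08
    auto_disagree_rate: float = 0.12
    discordance_unresolved_rate: float = 0.0
    broken_rate: float = 0.0
    illegible_rate: float = 0.0
    study_window: tuple[dt.date, dt.date] = STUDY_WINDOW

    def validate(self) -> None:
        for name, sc in self.sites.items():
            w = np.asarray(sc.age_weights, float)
            if w.sum() <= 0 or np.any(w < 0):
                raise ValueError(f"config error: invalid age weights for {name}")
            linf, k, t0 = sc.vbgm
            if linf <= 0 or k <= 0:
                raise ValueError(f"config error: non-positive growth scale for {name}")
            if sc.n <= 0:
                raise ValueError(f"config error: non-positive sample size for {name}")


# age-composition margins of the published site keys (ages 0..12)
_SITE_AGE_COUNTS = {
    "celestun": [9, 13, 213, 76, 17, 4, 3, 1, 0, 2, 0, 0, 0],
    "dzilam": [0, 1, 53, 82, 46, 70, 47, 23, 10, 33, 10, 11, 5],
    "rio_lagartos": [0, 0, 65, 125, 51, 60, 28, 13, 6, 20, 11, 14, 2],
}
_SITE_VBGM = {
    "celestun": (41.59, 0.11, -4.86),
    "dzilam": (38.36, 0.16, -3.25),
    "rio_lagartos": (40.28, 0.12, -4.99),
}
_SITE_N = {"celestun": 338, "dzilam": 391, "rio_lagartos": 395}


#: site-level means of the two latent shape factors (residual SD is 1);
#: factor "size" drives the bulky-otolith variable family, factor
#: "roundness" the outline-regularity family
_FACTOR_SITE_MEANS = {
    "size": {"celestun": -0.9, "dzilam": 0.3, "rio_lagartos": 0.6},
    "roundness": {"celestun": 0.0, "dzilam": 0.7, "rio_lagartos": -0.7},
}


def _default_shape_vars() -> dict:
    """Shape-variable truth covering the three ANCOVA outcomes.

    The seven variables that track length only carry the published
    common-slope values; variables confounded with site get distinct
    per-site multipliers on top of a length effect; the remaining
    variables are length-independent but share latent shape factors
    whose means differ by site — the structure that lets the surviving
    variables discriminate sites in the ordination.
    """
    mult = {"celestun": 0.88, "dzilam": 1.02, "rio_lagartos": 1.10}
    flat = {"celestun": 1.0, "dzilam": 1.0, "rio_lagartos": 1.0}
    sv: dict[str, ShapeVarModel] = {}
    # corrected group: length-only allometry, common slope across sites
    for name, a, b in [("A", 0.05, 1.4235), ("MaxD", 2.0, 0.1767),
                       ("P", 3.0, 0.5842), ("R", 1.15, 0.0102),
                       ("E", 2.5, 0.4316), ("Fi", 1.30, 0.0008),
                       ("Osl", 1.5, 0.0708)]:
        sv[name] = ShapeVarModel(a=a, b=b, site_mult=dict(flat), cv=0.10)
    # removed group: length effect plus site-specific level
    for name, a, b in [("MinD", 0.8, 0.8), ("Rw", 0.25, 0.6), ("EA", 0.02, 1.2),
                       ("AAs", 0.9, 0.3), ("SAl", 0.7, 0.9), ("OsA", 0.01, 1.6),
                       ("Cl", 0.5, 0.9)]:
        sv[name] = ShapeVarModel(a=a, b=b, site_mult=dict(mult), cv=0.10)
    # kept group: no length effect; latent-factor structure with site means
    for name, a in [("Rl", 1.2), ("Al", 0.6), ("Aw", 0.3),
                    ("SAA", 4.5), ("CA", 2.2)]:
        sv[name] = ShapeVarModel(a=a, b=0.0, site_mult=dict(flat), cv=0.05,
                                 factor="size", loading=0.25)
    for name, a in [("RE", 0.7), ("As", 1.8), ("RAs", 0.5)]:
        sv[name] = ShapeVarModel(a=a, b=0.0, site_mult=dict(flat), cv=0.05,
                                 factor="roundness", loading=0.25)
    # percentage indices (logistic-normal)
    sv["OsA_SAA"] = ShapeVarModel(pct_mean=60.0, pct_site_shift={}, pct_fl_slope=0.0)
    sv["Osl_SAl"] = ShapeVarModel(
        pct_mean=45.0,
        pct_site_shift={"celestun": -0.25, "dzilam": 0.0, "rio_lagartos": 0.25},
        pct_fl_slope=0.6)
    return sv


def default_config() -> PopulationConfig:
    """The default study conditions: published growth truth and age margins."""
    sites = {
        name: SiteConfig(vbgm=_SITE_VBGM[name],
                         age_weights=np.asarray(_SITE_AGE_COUNTS[name], float)
                         / sum(_SITE_AGE_COUNTS[name]),
                         n=_SITE_N[name])
        for name in _SITE_VBGM
    }
    return PopulationConfig(sites=sites, shape_vars=_default_shape_vars())


@dataclass
class SimPopulation:
    """Generated population with its flat-table view and the truth used."""

    fish: list
    readings: list
    shape: ShapeTable
    frame: pd.DataFrame       # merged flat table in the canonical CSV layout
    truth: pd.DataFrame       # per-fish latent values (true age, month, ...)
    config: PopulationConfig
    seed: int

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _random_dates(rng: np.random.Generator, n: int,
                  window: tuple[dt.date, dt.date]) -> list[dt.date]:
    lo, hi = window
    span = (hi - lo).days
    return [lo + dt.timedelta(days=int(d)) for d in rng.integers(0, span + 1, n)]


def _fraction_since_birthday(date: dt.date, birth=(5, 1)) -> float:
    bd = dt.date(date.year, *birth)
    if bd > date:
        bd = dt.date(date.year - 1, *birth)
    return (date - bd).days / 365.25


def _tau_since_deposition(date: dt.date, dep_month: int) -> float:
    """Fraction of a year elapsed since the middle of the deposition month."""
    dep = dt.date(date.year, dep_month, 15)
    if dep > date:
        dep = dt.date(date.year - 1, dep_month, 15)
    return (date - dep).days / 365.25


def generate_population(config: Optional[PopulationConfig] = None,
                        seed: int = 0) -> SimPopulation:
    """Draw a full linked dataset under the configured truth."""
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(seed)
    r_inf, kr, t0r = config.radius_model
    dep_mid = sorted(config.deposition_window)[len(config.deposition_window) // 2]
    window = set(config.deposition_window)

    fish: list[FishRecord] = []
    readings: list[OtolithReading] = []
    shape_rows: list[dict] = []
    truth_rows: list[dict] = []
    fid_counter = 0

    for site, sc in config.sites.items():
        linf, k, t0 = sc.vbgm
        w = np.asarray(sc.age_weights, float)
        w = w / w.sum()
        ages_cls = rng.choice(w.size, size=sc.n, p=w)
        dates = _random_dates(rng, sc.n, config.study_window)
        sexes = np.where(rng.random(sc.n) < 0.5, "female", "male")

        for i in range(sc.n):
            fid_counter += 1
            fid = f"F{fid_counter:05d}"
            annuli = int(ages_cls[i])
            cap = dates[i]
            frac = _fraction_since_birthday(cap)
            true_age = annuli + frac

            fl = float(vbgm_predict(linf, k, t0, true_age)
                       + rng.normal(0, config.length_noise_sd))
            fl = max(fl, 1.0)

            sex = str(sexes[i])
            b0, b1 = config.maturity[sex]
            mature = rng.random() < 1.0 / (1.0 + np.exp(-(b0 + b1 * true_age)))

            ww = 0.0126 * fl ** 3.05 * np.exp(rng.normal(0, 0.10))
            ow_mult = {"celestun": 0.060, "dzilam": 0.085,
                       "rio_lagartos": 0.100}.get(site, 0.08)
            rec = FishRecord(
                fish_id=fid, site=site, sex=sex,
                maturity="mature" if mature else "immature",
                capture_date=cap, fl_cm=round(fl, 2),
                tl_cm=round(fl * 1.08, 2), sl_cm=round(fl * 0.93, 2),
                ww_g=round(ww, 1), gw_g=round(0.90 * ww, 1),
                ow_g=round(ow_mult * (fl / 25.0) ** 2
                           * np.exp(rng.normal(0, 0.15)), 4))
            rec.validate()
            fish.append(rec)

            # otolith radii: deterministic map times a per-fish scale factor
            scale = float(np.exp(rng.normal(0, 0.05)))
            tau = float(np.clip(_tau_since_deposition(cap, dep_mid)
                                + rng.normal(0, 0.04), 0.01, 0.99))
            r_last = r_inf * (1 - np.exp(-kr * (annuli - t0r))) if annuli >= 1 else None
            r_prev = (r_inf * (1 - np.exp(-kr * (annuli - 1 - t0r)))
                      if annuli >= 2 else None)
            r_edge = r_inf * (1 - np.exp(-kr * (annuli + tau - t0r)))
            R = scale * r_edge
            ri = scale * r_last if r_last is not None else None
            rim1 = scale * r_prev if r_prev is not None else None

            # reader counts and reconciliation
            d2 = int(rng.random() < config.reader_disagree_rate) * int(
                rng.choice([-1, 1]))
            da = int(rng.random() < config.auto_disagree_rate) * int(
                rng.choice([-1, 1]))
            c1, c2 = annuli, max(annuli + d2, 0)
            ca = max(annuli + da, 0)
            unresolved = (c1 != c2 and
                          rng.random() < config.discordance_unresolved_rate)
            reading = OtolithReading(
                fish_id=fid, annuli_counts=(c1, c2, ca),
                consensus_annuli=None if unresolved else annuli,
                otolith_radius_mm=R, last_annulus_mm=ri,
                penultimate_annulus_mm=rim1,
                edge_opaque=cap.month in window,
                broken=bool(rng.random() < config.broken_rate),
                illegible=bool(rng.random() < config.illegible_rate))
            reading.validate()
            readings.append(reading)

            factors = {name: means.get(site, 0.0) + rng.normal(0, 1.0)
                       for name, means in config.factor_site_means.items()}
            srow = {}
            for var, vm in config.shape_vars.items():
                if var in PERCENT_VARS or vm.pct_mean is not None:
                    mu = np.log(vm.pct_mean / (100 - vm.pct_mean))
                    mu += vm.pct_site_shift.get(site, 0.0)
                    mu += vm.pct_fl_slope * np.log(fl / 25.0)
                    z = rng.normal(mu, vm.pct_sd)
                    srow[var] = 100.0 / (1.0 + np.exp(-z))
                else:
                    sigma = np.sqrt(np.log(1 + vm.cv ** 2))
                    latent = (vm.loading * factors.get(vm.factor, 0.0)
                              if vm.factor else 0.0)
                    srow[var] = (vm.a * fl ** vm.b * vm.site_mult.get(site, 1.0)
                                 * np.exp(latent + rng.normal(0, sigma)))
            shape_rows.append(srow)
            truth_rows.append({
                "fish_id": fid, "site": site, "sex": sex, "annuli": annuli,
                "true_age": true_age, "month": cap.month, "tau": tau,
                "mature": int(mature)})

    shape_df = pd.DataFrame(shape_rows,
                            index=pd.Index([f.fish_id for f in fish],
                                           name="fish_id"))
    shape = ShapeTable(values=shape_df)
    shape.validate()
    truth = pd.DataFrame(truth_rows).set_index("fish_id")

    from .io import write_fish_table  # local import to avoid a cycle
    import io as _io
    buf = _io.StringIO()
    frame = write_fish_table(buf, fish, readings, shape)
    return SimPopulation(fish=fish, readings=readings, shape=shape,
                         frame=frame, truth=truth, config=config, seed=seed)


def fixture_from_age_length_key(key) -> pd.DataFrame:
    """Expand an age-length key into records at the bin midpoints.

    Each count in the bin x age matrix becomes that many rows with
    FL = bin midpoint and age = the column's age class.
    """
    key.validate()
    mids = key.midpoints
    rows = []
    for i in range(key.counts.shape[0]):
        for j, age in enumerate(np.asarray(key.ages)):
            c = int(key.counts[i, j])
            if c:
                rows.extend({"age": float(age), "fl_cm": float(mids[i])}
                            for _ in range(c))
    return pd.DataFrame(rows, columns=["age", "fl_cm"])
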