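"""Otolith ageing: marginal-increment analysis, reader precision, fractional age.

Marginal-increment analysis (MIA) indirectly validates that one annulus
(opaque + translucent zone pair) is deposited per year: the relative edge
growth MIA = (R - r_i)/(r_i - r_{i-1}) drops to its seasonal minimum just
after the opaque zone forms, so the calendar months with the lowest mean
increment identify the deposition window.  The absolute increment R - r_i
(in mm) is computed and reported separately from the dimensionless ratio.

Reader precision uses the average percent error (APE, Beamish-Fournier)
and the coefficient of variation (CV, Chang), both expressed in percent
and both exactly zero when every reader agrees on every fish.

Fractional ("biological") age anchors each fish to a theoretical May 1
birthdate: age = annuli + elapsed fraction of a year since the most
recent birthday, with one extra year added for fish caught inside the
deposition window whose otolith edge shows no new opaque zone yet.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "marginal_increment",
    "absolute_increment",
    "mia_series",
    "MIASeries",
    "ape_cv",
    "PrecisionReport",
    "fractional_age",
    "DEFAULT_BIRTHDATE",
    "DEFAULT_DEPOSITION_WINDOW",
]

#: theoretical birthdate: midpoint of the protracted spawning season
DEFAULT_BIRTHDATE: tuple[int, int] = (5, 1)
#: months of annulus (opaque-zone) deposition, overall finding; individual
#: sites can differ and may override this
DEFAULT_DEPOSITION_WINDOW: frozenset[int] = frozenset({7, 8, 9})

DAYS_PER_YEAR = 365.25


def marginal_increment(R: float, r_i: float, r_im1: float) -> float:
    """Relative marginal increment (R - r_i)/(r_i - r_{i-1}).

    Dimensionless and scale-invariant; 0 exactly when the last annulus
    lies on the otolith edge.  Requires 0 < r_{i-1} < r_i <= R.
    """
    if r_i == r_im1:
        raise ValueError("degenerate annulus spacing: r_i == r_{i-1}")
    if not (0 < r_im1 < r_i <= R):
        raise ValueError(
            f"radius ordering violated: need 0 < r_im1 < r_i <= R, "
            f"got R={R}, r_i={r_i}, r_im1={r_im1}")
    return (R - r_i) / (r_i - r_im1)


def absolute_increment(R: float, r_i: float) -> float:
    """Absolute edge growth R - r_i in mm (distinct from the MIA ratio)."""
    if not (0 < r_i <= R):
        raise ValueError(f"radius ordering violated: need 0 < r_i <= R, got {R}, {r_i}")
    return R - r_i


@dataclass
class MIASeries:
    """Monthly marginal-increment summary per group.

    ``table`` has one row per (group, month) cell with n, mean and SD of
    the chosen increment measure; ``deposition_months`` maps each group
    to the month(s) attaining the minimum mean — the inferred deposition
    window.
    """

    table: pd.DataFrame
    deposition_months: dict
    measure: str = "mia"

    def months_for(self, group) -> set[int]:
        return set(self.deposition_months.get(group, set()))


def mia_series(records: pd.DataFrame, group_by: str = "annuli",
               value: str = "mia") -> MIASeries:
    """Monthly n/mean/SD of the marginal increment, grouped by annuli count
    or by site.

    ``records`` needs columns ``month`` (1-12), the grouping column
    (``annuli`` or ``site``) and the value column (``mia`` ratio or
    ``mi_mm`` absolute increment).  Cells with a single observation get
    SD reported as 0 with ``sd_undefined`` flagged; empty cells are
    omitted.
    """
    if group_by not in records.columns:
        raise KeyError(f"grouping column {group_by!r} not in records")
    df = records.dropna(subset=[value, "month"])
    rows = []
    for (g, m), sub in df.groupby([group_by, "month"]):
        x = sub[value].to_numpy(float)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        rows.append({group_by: g, "month": int(m), "n": int(x.size),
                     "mean": float(np.mean(x)), "sd": sd,
                     "sd_undefined": x.size < 2})
    table = pd.DataFrame(rows, columns=[group_by, "month", "n", "mean", "sd",
                                        "sd_undefined"])
    deposition = {}
    for g, sub in table.groupby(group_by):
        lo = sub["mean"].min()
        deposition[g] = set(sub.loc[np.isclose(sub["mean"], lo), "month"].astype(int))
    return MIASeries(table=table, deposition_months=deposition, measure=value)


@dataclass
class PrecisionReport:
    """Ageing precision percentages; all >= 0, all 0 under full agreement."""

    ape_global_pct: float
    ape_between_readers_pct: Optional[float] = None
    ape_automatic_pct: Optional[float] = None
    cv_global_pct: float = 0.0
    n_fish: int = 0
    n_excluded: int = 0


def _ape(counts: np.ndarray) -> float:
    """Beamish-Fournier APE over a fish x reader matrix (rows complete).

    Fish with a zero mean count (APE undefined) are excluded.
    """
    R = counts.shape[1]
    mean = counts.mean(axis=1)
    ok = mean > 0
    per_fish = ((100.0 / R) * np.abs(counts[ok] - mean[ok, None]).sum(axis=1)
                / mean[ok])
    return float(per_fish.mean())


def _cv(counts: np.ndarray) -> float:
    """Chang CV: mean over fish of 100*sd/mean, zero-mean fish excluded."""
    mean = counts.mean(axis=1)
    ok = mean > 0
    sd = counts[ok].std(axis=1, ddof=1)
    return float((100.0 * sd / mean[ok]).mean())


def ape_cv(counts: pd.DataFrame, reader_cols: Optional[Sequence[str]] = None,
           auto_col: Optional[str] = None,
           consensus: Optional[Sequence[int]] = None) -> PrecisionReport:
    """Reading-precision statistics from a fish x reader count matrix.

    APE_j = (100/R) * sum_i |x_ij - xbar_j| / xbar_j and
    CV_j = 100 * sd_j / xbar_j, both averaged over fish j.  Fish with a
    zero mean count (APE/CV undefined) or missing reads are excluded and
    counted.  The global figures use every count column; the
    between-readers figure uses the human reader columns only; the
    automatic-count figure is the pairwise APE of the automatic column
    against the consensus ages.
    """
    cols = list(counts.columns)
    if len(cols) < 2:
        raise ValueError("need at least two reader columns")
    full = counts.dropna()
    X = full.to_numpy(float)
    usable = X.mean(axis=1) > 0
    n_excluded = (len(counts) - len(full)) + int((~usable).sum())
    X = X[usable]
    if X.shape[0] == 0:
        raise ValueError("no fish with all readers present and nonzero mean count")

    report = PrecisionReport(
        ape_global_pct=_ape(X), cv_global_pct=_cv(X),
        n_fish=int(X.shape[0]), n_excluded=n_excluded)

    if reader_cols is not None:
        Xr = full.loc[usable, list(reader_cols)].to_numpy(float)
        report.ape_between_readers_pct = _ape(Xr)
    if auto_col is not None and consensus is not None:
        cons = np.asarray(consensus, float)
        auto = counts[auto_col].to_numpy(float)
        ok = ~np.isnan(auto) & ~np.isnan(cons)
        pair = np.column_stack([auto[ok], cons[ok]])
        pair = pair[pair.mean(axis=1) > 0]
        report.ape_automatic_pct = _ape(pair)
    return report


def _most_recent_birthday(capture: dt.date, birth_md: tuple[int, int]) -> dt.date:
    month, day = birth_md
    bd = dt.date(capture.year, month, min(day, calendar.monthrange(capture.year, month)[1]))
    if bd > capture:
        bd = dt.date(capture.year - 1, month,
                     min(day, calendar.monthrange(capture.year - 1, month)[1]))
    return bd


def fractional_age(annuli: int, capture_date: dt.date, edge_opaque: bool,
                   birthdate: tuple[int, int] = DEFAULT_BIRTHDATE,
                   deposition_window: Iterable[int] = DEFAULT_DEPOSITION_WINDOW,
                   ) -> float:
    """Biological (fractional) age in years.

    age = annuli + days since the most recent birthdate anniversary
    divided by 365.25.  For fish captured during the deposition window
    whose otolith edge shows no opaque zone, one year is added on the
    assumption that a new opaque zone is about to deposit.
    """
    if annuli < 0:
        raise ValueError("annuli must be non-negative")
    bd = _most_recent_birthday(capture_date, birthdate)
    elapsed = (capture_date - bd).days / DAYS_PER_YEAR
    age = annuli + elapsed
    if capture_date.month in set(deposition_window) and not edge_opaque:
        age += 1.0
    return age
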