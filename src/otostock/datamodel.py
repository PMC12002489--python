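"""Domain types and invariant checks for the life-history / otolith-shape pipeline.

The working unit of the analysis is one sampled fish: its biological
covariates (site, sex, maturity, capture date, lengths, weights), the
otolith reading used to age it (annuli counts per reader plus radial
measurements for marginal-increment analysis), and the otolith/sulcus
morphometric variables used for stock discrimination.

All lengths are fork length in centimetres, otolith radii in millimetres,
weights in grams, dates ISO-8601.  Keeping the units fixed here prevents
silent cm/mm scale bugs downstream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "InvariantError",
    "FishRecord",
    "OtolithReading",
    "AgedFish",
    "AgeLengthKey",
    "ShapeTable",
    "QCReport",
    "SEXES",
    "MATURITY_STATES",
    "OTOLITH_VARS",
    "SULCUS_VARS",
    "SHAPE_VARS",
    "PERCENT_VARS",
]

SEXES = ("female", "male", "unknown")
MATURITY_STATES = ("immature", "mature", "unknown")

# Otolith (sagitta) outline variables: areas/lengths plus dimensionless
# shape indices; sulcus acusticus variables likewise.  The two ratio
# indices are expressed as percentages (0-100).
OTOLITH_VARS = (
    "A", "MaxD", "MinD", "P", "Rl", "Rw", "Al", "Aw", "EA",
    "RE", "R", "E", "Fi", "As", "RAs", "AAs",
)
SULCUS_VARS = ("SAl", "SAA", "Osl", "OsA", "Cl", "CA", "OsA_SAA", "Osl_SAl")
SHAPE_VARS = OTOLITH_VARS + SULCUS_VARS
PERCENT_VARS = frozenset({"OsA_SAA", "Osl_SAl"})


class InvariantError(ValueError):
    """A typed record violated one of its declared invariants."""


@dataclass
class FishRecord:
    """One sampled individual.

    ``fl_cm`` (fork length) is the working size measure; total and
    standard length are optional and, when present, must bracket it
    (TL >= FL >= SL).
    """

    fish_id: str
    site: str
    sex: str
    maturity: str
    capture_date: dt.date
    fl_cm: float
    tl_cm: Optional[float] = None
    sl_cm: Optional[float] = None
    ww_g: Optional[float] = None
    gw_g: Optional[float] = None
    ow_g: Optional[float] = None

    def validate(self, sites: Optional[Sequence[str]] = None,
                 study_window: Optional[tuple[dt.date, dt.date]] = None) -> None:
        if self.sex not in SEXES:
            raise InvariantError(f"invariant: sex in {SEXES} (got {self.sex!r})")
        if self.maturity not in MATURITY_STATES:
            raise InvariantError(
                f"invariant: maturity in {MATURITY_STATES} (got {self.maturity!r})")
        if sites is not None and self.site not in sites:
            raise InvariantError(f"invariant: site in {tuple(sites)} (got {self.site!r})")
        if not (self.fl_cm > 0):
            raise InvariantError("invariant: fl_cm>0")
        if self.tl_cm is not None and self.tl_cm < self.fl_cm:
            raise InvariantError("invariant: tl_cm>=fl_cm")
        if self.sl_cm is not None and self.sl_cm > self.fl_cm:
            raise InvariantError("invariant: fl_cm>=sl_cm")
        for name in ("ww_g", "gw_g", "ow_g", "tl_cm", "sl_cm"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise InvariantError(f"invariant: {name}>0")
        if study_window is not None:
            lo, hi = study_window
            if not (lo <= self.capture_date <= hi):
                raise InvariantError("invariant: capture_date within study window")


@dataclass
class OtolithReading:
    """Annuli counts per reader plus the radial measurements for MIA.

    ``annuli_counts`` holds one count per reader (two human readers and,
    optionally, the automatic count).  ``consensus_annuli`` is set only
    when reconciliation succeeded; a reading without a consensus counts
    as discordant in QC.  Radii: R is the centre-to-edge otolith radius,
    r_i and r_{i-1} the distances to the last and penultimate opaque
    zones; the penultimate radius is absent when fewer than two annuli
    exist.
    """

    fish_id: str
    annuli_counts: tuple[int, ...]
    consensus_annuli: Optional[int] = None
    otolith_radius_mm: Optional[float] = None
    last_annulus_mm: Optional[float] = None
    penultimate_annulus_mm: Optional[float] = None
    edge_opaque: bool = False
    broken: bool = False
    illegible: bool = False

    def validate(self) -> None:
        if any(c < 0 for c in self.annuli_counts):
            raise InvariantError("invariant: annuli counts non-negative")
        if self.consensus_annuli is not None and self.consensus_annuli < 0:
            raise InvariantError("invariant: consensus_annuli non-negative")
        R = self.otolith_radius_mm
        ri = self.last_annulus_mm
        rim1 = self.penultimate_annulus_mm
        if ri is not None and R is not None and not (0 < ri <= R):
            raise InvariantError("invariant: 0<r_i<=R")
        if rim1 is not None:
            if ri is None:
                raise InvariantError("invariant: r_{i-1} requires r_i")
            if not (0 < rim1 < ri):
                raise InvariantError("invariant: 0<r_{i-1}<r_i")
            if self.consensus_annuli is not None and self.consensus_annuli < 2:
                raise InvariantError("invariant: r_{i-1} absent when annuli<2")


@dataclass
class AgedFish:
    """Age assignment for one fish: annuli count, fractional (biological)
    age and, when radii are available, the marginal increment ratio."""

    fish_id: str
    annuli: int
    fractional_age_years: float
    mia: Optional[float] = None

    def validate(self) -> None:
        if self.annuli < 0:
            raise InvariantError("invariant: annuli>=0")
        if self.fractional_age_years < 0:
            raise InvariantError("invariant: fractional_age>=0")
        # base fraction is in [0,1); the edge rule can add one more year
        if not (self.annuli - 1 <= self.fractional_age_years < self.annuli + 2):
            raise InvariantError("invariant: fractional age within [annuli-1, annuli+2)")
        if self.mia is not None and self.mia < 0:
            raise InvariantError("invariant: mia>=0")


@dataclass
class AgeLengthKey:
    """Counts of fish by fork-length bin and age class for one group."""

    bin_lower: np.ndarray   # (n_bins,) FL cm
    bin_upper: np.ndarray   # (n_bins,)
    ages: np.ndarray        # (n_ages,) years, 0 encodes the 0+ class
    counts: np.ndarray      # (n_bins, n_ages) non-negative integers
    group: str = ""

    def validate(self) -> None:
        lo = np.asarray(self.bin_lower, dtype=float)
        hi = np.asarray(self.bin_upper, dtype=float)
        if lo.shape != hi.shape or np.any(hi <= lo):
            raise InvariantError("invariant: bins well-formed")
        if not np.allclose(lo[1:], hi[:-1]):
            raise InvariantError("invariant: bins contiguous and non-overlapping")
        c = np.asarray(self.counts)
        if c.shape != (lo.size, np.asarray(self.ages).size):
            raise InvariantError("invariant: counts shape bins x ages")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise InvariantError("invariant: counts non-negative integers")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())

    @property
    def midpoints(self) -> np.ndarray:
        return (np.asarray(self.bin_lower, float) + np.asarray(self.bin_upper, float)) / 2.0


@dataclass
class QCReport:
    """Bookkeeping of the otolith quality-control filter.

    ``collected`` = ``broken`` + ``unreadable_or_discordant`` + ``retained``
    always holds exactly.
    """

    collected: int
    broken: int
    unreadable_or_discordant: int
    retained: int

    def __post_init__(self) -> None:
        if self.retained != self.collected - self.broken - self.unreadable_or_discordant:
            raise InvariantError("invariant: QC counts must sum to collected")
        if min(self.collected, self.broken, self.unreadable_or_discordant, self.retained) < 0:
            raise InvariantError("invariant: QC counts non-negative")

    @classmethod
    def from_counts(cls, collected: int, broken: int,
                    unreadable_or_discordant: int) -> "QCReport":
        return cls(collected, broken, unreadable_or_discordant,
                   collected - broken - unreadable_or_discordant)


@dataclass
class ShapeTable:
    """Per-otolith morphometric variables with per-variable processing state.

    ``values`` is a pandas DataFrame indexed by fish_id with one column per
    shape variable.  ``states`` maps variable name to its preprocessing
    outcome: ``raw`` before preprocessing, then exactly one of
    ``removed_site_x_length`` / ``corrected`` / ``kept`` (or ``excluded``
    for unusable columns); ``slopes`` holds the common within-group
    allometric slope b for corrected variables.
    """

    values: "pandas.DataFrame"  # noqa: F821 - imported lazily by io
    states: dict = field(default_factory=dict)
    slopes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.states:
            self.states = {c: "raw" for c in self.values.columns}

    def validate(self) -> None:
        for var in self.values.columns:
            col = self.values[var].dropna()
            if (col <= 0).any():
                raise InvariantError(f"invariant: {var} positive")
            if var in PERCENT_VARS and ((col < 0) | (col > 100)).any():
                raise InvariantError(f"invariant: {var} in [0,100]")
        for var, state in self.states.items():
            if state not in ("raw", "removed_site_x_length", "corrected", "kept",
                             "excluded"):
                raise InvariantError(f"invariant: unknown state {state!r} for {var}")
            if state == "corrected" and not np.isfinite(self.slopes.get(var, np.nan)):
                raise InvariantError(f"invariant: corrected {var} needs finite slope")
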