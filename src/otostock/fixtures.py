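"""Packaged reference tables: age-length keys and growth parameters.

These are the published summary tables for the yellowtail snapper
(*Ocyurus chrysurus*) study populations of the southern Gulf of Mexico:
age-length keys (counts of fish per fork-length bin and age class, by
sex and by fishing site) and the fitted von Bertalanffy parameters per
group.  They serve as inputs for scaled-down reproduction runs — e.g.
expanding a key at bin midpoints and refitting the growth curve — and
for the closed-form life-history quantities (PHI', t_max, M).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .datamodel import AgeLengthKey

__all__ = [
    "GROUPS",
    "SITES",
    "load_age_length_key",
    "load_growth_params",
    "growth_params_dict",
]

GROUPS = ("females", "males", "celestun", "dzilam", "rio_lagartos")
SITES = ("celestun", "dzilam", "rio_lagartos")

#: the common fork-length binning of the published keys (12 bins, FL cm)
_BIN_EDGES = np.array([16.00, 18.18, 20.36, 22.55, 24.73, 26.91, 29.09,
                       31.27, 33.45, 35.64, 37.82, 40.00, 42.18])
_AGES = np.arange(13)  # 0 encodes the 0+ (young-of-the-year) class


def _read(name: str) -> pd.DataFrame:
    with resources.files("otostock.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_age_length_key(group: str) -> AgeLengthKey:
    """The published age-length key for one group (sex or site)."""
    if group not in GROUPS:
        raise KeyError(f"group must be one of {GROUPS}, got {group!r}")
    df = _read("age_length_keys.csv")
    df = df[df["group"] == group]
    counts = np.zeros((_BIN_EDGES.size - 1, _AGES.size), dtype=int)
    lowers = _BIN_EDGES[:-1]
    for _, row in df.iterrows():
        i = int(np.argmin(np.abs(lowers - row["bin_lower"])))
        counts[i, int(row["age"])] += int(row["count"])
    key = AgeLengthKey(bin_lower=_BIN_EDGES[:-1].copy(),
                       bin_upper=_BIN_EDGES[1:].copy(),
                       ages=_AGES.copy(), counts=counts, group=group)
    key.validate()
    return key


def load_growth_params(group: str | None = None) -> pd.DataFrame:
    """Published VBGM parameter table (estimate, SE, 95% CI, df) per group."""
    df = _read("growth_params.csv")
    if group is not None:
        df = df[df["group"] == group]
        if df.empty:
            raise KeyError(f"no growth parameters for group {group!r}")
    return df.reset_index(drop=True)


def growth_params_dict(group: str) -> dict[str, float]:
    """Point estimates {linf, k, t0} for one group."""
    df = load_growth_params(group)
    return dict(zip(df["param"], df["estimate"].astype(float)))
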