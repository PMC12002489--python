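"""Otolith-shape stock discrimination.

Pipeline: allometric size correction -> scaling -> Euclidean PCoA ->
variable selection by axis contribution -> PERMANOVA -> dispersion
(betadisper-style centroid distances).

Size correction follows the common-within-group-slope approach: for each
variable V an ANCOVA of log(V) on log(FL) crossed with group decides its
fate.  A significant length-by-group interaction, or a significant group
effect alongside length, means the variable confounds size and site and
is removed; a variable that tracks length only is corrected
multiplicatively to the grand-mean fork length,

    V_adj = V * (FL_ref / FL)^b,

with b the common within-group log-log slope; everything else is kept
unchanged.  Indices expressed as percentages are arcsine-square-root
transformed (arcsin sqrt(p/100)) before testing and scaling.

PCoA on a Euclidean distance matrix is computed by Gower double
centering of -D^2/2 and eigendecomposition; on truly Euclidean input it
coincides with PCA of the underlying data matrix, which serves as an
independent cross-check.  A variable's "contribution" to an axis is
operationalised as 100*r^2 between the variable and the axis scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.spatial.distance import pdist, squareform

from .datamodel import PERCENT_VARS

__all__ = [
    "CorrectionDecision",
    "classify_and_correct",
    "normalize",
    "collinearity_screen",
    "OrdinationResult",
    "pcoa",
    "variable_contributions",
    "select_variables",
    "PermanovaResult",
    "permanova",
    "DispersionResult",
    "betadisper",
    "euclidean_distance",
]


@dataclass
class CorrectionDecision:
    """Outcome of the ANCOVA screen for one shape variable."""

    variable: str
    state: str                       # removed_site_x_length | corrected | kept | excluded
    slope: Optional[float] = None    # common within-group log-log slope b
    p_interaction: Optional[float] = None
    p_group: Optional[float] = None
    p_length: Optional[float] = None
    reason: str = ""


def _arcsine_pct(p: np.ndarray) -> np.ndarray:
    return np.arcsin(np.sqrt(np.clip(p / 100.0, 0.0, 1.0)))


def classify_and_correct(table: pd.DataFrame, lengths: Sequence[float],
                         groups: Sequence[str], alpha: float = 0.05,
                         percent_vars: frozenset = PERCENT_VARS,
                         ) -> tuple[list[CorrectionDecision], pd.DataFrame]:
    """ANCOVA-based allometric screen and correction of shape variables.

    Returns the per-variable decisions and the corrected table on the
    analysis scale (percent indices arcsine-transformed).  Removed and
    excluded variables are absent from the corrected table.
    """
    fl = np.asarray(lengths, float)
    g = pd.Categorical(groups)
    if len(g.categories) < 2:
        raise ValueError("need at least 2 groups for the ANCOVA screen")
    decisions: list[CorrectionDecision] = []
    corrected = {}
    fl_ref = float(fl.mean())

    for var in table.columns:
        v = table[var].to_numpy(float)
        if np.any(~np.isfinite(v)) or np.any(v <= 0):
            decisions.append(CorrectionDecision(
                variable=var, state="excluded",
                reason="non-positive or missing values"))
            continue
        w = _arcsine_pct(v) if var in percent_vars else v
        df = pd.DataFrame({"y": np.log(w), "x": np.log(fl), "g": g})

        m_int = smf.ols("y ~ x * g", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = sm.stats.anova_lm(m_int, typ=2)
        p_int = float(aov.loc["x:g", "PR(>F)"])

        m_add = smf.ols("y ~ x + g", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov_add = sm.stats.anova_lm(m_add, typ=2)
        p_grp = float(aov_add.loc["g", "PR(>F)"])
        p_len = float(aov_add.loc["x", "PR(>F)"])
        b = float(m_add.params["x"])

        # removal requires the size-by-site confound: a length-by-group
        # interaction, or group and length effects jointly; a group
        # effect without any length dependence is not a size artefact
        # and the variable stays available for discrimination
        if p_int < alpha or (p_grp < alpha and p_len < alpha):
            decisions.append(CorrectionDecision(
                variable=var, state="removed_site_x_length",
                p_interaction=p_int, p_group=p_grp, p_length=p_len,
                reason="correlates with group and length"))
            continue
        if p_len < alpha:
            adj = w * (fl_ref / fl) ** b
            corrected[var] = adj
            decisions.append(CorrectionDecision(
                variable=var, state="corrected", slope=b,
                p_interaction=p_int, p_group=p_grp, p_length=p_len))
        else:
            corrected[var] = w
            decisions.append(CorrectionDecision(
                variable=var, state="kept",
                p_interaction=p_int, p_group=p_grp, p_length=p_len))

    out = pd.DataFrame(corrected, index=table.index)
    return decisions, out


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each variable to zero mean and unit sample SD (ddof=1).

    Constant columns are dropped with a warning.
    """
    out = {}
    for c in table.columns:
        x = table[c].to_numpy(float)
        sd = np.std(x, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"dropping constant variable {c!r}", RuntimeWarning,
                          stacklevel=2)
            continue
        out[c] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)


def collinearity_screen(table: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Report (not drop) variable pairs with |r| >= threshold."""
    corr = table.corr()
    rows = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                rows.append({"var1": a, "var2": b, "r": float(r)})
    return pd.DataFrame(rows, columns=["var1", "var2", "r"])


@dataclass
class OrdinationResult:
    """PCoA output: eigenvalues, coordinates, variance shares."""

    eigenvalues: np.ndarray          # descending, clipped at 0
    coordinates: pd.DataFrame        # one row per otolith, columns PCo1..
    proportion_explained: np.ndarray
    n_negative_clipped: int = 0
    contributions: Optional[pd.DataFrame] = None

    def percent_two_axes(self) -> float:
        return float(100 * self.proportion_explained[:2].sum())


def pcoa(distance: np.ndarray | pd.DataFrame,
         index: Optional[Sequence] = None) -> OrdinationResult:
    """Principal coordinates analysis of a (Euclidean) distance matrix.

    Gower double-centers -D^2/2, eigendecomposes, and scales the
    eigenvectors by sqrt(eigenvalue).  Negative eigenvalues — numerically
    impossible for true Euclidean input — are clipped at zero with a
    warning.  The coordinates are centred at the origin.
    """
    if isinstance(distance, pd.DataFrame):
        index = distance.index
        D = distance.to_numpy(float)
    else:
        D = np.asarray(distance, float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-8):
        raise ValueError("distance matrix must have zero diagonal")

    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(1e-8 * max(evals.max(), 1.0), 0.0)
    n_neg = int((evals < -tol).sum())
    if n_neg:
        warnings.warn(f"clipping {n_neg} negative eigenvalue(s) at 0",
                      RuntimeWarning, stacklevel=2)
    evals = np.clip(evals, 0.0, None)
    keep = evals > tol
    lam = evals[keep]
    coords = evecs[:, keep] * np.sqrt(lam)
    total = lam.sum()
    prop = lam / total if total > 0 else lam
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    cdf = pd.DataFrame(coords, columns=cols,
                       index=index if index is not None else range(n))
    return OrdinationResult(eigenvalues=lam, coordinates=cdf,
                            proportion_explained=prop, n_negative_clipped=n_neg)


def variable_contributions(ordination: OrdinationResult, table: pd.DataFrame,
                           n_axes: int = 2) -> pd.DataFrame:
    """Per-variable contribution to each of the first axes: 100*r^2
    between the variable and the axis scores."""
    coords = ordination.coordinates
    n_axes = min(n_axes, coords.shape[1])
    rows = {}
    for var in table.columns:
        x = table[var].to_numpy(float)
        rows[var] = {}
        for i in range(n_axes):
            y = coords.iloc[:, i].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
            rows[var][coords.columns[i]] = 100.0 * r2
    out = pd.DataFrame(rows).T
    ordination.contributions = out
    return out


def select_variables(contributions: pd.DataFrame,
                     threshold: float = 80.0) -> list[str]:
    """Variables contributing >= threshold percent on axis 1 or axis 2.

    An empty selection falls back to all variables with a warning.
    """
    axes = contributions.columns[:2]
    mask = (contributions[axes] >= threshold).any(axis=1)
    selected = list(contributions.index[mask])
    if not selected:
        warnings.warn("no variable reached the contribution threshold; "
                      "falling back to all variables", RuntimeWarning,
                      stacklevel=2)
        return list(contributions.index)
    return selected


@dataclass
class PermanovaResult:
    """PERMANOVA table: an overall row plus one-vs-rest rows per level."""

    table: pd.DataFrame   # columns: level, df, ss, pseudo_f, p, n
    n_permutations: int
    seed: int

    def overall(self) -> pd.Series:
        return self.table[self.table["level"] == "overall"].iloc[0]


def _permanova_stat(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float, int, int]:
    """Pseudo-F from the distance partition (squared distances D2)."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    levels = np.unique(labels)
    for lv in levels:
        idx = np.flatnonzero(labels == lv)
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = levels.size - 1
    df_within = n - levels.size
    f = (ss_among / df_among) / (ss_within / df_within)
    return f, ss_among, df_among, df_within


def permanova(distance: np.ndarray | pd.DataFrame, labels: Sequence,
              n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutation-based multivariate ANOVA on a distance matrix.

    The pseudo-F statistic partitions the squared distances among vs
    within groups; the p-value counts permutations with F >= F_obs,
    including the observed labelling: p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm).  Besides the overall test, each level is tested
    one-vs-rest (same permutation scheme) to localise differences.
    """
    D = distance.to_numpy(float) if isinstance(distance, pd.DataFrame) else np.asarray(distance, float)
    labels = np.asarray(labels)
    levels, counts = np.unique(labels, return_counts=True)
    if levels.size < 2:
        raise ValueError("need at least 2 label levels")
    if counts.min() < 2:
        raise ValueError("every level needs at least 2 members")
    D2 = D ** 2
    rng = np.random.default_rng(seed)
    n = D.shape[0]

    def run(lab: np.ndarray) -> dict:
        f_obs, ss, dfa, dfw = _permanova_stat(D2, lab)
        count = 1
        for _ in range(n_perm):
            perm = rng.permutation(n)
            f_p, _, _, _ = _permanova_stat(D2, lab[perm])
            if f_p >= f_obs - 1e-12:
                count += 1
        return {"df": dfa, "ss": ss, "pseudo_f": f_obs,
                "p": count / (n_perm + 1), "n": n}

    rows = []
    overall = run(labels)
    for lv in levels:
        binary = np.where(labels == lv, str(lv), "rest")
        res = run(binary)
        res["level"] = str(lv)
        rows.append(res)
    overall["level"] = "overall"
    rows.append(overall)
    table = pd.DataFrame(rows)[["level", "df", "ss", "pseudo_f", "p", "n"]]
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed)


@dataclass
class DispersionResult:
    """Group centroids and mean member-to-centroid distances."""

    centroids: pd.DataFrame       # one row per group
    mean_distances: pd.Series     # group -> mean distance
    distances: pd.Series = field(default=None)  # per-otolith distance


def betadisper(ordination: OrdinationResult, labels: Sequence) -> DispersionResult:
    """Homogeneity-of-dispersion summary in ordination space.

    Per group: the coordinate-mean centroid and the mean Euclidean
    distance of members to it.  Empty groups are omitted with a warning.
    """
    coords = ordination.coordinates
    labels = pd.Series(np.asarray(labels), index=coords.index, name="group")
    cents = {}
    means = {}
    dists = pd.Series(np.nan, index=coords.index, dtype=float)
    for g, idx in labels.groupby(labels).groups.items():
        sub = coords.loc[idx].to_numpy()
        if sub.shape[0] == 0:  # pragma: no cover - grouping never yields empties
            warnings.warn(f"empty group {g!r} omitted", RuntimeWarning, stacklevel=2)
            continue
        c = sub.mean(axis=0)
        d = np.linalg.norm(sub - c, axis=1)
        cents[g] = c
        means[g] = float(d.mean())
        dists.loc[idx] = d
    centroids = pd.DataFrame(cents, index=coords.columns).T
    return DispersionResult(centroids=centroids,
                            mean_distances=pd.Series(means, name="mean_distance"),
                            distances=dists)


def euclidean_distance(table: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance matrix of a scaled variable table."""
    D = squareform(pdist(table.to_numpy(float)))
    return pd.DataFrame(D, index=table.index, columns=table.index)
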