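# Methods

## Ageing

One annulus is an opaque + translucent zone pair in an otolith thin
section. The marginal increment ratio `MIA = (R − r_i)/(r_i − r_{i−1})`
(R: centre-to-edge radius; r_i, r_{i−1}: distances to the last and
penultimate opaque zones, all mm) is dimensionless and scale-invariant;
its monthly mean bottoms out just after the opaque zone deposits, so the
months attaining the minimum mean identify the deposition window. The
absolute increment `R − r_i` (mm) is computed and labelled separately —
published marginal-increment plots are often on the absolute scale while
the validation statistic is the ratio; the package never conflates the
two.

Reader precision follows Beamish–Fournier and Chang:
`APE_j = (100/R)·Σ_i |x_ij − x̄_j| / x̄_j` and `CV_j = 100·sd_j/x̄_j`,
averaged over fish. Fish with zero mean count are excluded and counted.
The automatic count is treated as an extra reader column for the global
figures; its dedicated statistic is the pairwise APE against the
consensus ages. Reader reconciliation accepts agreement within a
configurable tolerance (default exact), lets a recorded re-read resolve
first-pass disagreement, and otherwise rejects the otolith as
discordant.

Fractional ("biological") age anchors each fish to a theoretical May 1
birthdate (midpoint of the protracted spawning season):
`age = annuli + days since the last anniversary / 365.25`. A fish caught
inside the deposition window whose otolith edge shows no opaque zone
gets one extra year, on the assumption that the new zone is about to
deposit. The year length is fixed at 365.25 days to avoid leap-year
branches. The deposition window defaults to July–September (the overall
finding) and is site-overridable, since individual sites can differ.

## Growth

The von Bertalanffy model `E[L|t] = L∞(1 − e^{−K(t−t0)})` is fitted by
nonlinear least squares (scipy trust-region-reflective with an analytic
Jacobian) under Gaussian additive error of constant variance; there is
no lognormal-error option in this version. Default start values
L∞ = 1.1·max length, K = 0.2/yr, t0 = −1 yr; because the RSS surface is
flat along the L∞/K ridge, up to five jittered restarts are attempted
before a fit is declared failed. Fits use fractional ages, not integer
annuli counts.

The profiled-variance Gaussian log-likelihood
`logL = −(n/2)(ln2π + ln(RSS/n) + 1)` makes nested models comparable:
`χ² = 2(logL_full − logL_reduced)` with df equal to the parameter-count
difference, algebraically identical to the RSS-ratio form
`n·ln(RSS_red/RSS_full)` (both are exposed and tested against each
other). The comparison lattice over g groups holds eight models — all
three parameters shared (3 parameters) up to all distinct (3g) — and the
selection walks hierarchically from the most complex model: the fully
distinct model is first confronted with the coincident curve; while
simplifications are non-significant (α = 0.05) the walk keeps the more
parsimonious model, breaking ties among equally acceptable reductions by
the highest log-likelihood, and finally confirms the surviving model
against the coincident curve. The selection is invariant to group-label
permutation. If any single group cannot be fitted at all, the
comparison raises with diagnostics rather than returning a partial
lattice: every lattice member pools all groups' data, so there is no
meaningful subset of comparisons to report.

Bootstrap CIs resample (age, length) pairs with replacement, refit, and
take 2.5/97.5 percentiles; non-converged replicates are dropped and
counted, with a warning (error under strict mode) above 20%. The API
default is B = 9999; the orchestrated CLI pipeline defaults to B = 999
in its config for run-time reasons, and B is always recorded.

Derived quantities are exact closed forms: `Φ′ = log₁₀K + 2log₁₀L∞`
(base-10; comparable across populations of a species) and
`t_max = 3/K + t0` (age at ~95% of L∞). Reports round parameters and
t_max to 2 dp and Φ′ to 1 dp; internal values stay unrounded.

## Demography

The maturity ogive is a binomial-logit GLM of maturity on fractional
age; `A50 = −β₀/β₁`, with a percentile bootstrap (default B = 999) over
jointly resampled individuals. Complete separation is detected from the
data (maturity classes disjoint in age) rather than from coefficient
magnitudes — the GLM converges to finite but meaningless slopes on
separated data — and then A50 is reported as the boundary midpoint with
a quality warning. Ogives are fitted per sex; per-site ogives make sense
only where both classes occur (at some sites every sampled fish is
mature).

Natural mortality: the maximum-age estimator `M = 4.899·t_max^−0.916`
and the length-at-age estimator
`M = exp(0.55 − 1.61·lnFL + 1.44·lnL∞ + lnK)` with FL the VBGM-predicted
fork length at the requested age. The latter is strictly decreasing in
age (juvenile predation dominates M in tropical fishes). Only computed
values are reported; no published mortality numbers are stored.

## Otolith shape

Per variable V, an ANCOVA of log V on log FL crossed with site decides
its fate at α = 0.05: a significant length-by-site interaction, or
significant site and length effects jointly, marks the variable as a
size–site confound and removes it; a significant length effect alone
triggers the multiplicative correction `V_adj = V·(FL_ref/FL)^b`, with b
the common within-group slope from the additive model and FL_ref the
grand-mean fork length of the shape sample; otherwise the variable is
kept unchanged. A site effect without any length dependence is *not*
grounds for removal — such variables are exactly the carriers of
stock-discriminating signal. The two percentage indices are
arcsine-square-root transformed (`arcsin√(p/100)`) before testing and
scaling. Non-positive columns are excluded with a reason.

Corrected variables are scaled to zero mean/unit SD; constant columns
are dropped with a warning; a collinearity screen reports (but never
auto-drops) pairs with |r| ≥ 0.9. PCoA Gower-double-centers −D²/2 and
eigendecomposes; negative eigenvalues — numerically impossible for true
Euclidean input — are clipped at zero with a warning. On Euclidean
distances PCoA coincides with PCA of the underlying matrix, which the
tests exploit as an independent oracle. A variable's contribution to an
axis is operationalised as 100·r² between the variable and the axis
scores; variables reaching ≥ 80% on axis 1 or 2 are selected, with a
fallback to all variables (plus warning) if none qualifies.

PERMANOVA partitions the squared distances among vs within groups;
`pseudo-F = (SS_among/df_among)/(SS_within/df_within)`; the p-value
counts whole-row label permutations with F ≥ F_obs and includes the
observed labelling, `p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)`, with
n_perm = 999 by default and the seed recorded. Besides the overall test,
each level is tested one-vs-rest to localise differences (our reading of
the published per-level table rows, which a standard one-way PERMANOVA
does not produce). Dispersion (betadisper-style) reports per-group
centroids in ordination space and the mean member-to-centroid distance.
The two-axis variance share is reported both before and after variable
selection, since it is not stated at which stage such figures are
conventionally computed.

## Synthetic data

The generator emulates the structure of the study's individual-level
tables under the published study conditions: per-site VBGM truth
(Celestún 41.59/0.11/−4.86, Dzilam de Bravo 38.36/0.16/−3.25, Río
Lagartos 40.28/0.12/−4.99), age compositions from the published site
age–length-key margins, site sample sizes 338/391/395 (the retained
sample; QC losses default to zero and are injectable for QC tests),
additive Gaussian length noise of SD 1.5 cm truncated positive, logistic
maturity with A50 = 1.3 yr (females) and 0.8 yr (males) at slope
3.5/yr, and a July–September deposition window.

Annulus radii follow a monotone saturating map
`R(t) = 4.0·(1 − e^{−0.25(t+1)})` mm scaled by a per-fish lognormal
factor (which cancels in the MIA ratio); the edge radius advances with
the time elapsed since the last pass through the deposition window, so
the monthly marginal-increment minimum falls in (or immediately after)
the window. Shape variables are lognormal-noise power laws `a·FL^b`:
the seven length-only variables carry the published common slopes
(e.g. otolith area b = 1.4235); the removed family adds site-specific
multipliers on top of a length effect; the kept family is
length-independent but loads one of two latent factors ("size",
"roundness") whose means differ by site — giving the ordination the
site-discriminating structure observed in real data. Percentage indices
are logistic-normal. Everything is deterministic under a fixed seed.

What the generator does **not** emulate: measurement error correlated
across variables within an otolith beyond the two factors, gear
selectivity (ages are drawn from the realised, already-selective age
composition), inter-annual environmental variation, and any spatial
structure within a site. Passing tests therefore demonstrate that the
estimators recover known truth under the assumed error structure, not
that the published point values are correct.

## Problem sizes and numerics

The test suite's simulation studies use: 200 replicates of n = 500 for
growth-parameter bias; 1000 null replicates (3 groups × 120 fish) for
the likelihood-ratio type-I error; 200 replicates with B = 299 for
bootstrap coverage; n = 2000 for A50 recovery; 20×8 matrices for the
PCoA/PCA equivalence; and n = 300 for allometric slope recovery — sizes
chosen so the full suite completes in about two minutes while leaving
the binomial acceptance bands meaningful. Optimizer tolerances are
xtol = ftol = gtol = 1e−12; the log-likelihood nesting monotonicity is
asserted to 1e−6; ties in model selection break by highest
log-likelihood; degenerate inputs (all ages equal, single maturity
class, zero annulus spacing, constant variables, empty selections) raise
or warn explicitly rather than propagating NaNs.

## Limitations

Only the von Bertalanffy model is implemented (no Gompertz/logistic/
Schnute alternatives, no random-effects growth). Error in length is
additive Gaussian; heavy-tailed or multiplicative error is not modelled.
The age-length-key refit inherits binning bias; its tolerance bands are
accordingly wide. PERMANOVA assumes exchangeability under the null and,
like the published analysis, is run on Euclidean distances of scaled
variables. XLSX supplements are handled only by a converter utility —
the runtime format is CSV throughout.
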