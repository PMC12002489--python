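# otostock

Age-based life history and otolith-shape stock structure for demersal
fishes, built around the yellowtail snapper (*Ocyurus chrysurus*)
populations of the southern Gulf of Mexico.

Fisheries biologists managing multi-site artisanal fisheries need to know
whether the fish landed at different ports belong to one homogeneous stock
or to demographically distinct units. This package implements the two
complementary lines of evidence used for that question:

1. **Age-based life history.** Fish are aged from annuli in otolith thin
   sections. The package provides marginal-increment analysis to validate
   annual ring deposition (`MIA = (R - r_i)/(r_i - r_{i-1})`), reader
   precision (Beamish–Fournier APE, Chang CV), and fractional-age
   assignment from a theoretical birthdate. Growth follows the von
   Bertalanffy model `E[L|t] = L∞(1 − e^{−K(t−t0)})`, fitted by nonlinear
   least squares with bootstrap confidence intervals, and compared across
   sexes or sites through the classical lattice of up to eight nested
   curves tested hierarchically by likelihood ratio
   (`χ² = 2(logL_full − logL_reduced)`). Derived quantities: growth
   performance `Φ′ = log₁₀K + 2·log₁₀L∞`, lifespan `t_max = 3/K + t0`,
   age at maturity A50 from a binomial-logit ogive with bootstrap CI, and
   natural mortality both from maximum age (`M = 4.899·t_max^−0.916`) and
   from length at age (`ln M = 0.55 − 1.61·lnFL + 1.44·lnL∞ + lnK`).
2. **Otolith-shape discrimination.** Otolith and sulcus morphometrics are
   screened by ANCOVA for size effects (variables confounding site and
   length removed; length-only variables corrected by
   `V_adj = V·(FL_ref/FL)^b` with the common within-group log–log slope
   b), scaled, ordinated by PCoA on Euclidean distances, filtered by axis
   contribution (100·r² ≥ 80%), and tested by PERMANOVA plus a
   betadisper-style dispersion analysis of group centroids.

A synthetic-data generator reproduces the statistical structure of the
study's individual-level data (site-stratified ages, VBGM lengths,
logistic maturity, annulus radii with a seasonal deposition signal,
allometric shape variables), so the full pipeline runs and is tested
without the original data supplements. The published age–length keys and
growth-parameter tables are packaged as fixtures.

## Worked example

Closed-form life history from the packaged growth parameters:

```python
from otostock import fixtures, growth, demography

for site in ("celestun", "dzilam", "rio_lagartos"):
    p = fixtures.growth_params_dict(site)
    t_max = growth.lifespan(p["k"], p["t0"])
    M = demography.mortality_from_tmax(t_max)
    phi = growth.growth_performance(p["k"], p["linf"])
    print(f"{site:13s} phi'={phi:.2f}  t_max={t_max:.2f} yr  M={M:.2f}/yr")
```

prints

```
celestun      phi'=2.28  t_max=22.41 yr  M=0.28/yr
dzilam        phi'=2.37  t_max=15.50 yr  M=0.40/yr
rio_lagartos  phi'=2.29  t_max=20.01 yr  M=0.31/yr
```

i.e. the slow-growing Celestún fish (K = 0.11/yr) live longest
(22.4 yr) and suffer the lowest natural mortality, while fast-growing
Dzilam de Bravo fish (K = 0.16/yr) turn over fastest — the demographic
contrast at the heart of the stock-structure question.

Refit the growth curve from the published all-fish age–length key
expanded at bin midpoints:

```python
import pandas as pd
from otostock import fixtures, growth, synthetic

recs = pd.concat([synthetic.fixture_from_age_length_key(
    fixtures.load_age_length_key(g)) for g in ("females", "males")])
fit = growth.fit_vbgm(recs["age"], recs["fl_cm"])
print(f"n={fit.n}  L_inf={fit.linf:.2f} cm  K={fit.k:.3f}/yr  t0={fit.t0:.2f}")
```

prints

```
n=1124  L_inf=38.39 cm  K=0.165/yr  t0=-3.62
```

within binning error of the parameters fitted on the individual data
(L∞ = 38.85 cm, K = 0.15/yr, t0 = −3.66).

The whole pipeline, from simulation through the shape analysis, runs as

```sh
otostock all --seed 7 --out-dir run --bootstrap 999 --permutations 999
```

writing per-stage CSV tables (aged fish, growth parameters and lattice,
maturity ogives, mortality schedules, shape decisions/ordination/
PERMANOVA/dispersion) plus a `manifest.json` with config, seed and
output digests.

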