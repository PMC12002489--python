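"""VBGM fitting, bootstrap, lattice comparison and derived quantities."""

import numpy as np
import pandas as pd
import pytest

from otostock import growth

TRUTH = (38.85, 0.15, -3.66)


def _simulate(rng, n, truth=TRUTH, sd=1.5, age_range=(0.5, 12.0)):
    ages = rng.uniform(*age_range, n)
    lengths = growth.vbgm_predict(*truth, ages) + rng.normal(0, sd, n)
    return ages, lengths


class TestPredict:
    def test_zero_at_t0(self):
        assert growth.vbgm_predict(40.0, 0.2, -1.5, -1.5) == pytest.approx(0.0)

    def test_monotone_approach_to_asymptote(self):
        ages = np.linspace(0, 60, 500)
        L = growth.vbgm_predict(40.0, 0.2, -1.5, ages)
        assert np.all(np.diff(L) > 0)
        assert np.all(L < 40.0)
        assert L[-1] == pytest.approx(40.0, abs=1e-3)

    def test_published_parameter_evaluation(self):
        # high-precision evaluation of the slow-growth site curve at age 2
        assert growth.vbgm_predict(41.59, 0.11, -4.86, 2.0) == pytest.approx(
            22.034437872742423, rel=1e-12)


class TestFit:
    def test_zero_noise_exact_recovery(self):
        ages = np.arange(0.5, 12.5, 0.5)
        L = growth.vbgm_predict(38.85, 0.15, -3.66, ages)
        fit = growth.fit_vbgm(ages, L)
        assert fit.linf == pytest.approx(38.85, rel=1e-6)
        assert fit.k == pytest.approx(0.15, rel=1e-6)
        assert fit.t0 == pytest.approx(-3.66, rel=1e-6)
        assert fit.df == fit.n - 3

    def test_fitted_rss_beats_generating_parameters(self, rng):
        ages, L = _simulate(rng, 300)
        fit = growth.fit_vbgm(ages, L)
        rss_truth = float(np.sum((L - growth.vbgm_predict(*TRUTH, ages)) ** 2))
        assert fit.rss <= rss_truth + 1e-9

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            growth.fit_vbgm([2, 2, 2, 2], [20, 21, 22, 23])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            growth.fit_vbgm([1, 2, 3], [10, 15, 18])

    def test_loglik_matches_profiled_gaussian_formula(self, rng):
        ages, L = _simulate(rng, 80)
        fit = growth.fit_vbgm(ages, L)
        n = fit.n
        expected = -0.5 * n * (np.log(2 * np.pi) + np.log(fit.rss / n) + 1)
        assert fit.loglik == pytest.approx(expected, rel=1e-12)


class TestBootstrap:
    def test_fixed_seed_reproducible(self, rng):
        ages, L = _simulate(rng, 120)
        a = growth.bootstrap_ci(ages, L, B=150, seed=7)
        b = growth.bootstrap_ci(ages, L, B=150, seed=7)
        assert a["ci"] == b["ci"]

    def test_near_zero_noise_shrinks_ci(self, rng):
        ages, L = _simulate(rng, 120, sd=1e-6)
        res = growth.bootstrap_ci(ages, L, B=150, seed=3)
        lo, hi = res["ci"]["linf"]
        assert hi - lo < 1e-3

    def test_point_estimate_inside_ci(self, rng):
        ages, L = _simulate(rng, 150)
        res = growth.bootstrap_ci(ages, L, B=200, seed=5)
        for p in growth.PARAMS:
            lo, hi = res["ci"][p]
            assert lo <= getattr(res["point"], p) <= hi

    def test_small_b_rejected(self, rng):
        ages, L = _simulate(rng, 50)
        with pytest.raises(ValueError, match="B >= 100"):
            growth.bootstrap_ci(ages, L, B=50)


@pytest.fixture(scope="module")
def null_data():
    rng = np.random.default_rng(99)
    frames = []
    for g in "abc":
        ages, L = _simulate(rng, 150)
        frames.append(pd.DataFrame({"age": ages, "length": L, "group": g}))
    return pd.concat(frames, ignore_index=True)


class TestLattice:
    def test_identical_groups_select_coincident(self, null_data):
        lattice = growth.compare_growth(null_data)
        assert lattice.selected == frozenset()
        first = lattice.comparisons.iloc[0]
        assert first["p"] > 0.05

    def test_nesting_monotonicity_of_loglik(self, null_data):
        lattice = growth.compare_growth(null_data)
        for key, fit in lattice.fits.items():
            for other, ofit in lattice.fits.items():
                if key < other:
                    assert fit.loglik <= ofit.loglik + 1e-6

    def test_parameter_counts_match_lattice_structure(self, null_data):
        lattice = growth.compare_growth(null_data)
        g = 3
        for key, fit in lattice.fits.items():
            assert fit.m == sum(g if p in key else 1 for p in growth.PARAMS)
        assert lattice.fits[frozenset()].m == 3
        assert lattice.fits[frozenset(growth.PARAMS)].m == 9

    def test_chi2_equals_rss_ratio_form(self, null_data):
        lattice = growth.compare_growth(null_data)
        full = lattice.fits[frozenset(growth.PARAMS)]
        red = lattice.fits[frozenset()]
        n = full.n
        chi2_rss = n * np.log(red.rss / full.rss)
        chi2_ll = 2 * (full.loglik - red.loglik)
        assert chi2_rss == pytest.approx(chi2_ll, rel=1e-9)

    def test_selection_invariant_to_label_permutation(self, null_data):
        relabel = {"a": "z", "b": "y", "c": "x"}
        permuted = null_data.assign(group=null_data["group"].map(relabel))
        l1 = growth.compare_growth(null_data)
        l2 = growth.compare_growth(permuted)
        assert l1.selected == l2.selected
        f1 = l1.fits[frozenset(growth.PARAMS)]
        f2 = l2.fits[frozenset(growth.PARAMS)]
        assert f1.loglik == pytest.approx(f2.loglik, rel=1e-9)

    def test_distinct_groups_detected(self):
        rng = np.random.default_rng(3)
        frames = []
        for g, truth in [("a", (38.0, 0.15, -3.5)), ("b", (46.0, 0.22, -1.0))]:
            ages, L = _simulate(rng, 200, truth=truth)
            frames.append(pd.DataFrame({"age": ages, "length": L, "group": g}))
        lattice = growth.compare_growth(pd.concat(frames, ignore_index=True))
        assert lattice.selected != frozenset()
        assert lattice.comparisons.iloc[0]["p"] < 0.05

    def test_single_group_rejected(self, null_data):
        with pytest.raises(ValueError, match="2 groups"):
            growth.compare_growth(null_data[null_data["group"] == "a"])


class TestDerived:
    def test_phi_prime_log_identities(self):
        assert growth.growth_performance(1.0, 10.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("k, linf, expected", [
        (0.14, 39.58, 2.3),   # females
        (0.16, 38.14, 2.4),   # males
    ])
    def test_phi_prime_published_rows(self, k, linf, expected):
        assert round(growth.growth_performance(k, linf), 1) == expected

    @pytest.mark.parametrize("k, t0, expected", [
        (0.11, -4.86, 22.41),
        (0.16, -3.25, 15.50),
        (3.0, 0.0, 1.0),
    ])
    def test_lifespan_closed_form(self, k, t0, expected):
        assert round(growth.lifespan(k, t0), 2) == pytest.approx(expected)

    def test_high_precision_against_independent_evaluation(self):
        # mpmath-free independent check via fractions of the closed forms
        from decimal import Decimal
        k, t0 = 0.12, -4.99
        exact = float(Decimal(3) / Decimal("0.12") + Decimal("-4.99"))
        assert growth.lifespan(k, t0) == pytest.approx(exact, abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            growth.growth_performance(-0.1, 40.0)
        with pytest.raises(ValueError):
            growth.lifespan(0.0, -1.0)
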