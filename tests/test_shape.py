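"""Allometric correction, PCoA, variable selection, PERMANOVA, dispersion."""

import numpy as np
import pandas as pd
import pytest

from otostock import shape


def _allometric_frame(rng, n=300, b=1.4235, site_effect=None,
                      interaction=False, cv=0.10):
    sites = rng.choice(["s1", "s2", "s3"], n)
    fl = rng.uniform(17, 39, n)
    sigma = np.sqrt(np.log(1 + cv ** 2))
    bb = np.where(sites == "s1", b + 0.6, b) if interaction else b
    mult = np.ones(n)
    if site_effect:
        mult = np.array([site_effect[s] for s in sites])
    v = 0.05 * fl ** bb * mult * np.exp(rng.normal(0, sigma, n))
    return pd.DataFrame({"V": v}), fl, sites


class TestClassifyAndCorrect:
    def test_length_only_variable_corrected_with_slope_recovered(self, rng):
        tbl, fl, sites = _allometric_frame(rng)
        decisions, corrected = shape.classify_and_correct(tbl, fl, sites)
        d = decisions[0]
        assert d.state == "corrected"
        assert d.slope == pytest.approx(1.4235, abs=0.05)
        assert "V" in corrected.columns

    def test_correction_removes_length_dependence(self, rng):
        import statsmodels.api as sm
        tbl, fl, sites = _allometric_frame(rng, n=500)
        _, corrected = shape.classify_and_correct(tbl, fl, sites)
        X = sm.add_constant(np.log(fl))
        res = sm.OLS(np.log(corrected["V"]), X).fit()
        slope, se = np.asarray(res.params)[1], np.asarray(res.bse)[1]
        assert abs(slope) <= 2 * se

    def test_site_specific_exponent_removed(self, rng):
        tbl, fl, sites = _allometric_frame(rng, interaction=True)
        decisions, corrected = shape.classify_and_correct(tbl, fl, sites)
        assert decisions[0].state == "removed_site_x_length"
        assert "V" not in corrected.columns

    def test_site_and_length_confound_removed(self, rng):
        tbl, fl, sites = _allometric_frame(
            rng, site_effect={"s1": 0.8, "s2": 1.0, "s3": 1.25})
        decisions, _ = shape.classify_and_correct(tbl, fl, sites)
        assert decisions[0].state == "removed_site_x_length"

    def test_independent_variable_kept(self, rng):
        n = 300
        tbl = pd.DataFrame({"V": np.exp(rng.normal(0, 0.1, n))})
        fl = rng.uniform(17, 39, n)
        sites = rng.choice(["s1", "s2"], n)
        decisions, corrected = shape.classify_and_correct(tbl, fl, sites)
        assert decisions[0].state == "kept"
        np.testing.assert_allclose(corrected["V"], tbl["V"])

    def test_nonpositive_variable_excluded_with_reason(self, rng):
        tbl = pd.DataFrame({"V": [1.0, -2.0, 3.0] * 20})
        fl = rng.uniform(17, 39, 60)
        sites = rng.choice(["s1", "s2"], 60)
        decisions, corrected = shape.classify_and_correct(tbl, fl, sites)
        assert decisions[0].state == "excluded"
        assert corrected.empty

    def test_percentage_index_arcsine_transformed(self, rng):
        n = 200
        pct = 100 / (1 + np.exp(-rng.normal(0.4, 0.2, n)))
        tbl = pd.DataFrame({"OsA_SAA": pct})
        fl = rng.uniform(17, 39, n)
        sites = rng.choice(["s1", "s2"], n)
        _, corrected = shape.classify_and_correct(tbl, fl, sites)
        expected = np.arcsin(np.sqrt(pct / 100))
        np.testing.assert_allclose(corrected["OsA_SAA"], expected)


class TestNormalize:
    def test_zero_mean_unit_sd(self, rng):
        tbl = pd.DataFrame(rng.lognormal(0, 0.4, (50, 3)), columns=list("abc"))
        z = shape.normalize(tbl)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, rtol=1e-12)
        assert len(z) == len(tbl)

    def test_constant_column_dropped_with_warning(self, rng):
        tbl = pd.DataFrame({"a": rng.normal(0, 1, 20), "c": np.full(20, 3.0)})
        with pytest.warns(RuntimeWarning, match="constant"):
            z = shape.normalize(tbl)
        assert list(z.columns) == ["a"]

    def test_identical_columns_flagged_by_collinearity_screen(self, rng):
        x = rng.normal(0, 1, 40)
        tbl = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 40)})
        z = shape.normalize(tbl)
        pd.testing.assert_series_equal(z["a"], z["b"], check_names=False)
        pairs = shape.collinearity_screen(z)
        assert {"a", "b"} in [set(p) for p in zip(pairs["var1"], pairs["var2"])]


class TestPcoa:
    def test_two_points_land_at_plus_minus_half_distance(self):
        d = 3.0
        D = np.array([[0.0, d], [d, 0.0]])
        res = shape.pcoa(D)
        coords = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        np.testing.assert_allclose(coords, [-d / 2, d / 2], atol=1e-12)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_matches_pca_scores_up_to_sign(self, rng):
        from sklearn.decomposition import PCA
        for _ in range(5):
            X = rng.normal(0, 1, (20, 8))
            D = shape.euclidean_distance(pd.DataFrame(X))
            res = shape.pcoa(D)
            scores = PCA(n_components=5).fit_transform(X)
            for i in range(5):
                ours = res.coordinates.iloc[:, i].to_numpy()
                theirs = scores[:, i]
                agree = min(np.abs(ours - theirs).max(),
                            np.abs(ours + theirs).max())
                assert agree < 1e-8

    def test_eigenvalue_total_matches_centered_trace(self, rng):
        X = rng.normal(0, 1, (30, 5))
        Xc = X - X.mean(axis=0)
        D = shape.euclidean_distance(pd.DataFrame(X))
        res = shape.pcoa(D)
        assert res.eigenvalues.sum() == pytest.approx(np.sum(Xc ** 2), rel=1e-9)
        assert np.all(np.diff(res.proportion_explained) <= 1e-12)

    def test_coordinates_centred_at_origin(self, rng):
        X = rng.normal(0, 1, (25, 4))
        res = shape.pcoa(shape.euclidean_distance(pd.DataFrame(X)))
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            shape.pcoa(D)

    def test_variable_equal_to_axis_scores_contributes_fully(self, rng):
        X = rng.normal(0, 1, (30, 4))
        res = shape.pcoa(shape.euclidean_distance(pd.DataFrame(X)))
        tbl = pd.DataFrame({"ax1": res.coordinates.iloc[:, 0]})
        contrib = shape.variable_contributions(res, tbl)
        assert contrib.loc["ax1", "PCo1"] == pytest.approx(100.0)


class TestSelectVariables:
    def test_threshold_logic(self):
        contrib = pd.DataFrame({"PCo1": [95.3, 79.9, 10.0],
                                "PCo2": [5.0, 50.0, 87.2]},
                               index=["a", "b", "c"])
        assert shape.select_variables(contrib) == ["a", "c"]

    def test_zero_threshold_selects_all(self):
        contrib = pd.DataFrame({"PCo1": [1.0, 2.0], "PCo2": [0.5, 0.1]},
                               index=["a", "b"])
        assert shape.select_variables(contrib, threshold=0.0) == ["a", "b"]

    def test_empty_selection_falls_back_with_warning(self):
        contrib = pd.DataFrame({"PCo1": [10.0], "PCo2": [20.0]}, index=["a"])
        with pytest.warns(RuntimeWarning, match="falling back"):
            assert shape.select_variables(contrib) == ["a"]

    def test_informative_variables_selected_in_clustered_data(self, rng):
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            n = 60
            cluster = rng.choice([0, 1], n)
            informative = (cluster[:, None] * 4.0
                           + rng.normal(0, 0.5, (n, 3)))
            noise = rng.normal(0, 1, (n, 5))
            tbl = pd.DataFrame(np.hstack([informative, noise]),
                               columns=[f"v{i}" for i in range(8)])
            z = shape.normalize(tbl)
            res = shape.pcoa(shape.euclidean_distance(z))
            contrib = shape.variable_contributions(res, z)
            sel = shape.select_variables(contrib)
            if {"v0", "v1", "v2"} <= set(sel):
                hits += 1
        assert hits / n_rep >= 0.95


class TestPermanova:
    def test_extreme_separation_reaches_minimum_p(self, rng):
        a = rng.normal(0, 0.1, (12, 3))
        b = rng.normal(50, 0.1, (12, 3))
        X = pd.DataFrame(np.vstack([a, b]))
        labels = ["a"] * 12 + ["b"] * 12
        res = shape.permanova(shape.euclidean_distance(X), labels,
                              n_perm=199, seed=4)
        assert res.overall()["p"] == pytest.approx(1 / 200)

    def test_null_p_values_roughly_uniform(self, rng):
        from scipy import stats
        pvals = []
        for _ in range(120):
            X = pd.DataFrame(rng.normal(0, 1, (24, 3)))
            labels = rng.permutation(["a"] * 12 + ["b"] * 12)
            res = shape.permanova(shape.euclidean_distance(X), labels,
                                  n_perm=99, seed=int(rng.integers(2 ** 31)))
            pvals.append(res.overall()["p"])
        rej = np.mean(np.array(pvals) <= 0.05)
        # binomial 95% band around 0.05 for 120 replicates
        assert rej <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / 120) + 1e-9
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_f_statistic_invariant_to_label_order(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (20, 4)))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        D = shape.euclidean_distance(X)
        f1 = shape.permanova(D, labels, n_perm=49, seed=1).overall()["pseudo_f"]
        order = rng.permutation(20)
        D2 = D.iloc[order, order]
        f2 = shape.permanova(D2, labels[order], n_perm=49, seed=2).overall()["pseudo_f"]
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_matches_reference_implementation_statistic(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova
        X = pd.DataFrame(rng.normal(0, 1, (18, 4)))
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        D = shape.euclidean_distance(X)
        ours = shape.permanova(D, labels, n_perm=49, seed=0).overall()
        dm = skbio.DistanceMatrix(D.to_numpy(), ids=[str(i) for i in range(18)])
        theirs = sk_permanova(dm, grouping=list(labels), permutations=49)
        assert ours["pseudo_f"] == pytest.approx(theirs["test statistic"],
                                                 rel=1e-9)

    def test_reproducible_under_fixed_seed(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (20, 3)))
        labels = ["a"] * 10 + ["b"] * 10
        D = shape.euclidean_distance(X)
        r1 = shape.permanova(D, labels, n_perm=99, seed=42)
        r2 = shape.permanova(D, labels, n_perm=99, seed=42)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_single_label_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (10, 3)))
        with pytest.raises(ValueError, match="2 label"):
            shape.permanova(shape.euclidean_distance(X), ["a"] * 10)

    def test_per_level_rows_present(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (18, 3)))
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        res = shape.permanova(shape.euclidean_distance(X), labels,
                              n_perm=49, seed=9)
        assert set(res.table["level"]) == {"a", "b", "c", "overall"}


class TestBetadisper:
    def test_identical_points_have_zero_dispersion(self):
        X = pd.DataFrame(np.zeros((6, 2)) + [[1.0, 2.0]])
        X.iloc[3:] = [5.0, 5.0]
        res = shape.pcoa(shape.euclidean_distance(X))
        disp = shape.betadisper(res, ["a"] * 3 + ["b"] * 3)
        assert disp.mean_distances["a"] == pytest.approx(0.0, abs=1e-9)
        assert disp.mean_distances["b"] == pytest.approx(0.0, abs=1e-9)

    def test_two_points_mean_distance_half_separation(self):
        X = pd.DataFrame({"x": [0.0, 4.0, 10.0, 10.0], "y": [0.0] * 4})
        res = shape.pcoa(shape.euclidean_distance(X))
        disp = shape.betadisper(res, ["a", "a", "b", "b"])
        assert disp.mean_distances["a"] == pytest.approx(2.0)

    def test_centroids_are_coordinate_means(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (20, 3)))
        res = shape.pcoa(shape.euclidean_distance(X))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        disp = shape.betadisper(res, labels)
        manual = res.coordinates[labels == "a"].mean(axis=0).to_numpy()
        np.testing.assert_allclose(disp.centroids.loc["a"].to_numpy(), manual,
                                   atol=1e-12)
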