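import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tipnet import wgcna as wg

from conftest import oracle_tom


def planted_blocks(rng, block_sizes, n_noise, n_samples=24, within=0.95):
    """Rows: correlated blocks then independent noise genes."""
    rows, labels = [], []
    for b, size in enumerate(block_sizes, start=1):
        factor = rng.standard_normal(n_samples)
        for _ in range(size):
            rows.append(within * factor + np.sqrt(1 - within**2)
                        * rng.standard_normal(n_samples))
            labels.append(b)
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        labels.append(0)
    return np.array(rows), np.array(labels)


class TestAdjacency:
    def test_power_one_is_absolute_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 10))
        np.testing.assert_allclose(
            wg.adjacency(x, 1), np.abs(np.corrcoef(x)), atol=1e-12
        )

    def test_powered_entry(self):
        # two genes engineered to correlate at exactly 0.8
        rng = np.random.default_rng(1)
        z1, z2 = rng.standard_normal((2, 2000))
        z2 = z2 - z2.mean() - (z1 - z1.mean()) * np.dot(z1 - z1.mean(), z2) / np.dot(
            z1 - z1.mean(), z1 - z1.mean()
        )
        x = np.vstack([z1, 0.8 * (z1 - z1.mean()) / z1.std()
                       + 0.6 * (z2 - z2.mean()) / z2.std()])
        a = wg.adjacency(x, 8)
        assert a[0, 1] == pytest.approx(0.8**8, rel=1e-9)

    def test_duplicated_gene_fully_connected(self):
        rng = np.random.default_rng(2)
        row = rng.standard_normal(12)
        a = wg.adjacency(np.vstack([row, row]), 13)
        assert a[0, 1] == pytest.approx(1.0)

    def test_zero_variance_gene_warns_and_zeroes(self):
        x = np.vstack([np.ones(8), np.arange(8.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            a = wg.adjacency(x, 2)
        assert a[0, 1] == 0.0 and a[0, 0] == 1.0


class TestSoftThreshold:
    def test_mean_connectivity_decreases_with_power(self, small_study):
        x = np.log2(small_study.expression.values.to_numpy(float) + 1)
        scan = wg.soft_threshold_scan(x, powers=[1, 2, 4, 8])
        assert all(
            a >= b for a, b in zip(scan.mean_connectivity, scan.mean_connectivity[1:])
        )

    def test_constant_connectivity_flagged_undefined(self):
        # two duplicated profiles: every |cor| = 1, connectivity constant
        rng = np.random.default_rng(3)
        row = rng.standard_normal(10)
        x = np.vstack([row, row, -row])
        scan = wg.soft_threshold_scan(x, powers=[1, 2])
        assert all(np.isnan(f) for f in scan.fit_r2)

    def test_chosen_power_matches_independent_fit(self):
        """Re-derive the scale-free fit with an independent regression and
        check the same power is selected on planted two-module data."""
        rng = np.random.default_rng(4)
        x, _ = planted_blocks(rng, [40, 40], 20)
        powers = list(range(1, 11))
        scan = wg.soft_threshold_scan(x, powers=powers)

        c = np.abs(np.corrcoef(x))
        np.fill_diagonal(c, 0.0)
        fits = []
        for beta in powers:
            k = (c**beta).sum(axis=1)
            edges = np.linspace(k.min(), k.max(), 11)
            which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
            xs, ys = [], []
            for b in range(10):
                m = which == b
                if m.any() and k[m].mean() > 0:
                    xs.append(np.log10(k[m].mean()))
                    ys.append(np.log10(m.mean()))
            slope, _, r, _, _ = stats.linregress(xs, ys)
            fits.append(r**2 * np.sign(-slope))
        arr = np.nan_to_num(np.array(fits), nan=-np.inf)
        expected = (
            powers[int(np.flatnonzero(arr >= 0.85)[0])]
            if (arr >= 0.85).any()
            else powers[int(arr.argmax())]
        )
        assert scan.chosen_power == expected


class TestTom:
    def test_uniform_triangle(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        t = wg.tom_similarity(a)
        assert t[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_no_edges_gives_zero_overlap(self):
        t = wg.tom_similarity(np.eye(4))
        assert np.allclose(t - np.eye(4), 0.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for n in (4, 6, 8, 10):
            c = rng.random((n, n))
            a = (c + c.T) / 2
            np.fill_diagonal(a, 1.0)
            np.testing.assert_allclose(
                wg.tom_similarity(a), oracle_tom(a), atol=1e-12
            )

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((30, 15))
        t = wg.tom_similarity(wg.adjacency(x, 4))
        assert np.allclose(t, t.T)
        assert t.min() >= 0 and t.max() <= 1 + 1e-12


class TestClusterModules:
    def test_two_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(7)
        x, truth = planted_blocks(rng, [40, 40], 20, within=0.995)
        tom = wg.tom_similarity(wg.adjacency(x, 6))
        labels = wg.cluster_modules(1 - tom, min_module_size=30)
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_small_cluster_goes_grey(self):
        rng = np.random.default_rng(8)
        x, _ = planted_blocks(rng, [10], 25, within=0.99)
        tom = wg.tom_similarity(wg.adjacency(x, 6))
        labels = wg.cluster_modules(1 - tom, min_module_size=30)
        assert set(labels) == {0}

    def test_gene_order_invariance(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(9)
        x, _ = planted_blocks(rng, [35, 32], 15)
        tom = wg.tom_similarity(wg.adjacency(x, 6))
        d = 1 - tom
        labels = wg.cluster_modules(d, min_module_size=30)
        perm = rng.permutation(x.shape[0])
        labels_p = wg.cluster_modules(d[np.ix_(perm, perm)], min_module_size=30)
        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)

    def test_fewer_genes_than_min_size_all_grey(self):
        with pytest.warns(UserWarning, match="unassigned"):
            labels = wg.cluster_modules(np.zeros((5, 5)), min_module_size=30)
        assert set(labels) == {0}


class TestEigengenes:
    def test_single_gene_module_is_standardised_profile(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((1, 12))
        eig, ve = wg.module_eigengenes(x, np.array([1]))
        expected = (x[0] - x[0].mean()) / x[0].std(ddof=1)
        np.testing.assert_allclose(eig.loc[1].to_numpy(), expected, atol=1e-9)

    def test_rank_one_module_fully_explained(self):
        rng = np.random.default_rng(11)
        row = rng.standard_normal(10)
        x = np.vstack([row, 2 * row + 3])
        _, ve = wg.module_eigengenes(x, np.array([1, 1]))
        assert ve[1] == pytest.approx(1.0)

    def test_orientation_invariant_to_global_sign_flip(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((6, 14)) + rng.standard_normal(14)
        labels = np.ones(6, dtype=int)
        eig1, _ = wg.module_eigengenes(x, labels)
        eig2, _ = wg.module_eigengenes(-x, labels)
        np.testing.assert_allclose(
            eig1.to_numpy(), -eig2.to_numpy(), atol=1e-9
        )

    def test_zero_variance_gene_raises(self):
        x = np.vstack([np.ones(8), np.arange(8.0)])
        with pytest.raises(ValueError, match="module 1"):
            wg.module_eigengenes(x, np.array([1, 1]))

    def test_eigengene_explains_most_variance(self):
        """PCA optimality: no single gene's standardised profile explains
        more module variance than the eigengene."""
        rng = np.random.default_rng(13)
        factor = rng.standard_normal(20)
        x = np.array([0.8 * factor + 0.6 * rng.standard_normal(20) for _ in range(8)])
        labels = np.ones(8, dtype=int)
        eig, ve = wg.module_eigengenes(x, labels)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        total = (z**2).sum()
        for g in range(8):
            d = z[g] / np.linalg.norm(z[g])
            explained = ((z @ d) ** 2).sum() / total
            assert explained <= ve[1] + 1e-9


class TestMergeAndColors:
    def _blocks(self, cor):
        rng = np.random.default_rng(14)
        f1 = rng.standard_normal(30)
        resid = rng.standard_normal(30)
        resid -= resid @ f1 / (f1 @ f1) * f1
        f1 = (f1 - f1.mean()) / f1.std()
        resid = (resid - resid.mean()) / resid.std()
        f2 = cor * f1 + np.sqrt(1 - cor**2) * resid
        x = np.vstack([
            np.array([f1 + 0.02 * rng.standard_normal(30) for _ in range(5)]),
            np.array([f2 + 0.02 * rng.standard_normal(30) for _ in range(5)]),
        ])
        return x, np.array([1] * 5 + [2] * 5)

    @pytest.mark.parametrize(
        "cor,should_merge", [(1.0, True), (0.8, True), (0.7, False)]
    )
    def test_merge_threshold_arithmetic(self, cor, should_merge):
        x, labels = self._blocks(cor)
        merged = wg.merge_close_modules(x, labels, cut_height=0.25)
        n_modules = len(set(merged) - {0})
        assert (n_modules == 1) == should_merge

    def test_colors_by_decreasing_size(self):
        labels = np.array([2] * 5 + [1] * 3 + [0] * 2)
        colors = wg.assign_colors(labels)
        assert list(colors[:5]) == ["turquoise"] * 5
        assert list(colors[5:8]) == ["blue"] * 3
        assert list(colors[8:]) == ["grey"] * 2

    def test_size_tie_broken_by_first_member(self):
        labels = np.array([5, 5, 9, 9])
        colors = wg.assign_colors(labels)
        assert list(colors) == ["turquoise", "turquoise", "blue", "blue"]


class TestMembershipAndTraits:
    def test_membership_of_eigengene_like_genes(self):
        rng = np.random.default_rng(15)
        e = rng.standard_normal(16)
        resid = rng.standard_normal(16)
        resid -= resid @ (e - e.mean()) / ((e - e.mean()) @ (e - e.mean())) * (
            e - e.mean()
        )
        x = np.vstack([e, -e, resid])
        eig = pd.DataFrame([e], index=[1])
        mm = wg.module_membership(x, eig)
        assert mm.loc[0, 1] == pytest.approx(1.0)
        assert mm.loc[1, 1] == pytest.approx(-1.0)
        assert mm.loc[2, 1] == pytest.approx(0.0, abs=1e-9)

    def test_gene_significance_absolute_by_default(self):
        trait = np.array([0.0, 0, 1, 1, 2, 2])
        x = np.vstack([trait, -trait])
        gs = wg.gene_significance(x + 1e-9, trait)
        assert gs[0] == pytest.approx(1.0, abs=1e-6)
        assert gs[1] == pytest.approx(1.0, abs=1e-6)
        signed = wg.gene_significance(x + 1e-9, trait, signed=True)
        assert signed[1] == pytest.approx(-1.0, abs=1e-6)

    def test_zero_variance_trait_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            wg.gene_significance(np.random.default_rng(0).random((3, 6)),
                                 np.ones(6))

    def test_trait_correlation_hand_example(self):
        eig = pd.DataFrame([np.arange(1.0, 7.0)], index=[1])
        traits = pd.DataFrame({"stage": [0.0, 0, 1, 1, 2, 2]})
        out = wg.module_trait_correlation(eig, traits)
        r_ref, p_ref = stats.pearsonr(np.arange(1.0, 7.0), [0, 0, 1, 1, 2, 2])
        assert out["r"].iloc[0] == pytest.approx(r_ref, rel=1e-9)
        assert out["r"].iloc[0] == pytest.approx(0.956, abs=5e-4)
        assert out["p"].iloc[0] == pytest.approx(p_ref, rel=1e-9)
        assert out["p"].iloc[0] == pytest.approx(0.0028, abs=2e-4)

    def test_trait_p_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(16)
        eig = pd.DataFrame(rng.standard_normal((4, 24)), index=[1, 2, 3, 4])
        traits = pd.DataFrame({"t": rng.standard_normal(24)})
        out = wg.module_trait_correlation(eig, traits)
        for _, row in out.iterrows():
            r_ref, p_ref = stats.pearsonr(
                eig.loc[row["module"]].to_numpy(), traits["t"].to_numpy()
            )
            assert row["r"] == pytest.approx(r_ref, rel=1e-12)
            assert row["p"] == pytest.approx(p_ref, rel=1e-9)

    def test_trait_p_uniform_under_null(self):
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(200):
            eig = pd.DataFrame(rng.standard_normal((1, 24)), index=[1])
            traits = pd.DataFrame({"t": rng.standard_normal(24)})
            ps.append(wg.module_trait_correlation(eig, traits)["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestHubGenes:
    def test_thresholds_strict(self):
        labels = np.array([1, 1, 1])
        mm = pd.DataFrame({1: [0.81, 0.80, 0.90]})
        gs = np.array([0.21, 0.50, 0.10])
        hub = wg.select_hub_genes(mm, gs, labels)
        # |mm|=0.81 & gs=0.21 -> hub; |mm|=0.80 exact -> not; gs=0.10 -> not
        assert list(hub) == [True, False, False]

    def test_restricted_to_selected_modules(self):
        labels = np.array([1, 2])
        mm = pd.DataFrame({1: [0.9, 0.1], 2: [0.1, 0.9]})
        gs = np.array([0.5, 0.5])
        hub = wg.select_hub_genes(mm, gs, labels, modules=[1])
        assert list(hub) == [True, False]
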