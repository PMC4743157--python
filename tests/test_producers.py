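import itertools
import math

import numpy as np
import pandas as pd
import pytest

from termclouds.producers import (
    ExpressionMatrix,
    associate_features,
    blocks_from_clusters,
    blocks_from_de,
    blocks_from_pca,
    blocks_from_pcoa,
    boxplot_stats,
    bray_curtis,
    loading_gene_lists,
    pca,
    pcoa,
    spearman_test,
)


def random_exprs(n_genes=40, n_samples=12, seed=0):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        values=pd.DataFrame(
            rng.normal(size=(n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )


class TestPCA:
    def test_orthonormal_loadings_and_score_projection(self):
        ex = random_exprs(seed=1)
        res = pca(ex)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        Xc = ex.values.to_numpy() - ex.values.to_numpy().mean(axis=1, keepdims=True)
        assert np.allclose(res.scores.to_numpy(), Xc.T @ L, atol=1e-8)

    def test_reconstruction_with_all_components(self):
        ex = random_exprs(n_genes=50, n_samples=8, seed=2)
        res = pca(ex)
        Xc = ex.values.to_numpy() - ex.values.to_numpy().mean(axis=1, keepdims=True)
        recon = res.loadings.to_numpy() @ res.scores.to_numpy().T
        assert np.allclose(recon, Xc, atol=1e-8)

    def test_variance_percentages(self):
        res = pca(random_exprs(seed=3))
        assert (np.diff(res.var_pct) <= 1e-12).all()
        assert res.var_pct.sum() <= 100 + 1e-9

    def test_sign_convention_largest_loading_positive(self):
        res = pca(random_exprs(seed=4))
        L = res.loadings.to_numpy()
        peaks = L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])]
        assert (peaks > 0).all()

    def test_two_gene_toy_dominant_variance(self):
        # closed form: cov diag (4, 0.01) -> PC1 along gene A, var split 99.75%
        rng = np.random.default_rng(5)
        a = rng.normal(0, 2.0, size=200)
        b = rng.normal(0, 0.1, size=200)
        ex = ExpressionMatrix(
            values=pd.DataFrame([a, b], index=["A", "B"], columns=[f"s{i}" for i in range(200)])
        )
        res = pca(ex, n_comp=2)
        assert abs(res.loadings.loc["A", "PC1"]) > abs(res.loadings.loc["B", "PC1"])
        assert res.var_pct[0] > res.var_pct[1]
        assert res.var_pct[0] == pytest.approx(
            100 * np.var(a - a.mean()) / (np.var(a - a.mean()) + np.var(b - b.mean())), rel=0.05
        )

    def test_n_comp_clamped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            res = pca(random_exprs(n_genes=30, n_samples=6), n_comp=50)
        assert res.loadings.shape[1] == 5
        assert any("clamped" in r.message for r in caplog.records)

    def test_matches_sklearn(self):
        # independent route: sklearn PCA on the transposed (samples x genes) data
        from sklearn.decomposition import PCA as SkPCA

        ex = random_exprs(n_genes=60, n_samples=15, seed=9)
        res = pca(ex, n_comp=4)
        sk = SkPCA(n_components=4).fit(ex.values.to_numpy().T)
        ours = res.var_pct / 100
        theirs = sk.explained_variance_ratio_
        # sklearn centers per gene across samples identically
        assert np.allclose(ours, theirs, atol=1e-10)
        for c in range(4):
            dot = abs(np.dot(res.loadings.to_numpy()[:, c], sk.components_[c]))
            assert dot == pytest.approx(1.0, abs=1e-8)


class TestLoadingLists:
    def test_exactly_500_per_side_on_2000_genes(self):
        ex = random_exprs(n_genes=2000, n_samples=20, seed=7)
        model = blocks_from_pca(ex, n_comp=2, n_genes=500)
        for block in model.blocks:
            neg, pos = block.gene_lists
            assert (len(neg), len(pos)) == (500, 500)
            assert neg.side == "negative" and pos.side == "positive"

    def test_sides_disjoint_and_sorted(self):
        ex = random_exprs(n_genes=200, n_samples=10, seed=8)
        res = pca(ex, n_comp=1)
        neg, pos = loading_gene_lists(res.loadings["PC1"], n_genes=500)
        assert not (set(neg.genes) & set(pos.genes))
        lv = res.loadings["PC1"]
        assert all(lv[g] > 0 for g in pos.genes)
        assert all(lv[g] < 0 for g in neg.genes)
        assert list(lv[list(pos.genes)]) == sorted(lv[list(pos.genes)], reverse=True)

    def test_truncation_respects_sign_counts(self):
        s = pd.Series([0.5, 0.1, 0.0, -0.2], index=list("abcd"))
        neg, pos = loading_gene_lists(s, n_genes=500)
        assert pos.genes == ("a", "b") and neg.genes == ("d",)

    def test_histogram_panel_annotation_has_variance(self):
        ex = random_exprs(n_genes=100, n_samples=16, seed=10)
        model = blocks_from_pca(ex, n_comp=1)
        assert model.blocks[0].annotation.endswith("%")
        panel = model.blocks[0].panel
        total = sum(sum(c) for c in panel.counts)
        assert total == 16  # every sample lands in a bin


class TestClusters:
    def test_k_blocks(self):
        ex = random_exprs(n_genes=30, n_samples=6, seed=1)
        assignment = {f"g{i}": (i % 5) + 1 for i in range(30)}
        model = blocks_from_clusters(ex, assignment)
        assert len(model.blocks) == 5
        assert [b.title for b in model.blocks] == [f"Cluster {i}" for i in range(1, 6)]
        assert model.blocks[0].annotation == "6 genes"

    def test_single_cluster_panel_equals_whole_matrix_stats(self):
        ex = random_exprs(n_genes=25, n_samples=5, seed=2)
        model = blocks_from_clusters(ex, {f"g{i}": 1 for i in range(25)})
        (block,) = model.blocks
        expected = [boxplot_stats(ex.values[c].to_numpy()) for c in ex.sample_ids]
        assert list(block.panel.stats) == expected

    def test_absent_gene_is_error_naming_it(self):
        ex = random_exprs(n_genes=5, n_samples=4)
        with pytest.raises(KeyError, match="ghost"):
            blocks_from_clusters(ex, {"ghost": 1})


class TestDE:
    def _table(self):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(20)],
                "effect": [1.0] * 10 + [-1.0] * 3 + [0.0] * 2 + [2.0] * 5,
                "p_adj": [0.01] * 13 + [0.001] * 2 + [0.9] * 5,
            }
        )

    def test_up_down_counts(self):
        model = blocks_from_de(self._table(), threshold=0.05)
        (block,) = model.blocks
        down, up = block.gene_lists
        assert (len(up), len(down)) == (10, 3)
        assert block.annotation == "10 up / 3 down"

    def test_zero_effect_in_neither_list(self):
        model = blocks_from_de(self._table(), threshold=0.05)
        down, up = model.blocks[0].gene_lists
        assert "g13" not in up.genes + down.genes  # effect 0, significant p

    def test_all_insignificant_still_emits_block(self):
        t = self._table()
        t["p_adj"] = 0.5
        model = blocks_from_de(t, threshold=0.05)
        (block,) = model.blocks
        assert all(len(gl) == 0 for gl in block.gene_lists)
        assert block.annotation == "0 up / 0 down"

    def test_contrast_column_splits_blocks(self):
        t = self._table()
        t["contrast"] = ["A vs B"] * 10 + ["C vs D"] * 10
        model = blocks_from_de(t)
        assert [b.title for b in model.blocks] == ["A vs B", "C vs D"]


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert bray_curtis(X)[0, 1] == 0.0

    def test_disjoint_support_one(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert bray_curtis(X)[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        X = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert bray_curtis(X)[0, 1] == pytest.approx(1 / 3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[1.0, -1.0], [0.0, 1.0]]))

    def test_all_zero_pair_defined_zero(self, caplog):
        import logging

        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with caplog.at_level(logging.WARNING):
            D = bray_curtis(X)
        assert D[0, 1] == 0.0
        assert np.isfinite(D).all()

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 50, size=(8, 12)).astype(float)
        D = bray_curtis(X)
        assert np.allclose(D, D.T)
        assert (D >= 0).all() and (D <= 1).all()
        assert np.allclose(np.diag(D), 0)


class TestPCoA:
    def test_euclidean_planar_points_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 2))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        res = pcoa(D, n_axes=2)
        D2 = squareform(pdist(res.coords.to_numpy()))
        assert np.allclose(D, D2, atol=1e-8)

    def test_identical_samples_coincide(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 0.0], [0.0, 4.0]])
        D = bray_curtis(X)
        res = pcoa(D, n_axes=2)
        c = res.coords.to_numpy()
        assert np.allclose(c[0], c[1], atol=1e-8)

    def test_eigenvalues_non_increasing(self):
        rng = np.random.default_rng(2)
        X = rng.integers(1, 30, size=(9, 15)).astype(float)
        res = pcoa(bray_curtis(X), n_axes=5)
        assert (np.diff(res.eigenvalues) <= 1e-10).all()
        assert (res.eigenvalues > 0).all()

    def test_spectrum_matches_pca_on_euclidean(self):
        # classical scaling of Euclidean distances == PCA of the point set
        rng = np.random.default_rng(3)
        ex = random_exprs(n_genes=6, n_samples=10, seed=3)
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(ex.values.to_numpy().T))
        res_pcoa = pcoa(D, n_axes=5)
        res_pca = pca(ex, n_comp=5)
        s2 = (res_pca.scores.to_numpy() ** 2).sum(axis=0)
        assert np.allclose(res_pcoa.eigenvalues, s2[: len(res_pcoa.eigenvalues)], atol=1e-8)

    def test_matches_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(4)
        X = rng.integers(0, 40, size=(10, 20)).astype(float)
        D = bray_curtis(X)
        ours = pcoa(D, n_axes=3)
        theirs = skbio_pcoa(D, method="eigh")
        pos = theirs.eigvals[theirs.eigvals > 1e-10].to_numpy()
        assert np.allclose(np.sort(ours.eigenvalues)[::-1], np.sort(pos)[::-1][: len(ours.eigenvalues)], atol=1e-8)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            pcoa(np.array([[1.0, 0.0], [0.0, 1.0]]))  # nonzero diagonal


class TestSpearman:
    def test_perfectly_monotone(self):
        rho, p = spearman_test(np.arange(6.0), np.arange(6.0) ** 2)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(6))  # two perfect orders

    def test_exact_p_matches_permutation_oracle_n5(self):
        # oracle: scipy rho over all 120 permutations, counted directly
        from scipy.stats import spearmanr

        rng = np.random.default_rng(6)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rho_obs, p_ours = spearman_test(x, y)
        count = 0
        for perm in itertools.permutations(range(5)):
            r = spearmanr(x, y[list(perm)]).statistic
            count += abs(r) >= abs(rho_obs) - 1e-12
        assert p_ours == pytest.approx(count / 120)

    def test_large_n_uses_t_approximation(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman_test(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_test(np.ones(6), np.arange(6.0))


class TestBlocksFromPcoa:
    def _abundance(self, seed=0, n=20):
        from termclouds.synthetic import make_abundance

        return make_abundance(n_features=30, n_samples=n, n_groups=2, seed=seed)

    def test_blocks_and_clouds(self):
        table, classes, _ = self._abundance()
        model = blocks_from_pcoa(table, sample_classes=classes, n_axes=2)
        assert len(model.blocks) == 2
        for block in model.blocks:
            neg, pos = block.gene_lists
            assert len(block.clouds[0]) == len(neg)
            assert len(block.clouds[1]) == len(pos)

    def test_feature_equal_to_axis_maximal(self):
        rng = np.random.default_rng(8)
        X = rng.integers(1, 50, size=(12, 10)).astype(float)
        D = bray_curtis(X)
        res = pcoa(D, n_axes=1)
        table = pd.DataFrame(X, index=res.coords.index, columns=[f"f{i}" for i in range(10)])
        table["mirror"] = res.coords.iloc[:, 0] - res.coords.iloc[:, 0].min() + 1
        associate_features(res, table)
        row = res.feature_assoc[0].loc["mirror"]
        assert row["rho"] == pytest.approx(1.0)
        assert row["p"] == res.feature_assoc[0]["p"].min()

    def test_constant_feature_excluded(self, caplog):
        import logging

        table, classes, _ = self._abundance(seed=1)
        table["flat"] = 7
        with caplog.at_level(logging.WARNING):
            model = blocks_from_pcoa(table, sample_classes=classes, n_axes=1)
        assert any("constant feature" in r.message for r in caplog.records)
        for gl in model.blocks[0].gene_lists:
            assert "flat" not in gl.genes

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError):
            blocks_from_pcoa(X)

    def test_permuted_feature_type_one_control(self):
        # a feature decoupled from the axis should rarely reach raw p <= alpha
        rng = np.random.default_rng(9)
        X = rng.integers(1, 60, size=(12, 8)).astype(float)
        res = pcoa(bray_curtis(X), n_axes=1)
        coord = res.coords.iloc[:, 0].to_numpy()
        feature = X[:, 0].copy()
        n_rep, hits = 300, 0
        for _ in range(n_rep):
            rng.shuffle(feature)
            _, p = spearman_test(feature, coord)
            hits += p <= 0.05
        assert hits / n_rep <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_rep)


def test_boxplot_stats_tukey():
    v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 100.0])
    s = boxplot_stats(v)
    assert s.med == pytest.approx(3.5)
    assert s.q1 == pytest.approx(np.percentile(v, 25))
    assert s.whishi == 5.0  # 100 is beyond 1.5*IQR
    assert s.whislo == 1.0
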