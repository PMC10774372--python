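"""Normalization, clustering, markers, scores, annotation, TF activity."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mbenkit.expression_core import (
    annotate_by_reference,
    batch_adjust,
    cell_cycle_phase,
    embed_and_cluster,
    find_markers,
    gene_set_overlap_test,
    merge_similar_clusters,
    module_score,
    normalize,
    tf_activity,
)


def _adata(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    return ad.AnnData(X=X, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


class TestNormalize:
    def test_zero_cell_stays_zero(self):
        norm = normalize(_adata([[0, 0, 0], [1, 2, 3]]))
        assert (norm.X[0] == 0).all()

    def test_proportional_cells_identical(self):
        norm = normalize(_adata([[1, 2, 3], [2, 4, 6]]))
        np.testing.assert_allclose(norm.X[0], norm.X[1])

    def test_expm1_roundtrip(self):
        X = np.array([[5.0, 0.0, 15.0], [1.0, 1.0, 2.0]])
        norm = normalize(_adata(X))
        scaled = np.expm1(norm.X)
        expected = X / X.sum(1, keepdims=True) * 1e4
        np.testing.assert_allclose(scaled, expected, atol=1e-9)


class TestCluster:
    def test_separated_gaussians_perfectly_recovered(self, rng):
        # resolution below 1 keeps each dense cloud a single community
        # (plain modularity would hit the resolution limit and split them)
        a = rng.normal(0, 1, (150, 20))
        b = rng.normal(10, 1, (150, 20))
        adata = _adata(np.vstack([a, b]))
        res = embed_and_cluster(adata, n_pcs=10, k=10, resolution=0.3, seed=0)
        truth = [0] * 150 + [1] * 150
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_partition_invariant_to_cell_order(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 15)), rng.normal(6, 1, (100, 15))])
        adata = _adata(X)
        base = embed_and_cluster(adata, n_pcs=5, k=8, seed=0)
        perm = rng.permutation(200)
        shuffled = ad.AnnData(X=X[perm], var=adata.var.copy())
        shuffled.obs_names = [f"cell{i}" for i in perm]
        out = embed_and_cluster(shuffled, n_pcs=5, k=8, seed=0)
        assert adjusted_rand_score(base.labels.to_numpy()[perm], out.labels.to_numpy()) == 1.0

    def test_default_cohort_recovers_states(self, cohort, cohort_clusters):
        adata, _ = cohort
        _, clusters = cohort_clusters
        assert adjusted_rand_score(adata.obs["state"], clusters.labels) >= 0.8

    def test_cluster_means_recomputable(self, cohort_clusters):
        norm, clusters = cohort_clusters
        lab = clusters.labels
        c0 = clusters.cluster_ids[0]
        manual = np.asarray(norm.X)[(lab == c0).to_numpy()].mean(axis=0)
        np.testing.assert_allclose(clusters.means.loc[c0].to_numpy(), manual)


class TestMergeClusters:
    def test_random_split_remerged(self, rng):
        # heterogeneous gene means give cluster profiles real structure
        gene_means = rng.lognormal(1, 0.8, 30)
        X = rng.normal(gene_means, 0.4, (200, 30))
        adata = _adata(X)
        labels = pd.Series(["a"] * 100 + ["b"] * 100, index=adata.obs_names)
        from mbenkit.expression_core import ClusterResult, cluster_means

        res = ClusterResult(labels=labels, means=cluster_means(adata, labels),
                            pcs=pd.DataFrame(np.zeros((200, 2)), index=adata.obs_names))
        merged = merge_similar_clusters(res, adata, r_min=0.95)
        assert len(merged.cluster_ids) == 1

    def test_rmin_one_keeps_distinct_clusters(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 10)), rng.normal(3, 1, (50, 10))])
        adata = _adata(X)
        labels = pd.Series(["a"] * 50 + ["b"] * 50, index=adata.obs_names)
        from mbenkit.expression_core import ClusterResult, cluster_means

        res = ClusterResult(labels=labels, means=cluster_means(adata, labels),
                            pcs=pd.DataFrame(np.zeros((100, 2)), index=adata.obs_names))
        assert len(merge_similar_clusters(res, adata, r_min=1.0).cluster_ids) == 2

    def test_transitive_closure_merges_three(self, rng):
        gene_means = rng.lognormal(1, 0.8, 30)
        base = rng.normal(gene_means, 0.4, (300, 30))
        adata = _adata(base)
        labels = pd.Series(["a"] * 100 + ["b"] * 100 + ["c"] * 100, index=adata.obs_names)
        from mbenkit.expression_core import ClusterResult, cluster_means

        res = ClusterResult(labels=labels, means=cluster_means(adata, labels),
                            pcs=pd.DataFrame(np.zeros((300, 2)), index=adata.obs_names))
        assert len(merge_similar_clusters(res, adata, r_min=0.9).cluster_ids) == 1


class TestFindMarkers:
    def test_planted_marker_top_ranked(self, rng):
        n = 200
        X = rng.lognormal(0, 0.3, (2 * n, 50))
        X[:n, 0] *= 4  # planted marker, log2FC ~ 2
        adata = _adata(X)
        labels = pd.Series(["hit"] * n + ["rest"] * n, index=adata.obs_names)
        table = find_markers(adata, labels)
        top = table[table.cluster == "hit"].iloc[0]
        assert top.gene == "g0"
        assert top.qvalue < 0.05

    def test_null_false_positive_rate(self, rng):
        X = rng.normal(5, 1, (400, 1000))
        adata = _adata(X)
        labels = pd.Series(["a"] * 200 + ["b"] * 200, index=adata.obs_names)
        table = find_markers(adata, labels)
        frac = (table[table.cluster == "a"].pvalue < 0.05).mean()
        assert abs(frac - 0.05) <= 0.02

    def test_zero_variance_gene_reported_p1(self, rng):
        X = rng.normal(5, 1, (60, 5))
        X[:, 2] = 7.0
        adata = _adata(X)
        labels = pd.Series(["a"] * 30 + ["b"] * 30, index=adata.obs_names)
        table = find_markers(adata, labels)
        assert (table[table.gene == "g2"].pvalue == 1.0).all()

    def test_qvalues_monotone_in_pvalues(self, rng):
        X = rng.normal(5, 1, (100, 40))
        X[:50, :5] += 1
        adata = _adata(X)
        labels = pd.Series(["a"] * 50 + ["b"] * 50, index=adata.obs_names)
        table = find_markers(adata, labels)
        sub = table[table.cluster == "a"].sort_values("pvalue")
        assert (np.diff(sub.qvalue.to_numpy()) >= -1e-12).all()

    def test_tiny_cluster_skipped_with_warning(self, rng):
        X = rng.normal(5, 1, (33, 5))
        adata = _adata(X)
        labels = pd.Series(["a"] * 31 + ["b"] * 2, index=adata.obs_names)
        with pytest.warns(UserWarning, match="fewer than"):
            table = find_markers(adata, labels)
        assert set(table.cluster) == {"a"}


class TestModuleScore:
    def test_random_set_scores_near_zero(self, rng):
        X = rng.lognormal(0, 0.5, (500, 200))
        norm = normalize(_adata(X))
        gene_set = [f"g{i}" for i in rng.choice(200, 20, replace=False)]
        score = module_score(norm, gene_set, seed=0)
        assert abs(score.mean()) <= 0.05

    def test_planted_shift_recovered(self, rng):
        # enough genes that set genes share their expression bins with
        # plenty of unshifted controls
        gene_means = rng.uniform(1, 5, 1000)
        X = rng.normal(gene_means, 0.2, (400, 1000))
        X[:20, :10] += 1.0  # +1 log-shift on set genes in a small subpopulation
        adata = _adata(X)
        score = module_score(adata, [f"g{i}" for i in range(10)], seed=0)
        assert score[:20].mean() == pytest.approx(1.0, abs=0.1)

    def test_order_invariance(self, rng):
        X = rng.lognormal(0, 0.5, (100, 50))
        norm = normalize(_adata(X))
        genes = [f"g{i}" for i in range(5, 15)]
        s1 = module_score(norm, genes, seed=3)
        s2 = module_score(norm, genes[::-1], seed=3)
        pd.testing.assert_series_equal(s1, s2)


class TestCellCycle:
    def test_argmax_rules(self, rng):
        gene_means = rng.uniform(1, 4, 60)
        X = rng.normal(gene_means, 0.2, (50, 60))
        X[:25, :5] += 2.0   # S genes up in first half
        X[25:, :10] -= 1.0  # both signatures suppressed in second half
        adata = _adata(X)
        df = cell_cycle_phase(adata, [f"g{i}" for i in range(5)],
                              [f"g{i}" for i in range(5, 10)])
        assert (df.phase[:25] == "S").mean() > 0.9
        assert (df.phase[25:] == "G1").mean() > 0.8

    def test_proliferating_state_called_cycling(self, cohort, cohort_clusters, spatial_panel):
        adata, _ = cohort
        norm, _ = cohort_clusters
        pro = spatial_panel[spatial_panel.marker_state == "proliferating_early_cgnp"]["gene"]
        df = cell_cycle_phase(norm, list(pro[:8]), list(pro[8:]))
        prolif = (adata.obs.state == "proliferating_early_cgnp").to_numpy()
        assert (df.phase[prolif] != "G1").mean() >= 0.9


class TestAnnotate:
    def test_exact_centroid_match(self, rng):
        centroids = pd.DataFrame(rng.uniform(0, 5, (3, 30)),
                                 index=["t1", "t2", "t3"],
                                 columns=[f"g{i}" for i in range(30)])
        adata = _adata(centroids.loc[["t2"]].to_numpy())
        out = annotate_by_reference(adata, centroids)
        assert out.label.iloc[0] == "t2"
        assert out.rho.iloc[0] == pytest.approx(1.0)

    def test_noise_profile_unassigned(self, rng):
        centroids = pd.DataFrame(
            np.tile(np.arange(50, dtype=float), (2, 1)) * np.array([[1.0], [-1.0]]),
            index=["up", "down"], columns=[f"g{i}" for i in range(50)],
        )
        # constant profile: zero rank variance, correlation undefined -> unassigned
        adata = _adata(np.full((1, 50), 3.0))
        out = annotate_by_reference(adata, centroids)
        assert out.label.iloc[0] == "unassigned"

    def test_cohort_accuracy_vs_generator_means(self, cohort, cohort_clusters):
        adata, truth = cohort
        norm, _ = cohort_clusters
        out = annotate_by_reference(norm, truth.state_means)
        acc = (out.label.to_numpy() == adata.obs.state.to_numpy()).mean()
        assert acc >= 0.9


class TestBatchAdjust:
    def test_batch_means_zeroed(self, rng):
        X = rng.normal(3, 1, (80, 20))
        adata = _adata(X)
        batches = pd.Series(["b1"] * 40 + ["b2"] * 40, index=adata.obs_names)
        out = batch_adjust(adata, batches)
        for b in ("b1", "b2"):
            assert np.abs(out.X[(batches == b).to_numpy()].mean(0)).max() < 1e-9

    def test_planted_batch_shift_removed(self, rng):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        X = rng.normal(0, 1, (300, 40))
        X[:150] += rng.normal(1.0, 0.2, 40)  # batch shift
        adata = _adata(X)
        batches = pd.Series(["b1"] * 150 + ["b2"] * 150, index=adata.obs_names)
        out = batch_adjust(adata, batches)
        from sklearn.decomposition import PCA

        pcs = PCA(n_components=10, svd_solver="full").fit_transform(out.X)
        acc = cross_val_score(LogisticRegression(max_iter=500), pcs,
                              batches.to_numpy(), cv=5).mean()
        assert acc <= 0.6

    def test_state_structure_survives_adjustment(self, cohort):
        adata, _ = cohort
        rng = np.random.default_rng(5)
        norm = normalize(adata)
        batches = pd.Series(rng.choice(["b1", "b2"], adata.n_obs), index=adata.obs_names)
        base = embed_and_cluster(norm, seed=0)
        adj = embed_and_cluster(batch_adjust(norm, batches), seed=0)
        ari_base = adjusted_rand_score(adata.obs.state, base.labels)
        ari_adj = adjusted_rand_score(adata.obs.state, adj.labels)
        assert ari_base - ari_adj <= 0.05


class TestTFActivity:
    @staticmethod
    def _regulons(rng, n_genes=60, tfs=("TF1", "TF2", "TF3")):
        rows = []
        for t, tf in enumerate(tfs):
            targets = rng.choice(n_genes, 12, replace=False)
            for g in targets:
                rows.append({"tf": tf, "target": f"g{g}", "weight": rng.choice([1.0, -1.0])})
        return pd.DataFrame(rows)

    def test_upshifted_targets_top_positive(self, rng):
        reg = self._regulons(rng)
        X = rng.normal(2, 0.3, (5, 60))
        up = reg[(reg.tf == "TF2") & (reg.weight > 0)].target
        dn = reg[(reg.tf == "TF2") & (reg.weight < 0)].target
        gidx = {f"g{i}": i for i in range(60)}
        for g in up:
            X[0, gidx[g]] += 2.0
        for g in dn:
            X[0, gidx[g]] -= 2.0
        adata = _adata(X)
        acts = tf_activity(adata, reg)
        assert acts.iloc[0].idxmax() == "TF2"
        assert acts.iloc[0]["TF2"] > 0

    def test_weight_negation_flips_sign(self, rng):
        reg = self._regulons(rng)
        X = rng.normal(2, 0.5, (4, 60))
        adata = _adata(X)
        a1 = tf_activity(adata, reg)
        reg2 = reg.copy()
        reg2.loc[reg2.tf == "TF1", "weight"] *= -1
        a2 = tf_activity(adata, reg2)
        np.testing.assert_allclose(a2["TF1"], -a1["TF1"], rtol=1e-8)

    def test_zero_weight_column_rejected(self, rng):
        reg = self._regulons(rng)
        reg.loc[reg.tf == "TF3", "weight"] = 0.0
        adata = _adata(rng.normal(2, 0.5, (3, 60)))
        with pytest.raises(ValueError, match="rank-deficient"):
            tf_activity(adata, reg)

    def test_too_few_tfs_rejected(self, rng):
        reg = pd.DataFrame({"tf": ["TF1"] * 4, "target": ["g0", "g1", "g2", "g3"],
                            "weight": [1.0] * 4})
        with pytest.raises(ValueError, match="at least 2"):
            tf_activity(_adata(rng.normal(0, 1, (3, 10))), reg)


class TestGeneSetOverlap:
    def test_disjoint_sets_not_enriched(self):
        out = gene_set_overlap_test(
            [f"a{i}" for i in range(20)], {"ref": [f"b{i}" for i in range(20)]}, 1000
        )
        assert out.pvalue[0] > 0.5
        assert out.overlap[0] == 0

    def test_chi_square_matches_hand_computation(self):
        # 50 of 100 query genes in a 100-gene reference, universe 1000:
        # table [[50, 50], [50, 850]]; all expected counts >= 5
        out = gene_set_overlap_test(
            [f"g{i}" for i in range(100)],
            {"ref": [f"g{i}" for i in range(50)] + [f"x{i}" for i in range(50)]},
            1000,
        )
        a, b, c, d = 50, 50, 50, 850
        n = a + b + c + d
        expected = [
            [(a + b) * (a + c) / n, (a + b) * (b + d) / n],
            [(c + d) * (a + c) / n, (c + d) * (b + d) / n],
        ]
        chi2 = sum(
            (abs(obs - exp) - 0.5) ** 2 / exp
            for row_o, row_e in zip([[a, b], [c, d]], expected)
            for obs, exp in zip(row_o, row_e)
        )
        assert out.method[0] == "chi2"
        assert out.statistic[0] == pytest.approx(chi2, rel=1e-9)

    def test_small_counts_use_fisher_exact(self):
        from scipy.stats import fisher_exact

        out = gene_set_overlap_test(
            [f"g{i}" for i in range(5)], {"ref": [f"g{i}" for i in range(3)]}, 50
        )
        assert out.method[0] == "fisher"
        expected_p = fisher_exact([[3, 2], [0, 45]])[1]
        assert out.pvalue[0] == pytest.approx(expected_p)
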