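import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import uegkit as uk


def two_shape_data(rng, n_per=30, dim=19, noise=0.01):
    X = np.vstack([
        0.8 + noise * rng.standard_normal((n_per, dim)),
        0.2 + noise * rng.standard_normal((n_per, dim)),
    ])
    labels = np.array([0] * n_per + [1] * n_per)
    return np.clip(X, 0, 1), labels


def as_drm(X, genes=None):
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    grid = tuple(range(5, 100, 5))
    pct = pd.DataFrame(np.sort(X, axis=1)[:, : len(grid)], index=genes,
                       columns=[f"q{g:02d}" for g in grid])
    q25, q50, q75 = np.percentile(X, [25, 50, 75], axis=1)
    summary = pd.DataFrame(
        {"q50": q50, "iqr": q75 - q25, "skewness": 0.0, "n": X.shape[1]}, index=genes
    )
    return uk.DynamicRangeMatrix(pct, summary, grid, X.shape[1])


class TestPercentileClusterer:
    def test_two_planted_shapes_recovered_exactly(self, rng):
        X, truth = two_shape_data(rng)
        model = uk.PercentileClusterer(method="affinity", random_state=7).fit(X)
        assert adjusted_rand_score(truth, model.labels_) == 1.0
        assert model.n_clusters_ == 2

    def test_identical_rows_single_cluster(self):
        X = np.tile(np.linspace(0, 1, 19), (10, 1))
        model = uk.PercentileClusterer(method="affinity", random_state=0).fit(X)
        assert model.n_clusters_ == 1

    def test_deterministic_for_fixed_seed(self, rng):
        X, _ = two_shape_data(rng, noise=0.05)
        a = uk.PercentileClusterer(method="affinity", random_state=3).fit(X)
        b = uk.PercentileClusterer(method="affinity", random_state=3).fit(X)
        assert np.array_equal(a.labels_, b.labels_)

    def test_kmeans_mode_recovers_shapes(self, rng):
        X, truth = two_shape_data(rng)
        model = uk.PercentileClusterer(
            method="kmeans", n_clusters=2, random_state=5
        ).fit(X)
        assert adjusted_rand_score(truth, model.labels_) == 1.0

    def test_kmeans_requires_k(self, rng):
        X, _ = two_shape_data(rng)
        with pytest.raises(ValueError, match="n_clusters"):
            uk.PercentileClusterer(method="kmeans").fit(X)

    def test_exemplars_belong_to_their_cluster(self, rng):
        X, _ = two_shape_data(rng)
        model = uk.PercentileClusterer(method="affinity", random_state=1).fit(X)
        for c, idx in enumerate(model.exemplar_indices_):
            assert model.labels_[idx] == c


class TestClusterGenes:
    def _spec(self, genes, phi01, phi10):
        return pd.DataFrame({"phi@TPM:0.1": phi01, "phi@TPM:1": phi10}, index=genes)

    def test_medians_and_sizes(self, rng):
        X, truth = two_shape_data(rng, n_per=20)
        drm = as_drm(X)
        spec = self._spec(drm.gene_ids, [1.0] * 20 + [0.1] * 20, [0.9] * 20 + [0.0] * 20)
        result = uk.cluster_genes(drm, spec, method="affinity", seed=2)
        assert result.medians["size"].sum() == 40
        assert result.n_clusters == 2
        # each exemplar is a member of its own cluster
        for c, g in result.exemplars.items():
            assert result.labels[g] == c

    def test_homogeneity_zero_for_identical_members(self):
        X = np.tile(np.linspace(0, 1, 19), (8, 1))
        drm = as_drm(X)
        spec = self._spec(drm.gene_ids, [1.0] * 8, [1.0] * 8)
        result = uk.cluster_genes(drm, spec, seed=0)
        assert uk.cluster_homogeneity(drm, result) == 0.0

    def test_true_labels_tighter_than_permuted(self, rng):
        X, truth = two_shape_data(rng, n_per=25, noise=0.03)
        drm = as_drm(X)
        spec = self._spec(drm.gene_ids, [1.0] * 50, [1.0] * 50)
        result = uk.cluster_genes(drm, spec, seed=4)
        good = uk.cluster_homogeneity(drm, result)
        permuted = uk.ClusterResult(
            labels=pd.Series(rng.permutation(result.labels.to_numpy()),
                             index=result.labels.index),
            exemplars=result.exemplars,
            medians=result.medians,
            method=result.method,
        )
        assert good < uk.cluster_homogeneity(drm, permuted)


class TestAssignCategories:
    def _clusters(self, rows):
        med = pd.DataFrame(rows).set_index("cluster_id")
        med["size"] = 1
        labels = pd.Series(med.index, index=[f"g{c}" for c in med.index])
        exemplars = pd.Series([f"g{c}" for c in med.index], index=med.index)
        return uk.ClusterResult(labels=labels, exemplars=exemplars, medians=med,
                                method="affinity")

    @pytest.mark.parametrize(
        "phi10, phi01, expected",
        [
            (0.95, 1.0, "UEGs@1.0"),
            (0.4, 0.9, "UEGs@0.1"),
            (0.2, 0.25, "SEGs@0.1"),
            (0.25, 0.5, "SEGs@1.0"),
            (0.5, 0.5, "MSG"),
            (0.8, 0.8, "UEGs@1.0"),   # boundary: inclusive >=
            (0.3, 0.3, "SEGs@0.1"),   # boundary: inclusive <=
        ],
    )
    def test_rule_order(self, phi10, phi01, expected):
        clusters = self._clusters(
            [{"cluster_id": 0, "median_phi@TPM:1": phi10, "median_phi@TPM:0.1": phi01}]
        )
        cats = uk.assign_categories(clusters)
        assert cats.cluster_category.loc[0] == expected

    def test_partition_no_gene_unassigned(self, demo_run):
        cats = demo_run.categories.gene_category
        assert not cats.isna().any()
        assert set(cats.unique()) <= set(uk.cluster.CATEGORIES)
        assert len(cats) == demo_run.drm.percentiles.shape[0]

    def test_ueg10_clusters_satisfy_their_rule(self, demo_run):
        med = demo_run.clusters.medians
        cats = demo_run.categories.cluster_category
        for c in med.index[cats == "UEGs@1.0"]:
            assert med.loc[c, "median_phi@TPM:1"] >= 0.8

    def test_missing_phi_column_is_error(self):
        clusters = self._clusters([{"cluster_id": 0, "median_phi@TPM:1": 0.9}])
        with pytest.raises(KeyError):
            uk.assign_categories(clusters)


class TestSelectLovar:
    def test_low_iqr_ueg_cluster_selected_msg_excluded(self):
        med = pd.DataFrame(
            {
                "cluster_id": [0, 1],
                "median_phi@TPM:1": [0.95, 0.5],
                "median_phi@TPM:0.1": [1.0, 0.6],
                "median_iqr": [0.05, 0.01],
            }
        ).set_index("cluster_id")
        labels = pd.Series([0, 0, 1, 1], index=["a", "b", "c", "d"])
        exemplars = pd.Series(["a", "c"], index=[0, 1])
        clusters = uk.ClusterResult(labels=labels, exemplars=exemplars,
                                    medians=med, method="affinity")
        cats = uk.assign_categories(clusters)
        drm = as_drm(np.vstack([np.full((2, 30), 0.9), np.full((2, 30), 0.5)]),
                     genes=["a", "b", "c", "d"])
        lv = uk.select_lovar(clusters, cats, drm, raw=None)
        assert sorted(lv.selected) == ["a", "b"]  # MSG cluster gated out
        assert lv.source_clusters == [0]

    def test_no_qualifying_cluster_empty_with_warning(self, rng):
        med = pd.DataFrame(
            {"cluster_id": [0], "median_phi@TPM:1": [0.2],
             "median_phi@TPM:0.1": [0.25], "median_iqr": [0.01]}
        ).set_index("cluster_id")
        labels = pd.Series([0, 0], index=["a", "b"])
        clusters = uk.ClusterResult(labels=labels,
                                    exemplars=pd.Series(["a"], index=[0]),
                                    medians=med, method="affinity")
        cats = uk.assign_categories(clusters)
        drm = as_drm(rng.random((2, 30)), genes=["a", "b"])
        lv = uk.select_lovar(clusters, cats, drm)
        assert lv.selected == []

    def test_planted_stable_gene_recall(self, demo_run):
        truth = demo_run.truth
        stable = set(truth.gene_ids("ueg_high", "stable"))
        recall = len(set(demo_run.lovar.selected) & stable) / len(stable)
        assert recall >= 0.9

    def test_selected_iqr_below_nonselected_uegs(self, demo_run):
        from scipy.stats import mannwhitneyu
        cats = demo_run.categories.gene_category
        sel = set(demo_run.lovar.selected)
        ueg = set(cats.index[cats.isin(uk.cluster.UEG_CATEGORIES)])
        nonsel = sorted(ueg - sel)
        iqr = demo_run.drm.summary["iqr"]
        res = mannwhitneyu(iqr[sorted(sel)], iqr[nonsel], alternative="less")
        assert res.pvalue < 1e-6

    def test_outliers_disjoint_from_selected(self, demo_run):
        assert not set(demo_run.lovar.selected) & set(demo_run.lovar.outliers_removed.index)
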