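"""k-means coarse-graining and similarity matrices."""

import numpy as np
import pytest

from oracles import brute_kmeans_2partition
from simseg import (
    ClusterModel,
    ProcessedSeries,
    build_similarities,
    kmeans_cluster,
    reassign_nuisance,
    sort_clusters_by_similarity,
)
from simseg.clustering import _pearson_rows


def make_series(features, nuisance=None):
    features = np.asarray(features, dtype=float)
    if nuisance is None:
        nuisance = np.zeros(len(features), dtype=bool)
    return ProcessedSeries(features=features, nuisance_flag=np.asarray(nuisance))


def two_cloud_series(rng, n_per=5, nuisance_rows=0):
    a = rng.normal([0, 0, 0, 0], 0.05, size=(n_per, 4))
    b = rng.normal([10, 10, -10, 3], 0.05, size=(n_per, 4))
    feats = np.vstack([a, b])
    if nuisance_rows:
        feats = np.vstack([feats, np.zeros((nuisance_rows, 4))])
    flag = np.zeros(len(feats), dtype=bool)
    flag[2 * n_per :] = True
    return make_series(feats, flag)


class TestKMeans:
    def test_two_clouds_match_exhaustive_partition(self):
        rng = np.random.default_rng(0)
        series = two_cloud_series(rng)
        model = kmeans_cluster(series, K=2, seed=0)
        found = frozenset(np.nonzero(model.labels == model.labels[0])[0].tolist())
        best = brute_kmeans_2partition(series.features)
        assert found in (best, frozenset(range(10)) - best)

    def test_nuisance_rows_keep_label_zero(self):
        rng = np.random.default_rng(1)
        series = two_cloud_series(rng, nuisance_rows=3)
        model = kmeans_cluster(series, K=2, seed=0)
        np.testing.assert_array_equal(model.labels[-3:], 0)
        assert set(model.labels[:-3]) == {1, 2}

    def test_too_few_expressed_positions(self):
        series = make_series(np.zeros((4, 3)), nuisance=[True, True, True, False])
        with pytest.raises(ValueError, match="expressed"):
            kmeans_cluster(series, K=2, seed=0)

    def test_identical_rows_degenerate(self):
        series = make_series(np.ones((6, 3)))
        with pytest.raises(ValueError):
            kmeans_cluster(series, K=2, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        series = make_series(rng.normal(size=(40, 5)))
        m1 = kmeans_cluster(series, K=3, seed=7)
        m2 = kmeans_cluster(series, K=3, seed=7)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        np.testing.assert_allclose(m1.centers, m2.centers)


class TestSimilarities:
    def test_position_equal_to_center_correlates_one(self):
        rng = np.random.default_rng(3)
        series = two_cloud_series(rng)
        model = kmeans_cluster(series, K=2, seed=0)
        model = build_similarities(series, model)
        probe = make_series(np.vstack([model.centers, series.features]))
        m2 = build_similarities(probe, model)
        assert m2.pos_cluster_sim[0, 0] == pytest.approx(1.0)
        assert m2.pos_cluster_sim[1, 1] == pytest.approx(1.0)

    def test_negated_center_anticorrelates(self):
        centers = np.array([[1.0, 2.0, -1.0], [-1.0, -2.0, 1.0]])
        sims = _pearson_rows(centers, centers)
        assert sims[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        rows = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [1.0, 1.0, 1.0]])
        centers = np.array([[0.0, 1.0, 2.0], [5.0, 0.0, 1.0]])
        got = _pearson_rows(rows, centers)
        for i, r in enumerate(rows):
            for j, c in enumerate(centers):
                num = np.sum((r - r.mean()) * (c - c.mean()))
                den = np.sqrt(np.sum((r - r.mean()) ** 2) * np.sum((c - c.mean()) ** 2))
                expected = num / den if den > 0 else 0.0
                assert got[i, j] == pytest.approx(expected)
        # zero-variance row -> 0 by convention, not NaN
        np.testing.assert_array_equal(got[2], [0.0, 0.0])

    def test_matrix_invariants(self):
        rng = np.random.default_rng(4)
        series = make_series(rng.normal(size=(50, 6)))
        model = build_similarities(series, kmeans_cluster(series, K=4, seed=1))
        ccs = model.cluster_cluster_sim
        np.testing.assert_allclose(ccs, ccs.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(ccs), 1.0)
        assert np.all(np.abs(ccs) <= 1 + 1e-12)
        assert np.all(np.abs(model.pos_cluster_sim) <= 1 + 1e-12)


class TestReassignNuisance:
    def build(self, own_corrs):
        n = len(own_corrs)
        model = ClusterModel(
            labels=np.ones(n, dtype=int),
            centers=np.zeros((2, 3)),
            K=2,
            pos_cluster_sim=np.column_stack([own_corrs, np.zeros(n)]),
            cluster_cluster_sim=np.eye(2),
        )
        return model

    def test_theta_minus_one_keeps_everything(self):
        model = reassign_nuisance(self.build([0.2, -0.9, 0.99]), theta=-1.0)
        np.testing.assert_array_equal(model.labels, 1)

    def test_theta_out_of_bounds(self):
        with pytest.raises(ValueError):
            reassign_nuisance(self.build([0.5]), theta=1.0 + 1e-9)

    def test_default_threshold_drops_low_correlation(self):
        model = reassign_nuisance(self.build([0.5, 0.7]), theta=0.6)
        np.testing.assert_array_equal(model.labels, [0, 1])

    def test_labeled_positions_meet_threshold_afterwards(self):
        rng = np.random.default_rng(5)
        series = make_series(rng.normal(size=(60, 6)))
        model = build_similarities(series, kmeans_cluster(series, K=3, seed=2))
        model = reassign_nuisance(model, theta=0.6)
        labeled = model.labels >= 1
        own = model.pos_cluster_sim[np.nonzero(labeled)[0], model.labels[labeled] - 1]
        assert (own >= 0.6).all()


class TestSortClusters:
    def test_two_clusters_swap_is_consistent(self):
        rng = np.random.default_rng(6)
        series = make_series(rng.normal(size=(30, 5)))
        model = build_similarities(series, kmeans_cluster(series, K=2, seed=3))
        before = model.cluster_cluster_sim.copy()
        model = sort_clusters_by_similarity(model)
        np.testing.assert_allclose(model.cluster_cluster_sim, before)  # K=2: symmetric swap

    def test_permutation_preserves_matrix_structure(self):
        rng = np.random.default_rng(7)
        series = make_series(rng.normal(size=(80, 6)))
        model = build_similarities(series, kmeans_cluster(series, K=4, seed=4))
        own_before = model.pos_cluster_sim[np.arange(model.n), np.maximum(model.labels - 1, 0)]
        model = sort_clusters_by_similarity(model)
        ccs = model.cluster_cluster_sim
        np.testing.assert_allclose(ccs, ccs.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(ccs), 1.0)
        # each position keeps the same correlation to its own (relabelled) center
        own_after = model.pos_cluster_sim[np.arange(model.n), np.maximum(model.labels - 1, 0)]
        np.testing.assert_allclose(own_after, own_before)
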