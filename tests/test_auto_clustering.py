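"""Distances, silhouette, clustering algorithms, k selection, display data."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from oracles import (
    brute_force_silhouette,
    greedy_agglomerative,
    labels_to_partition,
)
from peakflow import (
    DistanceMatrix,
    FixtureSpec,
    SignalMatrix,
    ValidationError,
    cluster_agglomerative,
    cluster_kmeans,
    embed_2d,
    heatmap_data,
    make_count_matrix,
    normalize,
    pairwise_distances,
    select_k,
    silhouette,
)


def matrix_from(values, kind="normalized"):
    values = np.asarray(values, dtype=float)
    return SignalMatrix(
        [f"f{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values, kind,
    )


def line_points():
    """The worked 4-point example: 1-D points 0, 1, 10, 11 in two clusters."""
    mat = matrix_from([[0, 0], [1, 0], [10, 0], [11, 0]])
    return pairwise_distances(mat, "euclidean"), np.array([0, 0, 1, 1])


class TestPairwiseDistances:
    def test_3_4_5_triangle(self):
        dist = pairwise_distances(matrix_from([[0, 0], [3, 4]]))
        assert dist.values[0, 1] == 5.0

    def test_identical_rows_correlation_zero(self):
        dist = pairwise_distances(matrix_from([[1, 2, 3], [1, 2, 3]]), "correlation")
        assert dist.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_row_convention(self):
        dist = pairwise_distances(
            matrix_from([[5, 5, 5], [5, 5, 5], [1, 2, 3]]), "correlation"
        )
        assert dist.values[0, 1] == 0.0   # identical constant rows
        assert dist.values[0, 2] == 1.0   # constant vs varying

    @pytest.mark.parametrize("metric", ["euclidean", "correlation"])
    def test_matches_double_loop(self, metric, rng):
        X = rng.normal(size=(20, 4))
        dist = pairwise_distances(matrix_from(X), metric)
        for i in range(20):
            for j in range(20):
                if metric == "euclidean":
                    expected = float(np.sqrt(((X[i] - X[j]) ** 2).sum()))
                else:
                    expected = 1.0 - float(np.corrcoef(X[i], X[j])[0, 1])
                assert dist.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_validation(self):
        with pytest.raises(ValidationError, match="metric"):
            pairwise_distances(matrix_from([[1, 2], [3, 4]]), "manhattan")
        with pytest.raises(ValidationError, match="2 features"):
            pairwise_distances(matrix_from([[1, 2]]))
        raw = matrix_from([[1, 2], [3, 4]], kind="raw_counts")
        with pytest.raises(ValidationError, match="normalized"):
            pairwise_distances(raw)


class TestSilhouette:
    def test_worked_line_example(self):
        dist, labels = line_points()
        mean, per_point = silhouette(labels, dist)
        expected = (9.5 / 10.5 + 8.5 / 9.5) / 2  # hand evaluation, symmetric pairs
        assert mean == pytest.approx(expected, abs=1e-12)
        assert mean == pytest.approx(0.8997, abs=5e-5)

    def test_coincident_points_zero(self):
        dist = pairwise_distances(matrix_from([[1, 1]] * 4))
        mean, per_point = silhouette(np.array([0, 0, 1, 1]), dist)
        assert mean == 0.0
        assert np.all(per_point == 0.0)

    def test_perfect_separation_limit(self):
        mat = matrix_from([[0, 0], [1e-9, 0], [1e9, 0], [1e9, 1e-9]])
        dist = pairwise_distances(mat)
        mean, _ = silhouette(np.array([0, 0, 1, 1]), dist)
        assert mean == pytest.approx(1.0, abs=1e-9)

    def test_triple_loop_oracle_and_sklearn(self, rng):
        """Vectorised silhouette equals the naive formula and sklearn."""
        for _ in range(10):
            n = int(rng.integers(5, 30))
            k = int(rng.integers(2, min(5, n - 1) + 1))
            X = rng.normal(size=(n, 3))
            labels = rng.integers(0, k, size=n)
            labels = np.unique(labels, return_inverse=True)[1]  # no empty ids
            if labels.max() == 0:
                continue
            dist = pairwise_distances(matrix_from(X))
            mean, per_point = silhouette(labels, dist)
            oracle_mean, oracle_pp = brute_force_silhouette(labels, dist.values)
            np.testing.assert_allclose(per_point, oracle_pp, atol=1e-10)
            assert mean == pytest.approx(oracle_mean, abs=1e-10)
            if np.min(np.bincount(labels)) > 1:  # sklearn has no singleton rule
                sk = silhouette_samples(dist.values, labels, metric="precomputed")
                np.testing.assert_allclose(per_point, sk, atol=1e-9)

    def test_label_permutation_invariance(self, rng):
        X = rng.normal(size=(15, 3))
        dist = pairwise_distances(matrix_from(X))
        labels = np.array([0, 1, 2] * 5)
        mean, _ = silhouette(labels, dist)
        perm = np.array([2, 0, 1])[labels]
        mean_perm, _ = silhouette(perm, dist)
        assert mean == pytest.approx(mean_perm, abs=1e-12)

    def test_validation(self):
        dist, _ = line_points()
        with pytest.raises(ValidationError, match="2 clusters"):
            silhouette(np.zeros(4, dtype=int), dist)
        with pytest.raises(ValidationError, match="empty"):
            silhouette(np.array([0, 0, 2, 2]), dist)


class TestKmeans:
    def test_two_blobs_ground_truth(self):
        mat, truth, _ = make_count_matrix(FixtureSpec(seed=0, planted_k=2))
        labels = cluster_kmeans(normalize(mat), 2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_minus_1_closest_pair(self, rng):
        """With k = n-1 the single doubleton is the minimising pair."""
        X = rng.normal(size=(6, 2)) * 10
        mat = matrix_from(X)
        labels = cluster_kmeans(mat, 5, seed=0, n_init=50)
        sizes = np.bincount(labels)
        assert sorted(sizes) == [1, 1, 1, 1, 2]
        pair = np.where(labels == np.argmax(sizes))[0]
        # brute force over all pairings: merging pair (i,j) costs d(i,j)^2 / 2
        best = min(
            ((i, j) for i in range(6) for j in range(i + 1, 6)),
            key=lambda ij: ((X[ij[0]] - X[ij[1]]) ** 2).sum(),
        )
        assert set(pair) == set(best)

    def test_same_seed_identical(self, blob_matrix):
        mat, _ = blob_matrix
        a = cluster_kmeans(mat, 3, seed=42)
        b = cluster_kmeans(mat, 3, seed=42)
        assert np.array_equal(a, b)

    def test_k_out_of_range(self, blob_matrix):
        mat, _ = blob_matrix
        with pytest.raises(ValidationError):
            cluster_kmeans(mat, 1)
        with pytest.raises(ValidationError):
            cluster_kmeans(mat, mat.shape[0])


class TestAgglomerative:
    def test_line_average_linkage(self):
        dist, _ = line_points()
        labels = cluster_agglomerative(dist, 2, "average")
        assert labels_to_partition(labels) == {frozenset({0, 1}), frozenset({2, 3})}

    def test_k_equals_n_degenerate(self):
        dist, _ = line_points()
        labels = cluster_agglomerative(dist, 4, "average")
        assert len(set(labels.tolist())) == 4

    @pytest.mark.parametrize("linkage", ["average", "complete"])
    def test_matches_greedy_merge_oracle(self, linkage, rng):
        for _ in range(10):
            n = int(rng.integers(4, 8))
            X = rng.normal(size=(n, 3))
            dist = pairwise_distances(matrix_from(X))
            k = int(rng.integers(2, n))
            labels = cluster_agglomerative(dist, k, linkage)
            expected = {
                frozenset(c) for c in greedy_agglomerative(dist.values, k, linkage)
            }
            assert labels_to_partition(labels) == expected

    def test_ward_requires_euclidean(self, rng):
        X = rng.normal(size=(6, 4))
        dist = pairwise_distances(matrix_from(X), "correlation")
        with pytest.raises(ValidationError, match="ward"):
            cluster_agglomerative(dist, 2, "ward")


class TestSelectK:
    def test_three_planted_clusters_recovered(self, blob_matrix):
        mat, truth = blob_matrix
        for algorithm in ("kmeans", "agglomerative"):
            result = select_k(mat, algorithm=algorithm, k_range=(2, 6), seed=0)
            assert result.k == 3
            assert adjusted_rand_score(truth, result.labels) == 1.0
            assert set(result.silhouette_by_k) == {2, 3, 4, 5, 6}
            assert all(-1 <= s <= 1 for s in result.silhouette_by_k.values())

    def test_collapsed_range_trivial_selection(self, blob_matrix):
        mat, _ = blob_matrix
        result = select_k(mat, k_range=(2, 2), seed=0)
        assert result.k == 2
        assert list(result.silhouette_by_k) == [2]

    def test_invalid_range(self, blob_matrix):
        mat, _ = blob_matrix
        with pytest.raises(ValidationError, match="k_range"):
            select_k(mat, k_range=(1, 5))
        with pytest.raises(ValidationError, match="k_range"):
            select_k(mat, k_range=(4, 3))


class TestEmbed2d:
    def test_deterministic_for_fixed_seed(self, blob_matrix):
        mat, _ = blob_matrix
        a = embed_2d(mat, seed=0, perplexity=20)
        b = embed_2d(mat, seed=0, perplexity=20)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (mat.shape[0], 2)

    def test_planted_structure_survives_embedding(self, blob_matrix):
        mat, truth = blob_matrix
        coords = embed_2d(mat, seed=0, perplexity=20)
        emb = matrix_from(coords)
        dist = pairwise_distances(emb)
        mean, _ = silhouette(np.asarray(truth), dist)
        assert mean > 0.25

    def test_perplexity_validation(self):
        mat = matrix_from(np.eye(5))
        with pytest.raises(ValidationError, match="perplexity"):
            embed_2d(mat, seed=0, perplexity=10)


class TestHeatmapData:
    def result_for(self, mat, labels):
        from peakflow import ClusteringResult

        return ClusteringResult(
            labels=labels, k=int(labels.max()) + 1, algorithm="kmeans",
            silhouette_by_k={int(labels.max()) + 1: 0.5}, seed=0,
        )

    def test_boundaries_after_cluster_sizes(self):
        mat = matrix_from(np.arange(10).reshape(5, 2))
        labels = np.array([0, 1, 0, 0, 1])
        data = heatmap_data(mat, self.result_for(mat, labels))
        assert data.boundaries == [3, 5]

    def test_rows_sorted_by_cluster_then_mean_desc(self):
        values = np.array([[1.0, 1], [5, 5], [3, 3], [9, 9]])
        mat = matrix_from(values)
        labels = np.array([0, 0, 1, 1])
        data = heatmap_data(mat, self.result_for(mat, labels))
        assert data.row_order.tolist() == [1, 0, 3, 2]

    def test_single_cluster_equal_rows_stable(self):
        mat = matrix_from(np.ones((4, 2)))
        labels = np.zeros(4, dtype=int)
        from peakflow import ClusteringResult

        result = ClusteringResult(labels=labels, k=1, algorithm="kmeans",
                                  silhouette_by_k={1: 0.0}, seed=0)
        data = heatmap_data(mat, result)
        assert data.row_order.tolist() == [0, 1, 2, 3]

    def test_row_multiset_preserved(self, rng):
        values = rng.normal(size=(12, 3))
        mat = matrix_from(values)
        labels = rng.integers(0, 3, size=12)
        labels = np.unique(labels, return_inverse=True)[1]
        data = heatmap_data(mat, self.result_for(mat, labels))
        got = sorted(map(tuple, np.round(data.values, 9)))
        expected = sorted(map(tuple, np.round(values, 9)))
        assert got == expected

    def test_length_mismatch(self):
        mat = matrix_from(np.ones((4, 2)))
        with pytest.raises(ValidationError, match="labels length"):
            heatmap_data(mat, self.result_for(mat, np.array([0, 1, 0])))


def test_distance_matrix_invariants():
    with pytest.raises(ValidationError, match="symmetric"):
        DistanceMatrix(np.array([[0, 1], [2, 0.0]]), "euclidean")
    with pytest.raises(ValidationError, match="diagonal"):
        DistanceMatrix(np.array([[1.0, 1], [1, 0]]), "euclidean")
    with pytest.raises(ValidationError, match="nonnegative"):
        DistanceMatrix(np.array([[0, -1], [-1, 0.0]]), "euclidean")
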