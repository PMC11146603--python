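"""K-means, rand index, silhouette, and K selection against oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import rand_score as sk_rand_score
from sklearn.metrics import silhouette_samples as sk_silhouette

from morphostrat.clustering import (SilhouetteCurve, assign, kmeans_fit,
                                    rand_index, select_k, silhouette_curve,
                                    silhouette_samples, stability_analysis)


def brute_force_rand_index(a, b):
    n = len(a)
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / (n * (n - 1) / 2)


def brute_force_silhouette(X, labels):
    n = len(X)
    D = squareform(pdist(X))
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(np.mean([D[i, j] for j in range(n) if labels[j] == c])
                for c in set(labels) if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


class TestKMeans:
    def test_k_equals_n_zero_inertia(self):
        X = np.arange(5.0)[:, None] * 10
        model = kmeans_fit(X, 5, seed=0)
        assert model.inertia == pytest.approx(0.0)
        assert len(set(model.labels_)) == 5

    def test_two_separated_pairs_1d(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        model = kmeans_fit(X, 2, seed=0, n_init=3)
        assert sorted(model.centroids.ravel()) == pytest.approx([0.05, 10.05])

    def test_duplicates_share_label(self):
        rng = np.random.default_rng(0)
        X = np.repeat(rng.standard_normal((10, 3)), 2, axis=0)
        model = kmeans_fit(X, 3, seed=1, n_init=3)
        assert (model.labels_[::2] == model.labels_[1::2]).all()

    def test_inertia_nonincreasing_within_fit(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 4))
        model = kmeans_fit(X, 5, seed=2)
        h = model.inertia_history
        assert all(a >= b - 1e-9 for a, b in zip(h, h[1:]))

    def test_rows_fewer_than_k_fails(self):
        with pytest.raises(ValueError, match="cannot fit"):
            kmeans_fit(np.ones((3, 2)), 4)

    def test_assign_reproduces_training_labels(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 3))
        model = kmeans_fit(X, 4, seed=0)
        assert np.array_equal(assign(model, X), model.labels_)

    def test_assign_tie_goes_to_lowest_index(self):
        model = kmeans_fit(np.array([[-1.0], [1.0]]), 2, seed=0)
        order = model.centroids.ravel().argsort()
        # the midpoint is equidistant; argmin picks the lowest centroid index
        lab = assign(model, np.array([[0.0]]))[0]
        assert lab == 0

    def test_assign_centroids_identity(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 3))
        model = kmeans_fit(X, 5, seed=0)
        assert np.array_equal(assign(model, model.centroids), np.arange(5))

    def test_dimension_mismatch(self):
        model = kmeans_fit(np.ones((4, 2)) * np.arange(4)[:, None], 2, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            assign(model, np.ones((2, 3)))


class TestRandIndex:
    def test_identical_and_permuted_labelings(self):
        a = np.array([0, 1, 1, 2, 0, 2])
        assert rand_index(a, a) == 1.0
        assert rand_index(a, (a + 1) % 3) == 1.0   # label-invariance

    def test_worked_example(self):
        assert rand_index([0, 0, 0, 1], [0, 0, 1, 1]) == pytest.approx(0.5)

    def test_matches_bruteforce_and_sklearn(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(2, 13)
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            ri = rand_index(a, b)
            assert ri == pytest.approx(brute_force_rand_index(a, b), abs=1e-12)
            assert ri == pytest.approx(sk_rand_score(a, b), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            rand_index([0, 1], [0, 1, 2])


class TestStability:
    def test_two_permutations_single_pair(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((60, 3))
        res = stability_analysis(X, [2], n_permutations=2, base_seed=0)
        a = kmeans_fit(X, 2, seed=0 + 7919 * 2 + 0, n_init=10).labels_
        b = kmeans_fit(X, 2, seed=0 + 7919 * 2 + 1, n_init=10).labels_
        assert res.mean_ri(2) == pytest.approx(rand_index(a, b))

    def test_planted_structure_more_stable_than_noise(self):
        rng = np.random.default_rng(7)
        noise = rng.standard_normal((300, 10))
        planted = np.vstack([rng.standard_normal((150, 10)) - 4,
                             rng.standard_normal((150, 10)) + 4])
        ri_noise = stability_analysis(noise, [2], n_permutations=20,
                                      base_seed=0, n_init=1).mean_ri(2)
        ri_planted = stability_analysis(planted, [2], n_permutations=20,
                                        base_seed=0, n_init=1).mean_ri(2)
        assert ri_planted > ri_noise


class TestSilhouette:
    def test_hand_arithmetic_1d_pairs(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        D = squareform(pdist(X))
        s = silhouette_samples(D, np.array([0, 0, 1, 1]))
        assert s[0] == pytest.approx((10.05 - 0.1) / 10.05)

    def test_matches_double_loop_oracle_and_sklearn(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            X = rng.standard_normal((100, 4))
            labels = rng.integers(0, 4, 100)
            D = squareform(pdist(X))
            s = silhouette_samples(D, labels)
            assert np.allclose(s, brute_force_silhouette(X, labels), atol=1e-10)
            assert np.allclose(s, sk_silhouette(X, labels), atol=1e-8)

    def test_misassigned_point_scores_lower(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 8])
        labels = np.array([0] * 5 + [1] * 4 + [0])  # last point misassigned
        D = squareform(pdist(X))
        s = silhouette_samples(D, labels)
        assert s[-1] < s[-2]

    def test_two_tight_blobs_near_one(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 0.01, (50, 3)), rng.normal(5, 0.01, (50, 3))])
        curve = silhouette_curve(X, [2, 3, 4], seed=0)
        assert curve.scores[0] >= 0.95

    def test_single_cluster_undefined(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            silhouette_samples(np.zeros((4, 4)), np.zeros(4, dtype=int))


class TestSelectK:
    def test_worked_example_both_methods(self):
        curve = SilhouetteCurve(grid=(2, 3, 4, 5),
                                scores=np.array([0.9, 0.88, 0.5, 0.48]))
        assert select_k(curve, method="largest_drop").chosen_k == 3
        assert select_k(curve, method="drop_from_peak").chosen_k == 3

    def test_flat_curve_warns_argmax(self):
        curve = SilhouetteCurve(grid=(2, 3, 4), scores=np.array([0.5, 0.5, 0.5]))
        sel = select_k(curve)
        assert sel.warning and sel.chosen_k == 2

    def test_monotone_rising_warns_argmax(self):
        curve = SilhouetteCurve(grid=(2, 3, 4), scores=np.array([0.1, 0.2, 0.3]))
        sel = select_k(curve)
        assert sel.warning and sel.chosen_k == 4

    def test_manual_override_recorded(self):
        curve = SilhouetteCurve(grid=(2, 3, 4), scores=np.array([0.3, 0.2, 0.1]))
        sel = select_k(curve, method="manual_override", manual_k=3,
                       rationale="clinical interpretability")
        assert sel.chosen_k == 3 and sel.rationale

    def test_manual_override_outside_grid_fails(self):
        curve = SilhouetteCurve(grid=(2, 3, 4), scores=np.array([0.3, 0.2, 0.1]))
        with pytest.raises(ValueError, match="inside the grid"):
            select_k(curve, method="manual_override", manual_k=9)

    def test_ties_break_toward_smaller_k(self):
        curve = SilhouetteCurve(grid=(2, 3, 4, 5),
                                scores=np.array([0.9, 0.6, 0.3, 0.2]))
        # drops (0.3, 0.3, 0.1): tie between K=2 and K=3 -> smaller
        assert select_k(curve, method="largest_drop").chosen_k == 2
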