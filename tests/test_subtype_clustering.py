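import itertools

import numpy as np
import pytest

from eigenbrains.subtype_clustering import (
    affinity_propagation,
    agglomerate_exemplars,
    build_similarity,
    cluster_scores,
    cut_merge_tree,
    merge_tree_linkage,
    net_similarity,
    pairwise_distance,
    preference_from_quantile,
    select_metric,
    silhouette,
    similarity_from_distance,
    standardize_scores,
)


def exhaustive_best_exemplars(s):
    """Brute-force optimum of the net-similarity objective."""
    n = s.shape[0]
    best_value, best_set = -np.inf, None
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            e = np.array(combo)
            rest = np.setdiff1d(np.arange(n), e)
            value = s[e, e].sum()
            if rest.size:
                value += s[np.ix_(rest, e)].max(axis=1).sum()
            if value > best_value:
                best_value, best_set = value, set(combo)
    return best_value, best_set


def separated_centroids(scale=8.0):
    """4 centroids in 6-D, pairwise distance >= scale, two on a common ray.

    The shared ray makes the clusters indistinguishable by profile shape
    (correlation distance) while trivially separable by magnitude-aware
    metrics, and every dimension carries between-cluster signal so the
    geometry survives per-column standardization.
    """
    u = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0]) / np.sqrt(6)
    v = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0]) / np.sqrt(6)
    w = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0]) / np.sqrt(6)
    return np.vstack([scale * u, 2.5 * scale * u, 1.5 * scale * v, 1.5 * scale * w])


def magnitude_ladder_centroids():
    """4 centroids on one ray, gaps >= 8x the unit within-cluster sd.

    Small clusters sit at the ends so splitting off a 4th exemplar beats
    the preference cost; all-positive magnitudes along a single axis give
    profile-shape metrics nothing to work with.
    """
    centroids = np.zeros((4, 6))
    centroids[:, 0] = [10.0, 20.0, 28.0, 38.0]
    return centroids


def similarity_for(points, q=0.1):
    d = pairwise_distance(np.asarray(points, dtype=float), "euclidean")
    s = similarity_from_distance(d)
    np.fill_diagonal(s, preference_from_quantile(s, q))
    return s, d


class TestPairwiseDistance:
    def test_euclidean(self):
        d = pairwise_distance(np.array([[0.0, 0.0], [3.0, 4.0]]), "euclidean")
        assert d[0, 1] == pytest.approx(5.0)

    def test_manhattan(self):
        d = pairwise_distance(np.array([[0.0, 0.0], [1.0, 1.0]]), "manhattan")
        assert d[0, 1] == pytest.approx(2.0)

    def test_correlation_identical_profiles(self):
        d = pairwise_distance(np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]),
                              "correlation")
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_correlation_needs_two_components(self):
        with pytest.raises(ValueError, match="2 components"):
            pairwise_distance(np.array([[1.0], [2.0]]), "correlation")

    def test_correlation_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pairwise_distance(np.array([[1.0, 1.0], [1.0, 2.0]]), "correlation")

    def test_unknown_metric(self):
        with pytest.raises(ValueError, match="unknown metric"):
            pairwise_distance(np.zeros((3, 2)), "cosine")


class TestSimilarityAndPreference:
    def test_negative_squared_distance(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        s = similarity_from_distance(d)
        assert s[0, 1] == pytest.approx(-4.0)
        assert s[0, 0] == 0.0

    def test_monotone_order_reversal(self, rng):
        d = pairwise_distance(rng.standard_normal((6, 3)), "euclidean")
        s = similarity_from_distance(d)
        iu = np.triu_indices(6, 1)
        assert np.array_equal(np.argsort(d[iu]), np.argsort(-s[iu]))

    def test_constant_similarities(self):
        s = np.full((4, 4), -4.0)
        np.fill_diagonal(s, 0.0)
        for q in (0.1, 0.5, 0.9):
            assert preference_from_quantile(s, q) == pytest.approx(-4.0)

    def test_interpolated_quantile_oracle(self):
        # {-1,-2,-3,-4} at q=0.5 interpolates to -2.5; pair duplication
        # (matrix symmetry) leaves the median unchanged
        s = np.zeros((4, 4))
        pairs = {(0, 1): -1.0, (0, 2): -2.0, (0, 3): -3.0,
                 (1, 2): -4.0, (1, 3): -1.5, (2, 3): -3.5}
        for (i, j), v in pairs.items():
            s[i, j] = s[j, i] = v
        off = s[~np.eye(4, dtype=bool)]
        for q in (0.1, 0.25, 0.5, 0.9):
            assert preference_from_quantile(s, q) == pytest.approx(
                np.quantile(off, q))
        assert float(np.quantile([-1.0, -2.0, -3.0, -4.0], 0.5)) == -2.5

    def test_quantile_range(self):
        with pytest.raises(ValueError, match="quantile"):
            preference_from_quantile(np.zeros((3, 3)), 1.5)


class TestAffinityPropagation:
    def test_coincident_points_single_cluster(self):
        s = np.array([[-1.0, 0.0], [0.0, -1.0]])  # preference -1, d = 0
        res = affinity_propagation(s, seed=0)
        assert res.n_clusters == 1
        assert res.net_similarity == pytest.approx(-1.0)

    def test_two_tight_pairs(self):
        s, _ = similarity_for([[0.0], [0.1], [10.0], [10.1]])
        res = affinity_propagation(s, seed=0)
        assert res.n_clusters == 2
        opt, _ = exhaustive_best_exemplars(s)
        # exemplar choice within a tight pair is tied; compare the objective
        assert res.net_similarity == pytest.approx(opt, abs=1e-9)
        assert np.array_equal(res.labels, [0, 0, 1, 1])

    def test_planted_clusters_exact_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        centroids = separated_centroids()
        sizes = (21, 19, 7, 5)
        points = np.vstack([centroids[i] + rng.standard_normal((n, 6))
                            for i, n in enumerate(sizes)])
        truth = np.repeat(np.arange(4), sizes)
        res = cluster_scores(points, "euclidean", seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_exemplar_labels_itself(self, rng):
        s, _ = similarity_for(rng.standard_normal((12, 3)))
        res = affinity_propagation(s, seed=1)
        for c, e in enumerate(res.exemplars):
            assert res.labels[e] == c

    def test_oracle_equivalence_small(self, rng):
        for t in range(30):
            n = int(rng.integers(3, 8))
            s, _ = similarity_for(rng.standard_normal((n, 2)) * 2)
            res = affinity_propagation(s, seed=t)
            opt, _ = exhaustive_best_exemplars(s)
            assert res.net_similarity >= opt - 0.01 * abs(opt)

    def test_net_similarity_matches_definition(self, rng):
        s, _ = similarity_for(rng.standard_normal((10, 2)))
        res = affinity_propagation(s, seed=0)
        assert res.net_similarity == pytest.approx(
            net_similarity(s, res.labels, res.exemplars))

    def test_damping_validated(self):
        with pytest.raises(ValueError, match="damping"):
            affinity_propagation(np.zeros((3, 3)), damping=0.3)

    def test_sign_flip_invariance(self, rng):
        scores = rng.standard_normal((20, 4))
        flipped = scores.copy()
        flipped[:, 2] *= -1
        for metric in ("euclidean", "manhattan"):
            a = cluster_scores(scores, metric, seed=0)
            b = cluster_scores(flipped, metric, seed=0)
            assert np.array_equal(a.labels, b.labels)


class TestAgglomeration:
    def test_two_clusters_one_merge(self):
        s, _ = similarity_for([[0.0], [0.1], [10.0], [10.1]])
        res = affinity_propagation(s, seed=0)
        merges = agglomerate_exemplars(s, res)
        assert len(merges) == 1

    def test_four_clusters_three_merges_against_oracle(self):
        rng = np.random.default_rng(5)
        centroids = np.array([[0.0, 0], [10, 0], [0, 10], [30, 30]])
        points = np.vstack([c + 0.5 * rng.standard_normal((6, 2)) for c in centroids])
        s, _ = similarity_for(points, q=0.5)
        res = affinity_propagation(s, seed=0)
        assert res.n_clusters == 4
        merges = agglomerate_exemplars(s, res)
        assert len(merges) == 3
        # greedy best-pair oracle at each step
        sims = [m[2] for m in merges]
        assert all(sims[i] >= sims[i + 1] - 1e-12 for i in range(len(sims) - 1))
        # first merge joins the two closest clusters (0,0) and (10,0) or (0,10)
        first = {merges[0][0], merges[0][1]}
        assert len(first & {0, 1, 2}) == 2

    def test_cut_merge_tree_groups(self):
        rng = np.random.default_rng(5)
        centroids = np.array([[0.0, 0], [10, 0], [0, 10], [30, 30]])
        points = np.vstack([c + 0.5 * rng.standard_normal((6, 2)) for c in centroids])
        s, _ = similarity_for(points, q=0.5)
        res = affinity_propagation(s, seed=0)
        merges = agglomerate_exemplars(s, res)
        cut2 = cut_merge_tree(merges, res.labels, 2)
        assert len(np.unique(cut2)) == 2
        cut_all = cut_merge_tree(merges, res.labels, res.n_clusters)
        assert len(np.unique(cut_all)) == res.n_clusters

    def test_linkage_table_shape(self):
        s, _ = similarity_for([[0.0], [0.1], [10.0], [10.1]])
        res = affinity_propagation(s, seed=0)
        merges = agglomerate_exemplars(s, res)
        link = merge_tree_linkage(merges, res.labels)
        assert link.shape == (1, 4)
        assert link[0, 3] == 4  # final merge spans all subjects

    def test_needs_two_clusters(self):
        s = np.array([[-1.0, 0.0], [0.0, -1.0]])
        res = affinity_propagation(s, seed=0)
        with pytest.raises(ValueError, match="2 clusters"):
            agglomerate_exemplars(s, res)


class TestSilhouette:
    def test_hand_computed_case(self):
        # clusters {0,1} and {10,11}: a(0)=1, b(0)=(10+11)/2=10.5
        points = np.array([[0.0], [1.0], [10.0], [11.0]])
        d = pairwise_distance(points, "euclidean")
        values, mean = silhouette(d, np.array([0, 0, 1, 1]))
        assert values[0] == pytest.approx((10.5 - 1) / 10.5)
        assert -1 <= mean <= 1

    def test_coincident_points_zero_with_warning(self):
        d = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="coincident"):
            values, mean = silhouette(d, np.array([0, 0, 1, 1]))
        assert mean == 0.0

    def test_single_cluster_rejected(self, rng):
        d = pairwise_distance(rng.standard_normal((5, 2)), "euclidean")
        with pytest.raises(ValueError, match="single cluster"):
            silhouette(d, np.zeros(5, dtype=int))

    def test_singleton_scores_zero(self):
        points = np.array([[0.0], [1.0], [50.0]])
        d = pairwise_distance(points, "euclidean")
        values, _ = silhouette(d, np.array([0, 0, 1]))
        assert values[2] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            points = rng.standard_normal((n, 3))
            labels = rng.integers(0, 3, size=n)
            if len(np.unique(labels)) < 2:
                continue
            d = pairwise_distance(points, "euclidean")
            values, _ = silhouette(d, labels)
            np.testing.assert_allclose(values, _silhouette_oracle(d, labels),
                                       atol=1e-12)
            assert np.all(values >= -1) and np.all(values <= 1)


def _silhouette_oracle(d, labels):
    """Independent double-loop silhouette straight from the definition."""
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            continue
        a = sum(d[i, j] for j in same) / len(same)
        b = np.inf
        for c in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(d[i, j] for j in members) / len(members))
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out


class TestSelectMetric:
    def test_magnitude_ladder_prefers_euclidean(self):
        # clusters along one ray differ in magnitude only: profile-shape
        # (correlation) distance carries no signal, so a magnitude-aware
        # metric must win the silhouette comparison
        rng = np.random.default_rng(1)
        centroids = magnitude_ladder_centroids()
        points = np.vstack([centroids[i] + rng.standard_normal((n, 6))
                            for i, n in enumerate((5, 21, 19, 7))])
        best, results = select_metric(points, seed=0, standardize=False)
        assert len(results) == 3
        assert best == "euclidean"
        assert results["euclidean"].silhouette_mean >= max(
            r.silhouette_mean for m, r in results.items() if m != "euclidean") - 1e-12

    def test_shape_clusters_prefer_correlation(self):
        rng = np.random.default_rng(2)
        up = np.array([1.0, 2.0, 3.0, 4.0])
        down = up[::-1].copy()
        points = []
        for shape in (up, down):
            for _ in range(12):
                magnitude = rng.uniform(0.5, 3.0)
                points.append(shape * magnitude + 0.05 * rng.standard_normal(4))
        best, results = select_metric(np.array(points), seed=0, standardize=False)
        assert best == "correlation"

    def test_one_result_per_metric(self, rng):
        best, results = select_metric(rng.standard_normal((15, 3)), seed=0)
        assert set(results) == {"euclidean", "manhattan", "correlation"}
        for res in results.values():
            if res.n_clusters >= 2:
                assert np.isfinite(res.silhouette_mean)

    def test_needs_two_metrics(self, rng):
        with pytest.raises(ValueError, match="2 candidate"):
            select_metric(rng.standard_normal((10, 3)), metrics=("euclidean",))


class TestStandardize:
    def test_columns_standardized(self, rng):
        z = standardize_scores(rng.standard_normal((30, 4)) * 5 + 2)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_scores(np.ones((5, 2)))


def test_preference_monotonicity_logged(rng):
    """Lower preference should not increase cluster count (empirical check)."""
    points = rng.standard_normal((20, 3))
    s_base, _ = similarity_for(points)
    off = s_base[~np.eye(20, dtype=bool)]
    counts = []
    for q in (0.05, 0.2, 0.5, 0.8):
        s = s_base.copy()
        np.fill_diagonal(s, np.quantile(off, q))
        counts.append(affinity_propagation(s, seed=0).n_clusters)
    assert counts == sorted(counts)
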