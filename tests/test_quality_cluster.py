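"""k-means tiering: fitting, elbow selection, labeling, sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from questqual.quality_cluster import (
    ClusterModel,
    fit_kmeans,
    label_clusters,
    select_k_elbow,
    sse_curve,
    standardize,
    stratified_sample,
)


def brute_force_sse(points, k):
    """Exhaustive minimum SSE over all k-partitions (tiny n only)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) != k:
            continue
        sse = 0.0
        for j in range(k):
            members = pts[[i for i in range(n) if assign[i] == j]]
            sse += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


SMALL_FIXTURES = [
    # 1-D tiers embedded in 2-D
    (np.array([[0, 0], [0.1, 0], [10, 0], [10.1, 0], [20, 0], [20.2, 0]]), 3),
    (np.array([[0, 0], [1, 1], [2, 0], [9, 9], [10, 10], [11, 9]]), 2),
    (np.array([[0, 0], [0, 5], [5, 0], [5, 5], [2, 2]]), 3),
    (np.array([[i, (i * 7) % 5] for i in range(8)], dtype=float), 3),
    (np.array([[0, 1], [1, 0], [4, 4], [5, 5], [8, 0], [0, 8], [7, 7]]), 4),
]


class TestFitKmeans:
    @pytest.mark.parametrize("points, k", SMALL_FIXTURES)
    def test_attains_brute_force_optimum_on_small_fixtures(self, points, k):
        model = fit_kmeans(points, k, seed=7, n_restarts=20, standardized=False)
        assert model.sse == pytest.approx(brute_force_sse(points, k), abs=1e-8)

    def test_matches_sklearn_inertia(self):
        pytest.importorskip("sklearn")
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(0)
        pts = np.vstack(
            [rng.normal(c, 0.3, size=(30, 2)) for c in ((0, 0), (4, 0), (0, 4))]
        )
        mine = fit_kmeans(pts, 3, seed=1, n_restarts=10, standardized=False)
        sk = KMeans(n_clusters=3, n_init=10, random_state=1).fit(pts)
        assert mine.sse == pytest.approx(sk.inertia_, rel=1e-6)

    def test_separated_tiers_recovered(self):
        pts = np.array([[0, 0], [0.1, 0], [10, 0], [10.1, 0], [20, 0], [20.2, 0]])
        model = fit_kmeans(pts, 3, seed=0, n_restarts=20, standardized=False)
        assign = model.assign(pts)
        groups = [set(np.where(assign == j)[0]) for j in range(3)]
        assert sorted(map(sorted, groups)) == [[0, 1], [2, 3], [4, 5]]

    def test_k1_closed_form(self):
        pts = np.array([[1.0, 2.0], [3.0, 6.0], [5.0, 4.0]])
        model = fit_kmeans(pts, 1, seed=0, standardized=False)
        assert model.centroids[0] == pytest.approx(pts.mean(axis=0))
        assert model.sse == pytest.approx(((pts - pts.mean(axis=0)) ** 2).sum())

    def test_k_equals_n_gives_zero_sse(self):
        pts = np.array([[0.0, 0], [1, 1], [2, 2], [3, 0]])
        model = fit_kmeans(pts, 4, seed=0, n_restarts=20, standardized=False)
        assert model.sse == pytest.approx(0.0, abs=1e-12)

    def test_sizing_and_degenerate_errors(self):
        with pytest.raises(ValueError, match="n_points >= k"):
            fit_kmeans(np.zeros((2, 2)), 3, seed=0)
        with pytest.raises(ValueError, match="identical"):
            fit_kmeans(np.ones((5, 2)), 2, seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            fit_kmeans(np.array([[np.nan, 0], [1, 1]]), 1, seed=0)

    def test_roundtrip_json(self):
        pts = np.array([[0, 0], [1, 1], [4, 4], [5, 5], [9, 0], [0, 9.0]])
        model = fit_kmeans(pts, 3, seed=3)
        label_clusters(model, pts)
        back = ClusterModel.from_json(model.to_json())
        assert back.labels == model.labels
        np.testing.assert_allclose(back.centroids, model.centroids)
        np.testing.assert_array_equal(back.assign(pts), model.assign(pts))


class TestElbow:
    def test_sse_curve_nonincreasing(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(40, 2))
        curve = sse_curve(pts, range(1, 9), seed=2, n_restarts=10)
        vals = [curve[k] for k in sorted(curve)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_three_planted_clusters_selected(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [rng.normal(c, 0.15, size=(40, 2)) for c in ((0, 2), (2, -1), (-2, -1))]
        )
        k, curve = select_k_elbow(pts, range(1, 9), seed=0, n_restarts=10)
        assert k == 3
        assert set(curve) == set(range(1, 9))

    def test_tie_broken_toward_smallest_k(self, monkeypatch):
        # a perfectly linear SSE decay has all second differences zero
        import questqual.quality_cluster as qc

        monkeypatch.setattr(
            qc, "sse_curve",
            lambda points, ks, seed, n_restarts: {k: 100.0 - 10 * k for k in ks},
        )
        k, _ = qc.select_k_elbow(np.zeros((20, 2)), range(1, 7), seed=0)
        assert k == 2  # smallest interior k

    def test_short_range_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            select_k_elbow(np.zeros((10, 2)), [2, 3], seed=0)


class TestLabeling:
    def _model_with_centroids(self, centroids):
        return ClusterModel(
            k=3, center=np.zeros(2), scale=np.ones(2),
            centroids=np.asarray(centroids, dtype=float),
            sse=0.0, seed=0, n_restarts=1,
        )

    def test_ordered_composites(self):
        pts = np.array([[1.0, 1], [0, 0], [-1, -1]])
        model = self._model_with_centroids(pts)
        labels = label_clusters(model, pts)
        assert labels == {0: 1, 1: 2, 2: 3}

    def test_tie_broken_by_clarity_mean(self):
        pts = np.array([[1.0, -1], [-1, 1], [0, 0]])
        model = self._model_with_centroids(pts)
        labels = label_clusters(model, pts)
        assert labels[1] == 1  # (-1, +1) wins on clarity
        assert labels[0] == 2 or labels[0] == 3

    def test_invariant_to_cluster_index_permutation(self):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [rng.normal(c, 0.2, size=(15, 2)) for c in ((2, 2), (0, 0), (-2, -2))]
        )
        model = fit_kmeans(pts, 3, seed=0)
        label_clusters(model, pts)
        quality = model.quality_of(pts)

        perm = [2, 0, 1]
        permuted = ClusterModel(
            k=3, center=model.center, scale=model.scale,
            centroids=model.centroids[perm], sse=model.sse,
            seed=model.seed, n_restarts=model.n_restarts,
        )
        label_clusters(permuted, pts)
        np.testing.assert_array_equal(permuted.quality_of(pts), quality)

    def test_requires_k3(self):
        pts = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        model = fit_kmeans(pts, 2, seed=0)
        with pytest.raises(ValueError, match="k = 3"):
            label_clusters(model, pts)


class TestStratifiedSample:
    @staticmethod
    def _assignments(sizes):
        rows = []
        i = 0
        for quality, size in sizes.items():
            for _ in range(size):
                rows.append({"id": f"q{i}", "cluster": quality - 1, "quality": quality})
                i += 1
        return pd.DataFrame(rows)

    def test_published_cluster_sizes_sample_10_17_35(self):
        """10% of tiers sized 101/169/354 rounds to 10, 17 and 35."""
        assign = self._assignments({1: 101, 2: 169, 3: 354})
        sample = stratified_sample(assign, fraction=0.10, seed=4)
        assert len(sample) == 10 + 17 + 35
        got = assign.set_index("id").loc[sample, "quality"].value_counts()
        assert got[1] == 10 and got[2] == 17 and got[3] == 35

    def test_minimum_one_per_nonempty_stratum(self):
        assign = self._assignments({1: 3, 2: 400, 3: 5})
        sample = stratified_sample(assign, fraction=0.01, seed=0)
        qualities = assign.set_index("id").loc[sample, "quality"]
        assert set(qualities) == {1, 2, 3}

    def test_fraction_one_returns_everything_shuffled(self):
        assign = self._assignments({1: 5, 2: 5, 3: 5})
        sample = stratified_sample(assign, fraction=1.0, seed=9)
        assert sorted(sample) == sorted(assign["id"])
        assert sample != assign["id"].tolist()  # order randomized

    def test_same_seed_same_sample(self):
        assign = self._assignments({1: 30, 2: 30, 3: 30})
        assert stratified_sample(assign, 0.2, seed=11) == stratified_sample(
            assign, 0.2, seed=11
        )

    def test_invalid_inputs(self):
        assign = self._assignments({1: 5})
        with pytest.raises(ValueError):
            stratified_sample(assign, fraction=0.0)
        with pytest.raises(ValueError):
            stratified_sample(assign.iloc[:0], fraction=0.5)
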