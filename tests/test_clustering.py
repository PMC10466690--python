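import numpy as np
import pytest

from peakshift import (
    cluster_composition, embed_2d, fit_kmeans, select_group_specific_clusters,
)
from peakshift.differential import PEAKS_0_5, PEAKS_2_0
from peakshift.motifs import FrequencyVector


def vectors_from(X, origins=None):
    origins = origins or [PEAKS_2_0] * len(X)
    return [
        FrequencyVector(f"p{i}", o, np.asarray(row, dtype=float))
        for i, (row, o) in enumerate(zip(X, origins))
    ]


def assert_model_invariants(model, X, tol=1e-9):
    X = np.asarray(X, dtype=float)
    labels = np.array([model.assignments[pid] for pid in model.peak_ids])
    for c in range(model.k):
        members = X[labels == c]
        if len(members):
            assert np.allclose(model.centroids[c], members.mean(axis=0), atol=tol)
    d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.min(axis=1)
    chosen = d2[np.arange(len(X)), labels]
    assert np.all(chosen <= nearest + tol)


def two_clouds(rng, n_per=20, sep=10.0):
    a = rng.normal(0, 0.5, (n_per, 3))
    b = rng.normal(0, 0.5, (n_per, 3)) + sep
    return np.vstack([a, b])


class TestFitKmeans:
    def test_separated_clouds_recover_cloud_means(self):
        rng = np.random.default_rng(0)
        X = two_clouds(rng)
        model = fit_kmeans(vectors_from(X), k=2, seed=0)
        got = sorted(model.centroids.tolist())
        want = sorted([X[:20].mean(axis=0).tolist(), X[20:].mean(axis=0).tolist()])
        assert np.allclose(got, want, atol=1e-9)
        wcss = sum(((X[:20] - X[:20].mean(0)) ** 2).sum() for X in (X[:20], X[20:]))
        assert model.wcss == pytest.approx(
            ((X[:20] - X[:20].mean(0)) ** 2).sum() + ((X[20:] - X[20:].mean(0)) ** 2).sum()
        )

    def test_k_equals_n_gives_zero_wcss(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 2))
        model = fit_kmeans(vectors_from(X), k=6, seed=0)
        assert model.wcss == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        m1 = fit_kmeans(vectors_from(X), k=5, seed=17)
        m2 = fit_kmeans(vectors_from(X), k=5, seed=17)
        assert m1.assignments == m2.assignments
        assert np.array_equal(m1.centroids, m2.centroids)

    def test_errors_on_degenerate_input(self):
        with pytest.raises(ValueError):
            fit_kmeans(vectors_from(np.zeros((3, 2))), k=5, seed=0)  # n < k
        with pytest.raises(ValueError):
            fit_kmeans(vectors_from(np.ones((10, 2))), k=2, seed=0)  # identical

    def test_invariants_on_random_fits(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            X = rng.normal(size=(int(rng.integers(12, 60)), int(rng.integers(2, 6))))
            k = int(rng.integers(2, 7))
            model = fit_kmeans(vectors_from(X), k=k, seed=trial)
            assert_model_invariants(model, X)

    def test_wcss_competitive_with_reference_kmeans(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 5))
        model = fit_kmeans(vectors_from(X), k=4, seed=0, n_restarts=8)
        ref = KMeans(n_clusters=4, n_init=10, random_state=0).fit(X)
        assert model.wcss <= ref.inertia_ * 1.05


class TestCompositionAndSelection:
    def fit_pure(self):
        rng = np.random.default_rng(5)
        X = two_clouds(rng, n_per=10)
        origins = [PEAKS_2_0] * 10 + [PEAKS_0_5] * 10
        vectors = vectors_from(X, origins)
        model = fit_kmeans(vectors, k=2, seed=0)
        return vectors, model

    def test_pure_cluster_proportions(self):
        vectors, model = self.fit_pure()
        comp = cluster_composition(model, vectors)
        for c in range(2):
            props = comp.proportions[c]
            assert props is not None
            assert sum(props.values()) == pytest.approx(1.0)
            assert max(props.values()) == 1.0

    def test_mixed_cluster_proportions(self):
        origins = [PEAKS_2_0] * 5 + [PEAKS_0_5] * 5
        X = np.vstack([np.zeros((10, 2)), np.full((2, 2), 9.0)])
        vectors = vectors_from(X, origins + [PEAKS_2_0] * 2)
        model = fit_kmeans(vectors, k=2, seed=0)
        comp = cluster_composition(model, vectors)
        mixed = model.assignments["p0"]
        assert comp.proportions[mixed][PEAKS_2_0] == pytest.approx(0.5)

    def test_empty_cluster_flagged_undefined(self):
        from peakshift.clustering import ClusterComposition, ClusterModel

        X = np.array([[0.0, 0], [9, 9]])
        vectors = vectors_from(X)
        model = ClusterModel(3, 0, ["p0", "p1"], {"p0": 0, "p1": 1},
                             np.array([[0., 0], [9, 9], [50, 50]]), 0.0)
        comp = cluster_composition(model, vectors)
        assert comp.proportions[2] is None
        assert comp.counts[2] == {PEAKS_2_0: 0, PEAKS_0_5: 0}

    def test_selection_by_purity_and_top_motifs(self):
        vectors, model = self.fit_pure()
        comp = cluster_composition(model, vectors)
        selected = select_group_specific_clusters(comp, model, purity_min=0.9,
                                                  n_top_motifs=1)
        assert len(selected) == 2
        for gs in selected:
            assert gs.purity == 1.0
            assert gs.top_motifs == [int(np.argmax(model.centroids[gs.cluster]))]
        none = select_group_specific_clusters(comp, model, purity_min=1.01)
        assert none == []

    def test_planted_usage_profiles_recovered(self):
        """Vectors drawn from two motif-usage profiles (origin A rich in
        motif 0, origin B rich in motif 1, Poisson counts) cluster into at
        least one >= 0.9-purity cluster per origin whose centroid argmax is
        the planted motif."""
        rng = np.random.default_rng(42)
        n = 60
        lam = np.array([[6.0, 0.3, 0.5, 0.5], [0.3, 6.0, 0.5, 0.5]])
        X = np.vstack([rng.poisson(lam[0], (n, 4)), rng.poisson(lam[1], (n, 4))])
        origins = [PEAKS_2_0] * n + [PEAKS_0_5] * n
        vectors = vectors_from(X.astype(float), origins)
        model = fit_kmeans(vectors, k=4, seed=7)
        assert_model_invariants(model, X)
        comp = cluster_composition(model, vectors)
        selected = select_group_specific_clusters(comp, model, 0.9, n_top_motifs=1)
        planted = {PEAKS_2_0: 0, PEAKS_0_5: 1}
        for origin, motif in planted.items():
            hits = [gs for gs in selected
                    if gs.dominant_origin == origin and gs.top_motifs[0] == motif]
            assert hits, origin


class TestEmbedding:
    def test_shape_determinism_and_continuity(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 4))
        X[1] = X[0]  # duplicated vector
        vectors = vectors_from(X)
        with pytest.warns(UserWarning):
            c1 = embed_2d(vectors, seed=3, n_neighbors=40)  # auto-shrunk
        c2 = embed_2d(vectors, seed=3, n_neighbors=40)
        assert c1.shape == (30, 2)
        assert np.array_equal(c1, c2)
        # duplicates stay close relative to the layout spread (the embedding
        # does not collapse them to identical coordinates)
        diameter = np.linalg.norm(c1.max(axis=0) - c1.min(axis=0))
        assert np.linalg.norm(c1[0] - c1[1]) <= 0.15 * diameter
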