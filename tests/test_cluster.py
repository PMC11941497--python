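"""Standardization, k-means, k selection, archetype matching, PCA."""

import numpy as np
import pytest

import epidermap as em
from epidermap.cluster import (
    ARCHETYPE_SIGNATURES,
    fit_cluster_model,
    match_archetypes,
)
from epidermap.datatypes import ParameterError


def brute_force_silhouette(X, labels):
    """Direct silhouette mean from the definition (pairwise distances)."""
    X = np.asarray(X, float)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s.mean()


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        X = rng.normal(5, 3, size=(200, 4))
        Z, means, sds = em.standardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-12)

    def test_constant_column_rejected(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.raises(ParameterError, match="zero-variance"):
            em.standardize(X)

    def test_round_trip_with_params(self, rng):
        X = rng.normal(size=(50, 3)) * [1, 10, 100] + [0, 5, -7]
        Z, means, sds = em.standardize(X)
        np.testing.assert_allclose(Z * sds + means, X, rtol=1e-12)


class TestKMeans:
    def test_two_separated_clouds(self, rng):
        a = rng.normal(0, 0.05, size=(50, 2))
        b = rng.normal(10, 0.05, size=(50, 2))
        X = np.vstack([a, b])
        labels, centroids, wss = em.kmeans_fit(X, 2, seed=0)
        got = sorted(centroids[:, 0])
        assert got[0] == pytest.approx(0, abs=0.05)
        assert got[1] == pytest.approx(10, abs=0.05)

    def test_k1_gives_grand_mean_and_total_ss(self, rng):
        X = rng.normal(size=(40, 3))
        labels, centroids, wss = em.kmeans_fit(X, 1, seed=0)
        np.testing.assert_allclose(centroids[0], X.mean(axis=0), atol=1e-9)
        assert wss == pytest.approx(((X - X.mean(0)) ** 2).sum(), rel=1e-9)

    def test_k_equals_n_gives_zero_wss(self, rng):
        X = rng.normal(size=(8, 2))
        _, _, wss = em.kmeans_fit(X, 8, seed=0)
        assert wss == pytest.approx(0.0, abs=1e-12)

    def test_k_exceeding_distinct_points_rejected(self):
        X = np.array([[0.0, 0], [0, 0], [1, 1]])
        with pytest.raises(ParameterError):
            em.kmeans_fit(X, 3, seed=0)

    def test_determinism(self, rng):
        X = rng.normal(size=(300, 4))
        l1, c1, _ = em.kmeans_fit(X, 4, seed=7, n_init=10)
        l2, c2, _ = em.kmeans_fit(X, 4, seed=7, n_init=10)
        assert (l1 == l2).all()
        np.testing.assert_array_equal(c1, c2)


class TestSelectK:
    def test_elbow_forced_by_second_difference(self):
        wss = {1: 100.0, 2: 20.0, 3: 18.0, 4: 17.0, 5: 16.0}
        assert em.select_k_elbow(wss) == 2

    def test_elbow_tie_takes_smallest(self, caplog):
        wss = {k: 100.0 - 10 * k for k in range(1, 6)}  # linear: all 2nd diffs 0
        with caplog.at_level("WARNING"):
            assert em.select_k_elbow(wss) == 2

    def test_elbow_needs_three_values(self):
        with pytest.raises(ParameterError):
            em.select_k_elbow({1: 10.0, 2: 5.0})

    def test_silhouette_prefers_two_pairs(self):
        """1-D points {0, 0.1, 10, 10.1}: brute-force silhouette is higher
        for k=2 than k=3."""
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        k, scores = em.select_k_silhouette(X, k_candidates=(2, 3), seed=0)
        assert k == 2
        bf2 = brute_force_silhouette(X, np.array([0, 0, 1, 1]))
        assert scores[2] == pytest.approx(bf2, abs=1e-9)
        assert scores[2] > scores[3]

    def test_duplicated_groups_near_perfect_silhouette(self):
        X = np.vstack([np.zeros((20, 2)), np.ones((20, 2)) * 50])
        X += np.random.default_rng(0).normal(0, 1e-3, X.shape)
        _, scores = em.select_k_silhouette(X, k_candidates=(2,), seed=0)
        assert scores[2] > 0.99

    def test_single_blob_has_low_silhouette(self, rng):
        X = rng.normal(size=(300, 2))
        _, scores = em.select_k_silhouette(X, k_candidates=(2, 3, 4), seed=0)
        assert all(v < 0.4 for v in scores.values())

    @pytest.mark.parametrize(
        "elbow,sil,forced,expected", [(4, 4, None, 4), (3, 4, None, 4), (3, 4, 6, 6)]
    )
    def test_choose_k_policy(self, elbow, sil, forced, expected):
        assert em.choose_k(elbow, sil, forced) == expected


class TestArchetypeMatching:
    def build_z(self, profiles):
        """Synthesize a standardized matrix whose per-cluster medians are
        the given profiles."""
        rng = np.random.default_rng(0)
        Z, labels = [], []
        for c, prof in enumerate(profiles):
            Z.append(rng.normal(0, 0.05, size=(30, 4)) + np.asarray(prof))
            labels += [c] * 30
        return np.vstack(Z), np.array(labels)

    def test_signature_examples(self):
        # cluster 0: high BrdU -> archetype 3; cluster 1: large area -> 4;
        # cluster 2: low circ small area -> 2; cluster 3: the rest -> 1
        Z, labels = self.build_z(
            [
                [1.5, 0.0, 0.0, 0.3],
                [-0.3, 0.2, 1.4, 0.3],
                [-0.3, -0.5, -1.0, -1.5],
                [-0.4, -0.5, -0.2, 0.4],
            ]
        )
        mapping = match_archetypes(labels, Z)
        assert mapping == {0: 3, 1: 4, 2: 2, 3: 1}

    def test_invariance_to_relabeling(self):
        Z, labels = self.build_z(
            [[1.5, 0, 0, 0.3], [-0.3, 0.2, 1.4, 0.3], [-0.3, -0.5, -1.0, -1.5], [-0.4, -0.5, -0.2, 0.4]]
        )
        mapping = match_archetypes(labels, Z)
        perm = np.array([2, 0, 3, 1])
        relabeled = perm[labels]
        mapping2 = match_archetypes(relabeled, Z)
        for c in np.unique(labels):
            assert mapping[int(c)] == mapping2[int(perm[c])]

    def test_identical_profiles_ambiguous(self):
        Z, labels = self.build_z([[1.0, 0, 0, 0]] * 2)
        Z[labels == 1] = Z[labels == 0]  # force identical medians
        with pytest.raises(ParameterError, match="ambiguous"):
            match_archetypes(labels, Z)

    def test_surplus_clusters_all_mapped(self):
        Z, labels = self.build_z(
            [
                [1.5, 0, 0, 0.3],
                [-0.3, 0.2, 1.4, 0.3],
                [-0.3, -0.5, -1.0, -1.5],
                [-0.4, -0.5, -0.2, 0.4],
                [2.5, 0.5, 0.1, 0.3],
            ]
        )
        mapping = match_archetypes(labels, Z)
        assert set(mapping) == {0, 1, 2, 3, 4}
        assert mapping[4] == 3  # the extra high-BrdU cluster joins archetype 3


class TestPCA:
    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(100, 4)) @ rng.normal(size=(4, 4))
        Z, _, _ = em.standardize(X)
        _, loadings, var = em.pca_project(Z)
        np.testing.assert_allclose(loadings @ loadings.T, np.eye(2), atol=1e-9)
        assert var[0] >= var[1]

    def test_rank_two_data_fully_explained(self, rng):
        basis = rng.normal(size=(2, 4))
        X = rng.normal(size=(200, 2)) @ basis
        X += rng.normal(size=(200, 1)) * 0  # keep rank 2
        Z = X - X.mean(0)
        _, _, var = em.pca_project(Z)
        assert var.sum() == pytest.approx(1.0, abs=1e-9)


class TestEndToEnd:
    def test_archetype_recovery_single_seed(self, default_dataset, analyzed):
        from sklearn.metrics import adjusted_rand_score

        g = analyzed.gated
        ari = adjusted_rand_score(g["true_archetype"], g["cluster"].astype(int))
        assert ari >= 0.8
        assert analyzed.model.chosen_k == 4
        # bijective archetype map at k=4
        assert sorted(analyzed.model.archetype_map.values()) == [1, 2, 3, 4]

    def test_wss_decreasing_in_k(self, analyzed):
        wss = analyzed.model.wss_by_k
        ks = sorted(wss)
        assert all(wss[a] > wss[b] for a, b in zip(ks, ks[1:]))

    def test_fit_deterministic(self, default_dataset):
        r1 = em.analyze_dataset(default_dataset, seed=1)
        r2 = em.analyze_dataset(default_dataset, seed=1)
        assert (r1.table["cluster"].fillna(-1) == r2.table["cluster"].fillna(-1)).all()
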