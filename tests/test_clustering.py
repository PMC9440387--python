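"""Fuzzy c-means, hierarchical linkage, and PCA contracts."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from maternalome.clustering import (
    assign_clusters,
    fuzzy_cmeans,
    hierarchical_linkage,
    pca_embed,
)
from maternalome.errors import ValidationError
from maternalome.preprocess import aggregate_replicates, profiles_to_matrix, standardize_profiles
from maternalome.simulate import simulate_dataset


class TestFuzzyCMeans:
    def test_two_point_fixed_point(self):
        a, b = np.array([0.0, 0.0, 0.0]), np.array([10.0, 10.0, 10.0])
        X = np.vstack([np.tile(a, (20, 1)), np.tile(b, (20, 1))])
        model = fuzzy_cmeans(X, c=2, m=2.0, seed=0)
        centers = model.centers[np.argsort(model.centers[:, 0])]
        assert np.allclose(centers[0], a, atol=1e-6)
        assert np.allclose(centers[1], b, atol=1e-6)
        assert (model.membership.max(axis=1) > 0.99).all()

    def test_membership_rows_sum_to_one_and_objective_nonincreasing(self):
        rng = np.random.default_rng(1)
        model = fuzzy_cmeans(rng.normal(size=(80, 6)), c=4, seed=1)
        assert np.allclose(model.membership.sum(axis=1), 1.0, atol=1e-9)
        assert (np.diff(model.objective_trace) <= 1e-9).all()

    def test_zero_distance_gives_membership_one(self):
        X = np.array([[0.0, 0.0], [4.0, 4.0], [0.0, 0.0], [4.0, 4.0]] * 5)
        model = fuzzy_cmeans(X, c=2, m=2.0, seed=0)
        # centers converge onto the two duplicated points; the points then sit
        # at exactly zero distance and take membership ~1 there
        assert (model.membership.max(axis=1) > 1 - 1e-6).all()

    def test_archetype_recovery_single_seed(self):
        ds, truth = simulate_dataset(300, noise_sd=0.3, dropout=0.0, seed=0)
        std, _ = standardize_profiles(aggregate_replicates(ds))
        X, ids = profiles_to_matrix(std)
        model = fuzzy_cmeans(X, c=3, m=2.0, seed=0, protein_ids=ids)
        labels = assign_clusters(model)["cluster"]
        arch = truth.archetype_of()
        assert adjusted_rand_score([arch[i] for i in ids], labels) >= 0.9

    def test_near_hard_limit_matches_kmeans(self):
        rng = np.random.default_rng(7)
        blobs = np.vstack(
            [rng.normal(c, 0.3, size=(40, 6)) for c in (-4.0, 0.0, 4.0)]
        )
        model = fuzzy_cmeans(blobs, c=3, m=1.05, seed=7)
        soft = assign_clusters(model)["cluster"]
        hard = KMeans(n_clusters=3, n_init=10, random_state=7).fit_predict(blobs)
        assert adjusted_rand_score(hard, soft) >= 0.95

    def test_seed_determinism_and_row_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 6))
        m1 = fuzzy_cmeans(X, c=3, seed=5)
        m2 = fuzzy_cmeans(X, c=3, seed=5)
        assert np.array_equal(m1.membership, m2.membership)
        perm = rng.permutation(60)
        m3 = fuzzy_cmeans(X[perm], c=3, seed=5)
        # same objective up to label permutation of clusters
        assert m3.objective == pytest.approx(m1.objective, rel=1e-6)

    def test_validation_errors(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValidationError):
            fuzzy_cmeans(X, c=6)
        with pytest.raises(ValidationError):
            fuzzy_cmeans(np.empty((0, 3)), c=2)
        with pytest.raises(ValidationError):
            fuzzy_cmeans(X, c=2, m=1.0)
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fuzzy_cmeans(X, c=2)


class TestAssignClusters:
    def _model(self, membership):
        from maternalome.clustering import ClusterModel

        membership = np.asarray(membership, dtype=float)
        return ClusterModel(
            c=membership.shape[1],
            m=2.0,
            centers=np.zeros((membership.shape[1], 2)),
            membership=membership,
            objective_trace=[1.0],
            seed=0,
            protein_ids=[f"p{i}" for i in range(membership.shape[0])],
        )

    def test_above_cutoff_passes(self):
        out = assign_clusters(self._model([[0.6, 0.4]]), 0.5)
        assert out.loc[0, "cluster"] == 0 and out.loc[0, "passes_cutoff"]

    def test_tie_breaks_low_and_fails_strict_cutoff(self):
        out = assign_clusters(self._model([[0.5, 0.5]]), 0.5)
        assert out.loc[0, "cluster"] == 0 and not out.loc[0, "passes_cutoff"]

    def test_cutoff_one_never_passes(self):
        out = assign_clusters(self._model([[1.0, 0.0], [0.7, 0.3]]), 1.0)
        assert not out["passes_cutoff"].any()


def brute_force_average_linkage(X: np.ndarray) -> list[float]:
    """Naive agglomeration; returns sorted merge heights."""
    clusters: list[list[int]] = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [
                        np.linalg.norm(X[i] - X[j])
                        for i in clusters[a]
                        for j in clusters[b]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


class TestHierarchicalLinkage:
    def test_identical_columns_merge_first_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        Z = hierarchical_linkage(X)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == 0.0

    def test_forced_geometry_on_a_line(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        Z = hierarchical_linkage(X, method="average")
        first_two = [{int(Z[i, 0]), int(Z[i, 1])} for i in range(2)]
        assert {0, 1} in first_two and {2, 3} in first_two

    def test_matches_brute_force_agglomeration(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        Z = hierarchical_linkage(X, method="average")
        assert np.allclose(sorted(Z[:, 2]), brute_force_average_linkage(X), atol=1e-9)

    def test_one_minus_pearson_and_errors(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 6))
        Z = hierarchical_linkage(X, distance="one_minus_pearson", method="complete")
        assert Z.shape == (4, 4)
        with pytest.raises(ValidationError):
            hierarchical_linkage(X[:1])
        with pytest.raises(ValidationError):
            hierarchical_linkage(X, distance="one_minus_pearson", method="ward")


class TestPCA:
    def test_line_in_2d_fully_explained_by_first_component(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([2 * t + 1, -3 * t + 4])
        _, fractions = pca_embed(X, 2)
        assert fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_fractions_non_increasing(self):
        rng = np.random.default_rng(10)
        _, fractions = pca_embed(rng.normal(size=(40, 6)), 6)
        assert (np.diff(fractions) <= 1e-12).all()
        assert fractions.sum() <= 1 + 1e-12

    def test_component_variances_match_eigendecomposition(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 6))
        coords, fractions = pca_embed(X, 6)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        comp_var = coords.var(axis=0, ddof=1)
        assert np.allclose(comp_var, eigvals, atol=1e-9)
        assert np.allclose(fractions, eigvals / eigvals.sum(), atol=1e-9)

    def test_degenerate_input_gives_zero_fractions(self):
        X = np.ones((10, 3))
        coords, fractions = pca_embed(X, 2)
        assert np.allclose(coords, 0) and np.allclose(fractions, 0)

    def test_too_many_components_is_error(self):
        with pytest.raises(ValidationError):
            pca_embed(np.ones((4, 3)), 4)
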