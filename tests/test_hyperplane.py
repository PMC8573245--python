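import numpy as np
import pytest
import scipy.optimize
from sklearn.neighbors import NearestNeighbors

from khknn import (
    ConfigError,
    DataError,
    FeatureTable,
    KernelSpec,
    classify,
    classify_batch,
    find_class_neighbors,
    solve_alpha_kernel,
    solve_alpha_linear,
)
from khknn.kernels import gram_matrix, kernel_value

from conftest import random_two_class_table, table_1d

LINEAR = KernelSpec("linear")


def neighbor_fixture(rng, k=3, d=4):
    table = random_two_class_table(rng, n_min=12, n_max=20, d_min=d, d_max=d)
    query = rng.standard_normal(d)
    return find_class_neighbors(query, table, 0, k), query


class TestFindClassNeighbors:
    def test_brute_force_example(self):
        table = table_1d([0.0, 1.0, 5.0], [9.0, 10.0])
        nbrs = find_class_neighbors(np.array([0.4]), table, 0, 2)
        assert sorted(nbrs.neighbors.ravel()) == [0.0, 1.0]
        assert nbrs.centroid == pytest.approx(0.5)
        np.testing.assert_allclose(sorted(nbrs.diffs.ravel()), [-0.5, 0.5])

    def test_whole_class_when_k_equals_size(self):
        table = table_1d([0.0, 1.0, 5.0], [9.0, 10.0])
        nbrs = find_class_neighbors(np.array([0.4]), table, 0, 3)
        assert nbrs.k == 3 and not nbrs.k_capped
        assert nbrs.centroid == pytest.approx(2.0)

    def test_k_capped_at_class_size(self):
        table = table_1d([0.0, 1.0], [9.0, 10.0])
        nbrs = find_class_neighbors(np.array([0.0]), table, 0, 5)
        assert nbrs.k == 2 and nbrs.k_capped

    def test_equidistant_tie_prefers_smaller_row_index(self):
        table = table_1d([1.0, -1.0], [9.0, 10.0])
        nbrs = find_class_neighbors(np.array([0.0]), table, 0, 1)
        assert nbrs.neighbors[0, 0] == 1.0  # row 0 wins the tie
        permuted = table_1d([-1.0, 1.0], [9.0, 10.0])
        nbrs2 = find_class_neighbors(np.array([0.0]), permuted, 0, 1)
        assert nbrs2.neighbors[0, 0] == -1.0  # tie follows the permuted order

    def test_neighbor_set_invariants(self, rng):
        nbrs, _ = neighbor_fixture(rng)
        np.testing.assert_allclose(nbrs.centroid, nbrs.neighbors.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(nbrs.diffs.sum(axis=0), 0.0, atol=1e-12)

    def test_empty_class_raises(self):
        table = table_1d([0.0, 1.0], [2.0, 3.0])
        with pytest.raises(DataError):
            find_class_neighbors(np.array([0.0]), table, 7, 1)


class TestSolveAlphaLinear:
    def test_query_at_centroid_gives_zero(self, rng):
        nbrs, _ = neighbor_fixture(rng)
        sol = solve_alpha_linear(nbrs, nbrs.centroid, 1.0)
        np.testing.assert_allclose(sol.alpha, 0.0, atol=1e-12)
        assert sol.decision_distance_sq == pytest.approx(0.0, abs=1e-20)

    def test_huge_ridge_shrinks_alpha(self, rng):
        nbrs, query = neighbor_fixture(rng)
        free = solve_alpha_linear(nbrs, query, 1e-9)
        shrunk = solve_alpha_linear(nbrs, query, 1e9)
        assert np.linalg.norm(shrunk.alpha) <= 1e-6 * max(np.linalg.norm(free.alpha), 1e-12)

    def test_matches_numerical_minimizer(self, rng):
        """Closed-form alpha vs a general-purpose minimizer of the ridge objective."""
        nbrs, query = neighbor_fixture(rng, k=3, d=4)
        lam = 1.0
        xbar = query - nbrs.centroid
        V = nbrs.diffs

        def objective(a):
            r = xbar - V.T @ a
            return r @ r + lam * a @ a

        res = scipy.optimize.minimize(objective, np.zeros(nbrs.k), method="BFGS", tol=1e-12)
        sol = solve_alpha_linear(nbrs, query, lam)
        np.testing.assert_allclose(sol.alpha, res.x, atol=1e-4)
        assert sol.objective_value == pytest.approx(objective(sol.alpha), abs=1e-10)

    def test_singular_lambda_zero_uses_minimum_norm(self):
        # duplicated neighbors make V V^T rank-deficient
        table = FeatureTable(
            np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [9.0, 9.0], [8.0, 8.0]]),
            ["a", "b"], ["continuous"] * 2, np.array([0, 0, 0, 1, 1]),
        )
        nbrs = find_class_neighbors(np.array([0.5, 0.5]), table, 0, 3)
        sol = solve_alpha_linear(nbrs, np.array([0.5, 0.5]), 0.0)
        assert sol.singular
        assert np.isfinite(sol.alpha).all()


class TestSolveAlphaKernel:
    def test_linear_kernel_matches_linear_path(self, rng):
        for _ in range(20):
            nbrs, query = neighbor_fixture(rng, k=4, d=5)
            lin = solve_alpha_linear(nbrs, query, 1.0)
            ker = solve_alpha_kernel(nbrs, query, LINEAR, 1.0)
            np.testing.assert_allclose(ker.alpha, lin.alpha, atol=1e-8)
            assert ker.decision_distance_sq == pytest.approx(
                lin.decision_distance_sq, abs=1e-8
            )

    def test_query_at_centroid_linear_kernel(self, rng):
        nbrs, _ = neighbor_fixture(rng)
        sol = solve_alpha_kernel(nbrs, nbrs.centroid, LINEAR, 1.0)
        np.testing.assert_allclose(sol.alpha, 0.0, atol=1e-12)
        assert sol.decision_distance_sq == pytest.approx(0.0, abs=1e-12)

    def test_rbf_matches_numerical_minimizer(self, rng):
        """Gram-system alpha vs a minimizer of the feature-space objective
        expanded through kernel values."""
        spec = KernelSpec("rbf", 1.0)
        lam = 1.0
        nbrs, query = neighbor_fixture(rng, k=2, d=2)
        xbar = query - nbrs.centroid
        G = gram_matrix(nbrs.diffs, spec)
        kappa = np.array([kernel_value(v, xbar, spec) for v in nbrs.diffs])
        kxx = kernel_value(xbar, xbar, spec)

        def objective(a):
            return kxx - 2 * a @ kappa + a @ G @ a + lam * a @ a

        res = scipy.optimize.minimize(objective, np.zeros(nbrs.k), method="BFGS", tol=1e-12)
        sol = solve_alpha_kernel(nbrs, query, spec, lam)
        np.testing.assert_allclose(sol.alpha, res.x, atol=1e-4)

    def test_nonpositive_lambda_rejected(self, rng):
        nbrs, query = neighbor_fixture(rng)
        with pytest.raises(ConfigError):
            solve_alpha_kernel(nbrs, query, KernelSpec("rbf", 1.0), 0.0)


class TestClassify:
    def test_well_separated_classes(self):
        table = table_1d([-10.0, -9.0, -8.0], [8.0, 9.0, 10.0])
        profile = classify(np.array([-9.5]), table, 2, None, 1.0)
        assert profile.predicted_class == 0

    def test_k1_reduces_to_per_class_nearest_neighbor(self, rng):
        """With k=1 the single difference vector is zero, so the decision
        distance is the squared distance to the per-class nearest neighbor;
        cross-checked against a library nearest-neighbor search."""
        table = random_two_class_table(rng)
        queries = rng.standard_normal((8, table.n_features))
        for q in queries:
            profile = classify(q, table, 1, None, 1.0)
            expected = np.empty(2)
            for c in (0, 1):
                rows = table.values[table.labels == c]
                nn = NearestNeighbors(n_neighbors=1).fit(rows)
                dist, _ = nn.kneighbors(q[None, :])
                expected[c] = dist[0, 0] ** 2
            np.testing.assert_allclose(profile.per_class_distance_sq, expected, atol=1e-10)
            assert profile.predicted_class == int(np.argmin(expected))

    def test_exact_tie_goes_to_class_zero(self):
        table = table_1d([-1.0, -2.0], [1.0, 2.0])
        profile = classify(np.array([0.0]), table, 2, None, 1.0)
        d = profile.per_class_distance_sq
        assert d[0] == pytest.approx(d[1], abs=1e-14)
        assert profile.predicted_class == 0

    def test_centroid_classifier_limit_linear(self, rng):
        """lambda -> inf on the linear path degenerates to local-centroid distances."""
        table = random_two_class_table(rng, n_min=12, n_max=20)
        q = rng.standard_normal(table.n_features)
        profile = classify(q, table, 3, None, 1e9)
        for c in (0, 1):
            nbrs = find_class_neighbors(q, table, c, 3)
            expected = np.sum((q - nbrs.centroid) ** 2)
            assert profile.per_class_distance_sq[c] == pytest.approx(expected, abs=1e-6)

    def test_rbf_degenerates_at_huge_lambda(self, rng):
        """lambda -> inf on the RBF path drives every class distance to
        K(xbar, xbar) = 1: the classifier becomes uninformative."""
        table = random_two_class_table(rng, n_min=12, n_max=20)
        q = rng.standard_normal(table.n_features)
        profile = classify(q, table, 3, KernelSpec("rbf", 0.5), 1e9)
        np.testing.assert_allclose(profile.per_class_distance_sq, 1.0, atol=1e-6)

    def test_training_row_permutation_invariance(self, rng):
        table = random_two_class_table(rng, n_min=20, n_max=30)
        perm = rng.permutation(table.n_samples)
        shuffled = FeatureTable(
            table.values[perm], table.feature_names, table.feature_kinds, table.labels[perm]
        )
        queries = rng.standard_normal((10, table.n_features))
        for q in queries:
            a = classify(q, table, 3, KernelSpec("rbf", 0.25), 1.0)
            b = classify(q, shuffled, 3, KernelSpec("rbf", 0.25), 1.0)
            assert a.predicted_class == b.predicted_class
            np.testing.assert_allclose(
                a.per_class_distance_sq, b.per_class_distance_sq, atol=1e-10
            )

    def test_feature_scale_changes_predictions(self):
        """Rescaling one column by 1000 flips a prediction — distance methods
        are scale-sensitive, which motivates standardization by default."""
        values = np.array([[1.0, 0.2], [1.2, 0.3], [0.25, 0.9], [0.3, 1.0]])
        labels = np.array([0, 0, 1, 1])
        table = FeatureTable(values, ["a", "b"], ["continuous"] * 2, labels)
        q = np.array([0.0, 0.0])
        before = classify(q, table, 1, None, 1.0).predicted_class
        scaled = FeatureTable(
            values * np.array([1.0, 1000.0]), ["a", "b"], ["continuous"] * 2, labels
        )
        after = classify(q, scaled, 1, None, 1.0).predicted_class
        assert before != after


class TestClassifyBatch:
    def test_empty_input(self, rng):
        table = random_two_class_table(rng)
        assert classify_batch(np.empty((0, table.n_features)), table, 2, None, 1.0) == []

    def test_matches_elementwise_classify(self, rng):
        table = random_two_class_table(rng)
        queries = rng.standard_normal((10, table.n_features))
        batch = classify_batch(queries, table, 2, KernelSpec("rbf", 1.0), 1.0)
        assert len(batch) == 10
        for q, got in zip(queries, batch):
            single = classify(q, table, 2, KernelSpec("rbf", 1.0), 1.0)
            assert got.predicted_class == single.predicted_class
            np.testing.assert_array_equal(
                got.per_class_distance_sq, single.per_class_distance_sq
            )
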