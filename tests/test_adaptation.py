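"""NMI co-occurrence graph, graph-regularized factorization, ridge alignment."""

import numpy as np
import pytest

from clintraj.adaptation import (
    GraphRegularizedMF,
    align_projection,
    cooccurrence_nmi,
    factorize,
    laplacian_smoothness,
    occurrence_matrix,
)
from clintraj.knowledge import graph_laplacian


class TestCooccurrenceNMI:
    def test_identical_columns_give_one(self):
        col = np.array([1, 0, 1, 1, 0, 0])
        B = np.column_stack([col, col])
        G = cooccurrence_nmi(B)
        assert abs(G[0, 1] - 1.0) < 1e-12

    def test_constant_column_gives_zero(self):
        B = np.column_stack([np.ones(5), np.array([1, 0, 1, 0, 1])])
        G = cooccurrence_nmi(B)
        assert G[0, 1] == 0.0

    def test_contingency_table_oracle(self):
        # counts over 6 patients: (1,1)=2, (1,0)=1, (0,1)=1, (0,0)=2
        x = np.array([1, 1, 1, 0, 0, 0])
        y = np.array([1, 1, 0, 1, 0, 0])
        G = cooccurrence_nmi(np.column_stack([x, y]))
        p = np.array([[2, 1], [1, 2]]) / 6.0
        px, py = p.sum(axis=1), p.sum(axis=0)
        mi = sum(
            p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
            for i in range(2)
            for j in range(2)
        )
        h = -(0.5 * np.log(0.5)) * 2
        assert abs(G[0, 1] - mi / h) < 1e-12

    def test_symmetry_range_zero_diagonal(self):
        rng = np.random.default_rng(3)
        B = (rng.random((20, 8)) < 0.4).astype(int)
        G = cooccurrence_nmi(B)
        np.testing.assert_allclose(G, G.T)
        assert np.all(G >= 0) and np.all(G <= 1)
        assert np.all(np.diag(G) == 0)


class TestLaplacianSmoothness:
    def test_identical_rows_zero(self):
        G = np.array([[0, 1.0], [1.0, 0]])
        V = np.ones((2, 3))
        assert laplacian_smoothness(V, graph_laplacian(G)) < 1e-12

    def test_hand_value(self):
        G = np.array([[0, 1.0], [1.0, 0]])
        V = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert abs(laplacian_smoothness(V, graph_laplacian(G)) - 1.0) < 1e-12

    def test_trace_equals_pairwise_form(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n, d = int(rng.integers(2, 8)), int(rng.integers(1, 5))
            G = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
            G = np.triu(G, 1)
            G = G + G.T
            V = rng.normal(size=(n, d))
            tr = laplacian_smoothness(V, graph_laplacian(G))
            pw = 0.5 * sum(
                G[i, j] * np.sum((V[i] - V[j]) ** 2) for i in range(n) for j in range(n)
            )
            assert abs(tr - pw) < 1e-10


class TestFactorize:
    def test_zero_matrix_zero_solution(self):
        U, V, trace = factorize(np.zeros((4, 3)), d=2, gamma=0.1)
        assert np.abs(U).max() < 1e-6 and np.abs(V).max() < 1e-6
        assert trace[-1] < 1e-10

    def test_rank_one_recovery(self):
        u = np.array([1, 0, 1, 1, 0])
        v = np.array([1, 1, 0, 1])
        B = np.outer(u, v).astype(float)
        U, V, _ = factorize(B, d=1, gamma=1e-9)
        rel = np.linalg.norm(B - U @ V.T) / np.linalg.norm(B)
        assert rel <= 1e-6

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(7)
        for k in range(50):
            B = (rng.random((8, 6)) < 0.5).astype(float)
            G = cooccurrence_nmi(B) if k % 2 else np.zeros((6, 6))
            L = graph_laplacian(G)
            est = GraphRegularizedMF(n_components=2, gamma=0.05, lam=0.5 if k % 2 else 0.0, seed=k, max_iter=40)
            est.fit(B, L)
            tr = est.objective_trace_
            assert all(b <= a + 1e-8 for a, b in zip(tr, tr[1:]))

    def test_objective_not_above_initial(self):
        rng = np.random.default_rng(11)
        for seed in range(20):
            B = (rng.random((6, 5)) < 0.5).astype(float)
            est = GraphRegularizedMF(n_components=2, gamma=0.1, seed=seed, max_iter=30).fit(B)
            assert est.objective_trace_[-1] <= est.objective_trace_[0] + 1e-10

    def test_invalid_dimension_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            GraphRegularizedMF(n_components=0).fit(np.zeros((3, 3)))


def _gd_align(V, V_pre, alpha, steps=20000, lr=None):
    """Gradient-descent oracle for the ridge alignment objective."""
    W = np.zeros((V.shape[1], V_pre.shape[1]))
    lip = 2 * (np.linalg.norm(V.T @ V, 2) + alpha)
    lr = lr or 1.0 / lip
    for _ in range(steps):
        grad = 2 * V.T @ (V @ W - V_pre) + 2 * alpha * W
        W -= lr * grad
    return W


class TestAlignProjection:
    def test_identity_design_recovers_targets(self):
        V_pre = np.random.default_rng(13).normal(size=(4, 2))
        W = align_projection(np.eye(4), V_pre, alpha=0.0)
        np.testing.assert_allclose(W, V_pre, atol=1e-12)

    def test_ridge_shrinkage_limit(self):
        rng = np.random.default_rng(17)
        V = rng.normal(size=(6, 3))
        V_pre = rng.normal(size=(6, 2))
        W = align_projection(V, V_pre, alpha=1e8)
        assert np.linalg.norm(W) <= 1e-6 * np.linalg.norm(V.T @ V_pre)

    def test_matches_gradient_descent_minimizer(self):
        rng = np.random.default_rng(19)
        V = rng.normal(size=(6, 3))
        V_pre = rng.normal(size=(6, 2))
        W = align_projection(V, V_pre, alpha=0.1)
        W_gd = _gd_align(V, V_pre, alpha=0.1)
        assert np.abs(W - W_gd).max() < 1e-5

    def test_residual_beats_random_matrices(self):
        rng = np.random.default_rng(23)
        V = rng.normal(size=(7, 3))
        V_pre = rng.normal(size=(7, 2))
        alpha = 0.05
        W = align_projection(V, V_pre, alpha=alpha)

        def obj(M):
            return np.sum((V @ M - V_pre) ** 2) + alpha * np.sum(M**2)

        best = obj(W)
        for _ in range(100):
            assert obj(rng.normal(size=W.shape)) >= best - 1e-10

    def test_rank_deficient_alpha_zero_rejected(self):
        V = np.zeros((4, 2))
        V[:, 0] = 1.0
        with pytest.raises(ValueError, match="alpha"):
            align_projection(V, np.ones((4, 1)), alpha=0.0)

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="row counts"):
            align_projection(np.ones((3, 2)), np.ones((4, 2)), alpha=0.1)


def test_occurrence_matrix(abc_vocab):
    from clintraj.cohort import PatientTrajectory, encode_state

    p1 = PatientTrajectory("p1", (0.0, 1.0), [encode_state(["a"], abc_vocab), encode_state(["b"], abc_vocab)])
    p2 = PatientTrajectory("p2", (0.0,), [encode_state(["c"], abc_vocab)])
    B = occurrence_matrix([p1, p2], 3)
    np.testing.assert_array_equal(B, [[1, 1, 0], [0, 0, 1]])
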