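"""Soft assignment, hinge penalties, prior alignment and latent refinement."""

import networkx as nx
import numpy as np
import pytest

from clintraj.refine import (
    PriorDistribution,
    RefinementConfig,
    causal_violation_loss,
    derive_prior,
    hierarchy_violation_loss,
    kl_alignment_loss,
    multistep_causal_loss,
    refine_trajectory,
    refinement_objective_and_grad,
    soft_assign,
)


def random_dag_matrix(rng, n, p=0.3):
    """Random DAG adjacency: edges i->j only for i < j under a permutation."""
    order = rng.permutation(n)
    M = np.zeros((n, n), dtype=np.int8)
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p:
                M[order[a], order[b]] = 1
    return M, order


class TestSoftAssign:
    def test_zero_logits_uniform(self):
        s = soft_assign(np.zeros(4), np.zeros((4, 3)))
        np.testing.assert_allclose(s, 1 / 3)

    def test_hand_softmax(self):
        P = np.eye(2)
        s = soft_assign(np.array([np.log(2.0), 0.0]), P)
        np.testing.assert_allclose(s, [2 / 3, 1 / 3], atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=5)
        P = rng.normal(size=(5, 6))
        s1 = soft_assign(z, P)
        # adding a constant to all logits = adding c * ones to P^T z
        P2 = P + np.outer(z, np.ones(6)) * (3.7 / (z @ z))
        s2 = soft_assign(z, P2)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            soft_assign(np.array([np.inf, 0.0]), np.eye(2))


class TestHingeLosses:
    def test_uniform_scores_zero(self):
        T = np.zeros((3, 3)); T[0, 1] = 1
        assert hierarchy_violation_loss(np.full(3, 1 / 3), T) == 0.0

    def test_hand_hinge(self):
        T = np.zeros((2, 2)); T[0, 1] = 1  # concept 0 ancestor of 1
        assert abs(hierarchy_violation_loss(np.array([0.3, 0.7]), T) - 0.4) < 1e-12

    def test_causal_satisfied_order(self):
        C = np.zeros((2, 2)); C[0, 1] = 1
        assert causal_violation_loss(np.array([0.6, 0.4]), C) == 0.0

    def test_causal_hand_value(self):
        C = np.zeros((2, 2)); C[0, 1] = 1
        assert abs(causal_violation_loss(np.array([0.2, 0.5]), C) - 0.3) < 1e-12

    def test_zero_on_topologically_sorted_assignments(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 11))
            M, order = random_dag_matrix(rng, n)
            # scores decreasing along the topological order: ancestors high
            vals = np.sort(rng.random(n))[::-1]
            s = np.empty(n)
            s[order] = vals / vals.sum()
            assert hierarchy_violation_loss(s, M) == 0.0
            # a single planted inversion makes it strictly positive
            edges = np.argwhere(M)
            if len(edges):
                i, j = edges[int(rng.integers(len(edges)))]
                s2 = s.copy()
                s2[i], s2[j] = s2[j], s2[i]
                if s[i] != s[j]:
                    assert hierarchy_violation_loss(s2, M) > 0.0


class TestMultistep:
    def test_single_step_zero(self):
        C = np.zeros((3, 3)); C[0, 1] = 1
        assert multistep_causal_loss(np.full((1, 3), 1 / 3), C) == 0.0

    def test_hand_value(self):
        C = np.zeros((2, 2)); C[0, 1] = 1
        S = np.array([[0.2, 0.8], [0.5, 0.5]])
        assert abs(multistep_causal_loss(S, C) - 0.3) < 1e-12

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            T = int(rng.integers(1, 6))
            C, _ = random_dag_matrix(rng, n)
            S = rng.random((T, n))
            S /= S.sum(axis=1, keepdims=True)
            oracle = 0.0
            for t in range(T - 1):
                for i in range(n):
                    for j in range(n):
                        if C[i, j]:
                            oracle += max(0.0, S[t + 1, j] - S[t, i])
            assert abs(multistep_causal_loss(S, C) - oracle) < 1e-10


class TestKLAlignment:
    def test_zero_at_equality(self):
        q = np.array([0.25, 0.75])
        assert kl_alignment_loss(q, q, eps=0.0) == 0.0

    def test_hand_value(self):
        assert abs(kl_alignment_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]), eps=0.0) - np.log(2)) < 1e-12

    def test_epsilon_bias_bounded_below(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(2, 10))
            q = rng.random(n)
            q /= q.sum()
            eps = 10.0 ** rng.uniform(-8, -2)
            v = kl_alignment_loss(q, q, eps=eps)
            assert v <= 0.0
            assert v >= -np.log(1 + eps * n) - 1e-12

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            kl_alignment_loss(np.array([0.0, 1.0]), np.array([1.0, 0.0]), eps=0.0)


class TestDerivePrior:
    def test_uniform(self):
        pr = derive_prior(None, 4, mode="uniform")
        np.testing.assert_allclose(pr.q, 0.25)

    def test_frequency_add_one(self, abc_vocab):
        from clintraj.cohort import PatientTrajectory, encode_state

        states = [encode_state(["a"], abc_vocab) for _ in range(3)] + [encode_state(["b"], abc_vocab)]
        p = PatientTrajectory("p", (0.0, 1.0, 2.0, 3.0), states)
        pr = derive_prior([p], 2, mode="frequency")
        np.testing.assert_allclose(pr.q, [4 / 6, 2 / 6])

    def test_sums_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            pr = derive_prior(None, int(rng.integers(2, 30)), mode="uniform")
            assert abs(pr.q.sum() - 1.0) < 1e-12

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            PriorDistribution(q=np.array([0.5, 0.2]))


def _random_instance(rng, n=6, d=5, T=3):
    P = rng.normal(size=(d, n))
    Z = rng.normal(size=(T, d))
    anc, _ = random_dag_matrix(rng, n)
    cau, _ = random_dag_matrix(rng, n)
    return Z, P, anc, cau


class TestRefinement:
    def test_consistent_assignment_returned_unchanged(self):
        # one concept dominating along the hierarchy order: no violation
        P = np.eye(3)
        Z = np.array([[3.0, 2.0, 1.0]])
        anc = np.zeros((3, 3)); anc[0, 1] = anc[0, 2] = anc[1, 2] = 1
        cau = np.zeros((3, 3)); cau[0, 1] = 1
        out = refine_trajectory(Z, P, anc, cau)
        np.testing.assert_array_equal(out, Z)

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(13)
        cfg = RefinementConfig()
        checked = 0
        for _ in range(50):
            Z, P, anc, cau = _random_instance(rng)
            gammas = np.exp(rng.normal(size=Z.shape[0]) * 0.3)
            obj, grad, _ = refinement_objective_and_grad(Z, P, anc, cau, cfg, gammas)
            if obj == 0:
                continue
            h = 1e-6
            for _ in range(4):
                t = int(rng.integers(Z.shape[0]))
                k = int(rng.integers(Z.shape[1]))
                Zp, Zm = Z.copy(), Z.copy()
                Zp[t, k] += h
                Zm[t, k] -= h
                op, *_ = refinement_objective_and_grad(Zp, P, anc, cau, cfg, gammas)
                om, *_ = refinement_objective_and_grad(Zm, P, anc, cau, cfg, gammas)
                fd = (op - om) / (2 * h)
                denom = max(abs(fd), abs(grad[t, k]), 1e-8)
                assert abs(fd - grad[t, k]) / denom < 1e-4
                checked += 1
        assert checked >= 50

    def test_descent_reduces_hierarchy_violation(self):
        # single ancestor pair with the child scored above the parent
        P = np.eye(2) * 5.0
        Z = np.array([[0.0, 1.0]])  # child (concept 1) scores higher
        anc = np.zeros((2, 2)); anc[0, 1] = 1
        cau = np.zeros((2, 2))
        cfg = RefinementConfig(step_size=1e-2, max_steps=50)
        before = hierarchy_violation_loss(soft_assign(Z[0], P), anc)
        out = refine_trajectory(Z, P, anc, cau, cfg)
        after = hierarchy_violation_loss(soft_assign(out[0], P), anc)
        assert after < before

    def test_safeguard_monotone_descent(self):
        rng = np.random.default_rng(17)
        cfg = RefinementConfig(step_size=0.5, max_steps=20, halving=True)
        for _ in range(100):
            Z, P, anc, cau = _random_instance(rng, n=5, d=4, T=2)
            _, trace = refine_trajectory(Z, P, anc, cau, cfg, return_trace=True)
            assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_assignments_stay_distributions_during_refinement(self):
        rng = np.random.default_rng(19)
        Z, P, anc, cau = _random_instance(rng)
        out = refine_trajectory(Z, P, anc, cau, RefinementConfig(max_steps=10))
        for t in range(out.shape[0]):
            s = soft_assign(out[t], P)
            assert np.all(s >= 0) and abs(s.sum() - 1.0) < 1e-8

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RefinementConfig(step_size=0.0)
        with pytest.raises(ValueError):
            RefinementConfig(lambda_hier=-1.0)
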