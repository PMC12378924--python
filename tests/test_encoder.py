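"""Temporal encoding, factor partition, disentanglement and smoothness."""

import numpy as np
import pytest

from clintraj.cohort import PatientTrajectory, build_event_graph, encode_state
from clintraj.encoder import (
    EncoderConfig,
    TemporalEncoder,
    covariance_loss,
    factor_partition,
    mi_disentanglement_loss,
    relation_tensor_mix,
    temporal_smoothness_loss,
)
from conftest import make_vocab


def small_config(**kw):
    defaults = dict(layers=2, hidden_dim=8, n_factors=2, factor_dim=3, attention_heads=2, seed=0)
    defaults.update(kw)
    return EncoderConfig(**defaults)


def make_traj(visits, vocab):
    states = [encode_state(v, vocab) for v in visits]
    return PatientTrajectory("p", tuple(float(i) for i in range(len(states))), states)


class TestRelationTensorMix:
    def test_identity_slice_identity_transform(self):
        x = np.array([1.0, 2.0, 3.0])
        out = relation_tensor_mix(x, [np.eye(3)], [np.eye(3)])
        np.testing.assert_allclose(out, x)

    def test_zero_slice_is_inert(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4)
        G1, W1 = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        one = relation_tensor_mix(x, [G1], [W1])
        two = relation_tensor_mix(x, [G1, np.zeros((4, 4))], [W1, rng.normal(size=(4, 4))])
        np.testing.assert_allclose(one, two)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        n, k = 5, 3
        x = rng.normal(size=n)
        Gs = [rng.normal(size=(n, n)) for _ in range(k)]
        Ws = [rng.normal(size=(n, n)) for _ in range(k)]
        out = relation_tensor_mix(x, Gs, Ws)
        oracle = np.zeros(n)
        for r in range(k):
            y = np.zeros(n)
            for i in range(n):
                for j in range(n):
                    y[i] += Gs[r][i, j] * x[j]
            for i in range(n):
                for j in range(n):
                    oracle[j] += y[i] * Ws[r][i, j]
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="transform"):
            relation_tensor_mix(np.ones(3), [np.eye(3)], [])


class TestEncodeTrajectory:
    def test_zero_transforms_mean_pooling_gives_projected_embedding(self):
        vocab = make_vocab(4)
        cfg = small_config()
        enc = TemporalEncoder(cfg, embed_dim=4)
        for lab in ("intra", "inter", "ontology"):
            enc.params[f"W_{lab}"] = np.zeros((4, 4))
        t = make_traj([["c1"], ["c2"]], vocab)
        table = np.random.default_rng(0).normal(size=(4, 4))
        Z = enc.encode(build_event_graph(t), table, n_visits=2)
        np.testing.assert_allclose(Z[0], table[1] @ enc.params["W_out"], atol=1e-12)
        np.testing.assert_allclose(Z[1], table[2] @ enc.params["W_out"], atol=1e-12)

    def test_permutation_of_event_order_leaves_latent_unchanged(self):
        vocab = make_vocab(6)
        cfg = small_config()
        table = np.random.default_rng(1).normal(size=(6, 4))
        enc = TemporalEncoder(cfg, embed_dim=4)
        t1 = make_traj([["c0", "c2", "c4"], ["c1", "c3"]], vocab)
        t2 = make_traj([["c4", "c0", "c2"], ["c3", "c1"]], vocab)
        Z1 = enc.encode(build_event_graph(t1), table, n_visits=2)
        Z2 = enc.encode(build_event_graph(t2), table, n_visits=2)
        np.testing.assert_allclose(Z1, Z2, atol=1e-10)

    def test_deterministic_given_seed(self):
        vocab = make_vocab(5)
        cfg = small_config(seed=7)
        t = make_traj([["c0", "c1"], ["c2"]], vocab)
        table = np.random.default_rng(3).normal(size=(5, 4))
        Z1 = TemporalEncoder(cfg, 4).encode(build_event_graph(t), table, n_visits=2)
        Z2 = TemporalEncoder(cfg, 4).encode(build_event_graph(t), table, n_visits=2)
        np.testing.assert_array_equal(Z1, Z2)

    def test_empty_visit_emits_zero_latent(self):
        vocab = make_vocab(3)
        cfg = small_config()
        enc = TemporalEncoder(cfg, 4)
        t = make_traj([["c0"]], vocab)
        g = build_event_graph(t)
        Z = enc.encode(g, np.ones((3, 4)), n_visits=3)  # visits 1,2 have no nodes
        assert np.all(Z[1] == 0) and np.all(Z[2] == 0)


class TestFactorPartition:
    def test_blocks_and_round_trip(self):
        z = np.arange(1.0, 7.0)
        blocks = factor_partition(z, 3)
        np.testing.assert_array_equal(blocks[0], [1, 2])
        np.testing.assert_array_equal(blocks[2], [5, 6])
        np.testing.assert_array_equal(np.concatenate(blocks), z)

    def test_single_factor(self):
        z = np.arange(4.0)
        np.testing.assert_array_equal(factor_partition(z, 1)[0], z)

    def test_round_trip_random(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            z = rng.normal(size=12)
            np.testing.assert_array_equal(np.concatenate(factor_partition(z, 4)), z)

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="7.*3|3.*7"):
            factor_partition(np.zeros(7), 3)


class TestCovarianceLoss:
    def test_orthogonal_factors_zero(self):
        assert covariance_loss([np.array([1.0, 0.0]), np.array([0.0, 2.0])]) == 0.0

    def test_identical_factors_two(self):
        v = np.array([1.0, 2.0])
        assert abs(covariance_loss([v, v]) - 2.0) < 1e-12

    def test_hand_cosine(self):
        loss = covariance_loss([np.array([1.0, 0.0]), np.array([1.0, 1.0])])
        assert abs(loss - 1.0) < 1e-12  # 2 * (1/sqrt(2))^2

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(9)
        blocks = [rng.normal(size=4) for _ in range(3)]
        base = covariance_loss(blocks)
        scaled = [b * s for b, s in zip(blocks, (0.1, 7.0, 3.3))]
        assert abs(covariance_loss(scaled) - base) < 1e-10

    def test_zero_norm_factor_contributes_nothing(self):
        loss = covariance_loss([np.zeros(3), np.ones(3), np.ones(3)])
        assert abs(loss - 2.0) < 1e-12


class TestTemporalSmoothness:
    def test_constant_trajectory_zero(self):
        Z = np.tile(np.arange(6.0), (4, 1))
        assert temporal_smoothness_loss(Z, per_factor=True, K=2) == 0.0

    def test_unit_step(self):
        Z = np.zeros((2, 4))
        Z[1, 0] = 1.0
        assert temporal_smoothness_loss(Z) == 1.0

    def test_per_factor_equals_whole_vector(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            Z = rng.normal(size=(5, 12))
            a = temporal_smoothness_loss(Z, per_factor=True, K=4)
            b = temporal_smoothness_loss(Z, per_factor=False)
            assert abs(a - b) < 1e-12

    def test_single_step_trajectory_zero(self):
        assert temporal_smoothness_loss(np.ones((1, 4))) == 0.0


class TestMIDisentanglement:
    def test_independent_blocks_near_zero(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10_000, 2, 3))
        assert mi_disentanglement_loss(X) <= 0.05

    def test_copied_block_hits_clipping_ceiling(self):
        rng = np.random.default_rng(17)
        A = rng.normal(size=(500, 1, 2))
        X = np.concatenate([A, A], axis=1)
        loss = mi_disentanglement_loss(X)
        ceiling = -0.5 * np.log(1e-6) * 2 * 2  # 2 ordered pairs x 2 canonical corrs
        assert np.isfinite(loss)
        assert loss > 0.9 * ceiling

    def test_bivariate_gaussian_closed_form(self):
        rng = np.random.default_rng(19)
        n = 100_000
        for rho in (0.0, 0.9):
            z = rng.normal(size=n)
            x = z
            y = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)
            X = np.stack([x[:, None], y[:, None]], axis=1)
            loss = mi_disentanglement_loss(X)
            expected = -0.5 * np.log(1 - rho**2) if rho else 0.0
            assert abs(loss / 2 - expected) < 0.05  # per ordered pair

    def test_small_batch_rejected(self):
        with pytest.raises(ValueError, match="batch"):
            mi_disentanglement_loss(np.zeros((4, 2, 2)))


def test_config_validates_dimensions():
    cfg = EncoderConfig()
    assert cfg.latent_dim == 384  # 6 factors x 64 dims
    with pytest.raises(ValueError):
        EncoderConfig(layers=0)


def test_attention_pooling_is_permutation_invariant():
    vocab = make_vocab(6)
    cfg = small_config(pooling="attention")
    enc = TemporalEncoder(cfg, embed_dim=4)
    table = np.random.default_rng(21).normal(size=(6, 4))
    t1 = make_traj([["c0", "c2", "c4"]], vocab)
    t2 = make_traj([["c4", "c0", "c2"]], vocab)
    Z1 = enc.encode(build_event_graph(t1), table, n_visits=1)
    Z2 = enc.encode(build_event_graph(t2), table, n_visits=1)
    np.testing.assert_allclose(Z1, Z2, atol=1e-10)
    assert Z1.shape == (1, cfg.latent_dim)
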