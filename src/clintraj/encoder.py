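"""Temporal encoding of patient event graphs into disentangled latent factors.

Per-visit latents ``z(t)`` are obtained by relation-aware residual message
passing over the patient's temporal event graph followed by permutation-
invariant pooling of the final-layer node embeddings at each timestamp.  Each
``z(t)`` is partitioned into K contiguous factor blocks; a covariance penalty
decorrelates the blocks, a temporal-consistency penalty discourages abrupt
per-factor jumps, and a Gaussian canonical-correlation surrogate stands in
for the mutual-information regularizer between blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from clintraj import autodiff as ad
from clintraj.cohort import TemporalEventGraph
from clintraj.embedding import xavier_uniform

EDGE_LABELS = ("intra", "inter", "ontology")


@dataclass
class EncoderConfig:
    """Architecture and training defaults for the temporal encoder.

    The pooled per-timestep latent dimension is ``n_factors × factor_dim``
    (384 with the defaults of 6 factors of 64 dimensions each).
    """

    layers: int = 4
    hidden_dim: int = 256
    n_factors: int = 6
    factor_dim: int = 64
    attention_heads: int = 8
    dropout: float = 0.3
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    reg_coefficient: float = 0.01
    pooling: str = "mean"  # "mean" | "attention"
    seed: int = 0

    @property
    def latent_dim(self) -> int:
        return self.n_factors * self.factor_dim

    def __post_init__(self) -> None:
        for name in ("layers", "hidden_dim", "n_factors", "factor_dim", "attention_heads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def relation_tensor_mix(x, slices: list, transforms: list):
    """Relation-tensor propagation ``x̃ = Σ_r (G_r x) W_r``.

    ``slices`` are k matrices |E|×|E| (one per semantic relation), and
    ``transforms`` the matching per-slice feature transforms.
    """
    if len(slices) != len(transforms):
        raise ValueError("need one transform per relation slice")
    n = ad.asdata(x).shape[0]
    out = None
    for G, W in zip(slices, transforms):
        if ad.asdata(G).shape[0] != n:
            raise ValueError(f"slice shape {ad.asdata(G).shape} does not match state length {n}")
        term = (G @ x) @ W if ad.asdata(x).ndim > 1 else (G @ x) @ W
        out = term if out is None else out + term
    return out


class TemporalEncoder:
    """Relation-aware graph encoder with per-visit pooling.

    Parameters are held as named numpy arrays in ``params``; the ``encode``
    method runs generically on ndarrays or autodiff Tensors, so the same
    forward pass serves scoring and training.  Dropout is applied only when
    ``training=True``; all evaluation paths are deterministic given the seed.
    """

    def __init__(self, config: EncoderConfig, embed_dim: int, rng: np.random.Generator | None = None):
        self.config = config
        self.embed_dim = embed_dim
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        for lab in EDGE_LABELS:
            self.params[f"W_{lab}"] = xavier_uniform((embed_dim, embed_dim), rng)
        self.params["W_out"] = xavier_uniform((embed_dim, config.latent_dim), rng)
        self.params["pool_q"] = xavier_uniform((config.attention_heads, embed_dim), rng)

    def _adjacency(self, graph: TemporalEventGraph) -> dict[str, np.ndarray]:
        """Per-label message adjacency: A[j, i] = 1 iff node j sends to node i.

        Intra-visit and ontology edges pass messages both ways; inter-visit
        edges pass information forward in time only.
        """
        pos = {node: i for i, node in enumerate(graph.nodes)}
        N = graph.n_nodes
        A = {lab: np.zeros((N, N)) for lab in EDGE_LABELS}
        for u, v, lab in graph.edges:
            iu, iv = pos[u], pos[v]
            if lab == "inter":
                A[lab][iu, iv] = 1.0
            else:
                A[lab][iu, iv] = 1.0
                A[lab][iv, iu] = 1.0
        return A

    def encode(
        self,
        graph: TemporalEventGraph,
        table,
        params: dict | None = None,
        n_visits: int | None = None,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Latent trajectory, one row z(t) per visit (zero rows for empty visits).

        One propagation layer updates every node with a ReLU-rectified,
        attention-weighted sum of relation-transformed neighbor features
        (keys double as values), added residually; the attention softmax runs
        jointly over all (edge label, neighbor) pairs of a node.
        """
        P = params if params is not None else self.params
        cfg = self.config
        is_tensor = isinstance(table, ad.Tensor) or any(isinstance(v, ad.Tensor) for v in P.values())
        if graph.n_nodes == 0:
            T = n_visits or 0
            return np.zeros((T, cfg.latent_dim))
        concept_idx = np.asarray([e for _, e in graph.nodes])
        feats = table[concept_idx]
        A = self._adjacency(graph)
        has_nbr = (sum(A.values()).sum(axis=0) > 0).astype(float)[:, None]
        N = graph.n_nodes
        scale = 1.0 / np.sqrt(self.embed_dim)
        for _ in range(cfg.layers):
            keys = {lab: feats @ P[f"W_{lab}"].T for lab in EDGE_LABELS}
            scores = {lab: (keys[lab] @ feats.T) * scale for lab in EDGE_LABELS}
            shift = np.max(np.stack([ad.asdata(s) for s in scores.values()]), axis=(0, 1))
            msg = None
            denom = None
            for lab in EDGE_LABELS:
                if not A[lab].any():
                    continue
                E = ad.exp(scores[lab] - shift[None, :]) * A[lab]
                d_lab = E.sum(axis=0)
                m_lab = E.T @ keys[lab]
                denom = d_lab if denom is None else denom + d_lab
                msg = m_lab if msg is None else msg + m_lab
            if msg is None:
                break
            inv = (denom + 1e-300) ** -1.0
            update = ad.relu(msg * (inv.reshape(N, 1) if is_tensor else inv[:, None]))
            feats = feats + update * has_nbr
        if training and cfg.dropout > 0:
            rng = rng if rng is not None else np.random.default_rng(cfg.seed)
            keep = (rng.random(ad.asdata(feats).shape) >= cfg.dropout) / (1 - cfg.dropout)
            feats = feats * keep
        T = n_visits if n_visits is not None else (max(t for t, _ in graph.nodes) + 1)
        if cfg.pooling == "attention":
            zs = []
            zero = np.zeros(self.embed_dim)
            for t in range(T):
                idx = [i for i, (tt, _) in enumerate(graph.nodes) if tt == t]
                if not idx:
                    zs.append(ad.Tensor(zero) if is_tensor else zero)
                    continue
                sub = feats[np.asarray(idx)]
                pooled = None
                for h in range(cfg.attention_heads):
                    a = ad.softmax(sub @ P["pool_q"][h], axis=-1)
                    ph = a @ sub
                    pooled = ph if pooled is None else pooled + ph
                pooled = pooled * (1.0 / cfg.attention_heads)
                zs.append(pooled)
            pooled_all = ad.stack(zs)
        else:
            pool = np.zeros((T, N))
            for i, (tt, _) in enumerate(graph.nodes):
                pool[tt, i] = 1.0
            counts = pool.sum(axis=1, keepdims=True)
            pool = pool / np.maximum(counts, 1.0)
            pooled_all = pool @ feats
        return pooled_all @ P["W_out"]


def encode_trajectory(graph: TemporalEventGraph, table, config: EncoderConfig, n_visits: int | None = None):
    """Functional wrapper: encode with freshly seeded encoder parameters."""
    enc = TemporalEncoder(config, ad.asdata(table).shape[1])
    return enc.encode(graph, table, n_visits=n_visits)


def factor_partition(z, K: int):
    """Split a latent vector (or T×d trajectory) into K contiguous blocks."""
    d = ad.asdata(z).shape[-1]
    if d % K != 0:
        raise ValueError(f"latent dimension {d} is not divisible by K={K}")
    fd = d // K
    if ad.asdata(z).ndim == 1:
        return [z[np.arange(k * fd, (k + 1) * fd)] for k in range(K)]
    return [z[:, k * fd : (k + 1) * fd] if not isinstance(z, ad.Tensor) else z[(slice(None), slice(k * fd, (k + 1) * fd))] for k in range(K)]


def covariance_loss(blocks) -> float:
    """Pairwise squared cosine similarity between factor blocks.

    ``Σ_{i≠j} (⟨z_i, z_j⟩ / (‖z_i‖‖z_j‖))²`` over ordered pairs; a zero-norm
    factor contributes 0 to all its pairs.  Accepts a list/array of K factor
    vectors, or a (T, K, fd) stack which is summed over T.
    """
    arr = np.asarray([ad.asdata(b) for b in blocks]) if isinstance(blocks, (list, tuple)) else ad.asdata(blocks)
    if arr.ndim == 3:
        return float(sum(covariance_loss(arr[t]) for t in range(arr.shape[0])))
    K = arr.shape[0]
    if K < 2:
        raise ValueError("need at least two factors")
    norms = np.linalg.norm(arr, axis=1)
    total = 0.0
    for i in range(K):
        for j in range(K):
            if i == j or norms[i] < 1e-12 or norms[j] < 1e-12:
                continue
            c = float(arr[i] @ arr[j] / (norms[i] * norms[j]))
            total += c * c
    return float(total)


def covariance_loss_t(blocks: list) -> "ad.Tensor":
    """Differentiable covariance penalty for a list of factor-block Tensors."""
    K = len(blocks)
    total = ad.Tensor(0.0)
    eps = 1e-12
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            ni = ((blocks[i] * blocks[i]).sum() + eps) ** 0.5
            nj = ((blocks[j] * blocks[j]).sum() + eps) ** 0.5
            c = (blocks[i] * blocks[j]).sum() / (ni * nj)
            total = total + c * c
    return total


def temporal_smoothness_loss(Z, per_factor: bool = True, K: int | None = None):
    """Temporal consistency penalty ``Σ_{t≥2} Σ_k ‖Δz_k(t)‖²``.

    For any complete partition into factor blocks this equals the
    whole-vector form ``Σ_{t≥2} ‖Δz(t)‖²`` exactly (direct-sum Pythagorean
    identity); ``per_factor=False`` computes the whole-vector form.
    """
    if isinstance(Z, ad.Tensor):
        T = Z.shape[0]
        if T < 2:
            return ad.Tensor(0.0)
        diff = Z[np.arange(1, T)] - Z[np.arange(0, T - 1)]
        return (diff * diff).sum()
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < 2:
        return 0.0
    diff = np.diff(Z, axis=0)
    if per_factor:
        if K is None:
            K = 1
        fd = Z.shape[1] // K
        blocks = diff.reshape(diff.shape[0], K, fd)
        return float(np.sum(np.sum(blocks**2, axis=2)))
    return float(np.sum(diff**2))


def mi_disentanglement_loss(batch_blocks: np.ndarray, clip: float = 1.0 - 1e-6) -> float:
    """Gaussian mutual-information surrogate between factor blocks.

    For each ordered pair of blocks, computes the canonical correlations ρ
    between the two coordinate sets across the batch and accumulates
    ``−½ Σ log(1 − ρ²)`` (the mutual information of a Gaussian with those
    canonical correlations), with ρ² clipped at ``clip``.  Zero iff all
    blocks are uncorrelated; requires a batch of at least 8 samples.
    """
    X = np.asarray(batch_blocks, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected (n_samples, K, factor_dim)")
    n, K, fd = X.shape
    if n < 8:
        raise ValueError(f"batch size {n} too small for MI estimation (need >= 8)")
    Xc = X - X.mean(axis=0, keepdims=True)
    total = 0.0
    ridge = 1e-10
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            A, B = Xc[:, i, :], Xc[:, j, :]
            Caa = A.T @ A / n + ridge * np.eye(fd)
            Cbb = B.T @ B / n + ridge * np.eye(fd)
            Cab = A.T @ B / n
            Wa = np.linalg.cholesky(np.linalg.inv(Caa))
            Wb = np.linalg.cholesky(np.linalg.inv(Cbb))
            M = Wa.T @ Cab @ Wb
            rho = scipy.linalg.svdvals(M)
            rho2 = np.clip(rho**2, 0.0, clip)
            total += -0.5 * float(np.sum(np.log1p(-rho2)))
    return float(total)
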