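"""Ontology-aware concept-embedding initialization and refinement.

Each concept vector is refined by attending to its ontology neighbors:
a context vector is the attention-weighted sum of neighbor embeddings, the
layer update adds a ReLU-rectified, relation-transformed neighborhood message
to the previous layer's embedding (residual update), and a structural
reconstruction penalty keeps the final embeddings near their ontology-informed
context.

All operations accept either plain ndarrays or autodiff Tensors, so the same
code serves gradient-free evaluation and training.
"""

from __future__ import annotations

import numpy as np

from clintraj import autodiff as ad
from clintraj.knowledge import KnowledgeBase


def xavier_uniform(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Xavier/Glorot uniform initialization: U(−a, a), a = sqrt(6/(fan_in+fan_out))."""
    fan_in, fan_out = (shape[0], shape[-1]) if len(shape) > 1 else (shape[0], shape[0])
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape)


def _similarity(ei, keys, similarity: str, concept_id: str | None = None):
    """Attention scores between one query vector and stacked keys."""
    d = ad.asdata(ei).shape[0]
    if similarity == "scaled_dot":
        return keys @ ei * (1.0 / np.sqrt(d))
    if similarity == "cosine":
        ei_n = float(np.linalg.norm(ad.asdata(ei)))
        key_n = np.linalg.norm(ad.asdata(keys), axis=1)
        if ei_n < 1e-12 or np.any(key_n < 1e-12):
            raise ValueError(
                f"zero-norm embedding under cosine similarity (concept {concept_id})"
            )
        return (keys @ ei) * (1.0 / ei_n) * ad.Tensor(1.0 / key_n) if isinstance(keys, ad.Tensor) else (keys @ ei) / (ei_n * key_n)
    raise ValueError(f"unknown similarity {similarity!r}")


def neighborhood_attention(
    table,
    knowledge_base: KnowledgeBase,
    similarity: str = "scaled_dot",
    return_weights: bool = False,
):
    """Context vectors ``ẽ_i = Σ_{j∈N(i)} α_ij e_j`` with softmax attention.

    Attention weights over each concept's ontology neighborhood are
    nonnegative and sum to one.  Isolated concepts (no ontology neighbors)
    get ``ẽ_i = e_i`` and are thereby loss-neutral under the structural
    penalty.
    """
    nbrs = knowledge_base.ontology_neighbors()
    is_tensor = isinstance(table, ad.Tensor)
    rows = []
    weights: dict[int, np.ndarray] = {}
    for i in range(knowledge_base.n_concepts):
        neigh = sorted({j for _, j in nbrs[i]})
        if not neigh:
            rows.append(table[i])
            continue
        keys = table[np.asarray(neigh)]
        scores = _similarity(table[i], keys, similarity, knowledge_base.vocabulary.concept_ids[i])
        alpha = ad.softmax(scores, axis=-1)
        rows.append(alpha @ keys)
        if return_weights:
            weights[i] = ad.asdata(alpha)
    out = ad.stack(rows) if is_tensor else np.stack([ad.asdata(r) for r in rows])
    return (out, weights) if return_weights else out


def relation_propagate(
    table,
    knowledge_base: KnowledgeBase,
    transforms: dict,
    n_layers: int = 1,
    similarity: str = "scaled_dot",
):
    """L layers of relation-aware residual propagation.

    Layer update: ``e_i ← e_i + ReLU(Σ_{(r,j)} α_ij^(r) W_r e_j)`` where the
    sum runs over all (relation, neighbor) pairs of concept *i*, keys and
    values are the transformed neighbors ``W_r e_j``, and the softmax is
    taken jointly over all (r, j) pairs so the weights form one distribution
    per concept.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    nbrs = knowledge_base.ontology_neighbors()
    labels_needed = {r for pairs in nbrs.values() for r, _ in pairs}
    missing = labels_needed - set(transforms)
    if missing:
        raise ValueError(f"missing relation transforms: {sorted(missing)}")
    is_tensor = isinstance(table, ad.Tensor) or any(
        isinstance(W, ad.Tensor) for W in transforms.values()
    )
    cur = table
    for _ in range(n_layers):
        rows = []
        for i in range(knowledge_base.n_concepts):
            pairs = nbrs[i]
            if not pairs:
                rows.append(cur[i])
                continue
            keys = [transforms[r] @ cur[j] for r, j in pairs]
            keys = ad.stack(keys) if is_tensor else np.stack(keys)
            scores = _similarity(cur[i], keys, similarity, knowledge_base.vocabulary.concept_ids[i])
            alpha = ad.softmax(scores, axis=-1)
            rows.append(cur[i] + ad.relu(alpha @ keys))
        cur = ad.stack(rows) if is_tensor else np.stack(rows)
    return cur


def embedding_struct_loss(refined, context):
    """Structural reconstruction penalty ``Σ_i ‖e_i^(L) − ẽ_i‖²``."""
    if ad.asdata(refined).shape != ad.asdata(context).shape:
        raise ValueError(
            f"shape mismatch: refined {ad.asdata(refined).shape} vs context {ad.asdata(context).shape}"
        )
    diff = refined - context
    return (diff * diff).sum()


def write_embeddings_tsv(path, table: np.ndarray, concept_ids) -> None:
    with open(path, "w") as fh:
        for cid, row in zip(concept_ids, np.asarray(table)):
            fh.write(cid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_embeddings_tsv(path) -> tuple[list[str], np.ndarray]:
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return ids, np.asarray(rows)
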