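"""Concept vocabulary, medical knowledge graph, and derived constraint matrices.

The knowledge base holds the fixed concept vocabulary ``E`` (each concept one
of ``c`` semantic types, by default diagnosis / medication / lab / procedure)
together with three binary constraint structures used downstream:

* an **ancestry matrix** — the strict transitive closure of the is-a
  hierarchy, entry ``(i, j) = 1`` iff concept *i* is a strict ancestor of *j*;
* a **relation matrix** — symmetric semantically-valid co-occurrence
  relations, consumed by the knowledge-guided masks;
* a **causal matrix** — curated causal precedence, ``(i, j) = 1`` iff event
  *i* causally precedes event *j*; acyclic by contract.

It also provides the spectral objects (graph Laplacian, Laplacian eigenmaps)
used to initialize the concept-to-latent projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

SEMANTIC_TYPES = ("diagnosis", "medication", "lab", "procedure")


@dataclass(frozen=True)
class ConceptVocabulary:
    """Ordered concept vocabulary with one semantic type per concept.

    Concept ids are unique strings; their position defines the canonical
    0-based index used by every matrix in the package.  ``value_bearing``
    marks concepts (labs) that carry an attached numeric value.
    """

    concept_ids: tuple[str, ...]
    semantic_types: tuple[str, ...]
    value_bearing: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(set(self.concept_ids)) != len(self.concept_ids):
            dupes = [c for c in self.concept_ids if self.concept_ids.count(c) > 1]
            raise ValueError(f"duplicate concept ids: {sorted(set(dupes))}")
        if not (len(self.concept_ids) == len(self.semantic_types) == len(self.value_bearing)):
            raise ValueError("concept_ids, semantic_types, value_bearing must have equal length")

    def __len__(self) -> int:
        return len(self.concept_ids)

    @property
    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.concept_ids)}

    @property
    def type_categories(self) -> tuple[str, ...]:
        """Distinct semantic types, in canonical order where applicable."""
        seen = [t for t in SEMANTIC_TYPES if t in self.semantic_types]
        extra = sorted(set(self.semantic_types) - set(SEMANTIC_TYPES))
        return tuple(seen + extra)

    def type_matrix(self) -> np.ndarray:
        """Binary |E|×c one-hot matrix of concept types (one 1 per row)."""
        cats = self.type_categories
        col = {t: k for k, t in enumerate(cats)}
        T = np.zeros((len(self), len(cats)), dtype=np.int8)
        for i, t in enumerate(self.semantic_types):
            T[i, col[t]] = 1
        return T


@dataclass(frozen=True)
class OntologyGraph:
    """Typed ontology edge lists over a vocabulary.

    ``hierarchy_edges`` are directed child→parent is-a pairs and must form a
    DAG; ``lateral_edges`` are (src, dst, relation_label) triples for every
    non-hierarchical relation.
    """

    hierarchy_edges: tuple[tuple[str, str], ...]
    lateral_edges: tuple[tuple[str, str, str], ...] = ()

    @property
    def relation_types(self) -> tuple[str, ...]:
        labels = sorted({r for _, _, r in self.lateral_edges})
        return ("is_a",) + tuple(labels) if self.hierarchy_edges else tuple(labels)

    def validate(self, vocabulary: ConceptVocabulary) -> None:
        known = set(vocabulary.concept_ids)
        for a, b in self.hierarchy_edges:
            if a not in known or b not in known:
                raise ValueError(f"hierarchy edge ({a}, {b}) references unknown concept")
        for a, b, _ in self.lateral_edges:
            if a not in known or b not in known:
                raise ValueError(f"lateral edge ({a}, {b}) references unknown concept")
        g = nx.DiGraph(self.hierarchy_edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"hierarchy contains a cycle: {cycle}")


def transitive_closure(
    hierarchy_edges: list[tuple[str, str]] | tuple[tuple[str, str], ...],
    vocabulary: ConceptVocabulary,
) -> np.ndarray:
    """Strict ancestry matrix from child→parent is-a edges.

    Returns a binary |E|×|E| matrix with ``(i, j) = 1`` iff concept *i* is a
    strict ancestor of concept *j* under the transitive closure of the
    hierarchy.  The diagonal is zero: reflexive ancestry would only add
    vacuous self-comparisons to the hierarchy hinge penalty.

    Raises ``ValueError`` on unknown concepts or a cyclic hierarchy (the
    offending cycle is listed).
    """
    index = vocabulary.index
    n = len(vocabulary)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for child, parent in hierarchy_edges:
        if child not in index or parent not in index:
            raise ValueError(f"edge ({child}, {parent}) references a concept outside the vocabulary")
        # store parent -> child so ancestry = reachability
        g.add_edge(index[parent], index[child])
    if not nx.is_directed_acyclic_graph(g):
        cycle = [(vocabulary.concept_ids[a], vocabulary.concept_ids[b]) for a, b, *_ in nx.find_cycle(g)]
        raise ValueError(f"hierarchy contains a cycle: {cycle}")
    T = np.zeros((n, n), dtype=np.int8)
    for anc in range(n):
        for desc in nx.descendants(g, anc):
            T[anc, desc] = 1
    return T


def graph_laplacian(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalized graph Laplacian ``L = D − A`` of a symmetric adjacency.

    ``A`` must be symmetric and nonnegative with zero diagonal; the result is
    symmetric positive semidefinite with exactly zero row sums.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    D = np.diag(A.sum(axis=1))
    return D - A


def laplacian_eigenmap(
    adjacency: np.ndarray,
    d: int,
    *,
    skip_trivial: bool = False,
) -> np.ndarray:
    """Spectral embedding minimizing ``Tr(EᵀLE)`` under ``EᵀE = I``.

    Returns the |E|×d matrix whose columns are the eigenvectors of the graph
    Laplacian with the ``d`` smallest eigenvalues — the exact minimizer of the
    trace objective over orthonormal frames (Ky Fan theorem).  By default the
    trivial near-constant eigenvector(s) are retained, which is the literal
    optimum; ``skip_trivial=True`` drops eigenvectors with eigenvalue below
    1e-10, the classical eigenmap convention.

    Ties among equal eigenvalues are broken by the ascending eigenvalue order
    of the symmetric eigensolver, which is deterministic.
    """
    L = graph_laplacian(adjacency)
    n = L.shape[0]
    if d > n:
        raise ValueError(f"target dimension d={d} exceeds number of concepts {n}")
    w, v = scipy.linalg.eigh(L)
    if skip_trivial:
        keep = np.flatnonzero(w > 1e-10)
        if len(keep) < d:
            keep = np.arange(n)[np.argsort(w)][-d:] if len(keep) < d else keep
        v = v[:, keep]
    if v.shape[1] < d:
        raise ValueError(f"not enough non-trivial eigenvectors for d={d}")
    return v[:, :d]


class LaplacianEigenmap(BaseEstimator):
    """Estimator wrapper over :func:`laplacian_eigenmap`.

    Parameters
    ----------
    n_components : target embedding dimension.
    skip_trivial : drop near-zero-eigenvalue (constant) eigenvectors.

    Attributes
    ----------
    embedding_ : (|E|, n_components) orthonormal-column embedding matrix.
    objective_ : achieved value of Tr(EᵀLE).
    """

    def __init__(self, n_components: int = 2, skip_trivial: bool = False):
        self.n_components = n_components
        self.skip_trivial = skip_trivial

    def fit(self, adjacency: np.ndarray, y=None) -> "LaplacianEigenmap":
        E = laplacian_eigenmap(adjacency, self.n_components, skip_trivial=self.skip_trivial)
        L = graph_laplacian(adjacency)
        self.embedding_ = E
        self.objective_ = float(np.trace(E.T @ L @ E))
        return self

    def fit_transform(self, adjacency: np.ndarray, y=None) -> np.ndarray:
        return self.fit(adjacency).embedding_


def _validate_binary_square(M: np.ndarray, n: int, name: str) -> np.ndarray:
    M = np.asarray(M)
    if M.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {M.shape}")
    if not np.isin(M, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return M.astype(np.int8)


@dataclass
class KnowledgeBase:
    """Vocabulary plus all derived constraint matrices.

    ``relation`` is symmetrized on construction (an edge in either direction
    sets both entries) and its diagonal is forced to zero so an event can
    never support itself through the masking rule.  ``causal`` must be an
    acyclic directed relation with zero diagonal.
    """

    vocabulary: ConceptVocabulary
    ontology: OntologyGraph
    relation: np.ndarray
    causal: np.ndarray
    ancestry: np.ndarray = field(init=False)
    type_matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.vocabulary)
        self.ontology.validate(self.vocabulary)
        self.ancestry = transitive_closure(self.ontology.hierarchy_edges, self.vocabulary)
        self.type_matrix = self.vocabulary.type_matrix()
        R = _validate_binary_square(self.relation, n, "relation matrix")
        R = ((R + R.T) > 0).astype(np.int8)
        np.fill_diagonal(R, 0)
        self.relation = R
        C = _validate_binary_square(self.causal, n, "causal matrix")
        if np.any(np.diag(C)):
            raise ValueError("causal matrix must have zero diagonal")
        gc = nx.from_numpy_array(C, create_using=nx.DiGraph)
        if not nx.is_directed_acyclic_graph(gc):
            raise ValueError(f"causal matrix contains a cycle: {nx.find_cycle(gc)}")
        self.causal = C

    @property
    def n_concepts(self) -> int:
        return len(self.vocabulary)

    def hierarchy_adjacency(self) -> np.ndarray:
        """Symmetric 0/1 adjacency of the undirected is-a hierarchy."""
        n = self.n_concepts
        idx = self.vocabulary.index
        A = np.zeros((n, n))
        for child, parent in self.ontology.hierarchy_edges:
            A[idx[child], idx[parent]] = 1.0
            A[idx[parent], idx[child]] = 1.0
        return A

    def ontology_neighbors(self) -> dict[int, list[tuple[str, int]]]:
        """Per-concept list of (relation label, neighbor index) pairs.

        Hierarchy edges contribute under the label ``is_a`` in both
        directions; lateral edges under their own label, directed.
        """
        idx = self.vocabulary.index
        nbrs: dict[int, list[tuple[str, int]]] = {i: [] for i in range(self.n_concepts)}
        for child, parent in self.ontology.hierarchy_edges:
            nbrs[idx[child]].append(("is_a", idx[parent]))
            nbrs[idx[parent]].append(("is_a", idx[child]))
        for a, b, r in self.ontology.lateral_edges:
            nbrs[idx[a]].append((r, idx[b]))
        return nbrs
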