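import numpy as np
import pytest

from clintraj.knowledge import ConceptVocabulary, KnowledgeBase, OntologyGraph


@pytest.fixture
def abc_vocab():
    """Three concepts a, b, c — a diagnosis chain with one lab."""
    return ConceptVocabulary(
        concept_ids=("a", "b", "c"),
        semantic_types=("diagnosis", "diagnosis", "lab"),
        value_bearing=(False, False, True),
    )


@pytest.fixture
def small_kb():
    """Five concepts: hierarchy a←b←c (c child of b child of a), d, e lateral."""
    vocab = ConceptVocabulary(
        concept_ids=("a", "b", "c", "d", "e"),
        semantic_types=("diagnosis", "diagnosis", "diagnosis", "medication", "lab"),
        value_bearing=(False, False, False, False, True),
    )
    ontology = OntologyGraph(
        hierarchy_edges=(("b", "a"), ("c", "b")),
        lateral_edges=(("d", "c", "treats"),),
    )
    R = np.zeros((5, 5), dtype=np.int8)
    R[2, 3] = 1  # c -- d (symmetrized on load)
    R[1, 2] = R[2, 1] = 1
    C = np.zeros((5, 5), dtype=np.int8)
    C[2, 3] = 1  # c causally precedes d
    return KnowledgeBase(vocabulary=vocab, ontology=ontology, relation=R, causal=C)


def random_dag_edges(rng, n):
    """Random DAG as child→parent edges over concepts c0..c{n-1}.

    Parent indices are always lower than child indices, so acyclicity holds
    by construction.
    """
    edges = []
    for child in range(1, n):
        for parent in range(child):
            if rng.random() < 0.25:
                edges.append((f"c{child}", f"c{parent}"))
    return edges


def make_vocab(n, rng=None):
    types = ("diagnosis", "medication", "lab", "procedure")
    return ConceptVocabulary(
        concept_ids=tuple(f"c{i}" for i in range(n)),
        semantic_types=tuple(types[i % 4] for i in range(n)),
        value_bearing=tuple((i % 4) == 2 for i in range(n)),
    )
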