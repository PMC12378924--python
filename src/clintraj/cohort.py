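"""Patient-trajectory data model.

A trajectory is an ordered sequence of visits; each visit is a multi-hot
*clinical state* over the concept vocabulary, with numeric values attached to
value-bearing concepts (labs).  From a trajectory we derive a temporal event
graph (one node per active event per visit) and a sparse binary transition
tensor recording which event pairs span consecutive visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from clintraj.knowledge import ConceptVocabulary, KnowledgeBase


@dataclass(frozen=True)
class PatientContext:
    """Static context: age (years), sex, binary comorbidity flags."""

    age: float = 0.0
    sex: str = "unknown"
    comorbidity_flags: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be nonnegative, got {self.age}")


@dataclass(frozen=True)
class ClinicalState:
    """Multi-hot indicator over the vocabulary plus sparse lab values.

    ``values`` maps concept index → raw value and may only contain indices
    that are active and value-bearing.  ``values_z`` holds the z-scored
    values used downstream; it mirrors the keys of ``values``.
    """

    indicator: np.ndarray
    values: dict[int, float] = field(default_factory=dict)
    values_z: dict[int, float] = field(default_factory=dict)

    def active(self) -> np.ndarray:
        return np.flatnonzero(self.indicator)

    def __len__(self) -> int:
        return int(self.indicator.sum())


def encode_state(
    events: list[str | tuple[str, float]],
    vocabulary: ConceptVocabulary,
) -> ClinicalState:
    """Build a clinical state from a list of event ids, optionally valued.

    Each element is either a concept id or a ``(concept_id, value)`` pair.
    Duplicate events collapse to a single indicator entry (set semantics).
    Unknown ids and values on non-value-bearing concepts are rejected.
    """
    indicator = np.zeros(len(vocabulary), dtype=np.int8)
    values: dict[int, float] = {}
    index = vocabulary.index
    for ev in events:
        if isinstance(ev, tuple):
            cid, val = ev
        else:
            cid, val = ev, None
        if cid not in index:
            raise ValueError(f"unknown event id: {cid!r}")
        i = index[cid]
        indicator[i] = 1
        if val is not None:
            if not vocabulary.value_bearing[i]:
                raise ValueError(f"value supplied for non-value-bearing concept {cid!r}")
            values[i] = float(val)
    return ClinicalState(indicator=indicator, values=values, values_z=dict(values))


def decode_state(state: ClinicalState, vocabulary: ConceptVocabulary) -> list[str | tuple[str, float]]:
    """Inverse of :func:`encode_state` (event set and raw values)."""
    out: list[str | tuple[str, float]] = []
    for i in state.active():
        if i in state.values:
            out.append((vocabulary.concept_ids[i], state.values[i]))
        else:
            out.append(vocabulary.concept_ids[i])
    return out


@dataclass
class PatientTrajectory:
    """Ordered visits of one patient: strictly increasing timestamps, one
    clinical state per timestamp, plus static context."""

    patient_id: str
    timestamps: tuple[float, ...]
    states: list[ClinicalState]
    context: PatientContext = field(default_factory=PatientContext)

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.states) or len(self.states) < 1:
            raise ValueError(
                f"patient {self.patient_id}: need equal, nonzero numbers of "
                f"timestamps ({len(self.timestamps)}) and states ({len(self.states)})"
            )
        ts = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(ts) <= 0):
            raise ValueError(f"patient {self.patient_id}: timestamps must be strictly increasing")

    @property
    def n_visits(self) -> int:
        return len(self.states)


@dataclass
class TemporalEventGraph:
    """Patient-specific temporal event graph.

    Nodes are ``(visit_index, concept_index)`` pairs, one per active event
    per visit.  Edges carry a label: ``intra`` (clique among co-occurring
    events within a visit), ``inter`` (complete bipartite between consecutive
    visits, directed forward in time), or an ontology relation label where
    the knowledge base relates two co-present concepts.
    """

    nodes: list[tuple[int, int]]
    edges: list[tuple[tuple[int, int], tuple[int, int], str]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges_by_label(self, label: str) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        return [(u, v) for u, v, lab in self.edges if lab == label]


def build_event_graph(
    trajectory: PatientTrajectory,
    knowledge_base: KnowledgeBase | None = None,
) -> TemporalEventGraph:
    """Construct the temporal event graph of a trajectory.

    Edge rules: intra-visit clique among co-occurring events; inter-visit
    complete bipartite between consecutive visits; and, when a knowledge base
    is given, an ``ontology`` edge wherever its relation matrix relates two
    co-present (same-visit) concepts.
    """
    nodes: list[tuple[int, int]] = []
    edges: list[tuple[tuple[int, int], tuple[int, int], str]] = []
    active = [sorted(st.active().tolist()) for st in trajectory.states]
    for t, evs in enumerate(active):
        nodes.extend((t, e) for e in evs)
    R = knowledge_base.relation if knowledge_base is not None else None
    for t, evs in enumerate(active):
        for ai in range(len(evs)):
            for bi in range(ai + 1, len(evs)):
                a, b = evs[ai], evs[bi]
                edges.append(((t, a), (t, b), "intra"))
                if R is not None and R[a, b]:
                    edges.append(((t, a), (t, b), "ontology"))
        if t + 1 < len(active):
            for a in evs:
                for b in active[t + 1]:
                    edges.append(((t, a), (t + 1, b), "inter"))
    return TemporalEventGraph(nodes=nodes, edges=edges)


@dataclass
class TransitionTensor:
    """Sparse binary |T|×|E|×|E| tensor of cross-visit event transitions."""

    n_visits: int
    n_concepts: int
    entries: set[tuple[int, int, int]]

    @property
    def nnz(self) -> int:
        return len(self.entries)

    def __getitem__(self, key: tuple[int, int, int]) -> int:
        return 1 if key in self.entries else 0

    def slice(self, t: int) -> np.ndarray:
        A = np.zeros((self.n_concepts, self.n_concepts), dtype=np.int8)
        for tt, i, j in self.entries:
            if tt == t:
                A[i, j] = 1
        return A


def transition_tensor(
    trajectory: PatientTrajectory,
    n_concepts: int,
    *,
    within_time: bool = False,
) -> TransitionTensor:
    """Event transition tensor: ``A[t, i, j] = 1`` iff event *i* is active at
    visit *t* and event *j* at visit *t+1*.

    The slice at the final visit is all zero.  ``within_time=True`` instead
    records same-visit pairs (the literal within-timestamp reading), which is
    available but not the default temporal semantics.
    """
    entries: set[tuple[int, int, int]] = set()
    active = [st.active().tolist() for st in trajectory.states]
    if within_time:
        for t, evs in enumerate(active[:-1] if len(active) > 1 else []):
            for i in evs:
                for j in evs:
                    if i != j:
                        entries.add((t, i, j))
    else:
        for t in range(len(active) - 1):
            for i in active[t]:
                for j in active[t + 1]:
                    entries.add((t, i, j))
    return TransitionTensor(n_visits=len(active), n_concepts=n_concepts, entries=entries)


def zscore_lab_values(cohort: list[PatientTrajectory], n_concepts: int) -> None:
    """Z-score lab values per concept across a cohort, in place.

    Raw values in ``state.values`` are preserved; the standardized value is
    written to ``state.values_z``.  Concepts with fewer than two observations
    or zero variance get z = 0.
    """
    per_concept: dict[int, list[float]] = {}
    for p in cohort:
        for st in p.states:
            for i, v in st.values.items():
                per_concept.setdefault(i, []).append(v)
    stats = {}
    for i, vals in per_concept.items():
        arr = np.asarray(vals)
        sd = arr.std()
        stats[i] = (arr.mean(), sd if sd > 1e-12 else None)
    for p in cohort:
        for st in p.states:
            for i, v in st.values.items():
                mu, sd = stats[i]
                st.values_z[i] = float((v - mu) / sd) if sd else 0.0
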