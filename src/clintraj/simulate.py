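"""Synthetic knowledge bases and patient cohorts with planted anomalies.

The generator emulates the inputs the method consumes: a layered is-a
ontology over a typed concept vocabulary, a symmetric relation matrix
(sibling/ancestor adjacency plus random lateral edges), a causal-precedence
DAG, and patient trajectories driven by a latent first-order Markov chain
over health states.  Each health state emits events from one *cluster* of
pairwise-related sibling concepts, so a clean cohort passes the hard
co-occurrence mask with zero rejections by construction, and causes are
always emitted at an earlier visit than their effects.

Three anomaly classes are planted with exact labels:

* ``cooccurrence`` — inject an event with no relation partner in its visit;
* ``causal``       — invert the visit order of one cause/effect pair;
* ``jump``         — replace one visit's events with a cluster at maximal
  ontology distance.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from clintraj.cohort import ClinicalState, PatientContext, PatientTrajectory
from clintraj.knowledge import ConceptVocabulary, KnowledgeBase, OntologyGraph

ANOMALY_TYPES = ("cooccurrence", "causal", "jump")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic data.

    Defaults give a cohort of 200 patients with 8–12 visits of 2–4 events
    each over a 48-concept, depth-3 ontology, with 10% of patients receiving
    exactly one planted anomaly drawn evenly from the three classes.
    """

    n_concepts: int = 48
    n_types: int = 4
    depth: int = 3
    lateral_density: float = 0.03
    n_patients: int = 200
    visits_min: int = 8
    visits_max: int = 12
    events_min: int = 2
    events_max: int = 4
    anomaly_rate: float = 0.10
    anomaly_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_health_states: int = 5
    self_transition: float = 0.7
    causal_emission_prob: float = 0.35
    lab_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.anomaly_rate <= 1):
            raise ValueError("anomaly_rate must be in [0, 1]")
        if not (0 <= self.lateral_density <= 1):
            raise ValueError("lateral_density must be in [0, 1]")
        for name in ("n_concepts", "n_types", "depth", "n_patients", "visits_min", "events_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth > self.n_concepts:
            raise ValueError("hierarchy depth cannot exceed the number of concepts")


@dataclass
class GroundTruth:
    """Exact planted-anomaly labels: per-patient binary label plus
    (patient_id, type, visit index) records."""

    labels: dict[str, int]
    records: list[tuple[str, str, int]] = field(default_factory=list)

    def label_vector(self, cohort: list[PatientTrajectory]) -> np.ndarray:
        return np.asarray([self.labels[p.patient_id] for p in cohort])


def _layer_sizes(config: GeneratorConfig) -> list[int]:
    n, depth = config.n_concepts, config.depth
    if depth == 1:
        return [n]
    roots = max(2, n // 24)
    sizes = [roots]
    remaining = n - roots
    for level in range(1, depth - 1):
        s = max(4, n // 6)
        sizes.append(min(s, remaining - (depth - 1 - level)))
        remaining -= sizes[-1]
    sizes.append(remaining)
    if remaining < 1:
        raise ValueError("infeasible config: depth too large for n_concepts")
    return sizes


def generate_knowledge_base(config: GeneratorConfig) -> KnowledgeBase:
    """Layered-DAG ontology, relation matrix and causal DAG, seeded.

    Each non-root concept gets one primary parent (the first listed
    hierarchy edge, which defines its sibling cluster) and possibly a second
    parent in the layer above.  The relation matrix contains all primary-
    sibling pairs and child–parent pairs, plus random lateral edges at
    ``lateral_density``.  Causal edges are reserved sibling pairs of the
    leaf layer, oriented by vocabulary index, hence acyclic.
    """
    rng = np.random.default_rng([config.seed, 11])
    sizes = _layer_sizes(config)
    n = config.n_concepts
    ids = [f"c{i:03d}" for i in range(n)]
    types = [("diagnosis", "medication", "lab", "procedure")[i % config.n_types] for i in range(n)]
    rng.shuffle(types)
    value_bearing = [t == "lab" for t in types]
    vocab = ConceptVocabulary(tuple(ids), tuple(types), tuple(value_bearing))

    # layer index ranges
    bounds = np.cumsum([0] + sizes)
    layers = [list(range(bounds[k], bounds[k + 1])) for k in range(len(sizes))]
    hierarchy: list[tuple[str, str]] = []
    primary_parent = {}
    for lvl in range(1, len(layers)):
        for c in layers[lvl]:
            parents = rng.choice(layers[lvl - 1], size=min(len(layers[lvl - 1]), int(1 + rng.integers(0, 2))), replace=False)
            primary_parent[c] = int(parents[0])
            for p in parents:
                hierarchy.append((ids[c], ids[int(p)]))

    R = np.zeros((n, n), dtype=np.int8)
    for c, p in primary_parent.items():
        R[c, p] = R[p, c] = 1
    clusters: dict[int, list[int]] = {}
    for c in layers[-1]:
        clusters.setdefault(primary_parent[c], []).append(c)
    for members in clusters.values():
        for a in members:
            for b in members:
                if a != b:
                    R[a, b] = 1

    lateral: list[tuple[str, str, str]] = []
    n_lateral = int(config.lateral_density * n * (n - 1) / 2)
    for _ in range(n_lateral):
        a, b = rng.choice(n, size=2, replace=False)
        lateral.append((ids[int(a)], ids[int(b)], "associated_with"))
        R[int(a), int(b)] = R[int(b), int(a)] = 1

    # causal DAG: one reserved sibling pair per leaf cluster, low->high index
    C = np.zeros((n, n), dtype=np.int8)
    for members in sorted(clusters.values()):
        if len(members) >= 4:  # keep >=2 free members for ordinary emission
            pair = sorted(rng.choice(members, size=2, replace=False).tolist())
            C[pair[0], pair[1]] = 1

    ontology = OntologyGraph(tuple(hierarchy), tuple(lateral))
    return KnowledgeBase(vocabulary=vocab, ontology=ontology, relation=R, causal=C)


def leaf_clusters(kb: KnowledgeBase) -> list[list[int]]:
    """Sibling clusters of leaf concepts, keyed by primary parent.

    The primary parent of a concept is the parent of its first listed
    hierarchy edge; leaves are concepts that are not themselves parents.
    """
    idx = kb.vocabulary.index
    primary: dict[int, int] = {}
    parents_seen = set()
    for child, parent in kb.ontology.hierarchy_edges:
        c, p = idx[child], idx[parent]
        if c not in primary:
            primary[c] = p
        parents_seen.add(p)
    groups: dict[int, list[int]] = {}
    for c, p in sorted(primary.items()):
        if c not in parents_seen:
            groups.setdefault(p, []).append(c)
    return [groups[k] for k in sorted(groups)]


def _cluster_pools(kb: KnowledgeBase):
    """Per-cluster free emission pool and reserved causal pair."""
    causal_pairs = {tuple(p) for p in zip(*np.nonzero(kb.causal))}
    reserved = {c for pair in causal_pairs for c in pair}
    pools, pairs = [], []
    for members in leaf_clusters(kb):
        free = [c for c in members if c not in reserved]
        pair = next((pr for pr in causal_pairs if pr[0] in members and pr[1] in members), None)
        pools.append(free)
        pairs.append(pair)
    return pools, pairs


def generate_cohort(kb: KnowledgeBase, config: GeneratorConfig) -> list[PatientTrajectory]:
    """Clean cohort from a latent Markov chain over health states.

    Each health state maps to one leaf cluster; every visit emits 2–4
    distinct free members of the current cluster (pairwise related, so the
    hard mask removes nothing).  With probability ``causal_emission_prob``
    per eligible transition, the cluster's reserved causal pair is emitted:
    the cause at visit t and the cause plus its effect at visit t+1, so the
    cause's first occurrence always precedes the effect's.  Lab events carry
    Gaussian values with a state-dependent mean and unit variance.
    """
    rng = np.random.default_rng([config.seed, 22])
    pools, pairs = _cluster_pools(kb)
    usable = [k for k, pool in enumerate(pools) if len(pool) >= config.events_min]
    if len(usable) < config.n_health_states:
        raise ValueError("not enough usable clusters for the requested number of health states")
    state_cluster = _related_state_clusters(kb, pools, usable, config.n_health_states, rng)
    K = config.n_health_states
    trans = np.full((K, K), (1 - config.self_transition) / (K - 1))
    np.fill_diagonal(trans, config.self_transition)
    lab_means = rng.normal(0.0, 2.0, size=(K, kb.n_concepts))

    cohort: list[PatientTrajectory] = []
    vb = kb.vocabulary.value_bearing
    for pi in range(config.n_patients):
        T = int(rng.integers(config.visits_min, config.visits_max + 1))
        h = int(rng.integers(K))
        hidden = [h]
        for _ in range(T - 1):
            h = int(rng.choice(K, p=trans[h]))
            hidden.append(h)
        visit_events: list[set[int]] = []
        visit_values: list[dict[int, float]] = []
        for t in range(T):
            pool = pools[state_cluster[hidden[t]]]
            k = int(rng.integers(config.events_min, min(config.events_max, len(pool)) + 1))
            evs = set(int(c) for c in rng.choice(pool, size=k, replace=False))
            visit_events.append(evs)
            visit_values.append({})
        # causal pair emission: cause at t, cause+effect at t+1
        emitted_pairs: set[tuple[int, int]] = set()
        for t in range(1, T - 1):  # start at 1 so every pair has a preceding visit
            pair = pairs[state_cluster[hidden[t]]]
            if pair is None or pair in emitted_pairs:
                continue
            if any(pair[0] in ev or pair[1] in ev for ev in visit_events):
                continue
            if rng.random() < config.causal_emission_prob:
                visit_events[t].add(pair[0])
                visit_events[t + 1].add(pair[0])
                visit_events[t + 1].add(pair[1])
                emitted_pairs.add(pair)
        for t in range(T):
            for c in visit_events[t]:
                if vb[c]:
                    visit_values[t][c] = float(rng.normal(lab_means[hidden[t], c], 1.0))
        timestamps = tuple(np.cumsum(rng.integers(3, 31, size=T)).astype(float))
        states = []
        for t in range(T):
            ind = np.zeros(kb.n_concepts, dtype=np.int8)
            ind[list(visit_events[t])] = 1
            states.append(ClinicalState(indicator=ind, values=visit_values[t], values_z=dict(visit_values[t])))
        ctx = PatientContext(
            age=float(rng.integers(20, 91)),
            sex=("F", "M")[int(rng.integers(2))],
            comorbidity_flags=tuple(int(b) for b in rng.integers(0, 2, size=3)),
        )
        cohort.append(PatientTrajectory(patient_id=f"p{pi:04d}", timestamps=timestamps, states=states, context=ctx))
    return cohort


def _related_state_clusters(kb, pools, usable, k_states, rng) -> list[int]:
    """Choose health-state clusters that are mutually close in the ontology.

    Disease processes evolve among related conditions, so the hidden states
    emit from neighboring sibling clusters; the ``jump`` anomaly then moves
    to an ontologically distant cluster, which is what makes it an anomaly
    rather than ordinary progression.  Greedy selection: for every seed
    cluster take the k nearest usable clusters; keep the set with the
    smallest total pairwise distance.  At least two selected clusters carry
    a reserved causal pair when possible.
    """
    dist = _hierarchy_distances(kb)
    _, pairs = _cluster_pools(kb)
    far = 10**6

    def cdist(a, b):
        return min((dist[x].get(y, far) for x in pools[a] for y in pools[b]), default=far)

    D = {(a, b): cdist(a, b) for a in usable for b in usable}
    best, best_cost = None, None
    for seed_c in usable:
        ranked = sorted(usable, key=lambda c: (D[(seed_c, c)], c))
        cand = ranked[:k_states]
        if sum(1 for c in cand if pairs[c] is not None) < min(2, sum(1 for c in usable if pairs[c])):
            continue
        cost = sum(D[(a, b)] for a in cand for b in cand)
        if best_cost is None or cost < best_cost:
            best, best_cost = cand, cost
    if best is None:
        best = sorted(usable)[:k_states]
    return list(best)


def _hierarchy_distances(kb: KnowledgeBase) -> dict[tuple[int, int], int]:
    g = nx.Graph()
    g.add_nodes_from(range(kb.n_concepts))
    idx = kb.vocabulary.index
    for child, parent in kb.ontology.hierarchy_edges:
        g.add_edge(idx[child], idx[parent])
    return dict(nx.all_pairs_shortest_path_length(g))


def plant_anomalies(
    cohort: list[PatientTrajectory],
    kb: KnowledgeBase,
    config: GeneratorConfig,
) -> tuple[list[PatientTrajectory], GroundTruth]:
    """Plant exactly one anomaly in ``round(rate · n)`` patients.

    Anomaly types cycle through the configured mix; planting never mutates
    the input cohort.  A patient with no valid injection site for its
    assigned type is resampled; after 100 failed attempts an error is raised.
    """
    rng = np.random.default_rng([config.seed, 33])
    cohort = copy.deepcopy(cohort)
    n_anom = int(round(config.anomaly_rate * len(cohort)))
    labels = {p.patient_id: 0 for p in cohort}
    records: list[tuple[str, str, int]] = []
    if n_anom == 0:
        return cohort, GroundTruth(labels=labels, records=records)
    if n_anom < 1:
        raise ValueError("anomaly_rate * n_patients must be >= 1")
    mix = np.asarray(config.anomaly_mix, dtype=float)
    mix = mix / mix.sum()
    counts = np.floor(mix * n_anom).astype(int)
    while counts.sum() < n_anom:
        counts[int(np.argmin(counts - mix * n_anom))] += 1
    type_list = [t for t, c in zip(ANOMALY_TYPES, counts) for _ in range(c)]
    order = rng.permutation(len(cohort))
    dist = _hierarchy_distances(kb)
    pools, _ = _cluster_pools(kb)
    chosen: set[int] = set()
    pos = 0
    for atype in type_list:
        planted = False
        for _ in range(100):
            while pos < len(order) and int(order[pos % len(order)]) in chosen:
                pos += 1
            pidx = int(order[pos % len(order)])
            pos += 1
            p = cohort[pidx]
            t = _plant_one(p, atype, kb, rng, dist, pools)
            if t is not None:
                chosen.add(pidx)
                labels[p.patient_id] = 1
                records.append((p.patient_id, atype, t))
                planted = True
                break
        if not planted:
            raise RuntimeError(f"no valid injection site found for anomaly type {atype!r}")
    return cohort, GroundTruth(labels=labels, records=records)


def _replace_state(p: PatientTrajectory, t: int, events: set[int], values: dict[int, float], kb: KnowledgeBase) -> None:
    ind = np.zeros(kb.n_concepts, dtype=np.int8)
    ind[list(events)] = 1
    p.states[t] = ClinicalState(indicator=ind, values=values, values_z=dict(values))


def _plant_one(p, atype, kb, rng, dist, pools):
    R = kb.relation
    T = p.n_visits
    if atype == "cooccurrence":
        for t in rng.permutation(T):
            active = p.states[t].active()
            cands = [
                c
                for c in range(kb.n_concepts)
                if p.states[t].indicator[c] == 0 and R[c, active].sum() == 0
            ]
            if cands:
                c = int(rng.choice(cands))
                evs = set(active.tolist()) | {c}
                _replace_state(p, int(t), evs, dict(p.states[t].values), kb)
                return int(t)
        return None
    if atype == "causal":
        first = {}
        for t in range(T):
            for c in p.states[t].active():
                first.setdefault(int(c), t)
        sites = []
        for i, j in zip(*np.nonzero(kb.causal)):
            i, j = int(i), int(j)
            if i in first and j in first and first[i] >= 1 and first[j] > first[i]:
                sites.append((i, j))
        if not sites:
            return None
        i, j = sites[int(rng.integers(len(sites)))]
        a = first[i]
        evs = set(p.states[a].active().tolist())
        evs.discard(i)
        evs.add(j)
        vals = {k: v for k, v in p.states[a].values.items() if k != i}
        _replace_state(p, a, evs, vals, kb)
        return a
    if atype == "jump":
        if T < 3:
            return None
        t = int(rng.integers(1, T - 1))
        active = set(p.states[t].active().tolist())
        best_pool, best_d = None, -1
        for pool in pools:
            if len(pool) < 2:
                continue
            if active & set(pool):
                continue
            d = min(dist[a].get(c, 10**6) for a in active for c in pool)
            if d > best_d:
                best_d, best_pool = d, pool
        if best_pool is None:
            return None
        k = min(len(best_pool), max(2, len(active)))
        evs = set(int(c) for c in rng.choice(best_pool, size=k, replace=False))
        vals = {c: float(rng.normal(0.0, 1.0)) for c in evs if kb.vocabulary.value_bearing[c]}
        _replace_state(p, t, evs, vals, kb)
        return t
    raise ValueError(f"unknown anomaly type {atype!r}")
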