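"""Synthetic knowledge bases and cohorts with planted ground truth."""

import numpy as np
import pytest

from clintraj.masking import hard_mask
from clintraj.simulate import (
    GeneratorConfig,
    generate_cohort,
    generate_knowledge_base,
    leaf_clusters,
    plant_anomalies,
)


def small_config(**kw):
    defaults = dict(n_patients=30, seed=5)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="module")
def kb_cohort():
    cfg = GeneratorConfig(n_patients=60, seed=9)
    kb = generate_knowledge_base(cfg)
    cohort = generate_cohort(kb, cfg)
    return cfg, kb, cohort


class TestGenerateKnowledgeBase:
    def test_deterministic_under_seed(self):
        cfg = small_config()
        kb1 = generate_knowledge_base(cfg)
        kb2 = generate_knowledge_base(cfg)
        assert kb1.vocabulary.concept_ids == kb2.vocabulary.concept_ids
        np.testing.assert_array_equal(kb1.relation, kb2.relation)
        np.testing.assert_array_equal(kb1.causal, kb2.causal)
        assert kb1.ontology.hierarchy_edges == kb2.ontology.hierarchy_edges

    def test_ancestry_invariants(self):
        kb = generate_knowledge_base(small_config(n_concepts=20, depth=3))
        T = kb.ancestry
        assert np.all(np.diag(T) == 0)
        assert not np.any((T == 1) & (T.T == 1))
        T2 = ((T.astype(int) @ T.astype(int)) > 0).astype(int)
        assert np.all(T[T2 == 1] == 1)

    def test_zero_lateral_density_only_structural_relations(self):
        kb = generate_knowledge_base(small_config(lateral_density=0.0))
        assert len(kb.ontology.lateral_edges) == 0
        # every relation is a sibling or child-parent pair
        idx = kb.vocabulary.index
        parents = {}
        for child, parent in kb.ontology.hierarchy_edges:
            parents.setdefault(idx[child], set()).add(idx[parent])
        for i, j in zip(*np.nonzero(kb.relation)):
            ok = (
                j in parents.get(i, set())
                or i in parents.get(j, set())
                or (parents.get(i) and parents.get(j) and parents[i] & parents[j])
            )
            assert ok, (i, j)

    def test_infeasible_depth_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_concepts=3, depth=10)

    def test_causal_matrix_is_acyclic_dag(self):
        import networkx as nx

        kb = generate_knowledge_base(small_config())
        g = nx.from_numpy_array(kb.causal, create_using=nx.DiGraph)
        assert nx.is_directed_acyclic_graph(g)
        assert kb.causal.sum() >= 1


class TestGenerateCohort:
    def test_clean_cohort_passes_hard_mask(self, kb_cohort):
        _, kb, cohort = kb_cohort
        for p in cohort:
            for st in p.states:
                res = hard_mask(st.indicator, kb.relation)
                assert res.rejection_fraction == 0.0

    def test_deterministic_under_seed(self):
        cfg = small_config()
        kb = generate_knowledge_base(cfg)
        c1 = generate_cohort(kb, cfg)
        c2 = generate_cohort(kb, cfg)
        for p1, p2 in zip(c1, c2):
            assert p1.patient_id == p2.patient_id
            assert p1.timestamps == p2.timestamps
            for s1, s2 in zip(p1.states, p2.states):
                np.testing.assert_array_equal(s1.indicator, s2.indicator)
                assert s1.values == s2.values

    def test_causal_pairs_never_inverted(self, kb_cohort):
        _, kb, cohort = kb_cohort
        pairs = list(zip(*np.nonzero(kb.causal)))
        assert pairs
        for p in cohort:
            first = {}
            for t, st in enumerate(p.states):
                for c in st.active():
                    first.setdefault(int(c), t)
            for i, j in pairs:
                if int(i) in first and int(j) in first:
                    assert first[int(i)] < first[int(j)]

    def test_lab_values_on_value_bearing_only(self, kb_cohort):
        _, kb, cohort = kb_cohort
        for p in cohort:
            for st in p.states:
                for i in st.values:
                    assert kb.vocabulary.value_bearing[i]
                    assert st.indicator[i] == 1

    def test_visit_sizes_within_bounds(self, kb_cohort):
        cfg, kb, cohort = kb_cohort
        for p in cohort:
            assert cfg.visits_min <= p.n_visits <= cfg.visits_max
            for st in p.states:
                assert len(st) >= cfg.events_min


class TestPlantAnomalies:
    def test_rate_zero_leaves_cohort_unchanged(self, kb_cohort):
        cfg, kb, cohort = kb_cohort
        cfg0 = GeneratorConfig(**{**cfg.__dict__, "anomaly_rate": 0.0})
        planted, gt = plant_anomalies(cohort, kb, cfg0)
        assert sum(gt.labels.values()) == 0
        for p0, p1 in zip(cohort, planted):
            for s0, s1 in zip(p0.states, p1.states):
                np.testing.assert_array_equal(s0.indicator, s1.indicator)

    def test_exact_planting_count(self):
        cfg = GeneratorConfig(n_patients=200, anomaly_rate=0.1, seed=3)
        kb = generate_knowledge_base(cfg)
        cohort = generate_cohort(kb, cfg)
        planted, gt = plant_anomalies(cohort, kb, cfg)
        assert sum(gt.labels.values()) == 20
        assert len(gt.records) == 20
        assert gt.label_vector(planted).sum() == 20

    def test_cooccurrence_visits_fail_hard_mask(self, kb_cohort):
        cfg, kb, cohort = kb_cohort
        planted, gt = plant_anomalies(cohort, kb, cfg)
        found = 0
        for pid, atype, t in gt.records:
            if atype != "cooccurrence":
                continue
            p = next(q for q in planted if q.patient_id == pid)
            res = hard_mask(p.states[t].indicator, kb.relation)
            assert res.rejection_fraction > 0.0
            found += 1
        assert found >= 1
        # clean patients keep zero rejection
        for p in planted:
            if gt.labels[p.patient_id] == 0:
                for st in p.states:
                    assert hard_mask(st.indicator, kb.relation).rejection_fraction == 0.0

    def test_input_cohort_not_mutated(self, kb_cohort):
        cfg, kb, cohort = kb_cohort
        before = [st.indicator.copy() for p in cohort for st in p.states]
        plant_anomalies(cohort, kb, cfg)
        after = [st.indicator for p in cohort for st in p.states]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_separation_property_mask_component(self):
        """Mean mask rejection of cooccurrence-planted patients exceeds the
        clean mean in every seeded replicate."""
        for seed in range(10):
            cfg = GeneratorConfig(n_patients=50, seed=seed)
            kb = generate_knowledge_base(cfg)
            planted, gt = plant_anomalies(generate_cohort(kb, cfg), kb, cfg)
            rej = {
                p.patient_id: max(
                    hard_mask(st.indicator, kb.relation).rejection_fraction for st in p.states
                )
                for p in planted
            }
            cooc = [pid for pid, atype, _ in gt.records if atype == "cooccurrence"]
            clean = [pid for pid, lab in gt.labels.items() if lab == 0]
            assert np.mean([rej[c] for c in cooc]) > np.mean([rej[c] for c in clean])


def test_leaf_clusters_are_siblings():
    kb = generate_knowledge_base(GeneratorConfig(seed=2))
    for cluster in leaf_clusters(kb):
        for a in cluster:
            for b in cluster:
                if a != b:
                    assert kb.relation[a, b] == 1
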