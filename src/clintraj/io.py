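"""Readers and writers for the on-disk formats.

Formats: concept table TSV, ontology edge TSV (``is_a`` rows feed the
hierarchy, any other label is a lateral relation), causal edge TSV, matrices
in MatrixMarket coordinate format, cohorts as JSONL (one patient per line),
embeddings and scores as TSV, and a fitted model as a directory of a JSON
config snapshot plus TSV parameter arrays.  All round trips are identities.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from clintraj.cohort import ClinicalState, PatientContext, PatientTrajectory
from clintraj.encoder import EncoderConfig
from clintraj.knowledge import ConceptVocabulary, KnowledgeBase, OntologyGraph
from clintraj.pipeline import ObjectiveWeights, RiskPredictor, TrajectoryAnomalyDetector, RAW_COMPONENTS
from clintraj.refine import RefinementConfig
from clintraj.simulate import GeneratorConfig, GroundTruth


# ---------------------------------------------------------------- knowledge
def write_knowledge_base(kb: KnowledgeBase, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "concepts.tsv", "w") as fh:
        for i, cid in enumerate(kb.vocabulary.concept_ids):
            fh.write(
                f"{cid}\t{cid}\t{kb.vocabulary.semantic_types[i]}\t{int(kb.vocabulary.value_bearing[i])}\n"
            )
    with open(outdir / "ontology.tsv", "w") as fh:
        for child, parent in kb.ontology.hierarchy_edges:
            fh.write(f"{child}\t{parent}\tis_a\n")
        for a, b, r in kb.ontology.lateral_edges:
            fh.write(f"{a}\t{b}\t{r}\n")
    with open(outdir / "causal.tsv", "w") as fh:
        for i, j in zip(*np.nonzero(kb.causal)):
            fh.write(f"{kb.vocabulary.concept_ids[int(i)]}\t{kb.vocabulary.concept_ids[int(j)]}\n")
    scipy.io.mmwrite(str(outdir / "relation.mtx"), scipy.sparse.coo_matrix(kb.relation))


def read_knowledge_base(indir: str | Path) -> KnowledgeBase:
    indir = Path(indir)
    ids, types, vb = [], [], []
    with open(indir / "concepts.tsv") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"concepts.tsv line {ln}: expected 4 fields, got {len(parts)}")
            ids.append(parts[0])
            types.append(parts[2])
            vb.append(bool(int(parts[3])))
    vocab = ConceptVocabulary(tuple(ids), tuple(types), tuple(vb))
    known = set(ids)
    hier, lat = [], []
    with open(indir / "ontology.tsv") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"ontology.tsv line {ln}: expected 3 fields, got {len(parts)}")
            a, b, r = parts
            if a not in known or b not in known:
                raise ValueError(f"ontology.tsv line {ln}: dangling concept id")
            if r == "is_a":
                hier.append((a, b))
            else:
                lat.append((a, b, r))  # unknown labels load as lateral relations
    causal = np.zeros((len(ids), len(ids)), dtype=np.int8)
    idx = vocab.index
    cpath = indir / "causal.tsv"
    if cpath.exists():
        with open(cpath) as fh:
            for ln, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ValueError(f"causal.tsv line {ln}: expected 2 fields")
                if parts[0] not in known or parts[1] not in known:
                    raise ValueError(f"causal.tsv line {ln}: dangling concept id")
                causal[idx[parts[0]], idx[parts[1]]] = 1
    relation = np.asarray(scipy.io.mmread(str(indir / "relation.mtx")).todense()).astype(np.int8)
    return KnowledgeBase(
        vocabulary=vocab,
        ontology=OntologyGraph(tuple(hier), tuple(lat)),
        relation=relation,
        causal=causal,
    )


# ------------------------------------------------------------------- cohort
def write_cohort(cohort: list[PatientTrajectory], path: str | Path, vocabulary: ConceptVocabulary) -> None:
    with open(path, "w") as fh:
        for p in cohort:
            visits = []
            for t, st in zip(p.timestamps, p.states):
                events = []
                for i in sorted(st.active().tolist()):
                    ev = {"concept": vocabulary.concept_ids[i]}
                    if i in st.values:
                        ev["value"] = st.values[i]
                    events.append(ev)
                visits.append({"time": t, "events": events})
            rec = {
                "patient_id": p.patient_id,
                "context": {
                    "age": p.context.age,
                    "sex": p.context.sex,
                    "comorbidities": list(p.context.comorbidity_flags),
                },
                "visits": visits,
            }
            fh.write(json.dumps(rec) + "\n")


def read_cohort(path: str | Path, vocabulary: ConceptVocabulary) -> list[PatientTrajectory]:
    cohort = []
    index = vocabulary.index
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"cohort line {ln}: malformed JSON ({e})") from None
            pid = rec["patient_id"]
            times = [v["time"] for v in rec["visits"]]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"patient {pid}: timestamps not strictly increasing")
            states = []
            for v in rec["visits"]:
                ind = np.zeros(len(vocabulary), dtype=np.int8)
                values = {}
                for ev in v["events"]:
                    cid = ev["concept"]
                    if cid not in index:
                        raise ValueError(f"patient {pid}: unknown concept {cid!r}")
                    i = index[cid]
                    ind[i] = 1
                    if "value" in ev:
                        if not vocabulary.value_bearing[i]:
                            raise ValueError(
                                f"patient {pid}: value on non-value-bearing concept {cid!r}"
                            )
                        values[i] = float(ev["value"])
                states.append(ClinicalState(indicator=ind, values=values, values_z=dict(values)))
            ctx = rec.get("context", {})
            cohort.append(
                PatientTrajectory(
                    patient_id=pid,
                    timestamps=tuple(float(t) for t in times),
                    states=states,
                    context=PatientContext(
                        age=float(ctx.get("age", 0.0)),
                        sex=str(ctx.get("sex", "unknown")),
                        comorbidity_flags=tuple(int(x) for x in ctx.get("comorbidities", [])),
                    ),
                )
            )
    return cohort


# ------------------------------------------------------------- ground truth
def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    recs = {pid: (atype, t) for pid, atype, t in gt.records}
    with open(path, "w") as fh:
        fh.write("patient_id\tlabel\ttype\tt\n")
        for pid, label in gt.labels.items():
            atype, t = recs.get(pid, ("", ""))
            fh.write(f"{pid}\t{label}\t{atype}\t{t}\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    labels, records = {}, []
    with open(path) as fh:
        next(fh)
        for line in fh:
            pid, label, atype, t = line.rstrip("\n").split("\t")
            labels[pid] = int(label)
            if atype:
                records.append((pid, atype, int(t)))
    return GroundTruth(labels=labels, records=records)


def write_scores(path: str | Path, reports) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tscore\t" + "\t".join(RAW_COMPONENTS) + "\n")
        for r in reports:
            comps = "\t".join(f"{r.components[c]:.10g}" for c in RAW_COMPONENTS)
            fh.write(f"{r.patient_id}\t{r.score:.10g}\t{comps}\n")


def write_mask_audit(path: str | Path, cohort, kb: KnowledgeBase) -> None:
    """TSV audit of the hard mask: patient, time, concept, kept, confidence."""
    from clintraj.masking import hard_mask

    with open(path, "w") as fh:
        fh.write("patient\ttime\tconcept\tkept\tconfidence\n")
        for p in cohort:
            for t, st in zip(p.timestamps, p.states):
                res = hard_mask(st.indicator, kb.relation, st.values)
                for i in st.active():
                    fh.write(
                        f"{p.patient_id}\t{t:g}\t{kb.vocabulary.concept_ids[i]}\t"
                        f"{int(res.mask[i])}\t{res.confidence[i]:.6g}\n"
                    )


# -------------------------------------------------------------------- model
def save_model(model: TrajectoryAnomalyDetector, outdir: str | Path, kb: KnowledgeBase) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model._check_fitted()
    snap = model.config_snapshot()
    snap["predictor_b"] = model.predictor_.b
    with open(outdir / "config.json", "w") as fh:
        json.dump(snap, fh, indent=2)
    arrays = {
        "embedding_table": model.embedding_table_,
        "P": model.P_,
        "W_forecast": model.W_forecast_,
        "b_forecast": model.b_forecast_,
        "predictor_w": model.predictor_.w,
        "components": model.components_,
        "prior_q": model.prior_.q,
    }
    for k, v in model._encoder.params.items():
        arrays[f"encoder_{k}"] = v
    for name, arr in arrays.items():
        np.savetxt(outdir / f"{name}.tsv", np.atleast_2d(arr), delimiter="\t")
    write_knowledge_base(kb, outdir / "kb")


def load_model(indir: str | Path) -> tuple[TrajectoryAnomalyDetector, KnowledgeBase]:
    indir = Path(indir)
    if not (indir / "config.json").exists():
        raise ValueError(f"model not fitted: no model found at {indir}")
    with open(indir / "config.json") as fh:
        snap = json.load(fh)
    kb = read_knowledge_base(indir / "kb")
    cfg = EncoderConfig(**snap["encoder"])
    model = TrajectoryAnomalyDetector(
        config=cfg,
        weights=ObjectiveWeights(**snap["objective_weights"]),
        embed_dim=snap["embed_dim"],
        init=snap["init"],
        assignment_sharpness=snap["assignment_sharpness"],
        component_weights=tuple(snap["component_weights"]),
        seed=snap["seed"],
    )

    def arr(name):
        return np.loadtxt(indir / f"{name}.tsv", delimiter="\t", ndmin=2)

    model._cfg = cfg
    model._w = ObjectiveWeights(**snap["objective_weights"])
    model._kb = kb
    model.embedding_table_ = arr("embedding_table")
    model.P_ = arr("P")
    model.W_forecast_ = arr("W_forecast")
    model.b_forecast_ = arr("b_forecast").ravel()
    model.predictor_ = RiskPredictor(w=arr("predictor_w").ravel(), b=float(snap["predictor_b"]))
    model.components_ = arr("components")
    from clintraj.refine import PriorDistribution

    model.prior_ = PriorDistribution(q=arr("prior_q").ravel())
    from clintraj.encoder import TemporalEncoder

    model._encoder = TemporalEncoder(cfg, snap["embed_dim_resolved"])
    model._d_embed = snap["embed_dim_resolved"]
    for k in list(model._encoder.params):
        a = arr(f"encoder_{k}")
        model._encoder.params[k] = a.ravel() if model._encoder.params[k].ndim == 1 else a
    model._ref_sorted = [np.sort(model.components_[:, c]) for c in range(model.components_.shape[1])]
    model.fitted_ = True
    return model, kb


# ------------------------------------------------------------------- config
_SECTIONS = {
    "generator": GeneratorConfig,
    "encoder": EncoderConfig,
    "refinement": RefinementConfig,
    "objective_weights": ObjectiveWeights,
}
_DETECTOR_KEYS = {
    "embed_dim", "init", "assignment_sharpness", "n_epochs", "batch_size",
    "val_fraction", "patience", "ontology_layers", "component_weights",
}


def load_run_config(path: str | Path | None) -> dict:
    """Nested run configuration with schema validation.

    Sections: ``generator``, ``encoder``, ``refinement``,
    ``objective_weights``, ``detector``.  Unknown sections or keys are
    rejected; missing keys fall back to the defaults.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            raw = yaml.safe_load(text) or {}
    cfg: dict = {}
    for section, payload in raw.items():
        if section in _SECTIONS:
            valid = {f.name for f in dataclasses.fields(_SECTIONS[section])}
            unknown = set(payload) - valid
            if unknown:
                raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
            cfg[section] = dict(payload)
        elif section == "detector":
            unknown = set(payload) - _DETECTOR_KEYS
            if unknown:
                raise ValueError(f"unknown keys in [detector]: {sorted(unknown)}")
            cfg[section] = dict(payload)
        else:
            raise ValueError(f"unknown config section {section!r}")
    return cfg


def write_config_snapshot(cfg: dict, outdir: str | Path, seed: int) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_config.json", "w") as fh:
        json.dump({"seed": seed, **cfg}, fh, indent=2, default=str)
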