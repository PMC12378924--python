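"""End-to-end anomaly-detection pipeline.

Composes the spectrally initialized concept embeddings, the temporal graph
encoder, the knowledge-guided masks, the constraint hinges and the
knowledge-guided refinement into one trainable model, and scores patients by
combining four rank-normalized evidence components:

1. hard-mask rejection (implausible co-occurrence),
2. hierarchy + causal hinge violation magnitude — the violation mass the
   knowledge-guided refinement has to correct (its post-refinement residual
   is retained in the per-timestep report),
3. maximal per-factor latent jump between consecutive visits, measured in
   diffusion-map coordinates of the ontology,
4. worst per-event surprisal under the one-step forecast of each visit (the
   first visit is scored against the empty-history marginal forecast).

Training minimizes a weighted composite of the self-supervised task
(one-step forecast cross-entropy plus current-visit assignment
cross-entropy, standing in for the outcome task when no labels are given)
and the structural, disentanglement, temporal and knowledge-alignment
regularizers, with Adam and early stopping on a validation split.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, asdict

import numpy as np
import scipy.stats
from sklearn.base import BaseEstimator

from clintraj import autodiff as ad
from clintraj.adaptation import cooccurrence_nmi, occurrence_matrix, GraphRegularizedMF
from clintraj.cohort import PatientTrajectory, build_event_graph, zscore_lab_values
from clintraj.embedding import neighborhood_attention, relation_propagate, embedding_struct_loss, xavier_uniform
from clintraj.encoder import EncoderConfig, TemporalEncoder, factor_partition, mi_disentanglement_loss
from clintraj.knowledge import KnowledgeBase, graph_laplacian
from clintraj.masking import hard_mask
from clintraj.refine import (
    RefinementConfig,
    derive_prior,
    hierarchy_violation_loss,
    causal_violation_loss,
    multistep_causal_loss,
    refine_trajectory,
    soft_assign,
)

COMPONENT_NAMES = ("mask_rejection", "knowledge_violation", "factor_jump", "forecast_error")
# raw evidence columns; the two hinge channels are rank-normalized separately
# and combined into the knowledge_violation component
RAW_COMPONENTS = ("mask_rejection", "hierarchy_violation", "causal_violation", "factor_jump", "forecast_error")


@dataclass(frozen=True)
class RiskPredictor:
    """Linear-sigmoid trajectory risk head: σ(Σ_t wᵀz(t) + b)."""

    w: np.ndarray
    b: float = 0.0


def risk_score(Z: np.ndarray, predictor: RiskPredictor) -> float:
    """Trajectory risk ``σ(Σ_t wᵀz(t) + b)`` in (0, 1)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    logit = float(np.sum(Z @ predictor.w) + predictor.b)
    return float(1.0 / (1.0 + np.exp(-logit)))


def latent_hierarchy_loss(z: np.ndarray, ancestry: np.ndarray, P: np.ndarray) -> float:
    """Order-consistency hinge on pre-softmax concept logits ``Pᵀz``.

    Applied to logits rather than post-softmax scores so it remains distinct
    from the assignment-level hierarchy hinge; softmax is monotone, so the
    two flag the same ordering violations.
    """
    logits = np.asarray(P).T @ np.asarray(z, dtype=float)
    diff = logits[None, :] - logits[:, None]
    mask = (np.asarray(ancestry) > 0) & (diff > 0)
    return float(diff[mask].sum())


@dataclass
class ObjectiveWeights:
    """Coefficients of the composite training objective.

    Regularization coefficients default to 0.01; the task term (forecast
    cross-entropy, plus outcome cross-entropy when labels are supplied) has
    unit weight.  ``latent_cons`` (the logit-level hierarchy hinge) defaults
    to 0 so ordering violations are not double-penalized alongside the
    assignment-level hinge.
    """

    task: float = 1.0
    embed_struct: float = 0.01
    covariance: float = 0.01
    temporal: float = 0.01
    mi: float = 0.01
    smooth: float = 0.01
    latent_cons: float = 0.0
    p_anchor: float = 0.0
    hierarchy: float = 0.01
    kl: float = 0.01
    causal: float = 0.01
    multistep: float = 0.01
    laplacian: float = 0.0

    def __post_init__(self) -> None:
        for k, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"objective weight {k} must be nonnegative")


def _bce(p, target, weight=None):
    """Mean binary cross-entropy; works on Tensors and arrays."""
    eps = 1e-9
    t = np.asarray(target, dtype=float)
    loss = -(t * ad.log(p + eps) + (1 - t) * ad.log(1 - p + eps))
    return loss.mean() if weight is None else (loss * weight).mean()


def evaluate_detection(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """AUROC (rank statistic with midrank ties) plus thresholded P/R/F1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = scipy.stats.rankdata(scores)
    auroc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"auroc": float(auroc), "precision": prec, "recall": rec, "f1": f1}


@dataclass
class AnomalyReport:
    """Per-patient anomaly score with component breakdown."""

    patient_id: str
    score: float
    components: dict[str, float]
    normalized: dict[str, float]
    per_timestep: dict[str, list[float]]


class TrajectoryAnomalyDetector(BaseEstimator):
    """Knowledge-constrained anomaly detector over patient trajectories.

    Parameters
    ----------
    config : encoder architecture; defaults to the full-scale configuration
        (4 layers, 6 factors × 64 dims → 384-d latent).
    weights : composite-objective coefficients (0.01 regularizers).
    embed_dim : concept-embedding dimension.
    init : embedding initialization — ``eigenmap`` (spectral embedding of the
        hierarchy), ``xavier``, or ``adapted`` (graph-regularized matrix
        factorization of the patient–event matrix).
    assignment_sharpness : inverse temperature of the concept-assignment
        projection initialization; larger values concentrate s(t) on the
        concepts nearest the pooled latent.
    n_epochs, batch_size, val_fraction, patience : training loop controls
        (Adam, early stopping on validation loss).
    component_weights : ω over the four anomaly-evidence components.
    refine_config : gradient-refinement settings used at scoring time.

    Attributes (after fit)
    ----------------------
    embedding_table_, P_, W_forecast_, b_forecast_, predictor_ : fitted
        parameter arrays.
    components_ : (n_patients, 4) training-cohort component matrix, the
        reference distribution for rank normalization.
    scores_ : anomaly scores of the training cohort.
    loss_curve_ : composite training loss per epoch.
    """

    def __init__(
        self,
        config: EncoderConfig | None = None,
        weights: ObjectiveWeights | None = None,
        embed_dim: int | None = None,
        init: str = "eigenmap",
        assignment_sharpness: float = 60.0,
        diffusion_time: float = 2.0,
        causal_boost: float = 4.0,
        n_epochs: int = 5,
        batch_size: int = 16,
        val_fraction: float = 0.1,
        patience: int = 10,
        ontology_layers: int = 1,
        component_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
        refine_config: RefinementConfig | None = None,
        seed: int = 0,
    ):
        self.config = config
        self.weights = weights
        self.embed_dim = embed_dim
        self.init = init
        self.assignment_sharpness = assignment_sharpness
        self.diffusion_time = diffusion_time
        self.causal_boost = causal_boost
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.patience = patience
        self.ontology_layers = ontology_layers
        self.component_weights = component_weights
        self.refine_config = refine_config
        self.seed = seed

    # ------------------------------------------------------------------ fit
    def fit(self, cohort: list[PatientTrajectory], kb: KnowledgeBase, y=None) -> "TrajectoryAnomalyDetector":
        if not cohort:
            raise ValueError("cohort is empty")
        cfg = self.config or EncoderConfig(seed=self.seed)
        w = self.weights or ObjectiveWeights()
        self._cfg, self._w, self._kb = cfg, w, kb
        rng = np.random.default_rng([self.seed, 101])
        cohort = list(cohort)
        zscore_lab_values(cohort, kb.n_concepts)

        d_embed = self.embed_dim if self.embed_dim is not None else kb.n_concepts
        self._d_embed = d_embed
        table0, eigvals = self._init_table(cohort, kb, rng, d_embed)
        self._encoder = TemporalEncoder(cfg, d_embed, rng)
        params: dict[str, ad.Tensor] = {"table": ad.Tensor(table0, requires_grad=True)}
        for k, v in self._encoder.params.items():
            params[k] = ad.Tensor(v * 0.05, requires_grad=True)  # small transforms: residual-dominated at init
        # diffusion-map weighting: latent coordinates are eigenvector
        # coordinates shrunk by exp(-tau * eigenvalue), so latent distances
        # approximate ontology diffusion distance at time tau
        W_out0 = np.zeros((d_embed, cfg.latent_dim))
        m = min(d_embed, cfg.latent_dim)
        # weights are floored so the projection pseudo-inverse stays well
        # conditioned under parameter updates
        diag = np.maximum(np.exp(-self.diffusion_time * eigvals[:m]), 0.05) if eigvals is not None else np.ones(m)
        W_out0[np.arange(m), np.arange(m)] = diag
        params["W_out"] = ad.Tensor(W_out0, requires_grad=True)
        # the pseudo-inverse cancels the diffusion weighting, so assignment
        # logits are sharp similarities in the unweighted spectral basis
        P0 = np.linalg.pinv(W_out0) @ (self.assignment_sharpness * table0.T)
        params["P"] = ad.Tensor(P0, requires_grad=True)
        self._P0 = P0.copy()  # spectral anchor for the optional ||P - P0||^2 term
        # forecast head: unit-similarity persistence readout, plus a
        # knowledge-guided conditional term — an effect's logit is boosted by
        # the presence of its curated cause in the forecasting visit, so
        # effects observed without their cause surprise the forecaster
        W_f0 = P0 / self.assignment_sharpness
        for i, j in zip(*np.nonzero(kb.causal)):
            W_f0[:, int(j)] = W_f0[:, int(j)] + self.causal_boost * (P0[:, int(i)] / self.assignment_sharpness)
        params["W_f"] = ad.Tensor(W_f0, requires_grad=True)
        # forecast bias: add-one marginal per-visit log-odds of each event
        n_visits_total = sum(p.n_visits for p in cohort)
        counts = np.ones(kb.n_concepts)
        for p in cohort:
            for st in p.states:
                counts[st.active()] += 1
        rate = counts / (n_visits_total + 2)
        params["b_f"] = ad.Tensor(np.log(rate / (1 - rate)), requires_grad=True)
        params["w_risk"] = ad.Tensor(np.zeros(cfg.latent_dim), requires_grad=True)
        params["b_risk"] = ad.Tensor(np.zeros(1), requires_grad=True)
        self._rel_transforms = {
            r: ad.Tensor(np.eye(d_embed) * 0.5, requires_grad=True)
            for r in ("is_a", *{lab for *_, lab in kb.ontology.lateral_edges})
        }
        for r, t in self._rel_transforms.items():
            params[f"W_rel_{r}"] = t
        self.params_ = params
        self.prior_ = derive_prior(cohort, kb.n_concepts, mode="frequency")
        self._graphs = {p.patient_id: build_event_graph(p, kb) for p in cohort}

        # train/val split
        idx = rng.permutation(len(cohort))
        n_val = max(1, int(self.val_fraction * len(cohort))) if len(cohort) >= 10 else 0
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        y_arr = None if y is None else np.asarray(y, dtype=float)

        opt = ad.Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        self.loss_curve_: list[float] = []
        best_val, best_state, patience_left = np.inf, None, self.patience
        if n_val:
            # the initialization itself competes for the best validation loss
            val_total, _ = self.composite_objective([cohort[i] for i in val_idx], None)
            best_val = float(ad.asdata(val_total))
            best_state = {k: p.data.copy() for k, p in params.items()}
        last_good = {k: p.data.copy() for k, p in params.items()}
        self.diverged_ = False
        train_rng = np.random.default_rng([self.seed, 202])
        for epoch in range(self.n_epochs):
            order = train_rng.permutation(train_idx)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                batch = [cohort[i] for i in order[start : start + self.batch_size]]
                yb = None if y_arr is None else y_arr[order[start : start + self.batch_size]]
                total, _ = self.composite_objective(batch, yb, training=True, rng=train_rng)
                if not np.isfinite(total.data):
                    self.diverged_ = True
                    for k, p in params.items():
                        p.data = last_good[k]
                    break
                opt.zero_grad()
                total.backward()
                opt.step()
                epoch_loss += total.item()
                n_batches += 1
            if self.diverged_:
                break
            last_good = {k: p.data.copy() for k, p in params.items()}
            self.loss_curve_.append(epoch_loss / max(n_batches, 1))
            if n_val:
                val_total, _ = self.composite_objective([cohort[i] for i in val_idx], None)
                v = float(ad.asdata(val_total))
                if v < best_val - 1e-12:
                    best_val, best_state, patience_left = v, {k: p.data.copy() for k, p in params.items()}, self.patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_state is not None:
            for k, p in params.items():
                p.data = best_state[k]

        self.embedding_table_ = params["table"].data.copy()
        self.P_ = params["P"].data.copy()
        self.W_forecast_ = params["W_f"].data.copy()
        self.b_forecast_ = params["b_f"].data.copy()
        self.predictor_ = RiskPredictor(w=params["w_risk"].data.copy(), b=float(params["b_risk"].data[0]))
        self._encoder.params = {
            k: params[k].data.copy() for k in self._encoder.params
        }
        self.components_ = self._components(cohort)
        self._ref_sorted = [np.sort(self.components_[:, c]) for c in range(len(RAW_COMPONENTS))]
        self.scores_ = self._scores_from_components(self.components_)
        self.fitted_ = True
        return self

    # ------------------------------------------------------------ objective
    def composite_objective(self, batch, y=None, training: bool = False, rng=None):
        """Weighted composite loss over a batch; returns (total, breakdown).

        The breakdown maps component names to floats and sums to the total
        within numerical precision.  Gradients flow to the embedding table,
        relation transforms, encoder parameters, projection P and both
        decoder heads; the mutual-information surrogate enters as a
        stop-gradient estimate.
        """
        w = self._w
        kb = self._kb
        p = self.params_
        cfg = self._cfg
        terms: dict[str, ad.Tensor] = {}
        table = p["table"]
        if w.embed_struct > 0:
            refined = relation_propagate(table, kb, self._rel_transforms, n_layers=max(1, self.ontology_layers))
            context = neighborhood_attention(table, kb)
            terms["embed_struct"] = embedding_struct_loss(refined, context) * (1.0 / kb.n_concepts)
        if w.p_anchor > 0:
            dP = p["P"] - self._P0
            terms["p_anchor"] = (dP * dP).sum() * w.p_anchor
        anc = kb.ancestry.astype(float)
        cau = kb.causal.astype(float)
        q = self.prior_.q
        batch_factors = []
        acc: dict[str, ad.Tensor] = {}

        def add(name, val):
            acc[name] = val if name not in acc else acc[name] + val

        for bi, patient in enumerate(batch):
            graph = self._graphs.get(patient.patient_id) or build_event_graph(patient, kb)
            Z = self._encoder.encode(graph, table, params=p, n_visits=patient.n_visits, training=training, rng=rng)
            T = patient.n_visits
            X = np.stack([st.indicator for st in patient.states]).astype(float)
            # forecast next-visit indicator from z(t)
            if T > 1:
                logits = Z[np.arange(T - 1)] @ p["W_f"] + p["b_f"]
                add("task", _bce(ad.sigmoid(logits), X[1:]))
            if y is not None:
                r = ad.sigmoid((Z @ p["w_risk"]).sum() + p["b_risk"].sum())
                add("task", _bce(r, np.asarray([y[bi]])))
            # soft assignments; trained to reconstruct the visit's event set so
            # s(t) resolves individual events, not just clusters
            S = ad.softmax(Z @ p["P"], axis=-1)
            sizes = X.sum(axis=1, keepdims=True)
            U = X / np.maximum(sizes, 1.0)
            add("task", -(ad.log(S + 1e-12) * U).sum() * (1.0 / T))
            diff3 = S.reshape(T, 1, kb.n_concepts) - S.reshape(T, kb.n_concepts, 1)
            hinge3 = ad.relu(diff3)
            if w.hierarchy > 0:
                add("hierarchy", (hinge3 * anc).sum())
            if w.causal > 0:
                add("causal", (hinge3 * cau).sum())
            if w.kl > 0:
                sup = q > 0
                add("kl", (ad.log((S + self.prior_.eps) ** -1.0) * q).sum() + T * float(np.sum(q[sup] * np.log(q[sup]))))
            if w.latent_cons > 0:
                logits_all = Z @ p["P"]
                dl = logits_all.reshape(T, 1, kb.n_concepts) - logits_all.reshape(T, kb.n_concepts, 1)
                add("latent_cons", (ad.relu(dl) * anc).sum())
            if w.multistep > 0 and T > 1:
                dd = S[np.arange(1, T)].reshape(T - 1, 1, kb.n_concepts) - S[np.arange(T - 1)].reshape(T - 1, kb.n_concepts, 1)
                add("multistep", (ad.relu(dd) * cau).sum())
            # disentanglement + smoothness
            blocks = factor_partition(Z, cfg.n_factors)
            if w.covariance > 0:
                norms = [((b * b).sum(axis=1) + 1e-12) ** 0.5 for b in blocks]
                cov = None
                for i in range(cfg.n_factors):
                    for j in range(i + 1, cfg.n_factors):
                        c = (blocks[i] * blocks[j]).sum(axis=1) / (norms[i] * norms[j])
                        cc = (c * c).sum()
                        cov = cc if cov is None else cov + cc
                add("covariance", cov * 2.0)  # ordered pairs
            if (w.temporal > 0 or w.smooth > 0) and T > 1:
                dz = Z[np.arange(1, T)] - Z[np.arange(T - 1)]
                sm = (dz * dz).sum()
                add("temporal", sm)
                add("smooth", sm)
            batch_factors.append(np.stack([ad.asdata(b) for b in blocks], axis=1))
        nb = max(len(batch), 1)
        weight_map = {
            "task": w.task, "hierarchy": w.hierarchy, "causal": w.causal, "kl": w.kl,
            "latent_cons": w.latent_cons, "multistep": w.multistep,
            "covariance": w.covariance, "temporal": w.temporal, "smooth": w.smooth,
        }
        for name, val in acc.items():
            terms[name] = val * (weight_map[name] / nb)
        if "embed_struct" in terms:
            terms["embed_struct"] = terms["embed_struct"] * w.embed_struct
        if w.mi > 0:
            F = np.concatenate(batch_factors, axis=0)
            if F.shape[0] >= 8:
                terms["mi"] = ad.Tensor(w.mi * mi_disentanglement_loss(F))
        total = None
        breakdown = {}
        for name, val in terms.items():
            total = val if total is None else total + val
            breakdown[name] = float(ad.asdata(val))
        if total is None:
            total = ad.Tensor(0.0)
        if not np.isfinite(float(ad.asdata(total))):
            bad = [k for k, v in breakdown.items() if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite objective component(s): {bad}")
        return total, breakdown

    # ------------------------------------------------------------- scoring
    def _init_table(self, cohort, kb, rng, d_embed):
        """Concept table plus (for spectral inits) Laplacian eigenvalues."""
        if self.init == "eigenmap":
            import scipy.linalg

            L = graph_laplacian(kb.hierarchy_adjacency())
            if d_embed > kb.n_concepts:
                raise ValueError("embed_dim cannot exceed the vocabulary size")
            lam, E = scipy.linalg.eigh(L)
            return E[:, :d_embed], lam[:d_embed]
        if self.init == "xavier":
            return xavier_uniform((kb.n_concepts, d_embed), rng), None
        if self.init == "adapted":
            B = occurrence_matrix(cohort, kb.n_concepts)
            L = graph_laplacian(cooccurrence_nmi(B))
            mf = GraphRegularizedMF(n_components=d_embed, gamma=0.1, lam=0.1, seed=self.seed, max_iter=100)
            mf.fit(B, L)
            E = mf.V_
            return E / np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12), None
        raise ValueError(f"unknown init {self.init!r}")

    def _check_fitted(self) -> None:
        if not getattr(self, "fitted_", False):
            raise ValueError("model not fitted; call fit() first")

    def encode_cohort(self, cohort) -> list[np.ndarray]:
        self._check_fitted()
        out = []
        for patient in cohort:
            graph = build_event_graph(patient, self._kb)
            out.append(self._encoder.encode(graph, self.embedding_table_, n_visits=patient.n_visits))
        return out

    def _components(self, cohort) -> np.ndarray:
        """Per-patient raw evidence columns (max over timesteps each)."""
        kb = self._kb
        rcfg = self.refine_config or RefinementConfig()
        comps = np.zeros((len(cohort), len(RAW_COMPONENTS)))
        self._per_timestep: list[dict[str, list[float]]] = []
        for pi, patient in enumerate(cohort):
            T = patient.n_visits
            rej = [
                hard_mask(st.indicator, kb.relation, st.values).rejection_fraction
                for st in patient.states
            ]
            graph = build_event_graph(patient, kb)
            Z = self._encoder.encode(graph, self.embedding_table_, n_visits=T)
            S = np.stack([soft_assign(Z[t], self.P_) for t in range(T)])
            # violation magnitude the knowledge-guided refinement has to
            # correct: hinge penalties of the unrefined assignments (running
            # refinement to its fixed point would null the evidence it is
            # meant to surface; the residual after refinement is retained in
            # the per-timestep report)
            hier_t = [hierarchy_violation_loss(S[t], kb.ancestry) for t in range(T)]
            caus_t = [causal_violation_loss(S[t], kb.causal) for t in range(T)]
            for t in range(T - 1):
                caus_t[t + 1] += multistep_causal_loss(S[t : t + 2], kb.causal)
            Zr = refine_trajectory(Z, self.P_, kb.ancestry, kb.causal, rcfg)
            Sr = np.stack([soft_assign(Zr[t], self.P_) for t in range(T)])
            resid_t = [
                hierarchy_violation_loss(Sr[t], kb.ancestry) + causal_violation_loss(Sr[t], kb.causal)
                for t in range(T)
            ]
            for t in range(T - 1):
                resid_t[t + 1] += multistep_causal_loss(Sr[t : t + 2], kb.causal)
            jump_t = [0.0] + [float(np.sum((Z[t] - Z[t - 1]) ** 2)) for t in range(1, T)]
            # forecast surprisal: worst per-event negative log-probability of
            # the observed visit under the one-step forecast; the first visit
            # is scored against the empty-history (marginal-rate) forecast
            logits = np.vstack([self.b_forecast_, Z[:-1] @ self.W_forecast_ + self.b_forecast_])
            prob = 1.0 / (1.0 + np.exp(-logits))
            eps = 1e-12
            fc_t = []
            for t in range(T):
                act = patient.states[t].active()
                fc_t.append(float((-np.log(prob[t][act] + eps)).max()) if len(act) else 0.0)
            comps[pi] = [max(rej), max(hier_t), max(caus_t), max(jump_t), max(fc_t)]
            self._per_timestep.append(
                {
                    "mask_rejection": rej,
                    "hierarchy_violation": hier_t,
                    "causal_violation": caus_t,
                    "refined_residual": resid_t,
                    "factor_jump": jump_t,
                    "forecast_error": fc_t,
                }
            )
        return comps

    def _rank_normalize(self, comps: np.ndarray) -> np.ndarray:
        """Midrank position of each raw column within the training reference
        distribution, mapped to [0, 1]."""
        out = np.zeros_like(comps, dtype=float)
        for c in range(comps.shape[1]):
            ref = self._ref_sorted[c]
            # tolerance-snapped lookup: equal-within-roundoff values share a
            # midrank instead of jumping across a tie boundary
            tol = 1e-9 * (1.0 + np.abs(comps[:, c]))
            lo = np.searchsorted(ref, comps[:, c] - tol, side="left")
            hi = np.searchsorted(ref, comps[:, c] + tol, side="right")
            out[:, c] = (lo + hi) / 2.0 / len(ref)
        return out

    def _combine_normalized(self, normed: np.ndarray) -> np.ndarray:
        """Collapse the 5 normalized raw columns to the 4 score components.

        The hierarchy and causal hinge channels live on different scales, so
        each is rank-normalized on its own and the knowledge-violation
        component takes the dominant (maximal) normalized channel.
        """
        viol = np.maximum(normed[:, 1], normed[:, 2])
        return np.column_stack([normed[:, 0], viol, normed[:, 3], normed[:, 4]])

    def _scores_from_components(self, comps: np.ndarray) -> np.ndarray:
        omega = np.asarray(self.component_weights, dtype=float)
        if np.any(omega < 0) or omega.sum() <= 0:
            raise ValueError("component weights must be nonnegative with positive sum")
        normed = self._combine_normalized(self._rank_normalize(comps))
        return normed @ (omega / omega.sum())

    def score_samples(self, cohort) -> np.ndarray:
        """Anomaly score in [0, 1] per patient (higher = more anomalous)."""
        self._check_fitted()
        return self._scores_from_components(self._components(cohort))

    def predict(self, cohort, threshold: float = 0.8) -> np.ndarray:
        return (self.score_samples(cohort) >= threshold).astype(int)

    def report(self, cohort) -> list[AnomalyReport]:
        """Full per-patient anomaly reports with component breakdowns."""
        self._check_fitted()
        comps = self._components(cohort)
        per_t = self._per_timestep
        normed = self._combine_normalized(self._rank_normalize(comps))
        scores = self._scores_from_components(comps)
        out = []
        for i, patient in enumerate(cohort):
            out.append(
                AnomalyReport(
                    patient_id=patient.patient_id,
                    score=float(scores[i]),
                    components={k: float(v) for k, v in zip(RAW_COMPONENTS, comps[i])},
                    normalized={k: float(v) for k, v in zip(COMPONENT_NAMES, normed[i])},
                    per_timestep=per_t[i],
                )
            )
        return out

    def risk(self, cohort) -> np.ndarray:
        """Trajectory risk σ(Σ_t wᵀz(t) + b) per patient."""
        self._check_fitted()
        return np.asarray([risk_score(Z, self.predictor_) for Z in self.encode_cohort(cohort)])

    def config_snapshot(self) -> dict:
        cfg = self._cfg if hasattr(self, "_cfg") else (self.config or EncoderConfig(seed=self.seed))
        w = self._w if hasattr(self, "_w") else (self.weights or ObjectiveWeights())
        return {
            "encoder": asdict(cfg),
            "objective_weights": asdict(w),
            "embed_dim": self.embed_dim,
            "embed_dim_resolved": getattr(self, "_d_embed", self.embed_dim),
            "init": self.init,
            "assignment_sharpness": self.assignment_sharpness,
            "diffusion_time": self.diffusion_time,
            "causal_boost": self.causal_boost,
            "component_weights": list(self.component_weights),
            "seed": self.seed,
        }


def anomaly_score(patient: PatientTrajectory, model: TrajectoryAnomalyDetector) -> AnomalyReport:
    """Score one patient against a fitted model's reference cohort."""
    return model.report([patient])[0]


def train(cohort, kb, config: EncoderConfig | None = None, seed: int = 0, **kwargs) -> TrajectoryAnomalyDetector:
    """Fit a :class:`TrajectoryAnomalyDetector` on a cohort (thin wrapper)."""
    det = TrajectoryAnomalyDetector(config=config, seed=seed, **kwargs)
    return det.fit(cohort, kb)
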