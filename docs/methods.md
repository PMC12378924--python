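# Methods

`clintraj` detects anomalous patient trajectories in longitudinal coded
clinical-event data by combining representation learning with hard symbolic
knowledge: a medical is-a ontology, a symmetric matrix of semantically valid
co-occurrences, and a curated causal-precedence DAG. This note records the
model, its assumptions, the numerical choices, and what the synthetic study
does and does not demonstrate.

## Data model

A patient is an ordered sequence of visits. Each visit is a multi-hot
*clinical state* over a fixed vocabulary `E` of coded concepts (diagnoses,
medications, labs, procedures); value-bearing concepts (labs) carry a real
value, z-scored per concept across the cohort for numeric work with the raw
value preserved. Static context (age, sex, comorbidity flags) travels with
the trajectory. From a trajectory we derive a temporal event graph — one
node per active event per visit, with an intra-visit clique, a forward
complete-bipartite coupling between consecutive visits, and ontology-labelled
edges between co-present related concepts — and a sparse transition tensor
`A[t, i, j] = 1` iff event `i` is active at visit `t` and `j` at `t+1`. A
"within-timestamp" reading of transitions is available behind a flag but is
not the default temporal semantics.

## Knowledge structures

* **Ancestry matrix** `T`: strict transitive closure of the child→parent
  hierarchy; zero diagonal (a reflexive diagonal would only add vacuous
  self-comparisons to the order hinge), antisymmetric, transitively closed.
* **Relation matrix** `R`: symmetrized on load (an edge in either direction
  sets both entries; no directionality is defined for co-occurrence
  support), zero diagonal so an event cannot support itself through the
  masking rule.
* **Causal matrix** `C`: `C[i, j] = 1` iff `i` causally precedes `j`;
  validated acyclic.
* **Type matrix**: one-hot concept types, used by the type-consistent mask.

## Knowledge-guided masking

For a state `x`, the hard mask keeps event `i` iff some co-occurring `j` has
`R[i, j] = 1`; the typed variant additionally requires `type(i) = type(j)`
and is therefore elementwise at most the hard mask. The typed rule is
implemented literally even though cross-type support (a medication justified
by a diagnosis) never satisfies it, which is clinically restrictive; the
hard mask is the pipeline default. The normalized relational confidence
`s_i = (1/‖x‖₁) Σ_j R_ij x_j` feeds an optional differentiable sigmoid gate
with temperature `α` (default 4.0, giving ≈0.88 pass-through for an event
supported by half its co-occurring partners). An empty state would divide by
zero; it is passed through unmasked with a warning, because rejecting empty
encounters would break streaming use.

## Embeddings and the temporal encoder

Concept embeddings are grounded in the ontology three ways (config-selected):
`eigenmap` (default) takes the eigenvector basis of the unnormalized
hierarchy Laplacian `L = D − A`; `xavier` draws Xavier-uniform entries;
`adapted` row-normalizes the event factors of the graph-regularized matrix
factorization (below). Ontology refinement attends over each concept's
neighborhood (scaled dot-product scores by default, cosine by flag; the
softmax is taken jointly over all (relation, neighbor) pairs so each concept
carries one attention distribution) and applies residual relation-specific
updates `e ← e + ReLU(Σ α^(r) W_r e_j)`. A structural penalty
`Σ_i ‖e_i^(L) − ẽ_i‖²` keeps refined embeddings near their attention
context; isolated concepts use their own embedding as context and are
loss-neutral.

The temporal encoder runs the same relation-aware residual layer over the
patient event graph with edge labels {intra, inter, ontology} — the
inter-visit label passes information forward in time only — then pools
final-layer node embeddings per visit (mean pooling by default, which is
exactly permutation-invariant; 8-head attention pooling optional) and
projects with `W_out` into the latent space. Empty visits yield a zero
latent rather than an error, since real records contain empty encounters.

The default architecture follows the full-scale configuration: 4 propagation
layers, 256 hidden units, K = 6 factors of 64 dimensions (384-d latent),
8 attention heads, dropout 0.3 (training mode only; all scoring paths are
deterministic), Adam at 1e-4 with weight decay 1e-5, regularization
coefficients 0.01.

**Diffusion-map latent geometry.** With the spectral initialization the
projection `W_out` starts as the diagonal `exp(−τ λ_k)` over Laplacian
eigenvalues (τ = 2 by default, entries floored at 0.05 for conditioning), so
latent distances approximate the ontology's diffusion distance at time τ:
consecutive-visit jumps measure how far apart in the ontology two visits'
event sets are. The concept-assignment projection is initialized as
`P = β · pinv(W_out) @ Eᵀ` (sharpness β = 60), which cancels the diffusion
weighting: assignment logits are sharp similarities in the unweighted
orthonormal spectral basis, so `s(t) = softmax(Pᵀ z(t))` concentrates on the
events actually present at visit `t`. One latent thus serves both needs —
geometric smoothness for jump detection and event-level resolution for the
order constraints.

## Disentanglement and temporal regularizers

Each latent is partitioned into K contiguous factor blocks. The covariance
penalty sums squared cosine similarity over ordered block pairs (zero-norm
blocks contribute nothing; the loss is invariant to positive rescaling of
any block). The temporal-consistency penalty `Σ_{t≥2} Σ_k ‖Δz_k(t)‖²`
equals the whole-vector form exactly for any complete partition (direct-sum
Pythagorean identity); both forms are implemented and tested equal. Mutual
information between 64-d blocks is not estimable directly at this scale, so
the package uses a Gaussian canonical-correlation surrogate,
`−½ Σ log(1 − ρ²)` over canonical correlations per ordered pair with ρ²
clipped at 1 − 1e−6; it is zero iff blocks are (Gaussian-)uncorrelated and
requires a batch of at least 8. Batch losses are computed per sample and
averaged (the flattened-batch alternative is switchable).

## Knowledge-guided refinement

Hinge penalties on the soft assignment measure order violations: hierarchy
(`Σ T_ij max(0, s_j − s_i)`), within-step causal, and the multi-step causal
penalty coupling consecutive visits. A KL term `Σ q log(q/(s+ε))` aligns
assignments with a frequency-based (add-one-smoothed) or uniform prior;
ε = 1e−8 introduces a negative bias bounded below by `−log(1 + ε|E|)`,
documented and tested. Refinement performs gradient descent on `z(t)` with
hand-derived analytic gradients through the softmax (verified against
central finite differences at 1e−5 relative tolerance). The simplex
constraint is enforced structurally by the softmax, so no explicit
projection is needed; an optional step-halving safeguard (up to 20 halvings)
guarantees the combined objective never increases. The causal scale `γ_t` is
reparameterized `exp(g_t)` with `g_t = 0` and can be co-optimized, off by
default since descending on `g_t` alone trivially shrinks the penalty.
Refinement is per-timestep with the multi-step term coupling neighbors;
λ₁ = λ₂ = 1 inside refinement, global weighting (0.01) belongs to the
training objective.

## Population-level embedding adaptation

The binary patient–event matrix `B` is factorized as `U Vᵀ` by alternating
least squares on `‖B − UVᵀ‖² + γ(‖U‖² + ‖V‖²) + λ Tr(VᵀLV)`, where `L` is
the Laplacian of the event co-occurrence graph weighted by normalized mutual
information (plug-in entropies, constant columns contribute zero by
convention, values clipped to [0, 1]). The U-step is ridge regression; the
V-step solves the Sylvester system `λLV + V(UᵀU + γI) = BᵀU` exactly, so the
objective is non-increasing at every half-iteration — a provable property
the tests assert. Convergence: relative objective change below 1e−8 or 500
iterations. Ridge alignment to optional pre-trained vectors uses the closed
form `W = (VᵀV + αI)⁻¹ Vᵀ V_pre`.

## Training objective

The composite objective sums, with configurable nonnegative weights
(regularizers default 0.01): a self-supervised task term — one-step forecast
cross-entropy of the next visit's indicator plus a current-visit assignment
cross-entropy that teaches `s(t)` to resolve individual events (outcome
cross-entropy is added when labels are supplied); the embedding structural
penalty; covariance, temporal and MI disentanglement terms; the hierarchy,
KL, causal and multi-step assignment penalties; and optionally the
logit-level hierarchy hinge (off by default to avoid double-penalizing the
same ordering violations). The MI surrogate enters as a stop-gradient
estimate. Gradients flow to the embedding table, relation transforms,
encoder parameters, projection and decoder heads through a compact
reverse-mode automatic-differentiation layer written for this package.
Training uses Adam (1e-4, weight decay 1e-5), minibatches of 16, early
stopping on a 10% validation split with patience 10; the initialization
itself competes for the best validation loss, so training can only improve
on the analytic starting point. On divergence (non-finite loss) the last
good parameters are restored.

The forecast head is knowledge-initialized: bias = add-one marginal
log-odds of each event per visit, weights = unit-scale similarity readout
plus a conditional boost (default 4.0) wiring each curated cause into its
effect's logit, so an effect observed without its cause surprises the
forecaster even before any training.

## Anomaly score

Four evidence components per patient, each the maximum over visits:

1. **mask rejection** — hard-mask rejection fraction;
2. **knowledge violation** — hierarchy + causal(+multi-step) hinge magnitude
   of the unrefined assignments, i.e. the violation mass knowledge-guided
   refinement has to correct. (Scoring the *residual after* refinement was
   evaluated and discarded: the refiner removes the evidence it is designed
   to correct, so residuals stop discriminating; the post-refinement
   residual is still computed and reported per timestep.) The two hinge
   channels live on different scales, so each is rank-normalized separately
   and the component takes the dominant channel;
3. **factor jump** — `Σ_k ‖Δz_k(t)‖²` in the diffusion-weighted latent;
4. **forecast surprisal** — worst per-event negative log-probability of the
   observed visit under the one-step forecast; the first visit is scored
   against the empty-history marginal forecast.

Components are rank-normalized against the training cohort (midranks; the
lookup is tolerance-snapped at 1e−9 so equal-within-roundoff values share a
rank) and combined with configurable weights ω, uniform by default; scores
lie in [0, 1] and are invariant to monotone rescaling of any single
component. Risk prediction `σ(Σ_t wᵀ z(t) + b)` is exposed separately; with
no outcome labels the risk head stays at its neutral initialization.

Both risk and anomaly scores are exactly invariant under type-preserving
relabelings of the vocabulary applied consistently to matrices, parameters
and cohort (tested to 1e−10).

## Synthetic study

The generator emulates the framework's inputs with known ground truth. The
ontology is a layered DAG (2 roots, ~`|E|/6` mid-level concepts, the rest
leaves; each non-root has 1–2 parents in the layer above); sibling leaf
clusters under one primary parent are pairwise related, child–parent pairs
are related, and random lateral edges are added at density 0.03. One sibling
pair per sufficiently large cluster is reserved as a causal edge, oriented
by vocabulary index (hence a DAG). Patients follow a first-order Markov
chain over 5 hidden health states (0.7 self-transition); each state emits
2–4 free members of one cluster per visit, labs get unit-variance Gaussian
values with state-dependent means. Health states map to *mutually close*
clusters: disease processes evolve among related conditions, and that is
precisely what makes the planted distant jump an anomaly rather than
ordinary progression. Causal pairs are emitted cause-first (cause at `t`,
cause + effect at `t+1`), so a clean cohort has zero hard-mask rejections
and no causal inversion anywhere — both properties are asserted, not
assumed.

Planted anomalies (exactly `round(0.1 · n)` patients, one each, mixed evenly):

* `cooccurrence` — inject an event with no relation partner in its visit;
* `causal` — invert the first-occurrence order of one emitted cause/effect
  pair (the effect replaces the cause at its first visit);
* `jump` — replace one interior visit's events with a cluster at maximal
  shortest-path distance in the undirected hierarchy.

What passing tests show: the detector recovers these three planted
mechanisms (mean AUROC ≥ 0.80 over five seeded replicates at 200 patients)
and the mask component strictly separates co-occurrence corruption. What
they do not show: performance on real EHR data — the generator has no
coding noise, no missingness, no visit-level censoring, no cross-cluster
comorbidity structure, and its causal mechanism is far more regular than
clinical reality; the typed mask and lab values are exercised structurally
but carry no detection signal in this study.

## Problem sizes and numerical choices

The synthetic study in the acceptance script uses a scaled encoder chosen as
the package's default study configuration — 2 propagation layers, hidden 32,
6 factors × 8 dims (48-d latent matching the 48-concept vocabulary), 4
training epochs — while the library default remains the full-scale
configuration above. Eigen-decompositions are dense (`scipy.linalg.eigh`;
vocabularies here are a few hundred concepts at most), with ties among equal
eigenvalues broken by the solver's ascending order. The eigenmap keeps the
trivial constant eigenvector by default (the literal optimizer of the trace
problem); `skip_trivial` drops near-zero eigenvalues for classical eigenmap
use. Hinge gradients use the subgradient zero at ties. All randomness flows
from named substreams of a single seed; two runs with the same seed produce
bit-identical parameters and scores.

## Known limitations

* The forecast decoder is linear; it captures marginal rates, persistence
  and wired causal conditioning but not higher-order interactions.
* The MI surrogate detects only Gaussian (second-order) dependence between
  factor blocks.
* Rank normalization needs a reference cohort of meaningful size; scoring a
  single patient uses the stored training distribution.
* The hand-rolled autodiff supports exactly the operations the objective
  needs; it is not a general-purpose engine.
* Hierarchy violations are structural for any assignment that resolves
  leaf-level events (leaves outscore their ancestors by construction), so
  the hierarchy channel mostly contributes baseline noise unless anomalies
  specifically disorder the hierarchy.
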