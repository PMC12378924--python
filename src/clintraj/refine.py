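"""Knowledge-guided refinement of latent trajectories.

A latent vector ``z(t)`` is projected to a soft distribution over concepts,
``s(t) = softmax(Pᵀ z(t))``.  Hinge penalties measure how much the
assignment violates the ontology partial order (a descendant scored above an
ancestor) and curated causal precedence (an effect scored above its cause,
within a step or across consecutive steps); a KL term aligns the assignment
with a frequency or uniform prior.  Refinement performs gradient descent on
``z`` against the weighted hinge penalties, with an optional step-halving
safeguard that guarantees the combined objective never increases.  The
simplex constraint on ``s`` is enforced structurally by the softmax, so no
explicit projection step is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RefinementConfig:
    """Step size, penalty weights and safeguard settings for refinement.

    ``gamma`` is the per-timestep positive scale on the causal penalty,
    reparameterized as ``γ_t = exp(g_t)`` with ``g_t`` initialized to 0;
    ``optimize_gamma`` co-optimizes ``g_t`` by gradient descent.
    """

    step_size: float = 1e-2
    lambda_hier: float = 1.0
    lambda_causal: float = 1.0
    max_steps: int = 50
    halving: bool = True
    max_halvings: int = 20
    optimize_gamma: bool = False

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step size must be positive")
        if self.lambda_hier < 0 or self.lambda_causal < 0:
            raise ValueError("penalty weights must be nonnegative")


def soft_assign(z: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Soft concept assignment ``s = softmax(Pᵀ z)``."""
    logits = np.asarray(P).T @ np.asarray(z, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits in soft assignment")
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _hinge_loss_and_sgrad(s_hi: np.ndarray, s_lo: np.ndarray, M: np.ndarray):
    """Σ_ij M_ij max(0, s_lo[j] − s_hi[i]) and its gradients w.r.t. both args.

    ``s_hi`` carries the scores that should dominate (ancestors / causes),
    ``s_lo`` the scores that should be dominated (descendants / effects).
    """
    diff = s_lo[None, :] - s_hi[:, None]
    active = (M > 0) & (diff > 0)
    loss = float(diff[active].sum())
    g_lo = active.sum(axis=0).astype(float)
    g_hi = -active.sum(axis=1).astype(float)
    return loss, g_hi, g_lo


def hierarchy_violation_loss(s: np.ndarray, ancestry: np.ndarray) -> float:
    """Ontology-order hinge ``Σ_ij T_ij · max(0, s_j − s_i)``.

    Zero exactly when every descendant's score is at most every ancestor's.
    """
    loss, _, _ = _hinge_loss_and_sgrad(np.asarray(s, float), np.asarray(s, float), np.asarray(ancestry))
    return loss


def causal_violation_loss(s: np.ndarray, causal: np.ndarray) -> float:
    """Causal-precedence hinge ``Σ_ij C_ij · max(0, s_j − s_i)`` at one step."""
    loss, _, _ = _hinge_loss_and_sgrad(np.asarray(s, float), np.asarray(s, float), np.asarray(causal))
    return loss


def multistep_causal_loss(S: np.ndarray, causal: np.ndarray) -> float:
    """Cascaded causal hinge across consecutive steps.

    ``Σ_{t=1}^{T−1} Σ_ij C_ij · max(0, s_j(t+1) − s_i(t))``; zero for T = 1.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    total = 0.0
    for t in range(S.shape[0] - 1):
        loss, _, _ = _hinge_loss_and_sgrad(S[t], S[t + 1], np.asarray(causal))
        total += loss
    return total


def kl_alignment_loss(s: np.ndarray, q: np.ndarray, eps: float = 1e-8) -> float:
    """Prior alignment ``Σ_i q_i log(q_i / (s_i + ε))`` with 0·log 0 := 0.

    With ε = 0 this is the KL divergence (nonnegative, zero iff s = q on the
    support of q).  With ε > 0 the value can dip slightly below zero, bounded
    below by −log(1 + ε·|E|) by Jensen's inequality.
    """
    s = np.asarray(s, dtype=float)
    q = np.asarray(q, dtype=float)
    sup = q > 0
    denom = s[sup] + eps
    if np.any(denom <= 0):
        raise ValueError("s_i + eps must be positive wherever q_i > 0")
    return float(np.sum(q[sup] * (np.log(q[sup]) - np.log(denom))))


@dataclass(frozen=True)
class PriorDistribution:
    q: np.ndarray
    eps: float = 1e-8

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if np.any(q < 0) or not np.isclose(q.sum(), 1.0, atol=1e-8):
            raise ValueError("prior must be a probability vector")
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")


def derive_prior(source, n_concepts: int, mode: str = "frequency", eps: float = 1e-8) -> PriorDistribution:
    """Event prior from a cohort (add-one-smoothed frequencies) or uniform.

    ``source`` is a list of trajectories for ``mode="frequency"`` and is
    ignored for ``mode="uniform"``.
    """
    if mode == "uniform":
        q = np.full(n_concepts, 1.0 / n_concepts)
    elif mode == "frequency":
        counts = np.ones(n_concepts)  # add-one smoothing
        for p in source:
            for st in p.states:
                counts[st.active()] += 1
        q = counts / counts.sum()
    else:
        raise ValueError(f"unknown prior mode {mode!r}")
    return PriorDistribution(q=q, eps=eps)


def _softmax_vjp(s: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Jacobian-vector product of softmax: Jᵀ g = s⊙g − s·(sᵀg)."""
    return s * g - s * float(s @ g)


def refinement_objective_and_grad(
    Z: np.ndarray,
    P: np.ndarray,
    ancestry: np.ndarray,
    causal: np.ndarray,
    config: RefinementConfig,
    gammas: np.ndarray,
):
    """Combined refinement objective over a trajectory and its z-gradient.

    ``J(Z) = Σ_t [λ₁ L_hier(s(t)) + γ_t λ₂ L_causal(s(t))]
            + λ₂ L_multistep(S)`` with ``s(t) = softmax(Pᵀ z(t))``.
    Returns (J, dJ/dZ, dJ/dg) where g are the log-scales of γ.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    T = Z.shape[0]
    S = np.stack([soft_assign(Z[t], P) for t in range(T)])
    s_grads = np.zeros_like(S)
    g_grads = np.zeros(T)
    total = 0.0
    for t in range(T):
        lh, gh_hi, gh_lo = _hinge_loss_and_sgrad(S[t], S[t], np.asarray(ancestry))
        lc, gc_hi, gc_lo = _hinge_loss_and_sgrad(S[t], S[t], np.asarray(causal))
        total += config.lambda_hier * lh + gammas[t] * config.lambda_causal * lc
        s_grads[t] += config.lambda_hier * (gh_hi + gh_lo)
        s_grads[t] += gammas[t] * config.lambda_causal * (gc_hi + gc_lo)
        g_grads[t] = config.lambda_causal * gammas[t] * lc  # d/dg via gamma=exp(g)
    for t in range(T - 1):
        lm, gm_hi, gm_lo = _hinge_loss_and_sgrad(S[t], S[t + 1], np.asarray(causal))
        total += config.lambda_causal * lm
        s_grads[t] += config.lambda_causal * gm_hi
        s_grads[t + 1] += config.lambda_causal * gm_lo
    Zg = np.zeros_like(Z)
    for t in range(T):
        Zg[t] = np.asarray(P) @ _softmax_vjp(S[t], s_grads[t])
    if not np.all(np.isfinite(Zg)):
        raise FloatingPointError("non-finite refinement gradient")
    return total, Zg, g_grads


def refine_trajectory(
    Z: np.ndarray,
    P: np.ndarray,
    ancestry: np.ndarray,
    causal: np.ndarray,
    config: RefinementConfig | None = None,
    return_trace: bool = False,
):
    """Gradient-descent refinement of a latent trajectory against the
    hierarchy and causal hinge penalties.

    With the halving safeguard enabled, each step retries with a halved step
    size (up to ``max_halvings`` times) until the combined objective does not
    increase, so the returned objective is never above the initial one.  If
    the objective is already zero the input is returned unchanged.
    """
    config = config or RefinementConfig()
    Z = np.atleast_2d(np.asarray(Z, dtype=float)).copy()
    T = Z.shape[0]
    g = np.zeros(T)
    trace = []
    obj, grad, g_grad = refinement_objective_and_grad(Z, P, ancestry, causal, config, np.exp(g))
    trace.append(obj)
    if obj == 0.0:
        return (Z, trace) if return_trace else Z
    for step in range(config.max_steps):
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError(f"non-finite gradient at refinement step {step}")
        eta = config.step_size
        accepted = False
        for _ in range(config.max_halvings + 1):
            Z_new = Z - eta * grad
            g_new = g - eta * g_grad if config.optimize_gamma else g
            new_obj, new_grad, new_g_grad = refinement_objective_and_grad(
                Z_new, P, ancestry, causal, config, np.exp(g_new)
            )
            if (not config.halving) or new_obj <= obj:
                accepted = True
                break
            eta *= 0.5
        if config.halving and not accepted:
            break  # no non-increasing step found; keep current iterate
        Z, g, obj, grad, g_grad = Z_new, g_new, new_obj, new_grad, new_g_grad
        trace.append(obj)
        if obj == 0.0:
            break
    return (Z, trace) if return_trace else Z
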