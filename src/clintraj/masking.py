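"""Knowledge-guided masking of medically implausible co-occurrences.

Given a multi-hot state ``x`` and a binary relation matrix ``R`` (symmetric,
zero diagonal), the hard mask keeps an active event only if it has at least
one semantically related co-occurring partner; the typed variant additionally
requires the partner to share the event's semantic type.  A differentiable
soft gate scales events by a sigmoid of their normalized relational
confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_TEMPERATURE = 4.0  # sigma(alpha * 0.5) ~ 0.88 for half-supported events


@dataclass
class MaskResult:
    mask: np.ndarray
    masked: np.ndarray
    confidence: np.ndarray
    rejection_fraction: float
    dropped_values: dict[int, float] = field(default_factory=dict)


def _check_square(R: np.ndarray, n: int) -> np.ndarray:
    R = np.asarray(R)
    if R.shape != (n, n):
        raise ValueError(f"relation matrix shape {R.shape} does not match state length {n}")
    return R


def hard_mask(x: np.ndarray, R: np.ndarray, values: dict[int, float] | None = None) -> MaskResult:
    """Keep active events with at least one related active partner.

    ``m_i = 1`` iff ``x_i = 1`` and ``sum_{j active} R_ij > 0``.  The relation
    matrix diagonal is ignored (forced to zero) so an event cannot support
    itself.  An empty state is passed through unchanged with a warning.
    Values attached to masked-out events are reported in ``dropped_values``.
    """
    x = np.asarray(x)
    n = x.shape[0]
    R = _check_square(R, n).copy()
    np.fill_diagonal(R, 0)
    n_active = int((x > 0).sum())
    if n_active == 0:
        warnings.warn("empty clinical state: masking skipped", stacklevel=2)
        return MaskResult(np.zeros(n, dtype=np.int8), x.copy(), np.zeros(n), 0.0)
    support = R @ (x > 0).astype(float)
    m = ((x > 0) & (support > 0)).astype(np.int8)
    masked = (x * m).astype(x.dtype)
    s = relational_confidence(x, R)
    dropped = {i: v for i, v in (values or {}).items() if m[i] == 0}
    rej = float((n_active - m.sum()) / n_active)
    return MaskResult(m, masked, s, rej, dropped)


def relational_confidence(x: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Normalized relational confidence ``s_i = (1/‖x‖₁) Σ_j R_ij x_j``.

    For an all-zero state the convention is ``s = 0`` (the normalizing count
    is zero).
    """
    x = np.asarray(x, dtype=float)
    R = _check_square(R, x.shape[0])
    norm = x.sum()
    if norm == 0:
        return np.zeros_like(x)
    return (R.astype(float) @ x) / norm


def soft_mask(x: np.ndarray, s: np.ndarray, alpha: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Differentiable gate ``x̃_i = x_i · σ(α s_i)`` with temperature α ≥ 0."""
    if alpha < 0:
        raise ValueError(f"temperature must be nonnegative, got {alpha}")
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    return x / (1.0 + np.exp(-alpha * s))


def typed_mask(
    x: np.ndarray,
    R: np.ndarray,
    type_matrix: np.ndarray,
    values: dict[int, float] | None = None,
) -> MaskResult:
    """Hard mask with same-type support: a kept event needs an active related
    partner of its own semantic type.

    ``m_i = 1`` iff some active ``j`` has ``R_ij = 1`` and ``type(i) ==
    type(j)``.  The result is elementwise ≤ the plain hard mask.
    """
    x = np.asarray(x)
    n = x.shape[0]
    R = _check_square(R, n).copy()
    np.fill_diagonal(R, 0)
    Tm = np.asarray(type_matrix)
    if Tm.shape[0] != n:
        raise ValueError(f"type matrix has {Tm.shape[0]} rows, state has length {n}")
    if not np.all(Tm.sum(axis=1) == 1):
        raise ValueError("type matrix rows must be one-hot")
    n_active = int((x > 0).sum())
    if n_active == 0:
        warnings.warn("empty clinical state: masking skipped", stacklevel=2)
        return MaskResult(np.zeros(n, dtype=np.int8), x.copy(), np.zeros(n), 0.0)
    same_type = (Tm @ Tm.T).astype(bool)
    support = (R.astype(bool) & same_type) @ (x > 0).astype(float)
    m = ((x > 0) & (support > 0)).astype(np.int8)
    masked = (x * m).astype(x.dtype)
    s = relational_confidence(x, R)
    dropped = {i: v for i, v in (values or {}).items() if m[i] == 0}
    rej = float((n_active - m.sum()) / n_active)
    return MaskResult(m, masked, s, rej, dropped)
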