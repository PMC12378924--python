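"""Population-level embedding adaptation.

The patient–event occurrence matrix ``B`` (binary, |P|×|E|) is factorized as
``B ≈ U Vᵀ`` by alternating least squares under ridge penalties and a
Laplacian smoothness term ``λ Tr(VᵀLV)`` over an event–event co-occurrence
graph whose edge weights are the normalized mutual information between event
occurrence columns.  A ridge projection aligns the adapted event embeddings
with optional pre-trained vectors.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log(p) - (1 - p) * np.log(1 - p))


def cooccurrence_nmi(B: np.ndarray) -> np.ndarray:
    """Event co-occurrence graph weighted by normalized mutual information.

    ``G[i, j] = MI(B·i, B·j) / sqrt(H(B·i) H(B·j))`` with plug-in (maximum
    likelihood) entropies over patients.  Constant columns (zero entropy)
    contribute 0 by convention; the diagonal is zero.  Values lie in [0, 1]
    and the matrix is symmetric.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] < 2:
        raise ValueError("need a 2-d occurrence matrix with at least 2 patients")
    n, m = B.shape
    p1 = B.mean(axis=0)
    H = np.array([_binary_entropy(p) for p in p1])
    # joint probabilities of (1,1) for all pairs
    P11 = (B.T @ B) / n
    G = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if H[i] <= 0 or H[j] <= 0:
                continue
            pi, pj, pij = p1[i], p1[j], P11[i, j]
            cells = (
                (pij, pi * pj),
                (pi - pij, pi * (1 - pj)),
                (pj - pij, (1 - pi) * pj),
                (1 - pi - pj + pij, (1 - pi) * (1 - pj)),
            )
            mi = sum(p * np.log(p / q) for p, q in cells if p > 1e-15 and q > 0)
            val = max(0.0, float(mi)) / np.sqrt(H[i] * H[j])
            G[i, j] = G[j, i] = min(1.0, val)
    return G


def laplacian_smoothness(V: np.ndarray, L: np.ndarray) -> float:
    """Smoothness penalty ``Tr(VᵀLV) = ½ Σ_ij G_ij ‖v_i − v_j‖²``."""
    V = np.asarray(V, dtype=float)
    L = np.asarray(L, dtype=float)
    if L.shape != (V.shape[0], V.shape[0]):
        raise ValueError(f"Laplacian shape {L.shape} does not match V rows {V.shape[0]}")
    return float(np.trace(V.T @ L @ V))


def _mf_objective(B, U, V, gamma, lam, L) -> float:
    rec = float(np.sum((B - U @ V.T) ** 2))
    reg = gamma * (float(np.sum(U**2)) + float(np.sum(V**2)))
    smooth = lam * laplacian_smoothness(V, L) if lam > 0 else 0.0
    return rec + reg + smooth


class GraphRegularizedMF(BaseEstimator):
    """Laplacian-regularized matrix factorization of a binary occurrence matrix.

    Minimizes ``‖B − UVᵀ‖² + γ(‖U‖² + ‖V‖²) + λ Tr(VᵀLV)`` by alternating
    least squares.  The U-step is ridge regression; the V-step solves the
    Sylvester-type system ``λLV + V(UᵀU + γI) = BᵀU``.  Both steps are exact
    minimizers of their subproblem, so the objective is non-increasing at
    every half-iteration.

    Attributes
    ----------
    U_ : (|P|, d) patient factors.
    V_ : (|E|, d) event factors.
    objective_trace_ : objective after every half-iteration.
    n_iter_ : number of full ALS iterations run.
    """

    def __init__(
        self,
        n_components: int = 8,
        gamma: float = 1e-6,
        lam: float = 0.0,
        max_iter: int = 500,
        tol: float = 1e-8,
        seed: int = 0,
    ):
        self.n_components = n_components
        self.gamma = gamma
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, B: np.ndarray, laplacian: np.ndarray | None = None) -> "GraphRegularizedMF":
        B = np.asarray(B, dtype=float)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        nP, nE = B.shape
        d = self.n_components
        L = np.zeros((nE, nE)) if laplacian is None else np.asarray(laplacian, dtype=float)
        rng = np.random.default_rng(self.seed)
        scale = 1.0 / np.sqrt(d)
        U = rng.uniform(-scale, scale, size=(nP, d))
        V = rng.uniform(-scale, scale, size=(nE, d))
        trace = [_mf_objective(B, U, V, self.gamma, self.lam, L)]
        eye = np.eye(d)
        for it in range(self.max_iter):
            # U-step: ridge regression rows
            A = V.T @ V + self.gamma * eye
            try:
                U = np.linalg.solve(A, V.T @ B.T).T
            except np.linalg.LinAlgError:
                raise ValueError("singular normal equations; use gamma > 0") from None
            if self.gamma == 0 and np.linalg.cond(A) > 1e12:
                raise ValueError("near-singular normal equations; use gamma > 0")
            trace.append(_mf_objective(B, U, V, self.gamma, self.lam, L))
            # V-step: Sylvester-type solve  lam*L V + V (UᵀU + γI) = BᵀU
            A2 = U.T @ U + self.gamma * eye
            rhs = B.T @ U
            if self.lam > 0:
                V = scipy.linalg.solve_sylvester(self.lam * L, A2, rhs)
            else:
                try:
                    V = np.linalg.solve(A2, rhs.T).T
                except np.linalg.LinAlgError:
                    raise ValueError("singular normal equations; use gamma > 0") from None
            trace.append(_mf_objective(B, U, V, self.gamma, self.lam, L))
            self.n_iter_ = it + 1
            prev, cur = trace[-3], trace[-1]
            if prev > 0 and abs(prev - cur) / max(prev, 1e-300) < self.tol:
                break
            if prev == 0.0:
                break
        self.U_, self.V_ = U, V
        self.objective_trace_ = trace
        self.objective_ = trace[-1]
        return self


def factorize(
    B: np.ndarray,
    d: int,
    gamma: float,
    lam: float = 0.0,
    laplacian: np.ndarray | None = None,
    seed: int = 0,
    max_iter: int = 500,
):
    """Functional wrapper over :class:`GraphRegularizedMF`; returns (U, V, trace)."""
    est = GraphRegularizedMF(n_components=d, gamma=gamma, lam=lam, seed=seed, max_iter=max_iter)
    est.fit(B, laplacian)
    return est.U_, est.V_, est.objective_trace_


def align_projection(V: np.ndarray, V_pre: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge alignment ``W = (VᵀV + αI)⁻¹ Vᵀ V_pre``.

    The unique minimizer of ``‖VW − V_pre‖² + α‖W‖²`` for α > 0.  With
    α = 0 a rank-deficient ``V`` is rejected.
    """
    V = np.asarray(V, dtype=float)
    V_pre = np.asarray(V_pre, dtype=float)
    if V.shape[0] != V_pre.shape[0]:
        raise ValueError(f"row counts differ: V has {V.shape[0]}, V_pre has {V_pre.shape[0]}")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    G = V.T @ V + alpha * np.eye(V.shape[1])
    if alpha == 0 and np.linalg.matrix_rank(V) < V.shape[1]:
        raise ValueError("V is rank-deficient; use alpha > 0")
    return np.linalg.solve(G, V.T @ V_pre)


def occurrence_matrix(cohort, n_concepts: int) -> np.ndarray:
    """Binary |P|×|E| matrix: patient experienced event at any visit."""
    B = np.zeros((len(cohort), n_concepts), dtype=np.int8)
    for i, p in enumerate(cohort):
        for st in p.states:
            B[i, st.active()] = 1
    return B
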