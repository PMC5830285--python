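"""ℓ2,1-ℓq multikernel multitask regression over PSD matrices.

This solver couples tasks *in the kernel-induced feature spaces*: each
kernel j carries a learned symmetric PSD matrix Q_j (acting on the
kernel's empirical feature coordinates) subject to the mixed trace
constraint

    Q_j >= 0,    sum_j tr(Q_j)^qbar <= 1,      qbar = q/(2-q),  q in [1, 2).

Explicit feature maps are never materialised: with the eigendecomposition
G_j = V_j S_j^2 V_j^T of the pooled (unit-trace) training Gram, the maps
M_tj = S_j^{-1} V_j^T G_j[:, rows_t] carry each task's samples into the
kernel's r_j-dimensional empirical feature coordinates, and

    alpha_t = -(sum_j M_tj^T Q_j M_tj + I/lam)^{-1} y_t

is again a kernel-ridge-type solve.  The outer problem min_Q f(Q) is
solved by projected subgradient (a Euclidean mirror-descent instance):
gradient blocks -B_j/2 with B_j = sum_t M_tj alpha_t alpha_t^T M_tj^T,
step size step0/sqrt(l), Euclidean projection = PSD eigenvalue clip plus
closed-form trace rescale, with best-iterate tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh

from .data import MultitaskDataset
from .kernels import KernelPool

__all__ = [
    "KernelFactor",
    "L21LqModel",
    "factor_kernels",
    "solve_alpha_q",
    "objective_and_gradient",
    "project_Q",
    "fit_l21lq",
    "predict_l21lq",
]


@dataclass
class KernelFactor:
    """Eigendecomposition of one pooled Gram and the induced task maps."""

    eigvals: np.ndarray            # retained eigenvalues (S^2), descending
    eigvecs: np.ndarray            # matching eigenvectors, columns
    rank: int
    maps: list[np.ndarray]         # M_tj, each r_j x m_t

    def embed(self, cross_cols: np.ndarray) -> np.ndarray:
        """Embed new points given their Gram columns against training rows."""
        return (self.eigvecs.T @ cross_cols) / np.sqrt(self.eigvals)[:, None]


@dataclass
class L21LqModel:
    Q: list[np.ndarray]
    alpha: list[np.ndarray]
    lam: float
    q: float
    qbar: float
    factors: list[KernelFactor]
    task_rows: list[np.ndarray]
    pool: KernelPool
    objective_trace: list[float] = field(default_factory=list)
    best_objective: float = np.inf
    n_iter: int = 0


def _feature_qbar(q: float) -> float:
    if not (1.0 <= q < 2.0):
        raise ValueError(f"q must lie in [1, 2) so that q/(2-q) is finite; got {q}")
    return q / (2.0 - q)


def factor_kernels(
    pool: KernelPool,
    task_rows: list[np.ndarray],
    rank_tol: float = 1e-10,
) -> list[KernelFactor]:
    """Factor each pooled Gram and build the per-task maps M_tj.

    Eigenvalues below ``rank_tol`` times the largest are discarded to keep
    S^{-1} well-conditioned.  The reconstruction identity
    M_tj^T M_t'j = G_j[rows_t, rows_t'] holds up to the truncation level.
    """
    factors = []
    for j in range(pool.k):
        G = pool.gram_train[j]
        w, V = eigh(G)
        if w[0] < -1e-8 * max(1.0, w[-1]):
            raise ValueError(f"Gram {j} is not PSD (min eig {w[0]:.3g})")
        keep = w > rank_tol * w[-1]
        w, V = w[keep][::-1], V[:, keep][:, ::-1]
        inv_s = 1.0 / np.sqrt(w)
        shared = all(
            len(rows) == len(task_rows[0]) and np.array_equal(rows, task_rows[0])
            for rows in task_rows
        )
        if shared:
            M0 = inv_s[:, None] * (V.T @ G[:, task_rows[0]])
            maps = [M0] * len(task_rows)     # identical object => shared fast path
        else:
            maps = [inv_s[:, None] * (V.T @ G[:, rows]) for rows in task_rows]
        factors.append(KernelFactor(eigvals=w, eigvecs=V, rank=len(w), maps=maps))
    return factors


def _maps_shared(factors: list[KernelFactor]) -> bool:
    """True when every task uses the same sample rows (fully observed Y),
    in which case all tasks share one system matrix per Q."""
    return all(all(M is f.maps[0] for M in f.maps) for f in factors)


def _system_matrices(factors, Q, lam, T, m_per_task, shared):
    """A_t = sum_j M_tj^T Q_j M_tj + I/lam, assembled once when shared."""
    if shared:
        m = m_per_task[0]
        A = np.eye(m) / lam
        for f, Qj in zip(factors, Q):
            M = f.maps[0]
            A += M.T @ (Qj @ M)
        A = 0.5 * (A + A.T)
        return [A] * T
    mats = []
    for t in range(T):
        A = np.eye(m_per_task[t]) / lam
        for f, Qj in zip(factors, Q):
            M = f.maps[t]
            A += M.T @ (Qj @ M)
        mats.append(0.5 * (A + A.T))
    return mats


def solve_alpha_q(
    factors: list[KernelFactor],
    Q: list[np.ndarray],
    lam: float,
    y: list[np.ndarray],
) -> list[np.ndarray]:
    """alpha_t = -(sum_j M_tj^T Q_j M_tj + I/lam)^{-1} y_t via SPD solve."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    T = len(y)
    shared = _maps_shared(factors) and len({len(yt) for yt in y}) == 1
    mats = _system_matrices(factors, Q, lam, T, [len(yt) for yt in y], shared)
    if shared:
        c, low = cho_factor(mats[0], check_finite=False)
        return [-cho_solve((c, low), yt, check_finite=False) for yt in y]
    alpha = []
    for t in range(T):
        c, low = cho_factor(mats[t], check_finite=False)
        alpha.append(-cho_solve((c, low), y[t], check_finite=False))
    return alpha


def objective_and_gradient(
    factors: list[KernelFactor],
    Q: list[np.ndarray],
    lam: float,
    y: list[np.ndarray],
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """f(Q) at the optimal alpha, with subgradient blocks -B_j/2.

    Returns (f, grad blocks, alpha).  By the envelope argument alpha is
    held fixed at its optimum when differentiating, so
    grad_j = -1/2 sum_t M_tj alpha_t alpha_t^T M_tj^T.
    """
    T = len(y)
    shared = _maps_shared(factors) and len({len(yt) for yt in y}) == 1
    mats = _system_matrices(factors, Q, lam, T, [len(yt) for yt in y], shared)
    if shared:
        c, low = cho_factor(mats[0], check_finite=False)
        alpha = [-cho_solve((c, low), yt, check_finite=False) for yt in y]
    else:
        alpha = []
        for t in range(T):
            c, low = cho_factor(mats[t], check_finite=False)
            alpha.append(-cho_solve((c, low), y[t], check_finite=False))
    f = 0.0
    for t, a in enumerate(alpha):
        quad = a @ (mats[t] @ a) - (a @ a) / lam     # alpha^T (sum_j M^T Q M) alpha
        f += -a @ y[t] - 0.5 * quad - (a @ a) / (2.0 * lam)
    grads = []
    if shared:
        Amat = np.column_stack(alpha)                # m x T
        for fac in factors:
            MA = fac.maps[0] @ Amat                  # r x T
            grads.append(-0.5 * (MA @ MA.T))
    else:
        for fac in factors:
            B = np.zeros((fac.rank, fac.rank))
            for t, a in enumerate(alpha):
                Ma = fac.maps[t] @ a
                B += np.outer(Ma, Ma)
            grads.append(-0.5 * B)
    return float(f), grads, alpha


def project_Q(Q_raw: list[np.ndarray], qbar: float) -> list[np.ndarray]:
    """Euclidean projection onto {Q_j >= 0, sum_j tr(Q_j)^qbar <= 1}:
    clip negative eigenvalues, then rescale all blocks by the closed-form
    constant c = (sum_j tr(Q_j)^qbar)^{-1/qbar} if the constraint is violated."""
    out = []
    for Qr in Q_raw:
        Qs = 0.5 * (Qr + Qr.T)
        # fast path: a Cholesky of Q + eps*I succeeding certifies PSD-ness
        # (descent steps add a PSD matrix, so the clip is usually a no-op)
        if not _is_psd(Qs):
            w, V = eigh(Qs)
            Qs = (V * np.maximum(w, 0.0)) @ V.T
        out.append(Qs)
    traces = np.array([max(np.trace(Qj), 0.0) for Qj in out])
    total = float(np.sum(traces ** qbar))
    if total > 1.0:
        c = total ** (-1.0 / qbar)
        out = [c * Qj for Qj in out]
    return out


def _is_psd(Q: np.ndarray, shift: float = 1e-9) -> bool:
    """Certify min eigenvalue >= -shift via a shifted Cholesky attempt."""
    try:
        cho_factor(Q + shift * np.eye(Q.shape[0]), check_finite=False)
        return True
    except np.linalg.LinAlgError:
        return False


def _check_feasible(Q: list[np.ndarray], qbar: float) -> None:
    for Qj in Q:
        if not _is_psd(Qj):
            raise AssertionError("Q block lost positive semidefiniteness")
    total = float(np.sum(np.array([np.trace(Qj) for Qj in Q]) ** qbar))
    if total > 1.0 + 1e-9:
        raise AssertionError(f"trace constraint violated: {total}")


def fit_l21lq(
    ds: MultitaskDataset,
    pool: KernelPool,
    q: float = 1.5,
    lam: float = 1.0,
    max_outer: int = 200,
    step0: float | None = None,
    tol: float = 1e-6,
    rank_tol: float = 1e-10,
) -> L21LqModel:
    """Projected-subgradient outer loop with best-iterate return.

    ``step0=None`` picks the initial step by a 3-point heuristic on the
    first gradient (candidates scaled by the gradient norm).  Stops at
    ``max_outer`` or when the best objective improves by less than ``tol``
    (relative) over a 10-iteration window.  Deterministic.
    """
    qbar = _feature_qbar(q)
    T = ds.T
    task_rows = [ds.task_rows(t) for t in range(T)]
    y = [ds.Y[rows, t] for t, rows in enumerate(task_rows)]
    factors = factor_kernels(pool, task_rows, rank_tol=rank_tol)
    # uniform feasible start on the constraint boundary: Q_j = c I_{r_j}
    ranks = np.array([f.rank for f in factors], float)
    c0 = float(np.sum(ranks ** qbar)) ** (-1.0 / qbar)
    Q = [c0 * np.eye(f.rank) for f in factors]
    f_val, grads, alpha = objective_and_gradient(factors, Q, lam, y)
    best_f, best_Q, best_alpha = f_val, [Qj.copy() for Qj in Q], alpha
    trace = [f_val]
    if step0 is None:
        gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
        best_cand, step0 = np.inf, 1.0
        for s in (0.01, 0.1, 1.0):
            cand = project_Q([Qj - (s / max(gnorm, 1e-12)) * g
                              for Qj, g in zip(Q, grads)], qbar)
            fc, _, _ = objective_and_gradient(factors, cand, lam, y)
            if fc < best_cand:
                best_cand, step0 = fc, s / max(gnorm, 1e-12)
    it = 0
    for it in range(1, max_outer + 1):
        eta = step0 / np.sqrt(it)
        Q = project_Q([Qj - eta * g for Qj, g in zip(Q, grads)], qbar)
        _check_feasible(Q, qbar)
        f_val, grads, alpha = objective_and_gradient(factors, Q, lam, y)
        trace.append(f_val)
        if f_val < best_f:
            best_f, best_Q, best_alpha = f_val, [Qj.copy() for Qj in Q], alpha
        if it >= 10:
            window = min(trace[-10:])
            past = min(trace[:-10]) if len(trace) > 10 else trace[0]
            if past - window < tol * max(1.0, abs(past)):
                break
    return L21LqModel(Q=best_Q, alpha=best_alpha, lam=lam, q=q, qbar=qbar,
                      factors=factors, task_rows=task_rows, pool=pool,
                      objective_trace=trace, best_objective=best_f, n_iter=it)


def predict_l21lq(model: L21LqModel, X_new: np.ndarray) -> np.ndarray:
    """f_t(x) = -sum_j M_j(x)^T Q_j M_tj alpha_t with M_j(x) the embedded
    test point (training-trace-scaled Gram columns through the factor)."""
    cross = model.pool.gram_cross(X_new)           # [n_new x m] per kernel
    n_new = cross[0].shape[0]
    T = len(model.alpha)
    out = np.zeros((n_new, T))
    for j, fac in enumerate(model.factors):
        Mx = fac.embed(cross[j].T)                 # r_j x n_new
        QM = model.Q[j] @ Mx                       # r_j x n_new
        for t, a in enumerate(model.alpha):
            out[:, t] -= QM.T @ (fac.maps[t] @ a)
    return out
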