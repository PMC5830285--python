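"""ℓq,1 multikernel multitask regression (simplex kernel weights + dual-norm
task weights), solved by alternating closed-form block updates.

The model combines k base kernels with simplex weights mu and couples the
T tasks through nonnegative dual-norm weights nu_j in Delta_{T, qbar},
qbar = q/(q-2) (well-posed for q > 2; q = 2 is the degenerate limit with
uniform nu).  At fixed weights the per-task dual variables alpha_t solve
a kernel ridge system

    alpha_t = -(Ktilde_t + I/lam)^{-1} y_t,   Ktilde_t = sum_j mu_j nu_jt K_tj,

and predictions are f_t(x) = -sum_j mu_j nu_jt sum_i alpha_ti k_j(x_ti, x);
the single-kernel single-task case therefore reduces exactly to kernel
ridge regression with ridge 1/lam.

Block updates (both attainment conditions of the variational bounds, so
no inner iterative solver is needed):

* nu_j  maximizes  sum_t nu_jt a_jt  over Delta_{T,qbar}  with
  a_jt = alpha_t^T (mu_j K_tj) alpha_t, giving nu_jt ∝ a_jt^{1/(qbar-1)}
  normalized onto the qbar-sphere;
* mu_j = sqrt(b_j) / sum_i sqrt(b_i) with b_j = sum_t nu_jt alpha_t^T K_tj
  alpha_t (the r = 1 closed form of the simplex minimization lemma).

An entropic mirror-descent path for mu is available behind a flag as a
fidelity check of the closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import MultitaskDataset
from .kernels import KernelPool

__all__ = [
    "SimplexWeights",
    "DualNormWeights",
    "MKMTLModel",
    "lemma1_minimizer",
    "solve_alpha",
    "update_nu",
    "update_mu",
    "fit_mkmtl",
    "predict_mkmtl",
]

_FEAS_TOL = 1e-9


@dataclass
class SimplexWeights:
    """Kernel combination weights mu on the probability simplex."""

    mu: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.check()

    def check(self) -> None:
        if np.any(self.mu < -_FEAS_TOL) or abs(self.mu.sum() - 1.0) > 1e-10:
            raise AssertionError(f"mu left the simplex: {self.mu}")


@dataclass
class DualNormWeights:
    """Task coupling weights; row j lies in Delta_{T,qbar}:
    nu_jt >= 0 and sum_t nu_jt^qbar <= 1."""

    nu: np.ndarray
    qbar: float

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, float)
        self.check()

    def check(self) -> None:
        if np.any(self.nu < -_FEAS_TOL):
            raise AssertionError("negative nu entry")
        if np.isfinite(self.qbar):
            norms = np.sum(self.nu ** self.qbar, axis=1)
            if np.any(norms > 1.0 + _FEAS_TOL):
                raise AssertionError(f"nu row left Delta_T,qbar: norms {norms}")
        else:
            if np.any(self.nu > 1.0 + _FEAS_TOL):
                raise AssertionError("nu entry above 1 with qbar = inf")


@dataclass
class MKMTLModel:
    alpha: list[np.ndarray]
    mu: SimplexWeights
    nu: DualNormWeights
    lam: float
    q: float
    pool: KernelPool
    task_rows: list[np.ndarray]
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _task_qbar(q: float) -> float:
    """Exponent of the task-weight constraint set: qbar = q/(q-2), q > 2."""
    if q == 2.0:
        return np.inf
    if np.isinf(q):
        return 1.0
    if q <= 2.0:
        raise ValueError(f"task coupling exponent q/(q-2) requires q > 2 (or q = 2 "
                         f"as the uniform limit); got q={q}")
    return q / (q - 2.0)


def lemma1_minimizer(a: np.ndarray, r: float) -> tuple[np.ndarray, float]:
    """Closed-form minimizer of sum_i a_i / eta_i over Delta_{d,r}.

    Returns (eta, min value): eta_i = a_i^{1/(r+1)} / (sum a^{r/(r+1)})^{1/r}
    and value (sum_i a_i^{r/(r+1)})^{(r+1)/r}.  Zero entries of ``a`` get
    eta_i = 0 under the a/0 := 0 convention.
    """
    a = np.asarray(a, float)
    if np.any(a < 0):
        raise ValueError("entries of a must be nonnegative")
    if r < 1:
        raise ValueError("r must be >= 1")
    s = float(np.sum(a ** (r / (r + 1.0))))
    if s == 0.0:
        return np.zeros_like(a), 0.0
    eta = a ** (1.0 / (r + 1.0)) / s ** (1.0 / r)
    return eta, s ** ((r + 1.0) / r)


def _task_gram_stacks(pool: KernelPool, task_rows: list[np.ndarray]) -> list[np.ndarray]:
    """Per-task stacks K_t of shape (k, m_t, m_t); the full shared stack is
    reused (no copies) when every task observes every sample."""
    Kstack = np.stack(pool.gram_train)
    m = pool.m
    out = []
    for rows in task_rows:
        if len(rows) == m:
            out.append(Kstack)
        else:
            out.append(Kstack[:, rows][:, :, rows])
    return out


def _quad_forms_from_stacks(Ktask: list[np.ndarray],
                            alpha: list[np.ndarray]) -> np.ndarray:
    """c[j, t] = alpha_t^T K_tj alpha_t (all nonnegative up to roundoff)."""
    k = Ktask[0].shape[0]
    T = len(alpha)
    c = np.empty((k, T))
    for t, a in enumerate(alpha):
        KA = Ktask[t] @ a            # (k, m_t)
        c[:, t] = KA @ a
    return np.maximum(c, 0.0)


def _quad_forms(pool: KernelPool, task_rows: list[np.ndarray],
                alpha: list[np.ndarray]) -> np.ndarray:
    return _quad_forms_from_stacks(_task_gram_stacks(pool, task_rows), alpha)


def _solve_alpha_from_stacks(Ktask: list[np.ndarray], mu: SimplexWeights,
                             nu: DualNormWeights, lam: float,
                             y: list[np.ndarray]) -> list[np.ndarray]:
    alpha = []
    for t, yt in enumerate(y):
        m_t = len(yt)
        w = mu.mu * nu.nu[:, t]
        Kt = np.tensordot(w, Ktask[t], axes=(0, 0))
        A = Kt + np.eye(m_t) / lam
        try:
            c, low = cho_factor(A, check_finite=False)
        except np.linalg.LinAlgError:
            warnings.warn("ill-conditioned dual system; adding 1e-10 jitter")
            c, low = cho_factor(A + 1e-10 * np.eye(m_t), check_finite=False)
        alpha.append(-cho_solve((c, low), yt, check_finite=False))
    return alpha


def solve_alpha(pool: KernelPool, mu: SimplexWeights, nu: DualNormWeights,
                lam: float, y: list[np.ndarray],
                task_rows: list[np.ndarray]) -> list[np.ndarray]:
    """Per-task dual solve alpha_t = -(Ktilde_t + I/lam)^{-1} y_t via Cholesky."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    return _solve_alpha_from_stacks(_task_gram_stacks(pool, task_rows),
                                    mu, nu, lam, y)


def update_nu(pool: KernelPool, mu: SimplexWeights, alpha: list[np.ndarray],
              q: float, task_rows: list[np.ndarray],
              quad: np.ndarray | None = None) -> DualNormWeights:
    """Dual-norm attainment: nu_j maximizes sum_t nu_jt a_jt over Delta_{T,qbar}."""
    qbar = _task_qbar(q)
    c = _quad_forms(pool, task_rows, alpha) if quad is None else quad
    a = mu.mu[:, None] * c
    k, T = a.shape
    if not np.isfinite(qbar):            # q = 2 degenerate limit: uniform nu
        return DualNormWeights(np.ones((k, T)), qbar)
    nu = np.empty((k, T))
    for j in range(k):
        row = a[j]
        if row.max() <= 0.0:
            nu[j] = T ** (-1.0 / qbar)   # uniform on the boundary
        elif qbar == 1.0:
            nu[j] = (row == row.max()) / np.count_nonzero(row == row.max())
        else:
            w = row ** (1.0 / (qbar - 1.0))
            nu[j] = w / float(np.sum(w ** qbar)) ** (1.0 / qbar)
    return DualNormWeights(nu, qbar)


def update_mu(pool: KernelPool, nu: DualNormWeights, alpha: list[np.ndarray],
              task_rows: list[np.ndarray],
              quad: np.ndarray | None = None) -> SimplexWeights:
    """Simplex attainment (lemma with r = 1): mu_j ∝ sqrt(b_j)."""
    c = _quad_forms(pool, task_rows, alpha) if quad is None else quad
    b = np.sum(nu.nu * c, axis=1)
    if b.max() <= 0.0:
        return SimplexWeights(np.full(pool.k, 1.0 / pool.k))
    eta, _ = lemma1_minimizer(b, r=1.0)
    return SimplexWeights(eta / eta.sum())


def _mirror_mu_step(mu: np.ndarray, grad: np.ndarray, step: float) -> np.ndarray:
    """One entropic mirror-descent step on the simplex."""
    g = grad - grad.max()
    w = mu * np.exp(-step * g)
    return w / w.sum()


def _primal_objective(pool: KernelPool, task_rows, alpha, mu, nu, q, lam,
                      quad: np.ndarray | None = None) -> float:
    """Kernelized value of the primal objective at the implied weights:
    (1/2)(sum_j (sum_t ||th_tj||^q)^{1/q})^2 + ||alpha||^2/(2 lam), where
    ||th_tj||^2 = mu_j^2 nu_jt^2 alpha_t^T K_tj alpha_t."""
    c = _quad_forms(pool, task_rows, alpha) if quad is None else quad
    norms = mu.mu[:, None] * nu.nu * np.sqrt(c)     # ||th_tj||_2, shape (k, T)
    if np.isinf(q):
        per_kernel = norms.max(axis=1)
    else:
        per_kernel = np.sum(norms ** q, axis=1) ** (1.0 / q)
    reg = 0.5 * float(np.sum(per_kernel)) ** 2
    loss = sum(float(a @ a) for a in alpha) / (2.0 * lam)
    return reg + loss


def fit_mkmtl(
    ds: MultitaskDataset,
    pool: KernelPool,
    q: float = 3.0,
    lam: float = 1.0,
    max_outer: int = 100,
    tol: float = 1e-7,
    mu_update: str = "closed_form",
    mirror_step: float = 1.0,
) -> MKMTLModel:
    """Alternate alpha-solve -> nu-update -> mu-update until the primal
    objective stabilises.  Deterministic: mu starts uniform, nu uniform on
    the Delta_{T,qbar} boundary."""
    if mu_update not in {"closed_form", "mirror"}:
        raise ValueError("mu_update must be 'closed_form' or 'mirror'")
    qbar = _task_qbar(q)
    k, T = pool.k, ds.T
    task_rows = [ds.task_rows(t) for t in range(T)]
    y = [ds.Y[rows, t] for t, rows in enumerate(task_rows)]
    mu = SimplexWeights(np.full(k, 1.0 / k))
    nu0 = np.ones((k, T)) if not np.isfinite(qbar) else np.full((k, T), T ** (-1.0 / qbar))
    nu = DualNormWeights(nu0, qbar)
    trace: list[float] = []
    Ktask = _task_gram_stacks(pool, task_rows)
    alpha = _solve_alpha_from_stacks(Ktask, mu, nu, lam, y)
    increases = 0
    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        c = _quad_forms_from_stacks(Ktask, alpha)
        nu = update_nu(pool, mu, alpha, q, task_rows, quad=c)
        if mu_update == "closed_form":
            mu = update_mu(pool, nu, alpha, task_rows, quad=c)
        else:
            grad = -0.5 * np.sum(nu.nu * c, axis=1)
            # diminishing step keeps the entropic path from collapsing onto
            # a vertex before the alternation settles
            mu = SimplexWeights(_mirror_mu_step(mu.mu, grad,
                                                mirror_step / np.sqrt(it)))
        mu.check()
        nu.check()
        alpha = _solve_alpha_from_stacks(Ktask, mu, nu, lam, y)
        obj = _primal_objective(pool, task_rows, alpha, mu, nu, q, lam,
                                quad=_quad_forms_from_stacks(Ktask, alpha))
        if trace:
            if obj > trace[-1] + 1e-9 * max(1.0, abs(trace[-1])):
                increases += 1
                if increases >= 3:
                    warnings.warn(
                        f"objective non-decreasing for 3 outer iterations; "
                        f"trace tail {trace[-3:] + [obj]}"
                    )
                    increases = 0
            else:
                increases = 0
            rel = abs(trace[-1] - obj) / max(1.0, abs(trace[-1]))
            trace.append(obj)
            if rel < tol:
                converged = True
                break
        else:
            trace.append(obj)
    return MKMTLModel(alpha=alpha, mu=mu, nu=nu, lam=lam, q=q, pool=pool,
                      task_rows=task_rows, objective_trace=trace,
                      n_iter=it, converged=converged)


def predict_mkmtl(model: MKMTLModel, X_new: np.ndarray) -> np.ndarray:
    """Predictions f_t(x) = -sum_j mu_j nu_jt sum_i alpha_ti k_j(x_ti, x)."""
    cross = model.pool.gram_cross(X_new)       # list of [n_new x m]
    n_new = cross[0].shape[0]
    T = len(model.alpha)
    out = np.zeros((n_new, T))
    for t, rows in enumerate(model.task_rows):
        acc = np.zeros(n_new)
        for j in range(model.pool.k):
            w = model.mu.mu[j] * model.nu.nu[j, t]
            if w != 0.0:
                acc += w * (cross[j][:, rows] @ model.alpha[t])
        out[:, t] = -acc
    return out
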