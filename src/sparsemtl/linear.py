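"""Linear ℓq,1-regularized multitask regression by accelerated proximal gradient.

Solves

    min_Theta  (1/2) ||Y - X Theta||_F^2  +  lam * sum_h ||theta_h.||_q

with a monotone accelerated proximal-gradient scheme: search points are
affine combinations of successive iterates, the step is the ℓq,1
projection of a gradient step, and the local curvature constant L is
found by an Armijo-Goldstein style doubling line search.  The monotone
variant keeps the better of the prox point and the previous iterate, so
the recorded objective trace never increases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import MultitaskDataset, ParameterMatrix
from .prox import ProxConfig, dual_exponent, project_matrix_lq1

__all__ = [
    "LinearSolverState",
    "objective",
    "gradient",
    "fit_lq1_mtl",
    "predict_linear",
    "save_linear_model",
    "load_linear_model",
]


@dataclass
class LinearSolverState:
    """Bookkeeping of the accelerated solve (iterates, line-search constant,
    momentum coefficient, objective trace)."""

    theta_curr: ParameterMatrix
    theta_prev: ParameterMatrix
    search_point: np.ndarray
    L_curr: float
    beta: float
    objective_trace: list[float] = field(default_factory=list)
    iteration: int = 0
    converged: bool = False


def _check_shapes(ds: MultitaskDataset, theta: np.ndarray) -> None:
    if theta.shape != (ds.p, ds.T):
        raise ValueError(f"theta shape {theta.shape} does not match (p={ds.p}, T={ds.T})")


def _penalty(theta: np.ndarray, q: float) -> float:
    if np.isinf(q):
        return float(np.abs(theta).max(axis=1).sum())
    return float(np.sum(np.linalg.norm(theta, q, axis=1)))


def objective(ds: MultitaskDataset, theta: ParameterMatrix | np.ndarray,
              q: float, lam: float) -> float:
    """Composite objective (1/2)||Y - X Theta||_F^2 + lam * sum_h ||theta_h.||_q."""
    th = theta.theta if isinstance(theta, ParameterMatrix) else np.asarray(theta, float)
    _check_shapes(ds, th)
    if not ds.is_complete():
        raise ValueError("linear solver requires a fully observed Y")
    resid = ds.Y - ds.X @ th
    return 0.5 * float(np.sum(resid * resid)) + lam * _penalty(th, q)


def gradient(ds: MultitaskDataset, theta: np.ndarray) -> np.ndarray:
    """Gradient of the squared loss only: X^T (X Theta - Y)."""
    th = theta.theta if isinstance(theta, ParameterMatrix) else np.asarray(theta, float)
    _check_shapes(ds, th)
    return ds.X.T @ (ds.X @ th - ds.Y)


def fit_lq1_mtl(
    ds: MultitaskDataset,
    q: float = 2.0,
    lam: float = 1.0,
    max_iter: int = 10000,
    tol: float = 1e-8,
    L0: float = 1.0,
) -> tuple[ParameterMatrix, LinearSolverState]:
    """Fit the ℓq,1 multitask linear model.

    Stops when the relative change of the composite objective falls below
    ``tol`` or after ``max_iter`` accelerated iterations.  Deterministic:
    Theta is initialised at zero and no randomness is used.
    """
    if not ds.is_complete():
        raise ValueError("linear solver requires a fully observed Y")
    if lam < 0 or q < 1:
        raise ValueError("need lam >= 0 and q >= 1")
    X, Y = ds.X, ds.Y
    p, T = ds.p, ds.T

    def F(th: np.ndarray) -> float:
        r = Y - X @ th
        return 0.5 * float(np.sum(r * r))

    theta = np.zeros((p, T))       # monotone iterate
    z = theta.copy()               # prox-point sequence driving the momentum
    z_prev = z.copy()
    t_prev = 1.0
    L = float(L0)
    phi = F(theta) + lam * _penalty(theta, q)
    trace = [phi]
    state = LinearSolverState(
        theta_curr=ParameterMatrix(theta), theta_prev=ParameterMatrix(theta),
        search_point=theta.copy(), L_curr=L, beta=0.0, objective_trace=trace,
    )
    for it in range(1, max_iter + 1):
        t_curr = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_prev * t_prev))
        beta = (t_prev - 1.0) / t_curr
        gamma = z + beta * (z - z_prev)
        g = X.T @ (X @ gamma - Y)
        f_gamma = F(gamma)
        L = max(L * 0.9, 1e-12)
        while True:
            cand = project_matrix_lq1(gamma - g / L, ProxConfig(q=q, lam=lam / L))
            diff = cand - gamma
            model = f_gamma + float(np.sum(diff * g)) + 0.5 * L * float(np.sum(diff * diff))
            if F(cand) <= model + 1e-12 * max(1.0, abs(model)):
                break
            L *= 2.0
            if L > 1e12 * L0:
                raise FloatingPointError(
                    f"line search diverged (L={L:.3g}); objective trace: {trace[-10:]}"
                )
        z_prev, z = z, cand
        phi_cand = F(cand) + lam * _penalty(cand, q)
        if phi_cand <= phi:           # monotone acceptance
            theta, phi = cand, phi_cand
        trace.append(phi)
        t_prev = t_curr
        state.search_point = gamma
        state.L_curr = L
        state.beta = beta
        state.iteration = it
        # require both the accepted trace and the raw prox sequence to have
        # stalled: a rejected candidate leaves the trace flat without meaning
        # convergence.
        rel = max(
            abs(trace[-2] - trace[-1]) / max(1.0, abs(trace[-2])),
            abs(phi_cand - phi) / max(1.0, abs(phi)),
        )
        if rel < tol and it > 1:
            state.converged = True
            break
    state.theta_curr = ParameterMatrix(theta)
    state.theta_prev = ParameterMatrix(z_prev)
    return ParameterMatrix(theta), state


def prox_residual(ds: MultitaskDataset, theta: np.ndarray, q: float, lam: float,
                  L: float) -> float:
    """Fixed-point residual ||Theta - prox(Theta - grad/L, lam/L)||_F."""
    g = gradient(ds, theta)
    step = project_matrix_lq1(theta - g / L, ProxConfig(q=q, lam=lam / L))
    return float(np.linalg.norm(theta - step))


def zero_solution_threshold(ds: MultitaskDataset, q: float) -> float:
    """Smallest lam for which Theta = 0 is optimal: max_h ||(X^T Y)_h.||_qbar."""
    G = ds.X.T @ ds.Y
    qbar = dual_exponent(q)
    if np.isinf(qbar):
        return float(np.abs(G).max())
    return float(np.max(np.linalg.norm(G, qbar, axis=1)))


def predict_linear(theta: ParameterMatrix | np.ndarray, X_new: np.ndarray) -> np.ndarray:
    th = theta.theta if isinstance(theta, ParameterMatrix) else np.asarray(theta, float)
    X_new = np.asarray(X_new, float)
    if X_new.shape[1] != th.shape[0]:
        raise ValueError(f"X_new has {X_new.shape[1]} columns, expected {th.shape[0]}")
    return X_new @ th


def save_linear_model(path: str | Path, theta: ParameterMatrix,
                      config: dict, scaler_json: str | None = None) -> None:
    """Serialize Theta + fit configuration (+ optional scaler record) as JSON."""
    payload = {
        "theta": theta.theta.tolist(),
        "config": config,
        "scaler": scaler_json,
    }
    Path(path).write_text(json.dumps(payload))


def load_linear_model(path: str | Path) -> tuple[ParameterMatrix, dict, str | None]:
    d = json.loads(Path(path).read_text())
    return ParameterMatrix(np.asarray(d["theta"], float)), d["config"], d["scaler"]
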