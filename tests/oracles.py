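"""Independent numerical oracles used by the tests.

Each oracle solves the same optimization problem as the library through a
different route (general-purpose smooth solvers on reformulations), so
agreement is evidence of correctness rather than repetition.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def prox_lq_oracle(v: np.ndarray, q: float, lam: float) -> np.ndarray:
    """Minimize 0.5||theta - v||^2 + lam*||theta||_q by a generic solver.

    The minimizer shares the sign pattern of v and can be searched over
    the nonnegative orthant after folding signs out.  The q = inf case is
    reformulated with an epigraph variable (a smooth QP); finite q uses
    L-BFGS-B with analytic gradients from several starts, compared
    against the candidate theta = 0.
    """
    v = np.asarray(v, float)
    sign = np.sign(v)
    b = np.abs(v)
    n = b.size

    def obj0() -> float:
        return 0.5 * float(b @ b)

    if lam == 0:
        return v.copy()

    if np.isinf(q):
        # variables z = (x, s): 0.5||x-b||^2 + lam*s, x_i <= s, 0 <= x <= b
        def f(z):
            x, s = z[:n], z[n]
            return 0.5 * np.sum((x - b) ** 2) + lam * s

        def fg(z):
            x, s = z[:n], z[n]
            g = np.concatenate([x - b, [lam]])
            return f(z), g

        cons = [{"type": "ineq", "fun": lambda z, i=i: z[n] - z[i],
                 "jac": lambda z, i=i: np.eye(n + 1)[n] - np.eye(n + 1)[i]}
                for i in range(n)]
        z0 = np.concatenate([b, [b.max() if n else 0.0]])
        res = minimize(fg, z0, jac=True, method="SLSQP", constraints=cons,
                       bounds=[(0, bi) for bi in b] + [(0, None)],
                       options={"maxiter": 500, "ftol": 1e-14})
        x = res.x[:n]
        if f(res.x) > obj0():
            x = np.zeros(n)
        return sign * x

    if q == 1:
        def fg(x):
            return (0.5 * np.sum((x - b) ** 2) + lam * np.sum(x),
                    x - b + lam)
        starts = [b, b / 2.0, np.zeros(n)]
    else:
        def fg(x):
            nrm = np.sum(x ** q) ** (1.0 / q)
            val = 0.5 * np.sum((x - b) ** 2) + lam * nrm
            if nrm == 0.0:
                g = x - b
            else:
                g = x - b + lam * (x / nrm) ** (q - 1.0)
            return val, g
        starts = [b, b / 2.0, b / 10.0]

    best_x, best_f = np.zeros(n), obj0()
    for x0 in starts:
        res = minimize(fg, x0, jac=True, method="L-BFGS-B",
                       bounds=[(0, bi) for bi in b],
                       options={"maxiter": 2000, "ftol": 1e-18, "gtol": 1e-12})
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    return sign * best_x


def lemma1_oracle(a: np.ndarray, r: float) -> tuple[np.ndarray, float]:
    """Minimize sum_i a_i/eta_i over {eta >= 0, sum eta^r <= 1} with SLSQP.

    Coordinates with a_i = 0 are fixed at eta_i = 0 (they only relax the
    constraint for the rest).
    """
    a = np.asarray(a, float)
    pos = a > 0
    ap = a[pos]
    d = ap.size
    if d == 0:
        return np.zeros_like(a), 0.0

    def f(eta):
        return float(np.sum(ap / eta))

    def g(eta):
        return -ap / eta ** 2

    cons = [{"type": "ineq", "fun": lambda e: 1.0 - np.sum(e ** r),
             "jac": lambda e: -r * e ** (r - 1.0)}]
    eta0 = np.full(d, d ** (-1.0 / r))
    res = minimize(f, eta0, jac=g, method="SLSQP", constraints=cons,
                   bounds=[(1e-9, 1.0)] * d,
                   options={"maxiter": 2000, "ftol": 1e-16})
    # restart from the solution: SLSQP's final polish step improves the
    # argmin by ~2 orders of magnitude
    res = minimize(f, res.x, jac=g, method="SLSQP", constraints=cons,
                   bounds=[(1e-9, 1.0)] * d,
                   options={"maxiter": 2000, "ftol": 1e-16})
    eta = np.zeros_like(a)
    eta[pos] = res.x
    return eta, float(res.fun)


def dualnorm_weight_oracle(a: np.ndarray, qbar: float) -> np.ndarray:
    """Maximize sum_t nu_t a_t over {nu >= 0, sum nu^qbar <= 1} with SLSQP."""
    a = np.asarray(a, float)
    T = a.size

    def f(nu):
        return -float(nu @ a)

    cons = [{"type": "ineq", "fun": lambda v: 1.0 - np.sum(v ** qbar)}]
    nu0 = np.full(T, T ** (-1.0 / qbar))
    res = minimize(f, nu0, jac=lambda v: -a, method="SLSQP", constraints=cons,
                   bounds=[(0.0, 1.0)] * T,
                   options={"maxiter": 1000, "ftol": 1e-14})
    return res.x


def ista_l21(X: np.ndarray, Y: np.ndarray, lam: float, max_iter: int = 20000,
             tol: float = 1e-14) -> tuple[np.ndarray, float]:
    """Momentum-free proximal gradient for the l2,1 problem (reference).

    Fixed step 1/L with L the top eigenvalue of X^T X; returns the final
    Theta and objective.  Deliberately minimal and independent of the
    package solver.
    """
    p, T = X.shape[1], Y.shape[1]
    L = float(np.linalg.eigvalsh(X.T @ X)[-1])
    theta = np.zeros((p, T))

    def phi(th):
        r = Y - X @ th
        return 0.5 * np.sum(r * r) + lam * np.sum(np.linalg.norm(th, axis=1))

    prev = phi(theta)
    for _ in range(max_iter):
        grad = X.T @ (X @ theta - Y)
        Z = theta - grad / L
        norms = np.linalg.norm(Z, axis=1)
        scale = np.maximum(1.0 - (lam / L) / np.maximum(norms, 1e-300), 0.0)
        theta = Z * scale[:, None]
        cur = phi(theta)
        if abs(prev - cur) < tol * max(1.0, abs(prev)):
            break
        prev = cur
    return theta, phi(theta)


def krr_predict(K_train: np.ndarray, K_cross: np.ndarray, y: np.ndarray,
                lam: float) -> np.ndarray:
    """Kernel ridge regression with ridge 1/lam: K_x (K + I/lam)^{-1} y."""
    m = K_train.shape[0]
    return K_cross @ np.linalg.solve(K_train + np.eye(m) / lam, y)
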