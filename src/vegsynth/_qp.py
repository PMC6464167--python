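"""Simplex-constrained convex quadratic programming.

Solves ``min_w  w'Gw - 2c'w  subject to  w >= 0, sum(w) = 1`` with ``G``
positive semidefinite — the inner weighting problem of synthetic-control
matching, where ``G = A'A`` and ``c = A'y`` for importance-scaled predictor
matrices. A primal active-set method gives the global optimum (the problem
is convex) to near machine precision, which the vertex solutions of
exact-match instances require; SciPy's SLSQP is kept as a fallback for the
rare instance where the active-set iteration stalls.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["solve_simplex_qp"]


def _eqp_solve(G: np.ndarray, c: np.ndarray, free: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the equality-constrained subproblem on the free set.

    KKT system:  [2G_ff  1] [w]   [2c_f]
                 [1'     0] [mu] = [1]
    ``lstsq`` handles the singular case of duplicated donors (min-norm
    solution splits weight between exact duplicates, same objective).
    """
    m = free.sum()
    kkt = np.empty((m + 1, m + 1))
    kkt[:m, :m] = 2.0 * G[np.ix_(free, free)]
    kkt[:m, m] = 1.0
    kkt[m, :m] = 1.0
    kkt[m, m] = 0.0
    rhs = np.empty(m + 1)
    rhs[:m] = 2.0 * c[free]
    rhs[m] = 1.0
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    return sol[:m], float(sol[m])


def _objective(G: np.ndarray, c: np.ndarray, w: np.ndarray) -> float:
    return float(w @ G @ w - 2.0 * c @ w)


def solve_simplex_qp(
    G: np.ndarray,
    c: np.ndarray,
    w0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int | None = None,
) -> np.ndarray:
    """Minimize ``w'Gw - 2c'w`` over the probability simplex.

    Parameters
    ----------
    G, c
        Quadratic/linear coefficients; ``G`` must be symmetric PSD.
    w0
        Optional warm-start point on the simplex (e.g. the solution for a
        nearby importance vector); its support seeds the active set.
    tol
        KKT tolerance for bound multipliers.
    """
    K = len(c)
    if K == 1:
        return np.ones(1)
    if max_iter is None:
        max_iter = 3 * K + 20

    if w0 is not None and w0.shape == (K,) and np.all(w0 >= 0) and abs(w0.sum() - 1) < 1e-6:
        w = np.maximum(w0, 0.0)
        w = w / w.sum()
        free = w > 1e-12
        if not free.any():
            free = np.ones(K, dtype=bool)
            w = np.full(K, 1.0 / K)
    else:
        # best single-donor vertex: cheap, and lets the active set grow
        # (few small KKT solves) instead of shrinking from all K donors
        k0 = int(np.argmin(np.diag(G) - 2.0 * c))
        w = np.zeros(K)
        w[k0] = 1.0
        free = np.zeros(K, dtype=bool)
        free[k0] = True

    for _ in range(max_iter):
        w_eq, mu = _eqp_solve(G, c, free)
        if np.all(w_eq >= -tol):
            w = np.zeros(K)
            w[free] = np.maximum(w_eq, 0.0)
            s = w.sum()
            if s > 0:
                w /= s
            # stationarity on the free set gives g_f = -mu; a bound
            # coordinate prices in when lambda_i = g_i + mu < 0
            grad = 2.0 * (G @ w - c)
            inactive = ~free
            if inactive.any():
                lam = grad[inactive] + mu
                j = np.argmin(lam)
                if lam[j] < -max(tol, 1e-9):
                    idx = np.flatnonzero(inactive)[j]
                    free[idx] = True
                    continue
            return w
        # step toward w_eq until a free coordinate hits its bound
        w_f = w[free]
        d = w_eq - w_f
        blocking = d < 0
        with np.errstate(divide="ignore", invalid="ignore"):
            alphas = np.where(blocking, -w_f / d, np.inf)
        j = int(np.argmin(alphas))
        alpha = min(1.0, max(alphas[j], 0.0))
        w_f = w_f + alpha * d
        w_f[j] = 0.0
        w_new = np.zeros(K)
        idx_free = np.flatnonzero(free)
        w_new[idx_free] = np.maximum(w_f, 0.0)
        s = w_new.sum()
        w = w_new / s if s > 0 else np.full(K, 1.0 / K)
        free = free.copy()
        free[idx_free[j]] = False
        if not free.any():
            free[idx_free[j]] = True  # cannot empty the free set

    return _slsqp_fallback(G, c, w)


def _slsqp_fallback(G: np.ndarray, c: np.ndarray, w_start: np.ndarray) -> np.ndarray:
    K = len(c)
    res = minimize(
        lambda w: _objective(G, c, w),
        w_start,
        jac=lambda w: 2.0 * (G @ w - c),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(K)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    w = np.maximum(res.x, 0.0)
    s = w.sum()
    return w / s if s > 0 else np.full(K, 1.0 / K)
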