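"""Independent generic convex solvers used only as test oracles.

Nothing here shares code with the package implementation: nuclear-norm and
l1 terms are handled by smoothing plus quasi-Newton continuation, and 1-D
total variation by its exact box-constrained dual quadratic program.  These
routines are slow and only meant for tiny instances.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize


def _smooth_abs(x: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    r = np.sqrt(x * x + eps * eps)
    return float(np.sum(r - eps)), x / r


def _smooth_nuclear(M: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    U, s, Vt = linalg.svd(M, full_matrices=False)
    r = np.sqrt(s * s + eps * eps)
    grad = (U * (s / r)) @ Vt
    return float(np.sum(r - eps)), grad


def _minimize_continuation(fun, x0, eps_schedule, maxiter=20000):
    x = np.asarray(x0, dtype=float).ravel()
    for eps in eps_schedule:
        res = optimize.minimize(
            fun,
            x,
            args=(eps,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-18, "gtol": 1e-12, "maxcor": 50},
        )
        x = res.x
    return x


def nuclear_norm(M: np.ndarray) -> float:
    return float(linalg.svdvals(M).sum())


def tv_1d(x: np.ndarray) -> float:
    return float(np.abs(np.diff(x)).sum())


def solve_tv_denoise(v: np.ndarray, weight: float) -> np.ndarray:
    """Exact 1-D TV denoising via the dual QP.

    min_u 1/2 ||v - F^T u||^2  s.t.  |u_i| <= weight, with F the first-order
    difference operator; the primal solution is y = v - F^T u.
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    if n == 1 or weight == 0:
        return v.copy()

    def ftu(u):
        # F^T u where (F y)_i = y[i+1] - y[i]
        out = np.zeros(n)
        out[:-1] -= u
        out[1:] += u
        return out

    def f(u):
        resid = v - ftu(u)
        # gradient wrt u: -F resid... d/du 1/2||v - F^T u||^2 = -F(v - F^T u)
        grad = -(resid[1:] - resid[:-1])
        return 0.5 * float(resid @ resid), grad

    u0 = np.zeros(n - 1)
    res = optimize.minimize(
        f,
        u0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(-weight, weight)] * (n - 1),
        options={"maxiter": 50000, "ftol": 1e-18, "gtol": 1e-14, "maxcor": 50},
    )
    return v - ftu(res.x)


def solve_prox_l1(X: np.ndarray, tau: float) -> np.ndarray:
    """Minimizer of 1/2||X - S||_F^2 + tau ||S||_1 by per-entry scalar search."""
    X = np.asarray(X, dtype=float)
    out = np.empty_like(X)
    for idx in np.ndindex(*X.shape):
        x = X[idx]
        res = optimize.minimize_scalar(
            lambda s: 0.5 * (x - s) ** 2 + tau * abs(s),
            bounds=(-abs(x) - 1, abs(x) + 1),
            method="bounded",
            options={"xatol": 1e-12},
        )
        out[idx] = res.x
    return out


def solve_prox_nuclear(X: np.ndarray, tau: float) -> np.ndarray:
    """Minimizer of 1/2||X - L||_F^2 + tau ||L||_* via the factored form.

    Uses the variational identity ||L||_* = min_{L=AB} (||A||_F^2 +
    ||B||_F^2) / 2, which turns the nonsmooth prox problem into a smooth
    unconstrained one that never touches an SVD; with full inner rank its
    local minimizers are global, and a few random restarts guard against
    saddle points.
    """
    X = np.asarray(X, dtype=float)
    p, n = X.shape
    r = min(p, n)
    na = p * r

    def fun(z):
        A = z[:na].reshape(p, r)
        B = z[na:].reshape(r, n)
        G = A @ B - X
        val = 0.5 * float(np.sum(G * G)) + 0.5 * tau * float(
            np.sum(A * A) + np.sum(B * B)
        )
        return val, np.concatenate([(G @ B.T + tau * A).ravel(),
                                    (A.T @ G + tau * B).ravel()])

    best_val, best_L = np.inf, None
    gen = np.random.default_rng(0)
    for _ in range(3):
        z0 = gen.normal(0, 1.0, na + r * n)
        res = optimize.minimize(
            fun, z0, jac=True, method="L-BFGS-B",
            options={"maxiter": 50000, "ftol": 1e-18, "gtol": 1e-12,
                     "maxcor": 50},
        )
        if res.fun < best_val:
            best_val = res.fun
            A = res.x[:na].reshape(p, r)
            B = res.x[na:].reshape(r, n)
            best_L = A @ B
    return best_L


def solve_low_rank_subproblem(
    D: np.ndarray, S: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """Minimizer of 1/2||D - S - L||_F^2 + alpha||L||_* + beta * sum_i TV(row_i L)."""
    D = np.asarray(D, dtype=float)
    R = D - S
    shape = R.shape

    def fun(l_flat, eps):
        L = l_flat.reshape(shape)
        nuc, g_nuc = _smooth_nuclear(L, eps)
        diffs = np.diff(L, axis=1)
        tv, g_abs = _smooth_abs(diffs, eps)
        g_tv = np.zeros(shape)
        g_tv[:, 1:] += g_abs
        g_tv[:, :-1] -= g_abs
        res = L - R
        val = 0.5 * float(np.sum(res * res)) + alpha * nuc + beta * tv
        grad = res + alpha * g_nuc + beta * g_tv
        return val, grad.ravel()

    x = _minimize_continuation(fun, np.zeros(shape), [1e-3, 1e-5, 1e-7, 1e-9])
    return x.reshape(shape)


def low_rank_subproblem_objective(
    D: np.ndarray, S: np.ndarray, L: np.ndarray, alpha: float, beta: float
) -> float:
    res = D - S - L
    tv = sum(tv_1d(row) for row in L)
    return 0.5 * float(np.sum(res * res)) + alpha * nuclear_norm(L) + beta * tv


def solve_full_objective(
    D: np.ndarray, alpha: float, lam: float, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Joint minimizer (L, S) of the full decomposition objective

    1/2||D - L - S||_F^2 + alpha||L||_* + lam||S||_1 + beta * sum_i TV(row_i L)
    """
    D = np.asarray(D, dtype=float)
    shape = D.shape
    m = D.size

    def fun(x, eps):
        L = x[:m].reshape(shape)
        S = x[m:].reshape(shape)
        nuc, g_nuc = _smooth_nuclear(L, eps)
        l1, g_l1 = _smooth_abs(S, eps)
        diffs = np.diff(L, axis=1)
        tv, g_abs = _smooth_abs(diffs, eps)
        g_tv = np.zeros(shape)
        g_tv[:, 1:] += g_abs
        g_tv[:, :-1] -= g_abs
        res = L + S - D
        val = (
            0.5 * float(np.sum(res * res))
            + alpha * nuc
            + lam * l1
            + beta * tv
        )
        gL = res + alpha * g_nuc + beta * g_tv
        gS = res + lam * g_l1
        return val, np.concatenate([gL.ravel(), gS.ravel()])

    x0 = np.concatenate([np.zeros(m), D.ravel()])
    x = _minimize_continuation(fun, x0, [1e-3, 1e-5, 1e-7, 1e-9])
    return x[:m].reshape(shape), x[m:].reshape(shape)


def full_objective(
    D: np.ndarray, L: np.ndarray, S: np.ndarray, alpha: float, lam: float, beta: float
) -> float:
    """Term-by-term recomputation of the decomposition objective."""
    res = D - L - S
    tv = sum(tv_1d(row) for row in L)
    return (
        0.5 * float(np.sum(res * res))
        + alpha * nuclear_norm(L)
        + lam * float(np.abs(S).sum())
        + beta * tv
    )
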