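"""Proximal and smoothness operators used by the decomposition solver.

Four primitives:

* :func:`soft_threshold` — elementwise shrinkage, the proximal operator of
  the l1 norm.
* :func:`svt` — singular value thresholding, the proximal operator of the
  nuclear norm.
* :func:`fod_seminorm` — first-order-difference (total-variation) seminorm
  of a vector, the per-row smoothness penalty.
* :func:`tv_denoise_row` — exact minimizer of the 1-D total-variation
  denoising problem ``1/2 ||v - y||^2 + w * sum |y_{t+1} - y_t|``, computed
  with a direct (non-iterative) taut-string-class algorithm.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import linalg

__all__ = ["soft_threshold", "svt", "fod_seminorm", "tv_denoise_row", "tv_denoise_rows"]


def soft_threshold(x: np.ndarray | float, tau: float) -> np.ndarray | float:
    """Shrink ``x`` towards zero by ``tau``: ``sign(x) * max(|x| - tau, 0)``.

    Applied elementwise when ``x`` is an array.  ``tau`` must be >= 0.
    """
    if tau < 0:
        raise ValueError(f"threshold must be non-negative, got {tau}")
    x_arr = np.asarray(x, dtype=float)
    out = np.sign(x_arr) * np.maximum(np.abs(x_arr) - tau, 0.0)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def fod_seminorm(x: np.ndarray) -> float:
    """Sum of absolute first-order differences, ``sum_t |x_{t+1} - x_t|``.

    The first-order difference operator is applied implicitly (O(n) time,
    no materialized difference matrix).  Requires ``len(x) >= 2``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("fod_seminorm expects a 1-D vector")
    if x.size < 2:
        raise ValueError(f"need at least 2 entries, got {x.size}")
    return float(np.abs(np.diff(x)).sum())


def svt(X: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: soft-threshold the singular values of X.

    Returns ``U diag((sigma_i - tau)_+) V^T``, the unique minimizer of
    ``1/2 ||X - L||_F^2 + tau ||L||_*``.
    """
    if tau < 0:
        raise ValueError(f"threshold must be non-negative, got {tau}")
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("svt requires a finite matrix")
    U, s, Vt = linalg.svd(X, full_matrices=False, lapack_driver="gesdd")
    s_shrunk = np.maximum(s - tau, 0.0)
    # drop the zeroed spectrum before the product: cheaper and exact
    keep = s_shrunk > 0
    if not keep.any():
        return np.zeros_like(X)
    return (U[:, keep] * s_shrunk[keep]) @ Vt[keep]


@njit(cache=True)
def _tv1d(y: np.ndarray, lam: float, out: np.ndarray) -> None:
    """Direct O(n) 1-D total variation denoising (Condat's algorithm).

    Exact minimizer of 1/2||y - x||^2 + lam * sum|x_{t+1} - x_t|, written
    into ``out``.
    """
    n = y.shape[0]
    if n == 0:
        return
    if n == 1 or lam <= 0.0:
        for i in range(n):
            out[i] = y[i]
        return
    k = 0          # current sample
    k0 = 0         # start of the segment still undecided
    kminus = 0     # last position where umin hit +lam
    kplus = 0      # last position where umax hit -lam
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        while k == n - 1:
            if umin < 0.0:
                # negative jump: the lower bound is tight up to kminus
                while k0 <= kminus:
                    out[k0] = vmin
                    k0 += 1
                k = k0
                kminus = k
                vmin = y[k]
                umin = lam
                umax = vmin + umin - vmax
            elif umax > 0.0:
                # positive jump: the upper bound is tight up to kplus
                while k0 <= kplus:
                    out[k0] = vmax
                    k0 += 1
                k = k0
                kplus = k
                vmax = y[k]
                umax = -lam
                umin = vmax + umax - vmin
            else:
                vmin += umin / (k - k0 + 1)
                while k0 <= k:
                    out[k0] = vmin
                    k0 += 1
                return
        umin += y[k + 1] - vmin
        if umin < -lam:
            while k0 <= kminus:
                out[k0] = vmin
                k0 += 1
            k = k0
            kminus = k
            kplus = k
            vmin = y[k]
            vmax = y[k] + 2.0 * lam
            umin = lam
            umax = -lam
        else:
            umax += y[k + 1] - vmax
            if umax > lam:
                while k0 <= kplus:
                    out[k0] = vmax
                    k0 += 1
                k = k0
                kminus = k
                kplus = k
                vmax = y[k]
                vmin = y[k] - 2.0 * lam
                umin = lam
                umax = -lam
            else:
                k += 1
                if umin >= lam:
                    kminus = k
                    vmin += (umin - lam) / (k - k0 + 1)
                    umin = lam
                if umax <= -lam:
                    kplus = k
                    vmax += (umax + lam) / (k - k0 + 1)
                    umax = -lam


@njit(cache=True)
def _tv_rows(Y: np.ndarray, lam: float, out: np.ndarray) -> None:
    for i in range(Y.shape[0]):
        _tv1d(Y[i], lam, out[i])


def tv_denoise_row(v: np.ndarray, weight: float) -> np.ndarray:
    """Exact 1-D total variation denoising of a single vector.

    Returns the unique minimizer of
    ``1/2 ||v - y||^2 + weight * sum_t |y_{t+1} - y_t|``.
    """
    if weight < 0:
        raise ValueError(f"weight must be non-negative, got {weight}")
    v = np.ascontiguousarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("tv_denoise_row expects a 1-D vector")
    if v.size < 1:
        raise ValueError("empty vector")
    out = np.empty_like(v)
    _tv1d(v, float(weight), out)
    return out


def tv_denoise_rows(V: np.ndarray, weight: float) -> np.ndarray:
    """Apply :func:`tv_denoise_row` to every row of a matrix."""
    if weight < 0:
        raise ValueError(f"weight must be non-negative, got {weight}")
    V = np.ascontiguousarray(V, dtype=float)
    out = np.empty_like(V)
    _tv_rows(V, float(weight), out)
    return out
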