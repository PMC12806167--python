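"""Numba kernels for block-coordinate-descent graphical lasso.

The outer loop cycles over columns of the working covariance W, solving
each column's lasso subproblem by coordinate descent (the classical
sparse-inverse-covariance algorithm).  This handles the rank-deficient
covariances produced by short tapered windows, where first-order
whole-matrix methods stall.  Kernels are JIT-compiled on first use.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _cholesky_lower(a):
    """Lower Cholesky factor with an explicit success flag (no exceptions)."""
    d = a.shape[0]
    low = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1):
            s = a[i, j]
            for t in range(j):
                s -= low[i, t] * low[j, t]
            if i == j:
                if s <= 0.0:
                    return low, False
                low[i, i] = np.sqrt(s)
            else:
                low[i, j] = s / low[j, j]
    return low, True


@njit(cache=True)
def _spd_inverse(a):
    """Inverse of an SPD matrix via Cholesky; flag is False when not SPD."""
    d = a.shape[0]
    low, ok = _cholesky_lower(a)
    if not ok:
        return np.zeros((d, d)), 0.0, False
    logdet = 0.0
    for i in range(d):
        logdet += 2.0 * np.log(low[i, i])
    # minv = low^{-1} by forward substitution on the identity
    minv = np.zeros((d, d))
    for col in range(d):
        for i in range(col, d):
            s = 1.0 if i == col else 0.0
            for t in range(col, i):
                s -= low[i, t] * minv[t, col]
            minv[i, col] = s / low[i, i]
    inv = minv.T @ minv
    return inv, logdet, True


@njit(cache=True)
def _objective_and_gap(s, theta, logdet_theta, lam):
    """Penalized negative log-likelihood and the duality-gap certificate."""
    d = s.shape[0]
    tr_s_theta = 0.0
    off_l1 = 0.0
    for i in range(d):
        for j in range(d):
            tr_s_theta += s[i, j] * theta[i, j]
            if i != j:
                off_l1 += abs(theta[i, j])
    obj = tr_s_theta - logdet_theta + lam * off_l1
    gap = tr_s_theta - d + lam * off_l1
    return obj, gap


@njit(cache=True)
def glasso_bcd(s, w, b, lam, max_sweeps, gap_tol, inner_tol, max_inner):
    """Block coordinate descent over columns of W with a lasso inner solver.

    Mutates ``w`` (working covariance) and ``b`` (per-column lasso
    coefficients, used for warm starts) in place.  Returns
    (theta, objective trace, n_sweeps, gap, status) with status 1 on
    convergence, 0 on sweep exhaustion, -1 when W loses positive
    definiteness (should not happen with exact updates).
    """
    d = s.shape[0]
    trace = np.empty(max_sweeps)
    gap = 1e300
    theta = np.zeros((d, d))
    n_sweeps = 0
    for sweep in range(max_sweeps):
        for j in range(d):
            bcol = b[:, j].copy()
            bcol[j] = 0.0
            r = w @ bcol  # r[i] = sum_t W[i,t] b[t], b[j] = 0
            for _ in range(max_inner):
                maxdiff = 0.0
                for i in range(d):
                    if i == j:
                        continue
                    wii = w[i, i]
                    z = s[i, j] - (r[i] - wii * bcol[i])
                    if z > lam:
                        bnew = (z - lam) / wii
                    elif z < -lam:
                        bnew = (z + lam) / wii
                    else:
                        bnew = 0.0
                    diff = bnew - bcol[i]
                    if diff != 0.0:
                        for t in range(d):
                            r[t] += diff * w[t, i]
                        bcol[i] = bnew
                        if abs(diff) > maxdiff:
                            maxdiff = abs(diff)
                if maxdiff < inner_tol:
                    break
            b[:, j] = bcol
            b[j, j] = 0.0
            for i in range(d):
                if i != j:
                    w[i, j] = r[i]
                    w[j, i] = r[i]
        theta, logdet, ok = _spd_inverse(w)
        n_sweeps = sweep + 1
        if not ok:
            return theta, trace[:n_sweeps], n_sweeps, gap, -1
        obj, gap = _objective_and_gap(s, theta, logdet, lam)
        trace[sweep] = obj
        if abs(gap) < gap_tol:
            return theta, trace[:n_sweeps], n_sweeps, gap, 1
    return theta, trace[:n_sweeps], n_sweeps, gap, 0
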