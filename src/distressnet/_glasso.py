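"""Graphical-lasso solver (block coordinate descent) compiled with numba.

Solves, for each penalty ``alpha`` on a decreasing grid,

    max_K  log det K - tr(S K) - alpha * sum_{i != j} |K_ij|

via the covariance-update algorithm: cycle over columns, solve the implied
lasso subproblem for the off-diagonal block by coordinate descent, and update
the working covariance W.  The diagonal is not penalized, so W_ii = S_ii and
the penalty threshold at which the graph becomes empty equals the largest
absolute off-diagonal of S.  Warm starts carry (W, B) along the grid, which
makes a full 100-penalty path on p ~ 16-30 nodes a few milliseconds.

Soft thresholding produces exact zeros in the regression coefficients B, so
edge support is exact (no epsilon test needed downstream).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _glasso_one(S, alpha, W, B, tol, max_iter):
    """One penalty value; W and B are warm-start state, updated in place.

    Returns (K, converged_flag).
    """
    p = S.shape[0]
    converged = False
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            beta = B[:, j]
            for _ in range(max_iter):
                cd_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * beta[l]
                    old = beta[k]
                    if r > alpha:
                        new = (r - alpha) / W[k, k]
                    elif r < -alpha:
                        new = (r + alpha) / W[k, k]
                    else:
                        new = 0.0
                    beta[k] = new
                    d = abs(new - old)
                    if d > cd_delta:
                        cd_delta = d
                if cd_delta < tol * 0.1:
                    break
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l != j:
                        w += W[k, l] * beta[l]
                d = abs(w - W[k, j])
                if d > max_delta:
                    max_delta = d
                W[k, j] = w
                W[j, k] = w
        if max_delta < tol:
            converged = True
            break
    K = np.zeros((p, p))
    for j in range(p):
        w12b = 0.0
        for l in range(p):
            if l != j:
                w12b += W[l, j] * B[l, j]
        k22 = 1.0 / (W[j, j] - w12b)
        K[j, j] = k22
        for l in range(p):
            if l != j:
                K[l, j] = -B[l, j] * k22
    for i in range(p):
        for jj in range(i + 1, p):
            if B[i, jj] == 0.0 and B[jj, i] == 0.0:
                v = 0.0
            else:
                v = 0.5 * (K[i, jj] + K[jj, i])
            K[i, jj] = v
            K[jj, i] = v
    return K, converged


@njit(cache=True)
def glasso_path(S, alphas, tol=1e-5, max_iter=500):
    """Precision estimates along a decreasing penalty grid.

    Returns (precisions[n_alpha, p, p], converged[n_alpha])."""
    p = S.shape[0]
    n_a = alphas.shape[0]
    Ks = np.zeros((n_a, p, p))
    flags = np.zeros(n_a, dtype=np.bool_)
    W = S.copy()
    B = np.zeros((p, p))
    for a in range(n_a):
        K, ok = _glasso_one(S, alphas[a], W, B, tol, max_iter)
        Ks[a] = K
        flags[a] = ok
    return Ks, flags
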