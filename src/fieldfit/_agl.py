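"""Numba kernels for the adaptive group LASSO.

The linear stage of the gene model is a penalized regression with three
coefficient groups (age; clock cos/sin pair; environmental response and its
interactions).  Stage one computes ridge pilot estimates; stage two solves a
group LASSO whose group weights are the reciprocal pilot norms, by FISTA with
an exact group soft-thresholding prox.  Everything operates on the Gram
representation (G = X'X/n, c = X'y/n) so a fit costs O(p^2) per iteration
regardless of sample size, which is what makes grid search over nonlinear
parameters affordable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RIDGE_EPS = 1e-4
FLOOR = 1e-10


@njit(cache=True)
def _power_L(G):
    p = G.shape[0]
    v = np.ones(p)
    L = 1.0
    for _ in range(60):
        w = G @ v
        L = np.sqrt(np.sum(w * w))
        if L < 1e-12:
            return 1e-12
        v = w / L
    return L * 1.001


@njit(cache=True)
def _group_prox(b, thr, group_ids, n_groups):
    p = b.shape[0]
    norms = np.zeros(n_groups)
    for j in range(p):
        g = group_ids[j]
        norms[g] += b[j] * b[j]
    scale = np.empty(n_groups)
    for g in range(n_groups):
        nrm = np.sqrt(norms[g])
        if nrm <= thr[g]:
            scale[g] = 0.0
        else:
            scale[g] = 1.0 - thr[g] / nrm
    out = np.empty(p)
    for j in range(p):
        out[j] = b[j] * scale[group_ids[j]]
    return out


@njit(cache=True)
def _fista(G, c, lam, gw, group_ids, n_groups, beta0, L, max_iter, tol):
    """Minimize 0.5 b'Gb - c'b + lam * sum_g gw[g] * ||b_g||_2."""
    p = G.shape[0]
    thr = np.empty(n_groups)
    for g in range(n_groups):
        thr[g] = lam * gw[g] / L
    x = beta0.copy()
    z = beta0.copy()
    tk = 1.0
    for _ in range(max_iter):
        grad = G @ z - c
        b = z - grad / L
        xb = _group_prox(b, thr, group_ids, n_groups)
        tk1 = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        mom = (tk - 1.0) / tk1
        z = xb + mom * (xb - x)
        diff = 0.0
        for j in range(p):
            d = abs(xb[j] - x[j])
            if d > diff:
                diff = d
        x = xb
        tk = tk1
        if diff < tol:
            break
    return x


@njit(cache=True)
def _pilot_weights(G, c, group_ids, n_groups):
    p = G.shape[0]
    A = G.copy()
    for j in range(p):
        A[j, j] += RIDGE_EPS
    pilot = np.linalg.solve(A, c)
    gn = np.zeros(n_groups)
    for j in range(p):
        g = group_ids[j]
        gn[g] += pilot[j] * pilot[j]
    gw = np.empty(n_groups)
    for g in range(n_groups):
        nrm = np.sqrt(gn[g])
        if nrm < FLOOR:
            nrm = FLOOR
        gw[g] = 1.0 / nrm
    return gw


@njit(cache=True)
def _agl_best(G, c, yty, n, group_ids, n_groups, rel_lams, max_iter, tol):
    """Adaptive group LASSO path with BIC selection on the Gram scale.

    Returns (beta, bic, lam) at the BIC-minimizing point of the path
    lam = lam_max * rel_lams (rel_lams descending, in (0, 1]).
    """
    p = G.shape[0]
    gw = _pilot_weights(G, c, group_ids, n_groups)
    # smallest lambda that zeroes every group at beta = 0
    cn = np.zeros(n_groups)
    for j in range(p):
        g = group_ids[j]
        cn[g] += c[j] * c[j]
    lam_max = 0.0
    for g in range(n_groups):
        v = np.sqrt(cn[g]) / gw[g]
        if v > lam_max:
            lam_max = v
    L = _power_L(G)
    beta = np.zeros(p)
    best_bic = np.inf
    best_beta = np.zeros(p)
    best_lam = 0.0
    logn = np.log(n)
    for i in range(rel_lams.shape[0]):
        lam = lam_max * rel_lams[i]
        beta = _fista(G, c, lam, gw, group_ids, n_groups, beta, L, max_iter, tol)
        rssn = yty - 2.0 * np.dot(c, beta) + beta @ G @ beta
        if rssn < 1e-12:
            rssn = 1e-12
        df = 1  # intercept
        for j in range(p):
            if beta[j] != 0.0:
                df += 1
        bic = n * np.log(rssn) + df * logn
        if bic < best_bic:
            best_bic = bic
            best_beta = beta.copy()
            best_lam = lam
    return best_beta, best_bic, best_lam


@njit(cache=True)
def _agl_best_batch(Gs, cs, ytys, n, group_ids, n_groups, rel_lams, max_iter, tol):
    m = Gs.shape[0]
    p = Gs.shape[1]
    betas = np.zeros((m, p))
    bics = np.empty(m)
    for i in range(m):
        b, bic, _ = _agl_best(
            Gs[i], cs[i], ytys[i], n, group_ids, n_groups, rel_lams, max_iter, tol
        )
        betas[i] = b
        bics[i] = bic
    return betas, bics
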