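"""Gram-based LARS-lasso path solver with an error-budget stop.

Solves, per patch y and dictionary Psi (columns unit norm),

    min ||alpha||_1   subject to   ||y - Psi alpha||_2^2 <= budget

by tracing the lasso regularization path from lambda_max downward.  The
constrained optimum lies on the path at the lambda whose residual equals the
budget; the squared residual is an explicit quadratic in the step length
along each path segment, so the stop point is found in closed form and the
coefficients are interpolated exactly — no grid search.

An optional support cap ``max_nnz`` implements a target-sparsity variant:
once the active set is full, further atom joins are ignored and the path
continues toward lambda=0 on the restricted support (drops re-open the set).

Everything is jitted with numba; the per-solve state is O(k) with k the
number of atoms, and the only O(k^2) input is the dictionary Gram matrix,
computed once per coding pass by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lars_lasso_gram", "batch_lasso_budget"]


@njit(cache=True)
def lars_lasso_gram(G, c0, y2, budget, max_nnz, tol):
    """One error-constrained min-l1 solve.

    Parameters: G = Psi'Psi (k,k); c0 = Psi'y (k,); y2 = ||y||^2;
    budget = residual bound; max_nnz = support cap (pass k to disable);
    tol = absolute feasibility slack.

    Returns (coefficients (k,), squared residual, feasible flag).
    """
    k = c0.shape[0]
    beta = np.zeros(k)
    if y2 <= budget + tol:
        return beta, y2, True  # alpha = 0 is feasible and l1-minimal

    in_act = np.zeros(k, np.bool_)
    sign = np.zeros(k)
    order = np.empty(k, np.int64)
    n_act = 0
    c = c0.copy()
    r2 = y2

    lam = 0.0
    j0 = -1
    for j in range(k):
        a = abs(c[j])
        if a > lam:
            lam = a
            j0 = j
    if lam <= 1e-14:
        return beta, r2, r2 <= budget + tol
    order[0] = j0
    in_act[j0] = True
    sign[j0] = 1.0 if c[j0] > 0 else -1.0
    n_act = 1

    max_steps = 8 * k + 64
    for _step in range(max_steps):
        if r2 <= budget + tol:
            return beta, r2, True
        # late joins: atoms whose correlation overtook lam while the support
        # cap was saturated enter as zero-length events once room frees up
        while n_act < max_nnz:
            jbest = -1
            cbest = lam * (1.0 + 1e-12)
            for j in range(k):
                if not in_act[j] and abs(c[j]) > cbest:
                    cbest = abs(c[j])
                    jbest = j
            if jbest < 0:
                break
            order[n_act] = jbest
            in_act[jbest] = True
            sign[jbest] = 1.0 if c[jbest] > 0 else -1.0
            n_act += 1
            lam = cbest

        # equiangular direction on the active set
        GA = np.empty((n_act, n_act))
        sA = np.empty(n_act)
        for ai in range(n_act):
            ia = order[ai]
            sA[ai] = sign[ia]
            for aj in range(n_act):
                GA[ai, aj] = G[ia, order[aj]]
            GA[ai, ai] += 1e-12
        d = np.linalg.solve(GA, sA)
        q = 0.0
        for ai in range(n_act):
            q += d[ai] * sA[ai]
        if q <= 0.0:
            break  # degenerate (duplicate atoms); stop at current point

        a_all = np.zeros(k)
        for ai in range(n_act):
            ia = order[ai]
            da = d[ai]
            for j in range(k):
                a_all[j] += G[j, ia] * da

        # next event along the segment: join, drop, or path end (lambda -> 0)
        best_delta = lam
        best_type = 0  # 0 end, 1 join, 2 drop
        best_idx = -1
        if n_act < max_nnz:
            for j in range(k):
                if in_act[j]:
                    continue
                den = 1.0 - a_all[j]
                if den > 1e-14:
                    dlt = (lam - c[j]) / den
                    if 1e-14 < dlt < best_delta:
                        best_delta = dlt
                        best_type = 1
                        best_idx = j
                den = 1.0 + a_all[j]
                if den > 1e-14:
                    dlt = (lam + c[j]) / den
                    if 1e-14 < dlt < best_delta:
                        best_delta = dlt
                        best_type = 1
                        best_idx = j
        for ai in range(n_act):
            ia = order[ai]
            if d[ai] != 0.0:
                dlt = -beta[ia] / d[ai]
                if 1e-14 < dlt < best_delta:
                    best_delta = dlt
                    best_type = 2
                    best_idx = ai

        # closed-form budget crossing: r(dl) = r2 - 2*lam*q*dl + q*dl^2
        disc = lam * lam - (r2 - budget) / q
        if disc < 0.0 and disc >= -1e-9 * (lam * lam + 1e-30):
            disc = 0.0  # grazing contact lost to rounding
        if disc >= 0.0:
            dl_b = lam - np.sqrt(disc)
            if 0.0 <= dl_b <= best_delta + 1e-14:
                for ai in range(n_act):
                    beta[order[ai]] += dl_b * d[ai]
                r2 = r2 - 2.0 * lam * q * dl_b + q * dl_b * dl_b
                if r2 < 0.0:
                    r2 = 0.0
                return beta, r2, True

        dl = best_delta
        for ai in range(n_act):
            beta[order[ai]] += dl * d[ai]
        r2 = r2 - 2.0 * lam * q * dl + q * dl * dl
        if r2 < 0.0:
            r2 = 0.0
        lam -= dl
        for j in range(k):
            c[j] -= dl * a_all[j]

        if best_type == 0 or lam <= 1e-14:
            break
        if best_type == 1:
            j = best_idx
            order[n_act] = j
            in_act[j] = True
            sign[j] = 1.0 if c[j] > 0 else -1.0
            n_act += 1
        else:
            ia = order[best_idx]
            beta[ia] = 0.0
            in_act[ia] = False
            sign[ia] = 0.0
            for ai in range(best_idx, n_act - 1):
                order[ai] = order[ai + 1]
            n_act -= 1
            if n_act == 0:
                lam2 = 0.0
                j0 = -1
                for j in range(k):
                    a = abs(c[j])
                    if a > lam2:
                        lam2 = a
                        j0 = j
                if lam2 <= 1e-14:
                    break
                lam = lam2
                order[0] = j0
                in_act[j0] = True
                sign[j0] = 1.0 if c[j0] > 0 else -1.0
                n_act = 1
    return beta, r2, r2 <= budget + tol


@njit(cache=True)
def batch_lasso_budget(G, C0, Y2, budget, max_nnz):
    """Code a whole patch matrix: C0 = Psi'Y (k, N), Y2 = per-patch ||y||^2."""
    k, n = C0.shape
    coefs = np.zeros((k, n))
    r2 = np.empty(n)
    feas = np.empty(n, np.bool_)
    for p in range(n):
        tol = 1e-10 * (Y2[p] + 1.0)
        b, r, f = lars_lasso_gram(G, C0[:, p].copy(), Y2[p], budget, max_nnz, tol)
        coefs[:, p] = b
        r2[p] = r
        feas[p] = f
    return coefs, r2, feas
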