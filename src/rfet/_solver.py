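"""Numba kernels: soft-margin linear-SVM dual solver and the RFE loop.

The dual is solved by sequential minimal optimization with maximal-violating-
pair working-set selection, operating on the Gram matrix only. The recursive
feature elimination loop lives here too so that one elimination step costs
an O(n^2) Gram downdate, a warm-started SMO solve, and an O(g*n) weight pass
— cheap enough to retrain hundreds of thousands of times in an ensemble.

Determinism: working-set ties resolve to the lowest sample index; the
convergence tolerance is pinned by the caller (default 1e-6).
"""

import numpy as np
from numba import njit

MAX_SMO_ITER = 100_000
# refresh the Gram matrix from scratch periodically to bound downdate drift
_GRAM_REFRESH = 32


@njit(cache=True)
def smo_solve(K, y, C, alpha, eps, max_iter):
    """Solve the C-SVM dual on Gram matrix K, warm-starting from alpha.

    alpha is updated in place (it must be feasible: 0 <= alpha <= C and
    sum(alpha*y) == 0; the zero vector always qualifies). Returns the final
    margin vector f with f[t] = sum_s alpha[s]*y[s]*K[s,t].
    """
    n = K.shape[0]
    f = np.zeros(n)
    for s in range(n):
        a = alpha[s] * y[s]
        if a != 0.0:
            for t in range(n):
                f[t] += a * K[s, t]
    for _ in range(max_iter):
        # maximal violating pair over g_t = y_t - f_t
        up_best = -1.0e300
        low_best = 1.0e300
        i = -1
        j = -1
        for t in range(n):
            g = y[t] - f[t]
            if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
                if g > up_best:
                    up_best = g
                    i = t
            if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
                if g < low_best:
                    low_best = g
                    j = t
        if i < 0 or j < 0 or up_best - low_best <= eps:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta < 1.0e-12:
            eta = 1.0e-12
        e_i = f[i] - y[i]
        e_j = f[j] - y[j]
        ai_old = alpha[i]
        aj_old = alpha[j]
        aj_new = aj_old + y[j] * (e_i - e_j) / eta
        if y[i] != y[j]:
            lo = max(0.0, aj_old - ai_old)
            hi = min(C, C + aj_old - ai_old)
        else:
            lo = max(0.0, ai_old + aj_old - C)
            hi = min(C, ai_old + aj_old)
        if aj_new < lo:
            aj_new = lo
        elif aj_new > hi:
            aj_new = hi
        ai_new = ai_old + y[i] * y[j] * (aj_old - aj_new)
        # snap to the box so stale 1e-17 residues cannot re-enter the
        # working set and stall progress
        if ai_new < 1.0e-12:
            ai_new = 0.0
        elif ai_new > C - 1.0e-12:
            ai_new = C
        if aj_new < 1.0e-12:
            aj_new = 0.0
        elif aj_new > C - 1.0e-12:
            aj_new = C
        di = (ai_new - ai_old) * y[i]
        dj = (aj_new - aj_old) * y[j]
        alpha[i] = ai_new
        alpha[j] = aj_new
        for t in range(n):
            f[t] += di * K[i, t] + dj * K[j, t]
    return f


@njit(cache=True)
def svm_bias(f, y, alpha, C):
    """Intercept: mean of y - f over free support vectors, else midpoint
    of the KKT violation interval."""
    n = f.shape[0]
    s = 0.0
    nfree = 0
    for t in range(n):
        if 1.0e-8 < alpha[t] < C - 1.0e-8:
            s += y[t] - f[t]
            nfree += 1
    if nfree > 0:
        return s / nfree
    up_best = -1.0e300
    low_best = 1.0e300
    for t in range(n):
        g = y[t] - f[t]
        if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
            if g > up_best:
                up_best = g
        if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
            if g < low_best:
                low_best = g
    return 0.5 * (up_best + low_best)


@njit(cache=True)
def rfe_core(X, y, C, eps, max_iter):
    """Eliminate one minimum-criterion gene per retraining round.

    X is samples x genes (already standardized if requested), y in {-1,+1}.
    Returns (elim_gene, elim_crit): the column index and squared weight of
    the gene removed at each step 1..g. Criterion ties eliminate the gene
    occurring later in the current column order.
    """
    n, g = X.shape
    active = np.arange(g)
    m = g
    elim_gene = np.empty(g, dtype=np.int64)
    elim_crit = np.empty(g, dtype=np.float64)
    alpha = np.zeros(n)
    K = np.zeros((n, n))
    since_refresh = _GRAM_REFRESH  # force initial build
    for step in range(g):
        if since_refresh >= _GRAM_REFRESH:
            for a in range(n):
                for b in range(a, n):
                    s = 0.0
                    for jj in range(m):
                        gi = active[jj]
                        s += X[a, gi] * X[b, gi]
                    K[a, b] = s
                    K[b, a] = s
            since_refresh = 0
        smo_solve(K, y, C, alpha, eps, max_iter)
        # criterion c_j = w_j^2 over surviving genes; pick last argmin
        best = -1
        best_c = 1.0e300
        for jj in range(m):
            gi = active[jj]
            w = 0.0
            for k in range(n):
                w += alpha[k] * y[k] * X[k, gi]
            c = w * w
            if c <= best_c:
                best_c = c
                best = jj
        gi = active[best]
        elim_gene[step] = gi
        elim_crit[step] = best_c
        for a in range(n):
            for b in range(n):
                K[a, b] -= X[a, gi] * X[b, gi]
        for jj in range(best, m - 1):
            active[jj] = active[jj + 1]
        m -= 1
        since_refresh += 1
    return elim_gene, elim_crit
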