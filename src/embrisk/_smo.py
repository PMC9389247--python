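"""Sequential minimal optimization core for the soft-margin linear SVM.

Solves the dual problem

    min_a  1/2 sum_ij a_i a_j y_i y_j K_ij - sum_i a_i
    s.t.   0 <= a_i <= C,   sum_i a_i y_i = 0

by pairwise coordinate steps with LIBSVM-style working-set selection:
the first index maximizes the KKT violation among "up" candidates, the
second maximizes the second-order objective decrease among "down"
candidates.  Bounded points that stop violating are periodically shrunk
out of the scans; convergence is always re-verified on the full set
(gradient recomputed from scratch) before the KKT violation is declared
below ``tol``.

``K`` is the Gram matrix of exactly the training rows, so callers that
share one large Gram matrix across folds or feature subsets extract the
contiguous submatrix first.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BOX_EPS = 1e-12


@njit(cache=True, fastmath=True)
def _full_recheck(K, y, C, alpha, G, act, tol):  # pragma: no cover - jitted
    """Recompute G on all points, measure the full KKT gap, rebuild the
    active set (free points plus violators).  Returns (gap, n_act)."""
    n = K.shape[0]
    for t in range(n):
        G[t] = -1.0
    for s in range(n):
        if alpha[s] > _BOX_EPS:
            cs = alpha[s] * y[s]
            row = K[s]
            for t in range(n):
                G[t] += y[t] * cs * row[t]
    fmax = -1e300
    fmin = 1e300
    for t in range(n):
        gt = -y[t] * G[t]
        at = alpha[t]
        if (y[t] > 0 and at < C - _BOX_EPS) or (y[t] < 0 and at > _BOX_EPS):
            if gt > fmax:
                fmax = gt
        if (y[t] > 0 and at > _BOX_EPS) or (y[t] < 0 and at < C - _BOX_EPS):
            if gt < fmin:
                fmin = gt
    gap = fmax - fmin
    n_act = 0
    for t in range(n):
        at = alpha[t]
        gt = -y[t] * G[t]
        free = at > _BOX_EPS and at < C - _BOX_EPS
        upv = ((y[t] > 0 and at < C - _BOX_EPS) or (y[t] < 0 and at > _BOX_EPS)) \
            and gt > fmin + 0.1 * tol
        lowv = ((y[t] > 0 and at > _BOX_EPS) or (y[t] < 0 and at < C - _BOX_EPS)) \
            and gt < fmax - 0.1 * tol
        if free or upv or lowv:
            act[n_act] = t
            n_act += 1
    return gap, n_act


@njit(cache=True, fastmath=True)
def smo_solve(K, y, C, tol, max_iter, alpha0):  # pragma: no cover - jitted
    """Run SMO on Gram matrix ``K`` (training rows only).

    ``alpha0`` warm-starts the multipliers (must satisfy the box and
    equality constraints; pass zeros for a cold start).  Returns
    ``(alpha, G, n_iter, gap)`` where ``G`` is the dual gradient
    ``Q alpha - 1`` and ``gap`` the final full-set KKT violation.
    """
    n = K.shape[0]
    alpha = alpha0.copy()
    G = -np.ones(n)
    for s in range(n):
        if alpha[s] > _BOX_EPS:
            cs = alpha[s] * y[s]
            row = K[s]
            for t in range(n):
                G[t] += y[t] * cs * row[t]
    act = np.empty(n, np.int64)
    for t in range(n):
        act[t] = t
    n_act = n
    gap = 1e300
    it = 0
    stalled = False
    since_shrink = 0
    while it < max_iter:
        it += 1
        since_shrink += 1
        gmax = -1e300
        gmin = 1e300
        i = -1
        for a in range(n_act):
            t = act[a]
            gt = -y[t] * G[t]
            at = alpha[t]
            if (y[t] > 0 and at < C - _BOX_EPS) or (y[t] < 0 and at > _BOX_EPS):
                if gt > gmax:
                    gmax = gt
                    i = t
            if (y[t] > 0 and at > _BOX_EPS) or (y[t] < 0 and at < C - _BOX_EPS):
                if gt < gmin:
                    gmin = gt
        if gmax - gmin <= tol or i < 0:
            gap, n_act = _full_recheck(K, y, C, alpha, G, act, tol)
            since_shrink = 0
            if gap <= tol or stalled:
                break
            stalled = n_act == 0
            continue
        if since_shrink >= 1000:
            # drop bounded points that are currently KKT-consistent;
            # the final full recheck protects against wrong shrinks
            since_shrink = 0
            m = 0
            for a in range(n_act):
                t = act[a]
                at = alpha[t]
                gt = -y[t] * G[t]
                free = at > _BOX_EPS and at < C - _BOX_EPS
                upv = ((y[t] > 0 and at < C - _BOX_EPS)
                       or (y[t] < 0 and at > _BOX_EPS)) and gt > gmin - tol
                lowv = ((y[t] > 0 and at > _BOX_EPS)
                        or (y[t] < 0 and at < C - _BOX_EPS)) and gt < gmax + tol
                if free or upv or lowv:
                    act[m] = t
                    m += 1
            n_act = m
            continue
        stalled = False
        # second member: maximal second-order gain among "down" candidates
        rowi = K[i]
        kii = rowi[i]
        j = -1
        best = 0.0
        for a in range(n_act):
            t = act[a]
            at = alpha[t]
            if (y[t] > 0 and at > _BOX_EPS) or (y[t] < 0 and at < C - _BOX_EPS):
                diff = gmax + y[t] * G[t]  # g_i - g_t
                if diff > 0.0:
                    qt = kii + K[t, t] - 2.0 * rowi[t]
                    if qt <= 1e-12:
                        qt = 1e-12
                    gain = diff * diff / qt
                    if gain > best:
                        best = gain
                        j = t
        if j < 0:
            gap, n_act = _full_recheck(K, y, C, alpha, G, act, tol)
            since_shrink = 0
            if gap <= tol or stalled:
                break
            stalled = True
            continue
        rowj = K[j]
        q = kii + rowj[j] - 2.0 * rowi[j]
        if q <= 1e-12:
            q = 1e-12
        # E_t = f_t - y_t = y_t * G_t; analytic two-variable step on alpha_j
        aj_new = alpha[j] + y[j] * (y[i] * G[i] - y[j] * G[j]) / q
        s = y[i] * y[j]
        if s < 0:
            lo = max(0.0, alpha[j] - alpha[i])
            hi = min(C, C + alpha[j] - alpha[i])
        else:
            lo = max(0.0, alpha[i] + alpha[j] - C)
            hi = min(C, alpha[i] + alpha[j])
        if aj_new < lo:
            aj_new = lo
        elif aj_new > hi:
            aj_new = hi
        daj = aj_new - alpha[j]
        if abs(daj) < 1e-15:
            gap, n_act = _full_recheck(K, y, C, alpha, G, act, tol)
            since_shrink = 0
            if gap <= tol or stalled:
                break
            stalled = True
            continue
        dai = -s * daj
        alpha[i] += dai
        alpha[j] += daj
        ci = dai * y[i]
        cj = daj * y[j]
        for a in range(n_act):
            t = act[a]
            G[t] += y[t] * (ci * rowi[t] + cj * rowj[t])
    if it >= max_iter:
        gap, n_act = _full_recheck(K, y, C, alpha, G, act, tol)
    return alpha, G, it, gap


def offset_from_gradient(alpha: np.ndarray, G: np.ndarray, y: np.ndarray,
                         C: float) -> float:
    """Hyperplane offset b from the dual gradient.

    Averaged over free support vectors (0 < alpha < C); when none are
    free, the midpoint of the feasible interval is used.
    """
    g = -y * G
    free = (alpha > _BOX_EPS) & (alpha < C - _BOX_EPS)
    if free.any():
        return float(g[free].mean())
    up = ((y > 0) & (alpha < C - _BOX_EPS)) | ((y < 0) & (alpha > _BOX_EPS))
    low = ((y > 0) & (alpha > _BOX_EPS)) | ((y < 0) & (alpha < C - _BOX_EPS))
    hi = g[up].max() if up.any() else 0.0
    lo = g[low].min() if low.any() else 0.0
    return float((hi + lo) / 2.0)
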