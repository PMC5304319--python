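"""Hot inner loops for the successive-averages game algorithms.

With step size ``alpha_m = 1/(m+1)`` the mixed strategies are running averages
of unit best-response vectors, so both players' strategies can be carried as
*count* vectors ``c`` with ``p = c/m`` (the uniform initial point contributes
one unit of count).  The loops below exploit this: each iteration touches one
entry of each weighted-score array, and convergence is checked against the
duality gap ``max_j p_j U_j - min_j q_j U_j``.

The loops are JIT-compiled with numba when it is importable; the plain-Python
definitions are the fallback and the reference for the step-function tests.
"""

from __future__ import annotations

import numpy as np


def _a0_loop(U, max_iter, tol_abs, tol_rel, trace_every):
    """Fictitious play on the diagonal exposure game.

    Returns ``(cp, cq, m, ub, lb, converged, tr_m, tr_ub, tr_lb, n_tr)``
    where ``cp/m`` and ``cq/m`` are the final mixed strategies.
    """
    n = U.shape[0]
    cp = np.full(n, 1.0 / n)
    cq = np.full(n, 1.0 / n)
    pU = cp * U
    qU = cq * U
    n_tr = max_iter // trace_every + 1 if trace_every > 0 else 0
    tr_m = np.zeros(n_tr, dtype=np.int64)
    tr_ub = np.zeros(n_tr)
    tr_lb = np.zeros(n_tr)
    k_tr = 0
    m = 1
    converged = False
    ub = np.inf
    lb = -np.inf
    while m <= max_iter:
        # scheduler's best response: least avoidance-weighted unfitness
        j = 0
        qmin = qU[0]
        for t in range(1, n):
            if qU[t] < qmin:
                qmin = qU[t]
                j = t
        if m > 1:
            lb = qmin / m
            gap = ub - lb
            if trace_every > 0 and (m - 1) % trace_every == 0:
                tr_m[k_tr] = m
                tr_ub[k_tr] = ub
                tr_lb[k_tr] = lb
                k_tr += 1
            if gap <= tol_abs or (tol_rel > 0.0 and gap <= tol_rel * lb):
                converged = True
                break
        cp[j] += 1.0
        pU[j] += U[j]
        # demon's best response: highest expected unfitness under updated p
        i = 0
        pmax = pU[0]
        for t in range(1, n):
            if pU[t] > pmax:
                pmax = pU[t]
                i = t
        cq[i] += 1.0
        qU[i] += U[i]
        m += 1
        ub = pmax / m
    # on max_iter exit the cached lb predates the final q update; recompute
    # both bounds from the final arrays so they always describe cp/m, cq/m
    ub = pU[0]
    lb = qU[0]
    for t in range(1, n):
        if pU[t] > ub:
            ub = pU[t]
        if qU[t] < lb:
            lb = qU[t]
    ub /= m
    lb /= m
    return cp, cq, m, ub, lb, converged, tr_m, tr_ub, tr_lb, k_tr


def _a1_loop_complete(U, offsets, max_iter, tol_abs, tol_rel):
    """Tier-coupled fictitious play under complete inter-tier adjacency.

    With complete adjacency the shortest-path best response separates into a
    per-tier argmin, so each tier runs the diagonal-game update on a shared
    iteration counter.  ``U`` holds the tier unfitness vectors concatenated;
    ``offsets`` delimits tiers.  Stops when every tier's gap passes the test.
    """
    K = offsets.shape[0] - 1
    ntot = U.shape[0]
    cp = np.empty(ntot)
    cq = np.empty(ntot)
    for k in range(K):
        a, b = offsets[k], offsets[k + 1]
        cp[a:b] = 1.0 / (b - a)
        cq[a:b] = 1.0 / (b - a)
    pU = cp * U
    qU = cq * U
    ubs = np.full(K, np.inf)
    lbs = np.full(K, -np.inf)
    jstar = np.zeros(K, dtype=np.int64)
    pmaxs = np.zeros(K)
    m = 1
    converged = False
    while m <= max_iter:
        # best path under complete adjacency = per-tier argmin of q_j U_j;
        # check all tiers' gaps before applying this iteration's update
        all_ok = m > 1
        for k in range(K):
            a, b = offsets[k], offsets[k + 1]
            j = a
            qmin = qU[a]
            for t in range(a + 1, b):
                if qU[t] < qmin:
                    qmin = qU[t]
                    j = t
            jstar[k] = j
            if m > 1:
                lbs[k] = qmin / m
                gap = ubs[k] - lbs[k]
                if not (
                    gap <= tol_abs
                    or (tol_rel > 0.0 and gap <= tol_rel * lbs[k])
                ):
                    all_ok = False
        if all_ok:
            converged = True
            break
        for k in range(K):
            a, b = offsets[k], offsets[k + 1]
            j = jstar[k]
            cp[j] += 1.0
            pU[j] += U[j]
            i = a
            pmax = pU[a]
            for t in range(a + 1, b):
                if pU[t] > pmax:
                    pmax = pU[t]
                    i = t
            cq[i] += 1.0
            qU[i] += U[i]
            pmaxs[k] = pmax
        m += 1
        for k in range(K):
            ubs[k] = pmaxs[k] / m
    for k in range(K):
        a, b = offsets[k], offsets[k + 1]
        ub = pU[a]
        lb = qU[a]
        for t in range(a + 1, b):
            if pU[t] > ub:
                ub = pU[t]
            if qU[t] < lb:
                lb = qU[t]
        ubs[k] = ub / m
        lbs[k] = lb / m
    return cp, cq, m, ubs, lbs, converged


try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _a0_loop = njit(cache=True)(_a0_loop)
    _a1_loop_complete = njit(cache=True)(_a1_loop_complete)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False
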