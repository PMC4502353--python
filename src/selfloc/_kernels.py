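"""Numba kernels: C-SVC training (SMO) and batched searchlight decoding.

The classifier is the soft-margin linear support-vector machine (C-SVC,
hinge loss, fixed C) solved in the dual by sequential minimal optimization
with second-order working-set selection — the LIBSVM algorithm, on a
precomputed Gram matrix. For the small problems a searchlight produces
(tens of trials, tens of voxels) a JIT-compiled batched solver is orders
of magnitude faster than per-cluster calls into a general-purpose library,
which is what makes permutation schemes with 10^4-scale iteration counts
tractable on one CPU. ``sklearn.svm.SVC(kernel="linear")`` solves the
identical optimization problem and serves as the independent cross-check
in the test suite.

Determinism: working-set selection has no random component; identical
inputs give bit-identical results.

Implementation notes (performance, not semantics):

* the per-fold Gram matrix is computed once and shared by every labeling
  of a permutation batch;
* when the training labels are balanced, alpha is initialized at the C
  bound (a dual-feasible point, since sum(y * alpha) = 0), which roughly
  halves SMO iteration counts on noise-dominated data where most dual
  variables end at the bound; the optimum reached is the same;
* the gradient update of one iteration is fused with the selection scan
  of the next.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: labels are +1 ("A") / -1 ("B"); zero decision values classify as +1.
LABEL_POS = 1
LABEL_NEG = -1

#: LIBSVM's default KKT-violation stopping tolerance.
SVM_TOL = 1e-3
SVM_MAX_ITER = 100_000

_NEG = -1e300


@njit(cache=True, fastmath=True)
def smo_solve(K, Qd, y, C, tol, max_iter, alpha, G, vU, dec, up, low):
    """Solve the C-SVC dual on a precomputed Gram matrix.

    min_a 0.5 a'Qa - e'a  s.t. 0 <= a <= C, y'a = 0,  Q_ij = y_i y_j K_ij.

    ``Qd`` is the diagonal of K; the remaining arrays are preallocated
    (n,) work/output buffers. On return ``alpha`` holds the dual solution
    and ``G`` the gradient. Returns ``(rho, iterations)``; the decision
    value of a point x is sum_i alpha_i y_i K(x_i, x) - rho.
    """
    n = K.shape[0]
    npos = 0
    for t in range(n):
        if y[t] > 0.0:
            npos += 1
    if 2 * npos == n:
        # balanced: start from the dual-feasible all-at-bound point
        for t in range(n):
            alpha[t] = C
        for t in range(n):
            s = 0.0
            for u in range(n):
                s += y[u] * K[t, u]
            G[t] = C * y[t] * s - 1.0
    else:
        for t in range(n):
            alpha[t] = 0.0
            G[t] = -1.0
    for t in range(n):
        a = alpha[t]
        if y[t] > 0.0:
            up[t] = a < C
            low[t] = a > 0.0
        else:
            up[t] = a > 0.0
            low[t] = a < C

    ci = 0.0
    cj = 0.0
    i = 0
    j = 0
    it = 0
    while True:
        # apply the pending rank-2 gradient update, refresh -y*G
        for t in range(n):
            g = G[t] + y[t] * (ci * K[i, t] + cj * K[j, t])
            G[t] = g
            vU[t] = -y[t] * g
        # maximal violating pair: i from I_up, stopping gap from I_low
        gmax = _NEG
        for t in range(n):
            if up[t] and vU[t] > gmax:
                gmax = vU[t]
        gmax2 = _NEG
        for t in range(n):
            if low[t] and -vU[t] > gmax2:
                gmax2 = -vU[t]
        if gmax + gmax2 < tol or it >= max_iter:
            break
        i = 0
        for t in range(n):
            if up[t] and vU[t] == gmax:
                i = t
                break
        # second-order j: maximize (grad gap)^2 / curvature
        si = y[i]
        Qdi = Qd[i]
        for t in range(n):
            gd = gmax - vU[t]
            quad = Qdi + Qd[t] - 2.0 * si * y[t] * K[i, t]
            quad = quad if quad > 1e-12 else 1e-12
            v = (gd * gd) / quad
            dec[t] = v if (low[t] and gd > 0.0) else _NEG
        dmax = _NEG
        for t in range(n):
            if dec[t] > dmax:
                dmax = dec[t]
        if dmax <= _NEG:
            break
        j = 0
        for t in range(n):
            if dec[t] == dmax:
                j = t
                break

        # analytic two-variable update with box clipping (LIBSVM)
        oai = alpha[i]
        oaj = alpha[j]
        qij = si * y[j] * K[i, j]
        if y[i] != y[j]:
            quad = Qd[i] + Qd[j] + 2.0 * qij
            if quad <= 0.0:
                quad = 1e-12
            delta = (-G[i] - G[j]) / quad
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0.0:
                if alpha[j] < 0.0:
                    alpha[j] = 0.0
                    alpha[i] = diff
            else:
                if alpha[i] < 0.0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
            if diff > 0.0:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = C - diff
            else:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = C + diff
        else:
            quad = Qd[i] + Qd[j] - 2.0 * qij
            if quad <= 0.0:
                quad = 1e-12
            delta = (G[i] - G[j]) / quad
            ssum = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if ssum > C:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = ssum - C
            else:
                if alpha[j] < 0.0:
                    alpha[j] = 0.0
                    alpha[i] = ssum
            if ssum > C:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = ssum - C
            else:
                if alpha[i] < 0.0:
                    alpha[i] = 0.0
                    alpha[j] = ssum

        ci = y[i] * (alpha[i] - oai)
        cj = y[j] * (alpha[j] - oaj)
        ai = alpha[i]
        aj = alpha[j]
        if y[i] > 0.0:
            up[i] = ai < C
            low[i] = ai > 0.0
        else:
            up[i] = ai > 0.0
            low[i] = ai < C
        if y[j] > 0.0:
            up[j] = aj < C
            low[j] = aj > 0.0
        else:
            up[j] = aj > 0.0
            low[j] = aj < C
        it += 1

    # rho from the KKT conditions
    ub = np.inf
    lb = -np.inf
    sum_free = 0.0
    nr_free = 0
    for t in range(n):
        yg = y[t] * G[t]
        if alpha[t] >= C:
            if y[t] < 0.0:
                if yg < ub:
                    ub = yg
            else:
                if yg > lb:
                    lb = yg
        elif alpha[t] <= 0.0:
            if y[t] > 0.0:
                if yg < ub:
                    ub = yg
            else:
                if yg > lb:
                    lb = yg
        else:
            nr_free += 1
            sum_free += yg
    rho = sum_free / nr_free if nr_free > 0 else (ub + lb) / 2.0
    return rho, it


@njit(cache=True, fastmath=True)
def svm_train_weights(X, y, C, tol, max_iter, w):
    """Train linear C-SVC on (X, y); fill w[:d] and return rho (bias -rho).

    Convenience single-problem entry point over :func:`smo_solve`.
    """
    n, d = X.shape
    K = np.dot(X, X.T)
    Qd = np.empty(n)
    for t in range(n):
        Qd[t] = K[t, t]
    alpha = np.empty(n)
    G = np.empty(n)
    vU = np.empty(n)
    dec = np.empty(n)
    up = np.zeros(n, np.bool_)
    low = np.zeros(n, np.bool_)
    rho, _ = smo_solve(K, Qd, y, C, tol, max_iter, alpha, G, vU, dec, up, low)
    for j in range(d):
        w[j] = 0.0
    for i in range(n):
        if alpha[i] != 0.0:
            a = alpha[i] * y[i]
            for j in range(d):
                w[j] += a * X[i, j]
    return rho


@njit(cache=True, fastmath=True)
def cluster_accuracies_batch(
    X,
    Y,
    run_of,
    runs_unique,
    members,
    C,
    tol,
    max_iter,
    Xt,
    yt,
    runt,
    do_transfer,
):
    """Leave-one-run-out cluster accuracies for many labelings at once.

    X        : (n, D) trial responses over the full ROI
    Y        : (L, n) labelings in {+1,-1}; row 0 is typically the true one
    run_of   : (n,) run index per trial
    members  : (n_clusters, k) ROI column indices of each cluster
    Xt/yt/runt : transfer test set (e.g. asynchronous trials) scored with
                 the fold classifiers trained on X; yt stays fixed (true)
                 while the training labels vary with Y.

    Returns (acc_within, acc_transfer), each (L, n_clusters) in percent.
    Fold accuracy is the percent correct in the left-out run; the cluster
    value is the unweighted mean over folds.
    """
    n, D = X.shape
    L = Y.shape[0]
    n_cl, k = members.shape
    R = runs_unique.shape[0]
    nt = Xt.shape[0]

    acc_w = np.zeros((L, n_cl))
    acc_t = np.zeros((L, n_cl))

    Xc = np.empty((n, k))
    Xtc = np.empty((nt, k))
    Xtr = np.empty((n, k))
    tr_idx = np.empty(n, np.int64)
    te_idx = np.empty(n, np.int64)
    ytr = np.empty(n)
    alpha = np.empty(n)
    G = np.empty(n)
    vU = np.empty(n)
    dec = np.empty(n)
    up = np.zeros(n, np.bool_)
    low = np.zeros(n, np.bool_)
    Qd = np.empty(n)
    w = np.empty(k)
    fold_w = np.empty((L, R))
    fold_t = np.empty((L, R))

    for c in range(n_cl):
        for i in range(n):
            for j in range(k):
                Xc[i, j] = X[i, members[c, j]]
        if do_transfer:
            for i in range(nt):
                for j in range(k):
                    Xtc[i, j] = Xt[i, members[c, j]]
        # fold-major: the training Gram is built once and reused by all
        # L labelings (only the labels change between permutations)
        for ri in range(R):
            r = runs_unique[ri]
            ntr = 0
            nte = 0
            for i in range(n):
                if run_of[i] != r:
                    tr_idx[ntr] = i
                    for j in range(k):
                        Xtr[ntr, j] = Xc[i, j]
                    ntr += 1
                else:
                    te_idx[nte] = i
                    nte += 1
            K = np.dot(Xtr[:ntr], Xtr[:ntr].T)
            for t in range(ntr):
                Qd[t] = K[t, t]
            for l in range(L):
                for m in range(ntr):
                    ytr[m] = Y[l, tr_idx[m]]
                rho, _ = smo_solve(
                    K, Qd[:ntr], ytr[:ntr], C, tol, max_iter,
                    alpha, G, vU, dec, up, low,
                )
                for j in range(k):
                    w[j] = 0.0
                for m in range(ntr):
                    if alpha[m] != 0.0:
                        a = alpha[m] * ytr[m]
                        for j in range(k):
                            w[j] += a * Xtr[m, j]
                correct = 0
                for m in range(nte):
                    i = te_idx[m]
                    s = -rho
                    for j in range(k):
                        s += w[j] * Xc[i, j]
                    pred = LABEL_POS if s >= 0.0 else LABEL_NEG
                    if pred == Y[l, i]:
                        correct += 1
                fold_w[l, ri] = 100.0 * correct / nte
                if do_transfer:
                    tc = 0
                    tn = 0
                    for i in range(nt):
                        if runt[i] == r:
                            s = -rho
                            for j in range(k):
                                s += w[j] * Xtc[i, j]
                            pred = LABEL_POS if s >= 0.0 else LABEL_NEG
                            if pred == yt[i]:
                                tc += 1
                            tn += 1
                    fold_t[l, ri] = 100.0 * tc / tn if tn > 0 else 0.0
        for l in range(L):
            sw = 0.0
            st = 0.0
            for ri in range(R):
                sw += fold_w[l, ri]
                if do_transfer:
                    st += fold_t[l, ri]
            acc_w[l, c] = sw / R
            if do_transfer:
                acc_t[l, c] = st / R
    return acc_w, acc_t
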