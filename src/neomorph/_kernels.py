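"""Numba kernels: linear-SVM dual coordinate descent, Platt sigmoid, AUC.

The exhaustive descriptor-subset search evaluates ~16k subsets x hundreds
of cross-validation repeats x 4 SVM fits each (3 calibration folds plus
the final model), i.e. millions of small fits.  These kernels implement
the hinge-loss linear SVM via dual coordinate descent (the liblinear
algorithm; bias handled as an augmented, regularized feature), Platt's
sigmoid calibration via Newton iterations, and the tie-aware rank AUC,
all JIT-compiled so a full search runs in minutes on one core.

Correctness is cross-checked against scikit-learn (SVC / LinearSVC /
CalibratedClassifierCV) in the test suite; every routine is a pure,
deterministic function of its inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

_MAX_EPOCHS = 1000
_TOL = 0.01  # projected-gradient spread; liblinear's dual solvers default to 0.1


@njit(cache=True)
def _shuffle_inplace(idx, state):
    """Fisher-Yates with a small LCG; deterministic given state."""
    n = idx.shape[0]
    mul = np.uint64(6364136223846793005)
    inc = np.uint64(1442695040888963407)
    shift = np.uint64(33)
    for i in range(n - 1, 0, -1):
        state = state * mul + inc
        j = int(state >> shift) % (i + 1)
        tmp = idx[i]
        idx[i] = idx[j]
        idx[j] = tmp
    return state


@njit(cache=True)
def _dual_cd_core(X, y, C, eps, max_epochs):
    """Dual coordinate descent with shrinking (Hsieh et al., Algorithm 3).

    Solves min 0.5*||u||^2 + C * sum_i max(0, 1 - y_i u.z_i) where z is X
    augmented with a constant 1 (regularized bias).  Stops when the
    projected-gradient spread over the active set drops below ``eps``,
    shrinking bounded variables whose gradients certify optimality.
    """
    n, d = X.shape
    w = np.zeros(d + 1)  # last component multiplies the bias feature
    alpha = np.zeros(n)
    qii = np.empty(n)
    for i in range(n):
        s = 1.0
        for j in range(d):
            s += X[i, j] * X[i, j]
        qii[i] = s
    index = np.arange(n)
    active = n
    pgmax_old = np.inf
    pgmin_old = -np.inf
    state = np.uint64(88172645463325252)
    for _ in range(max_epochs):
        state = _shuffle_inplace(index[:active], state)
        pgmax = -np.inf
        pgmin = np.inf
        t = 0
        while t < active:
            i = index[t]
            s = w[d]
            for j in range(d):
                s += w[j] * X[i, j]
            g = y[i] * s - 1.0
            pg = 0.0
            shrink = False
            if alpha[i] <= 0.0:
                if g > pgmax_old:
                    shrink = True
                elif g < 0.0:
                    pg = g
            elif alpha[i] >= C:
                if g < pgmin_old:
                    shrink = True
                elif g > 0.0:
                    pg = g
            else:
                pg = g
            if shrink:
                active -= 1
                index[t] = index[active]
                index[active] = i
                continue
            if pg > pgmax:
                pgmax = pg
            if pg < pgmin:
                pgmin = pg
            if abs(pg) > 1e-12:
                a_new = alpha[i] - g / qii[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                delta = (a_new - alpha[i]) * y[i]
                alpha[i] = a_new
                for j in range(d):
                    w[j] += delta * X[i, j]
                w[d] += delta
            t += 1
        if pgmax - pgmin <= eps:
            if active == n:
                break
            # optimal on the active set: re-admit everything and re-check
            active = n
            pgmax_old = np.inf
            pgmin_old = -np.inf
            continue
        pgmax_old = pgmax if pgmax > 0.0 else np.inf
        pgmin_old = pgmin if pgmin < 0.0 else -np.inf
    return w[:d], w[d]


@njit(cache=True)
def svm_dual_cd(X, y, C):
    """Hinge-loss linear SVM: returns (w, b) in the original coordinates.

    The dual coordinate-descent core is run on train-mean-centered
    features — centering decorrelates the (regularized) bias feature
    from columns that are all-positive after min-max scaling, which
    speeds convergence by an order of magnitude; the intercept is mapped
    back as b = b_centered - w . mean.
    """
    n, d = X.shape
    mu = np.empty(d)
    for j in range(d):
        s = 0.0
        for i in range(n):
            s += X[i, j]
        mu[j] = s / n
    Xc = np.empty_like(X)
    for i in range(n):
        for j in range(d):
            Xc[i, j] = X[i, j] - mu[j]
    w, bc = _dual_cd_core(Xc, y, C, _TOL, _MAX_EPOCHS)
    b = bc
    for j in range(d):
        b -= w[j] * mu[j]
    return w, b


@njit(cache=True)
def decision_values(X, w, b):
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        s = b
        for j in range(X.shape[1]):
            s += w[j] * X[i, j]
        out[i] = s
    return out


@njit(cache=True)
def platt_fit(f, y01):
    """Platt sigmoid parameters (A, B) for P(y=1|f) = 1/(1+exp(A*f+B)).

    Newton iterations with backtracking on the regularized targets
    t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2) (Platt 1999; Lin et al. 2007).
    """
    n = f.shape[0]
    npos = 0.0
    for i in range(n):
        if y01[i] > 0:
            npos += 1.0
    nneg = n - npos
    hi = (npos + 1.0) / (npos + 2.0)
    lo = 1.0 / (nneg + 2.0)
    t = np.empty(n)
    for i in range(n):
        t[i] = hi if y01[i] > 0 else lo

    a = 0.0
    b = np.log((nneg + 1.0) / (npos + 1.0))
    eps = 1e-12

    def _nll(a, b):
        s = 0.0
        for i in range(n):
            z = a * f[i] + b
            if z >= 0.0:
                s += t[i] * z + np.log(1.0 + np.exp(-z))
            else:
                s += (t[i] - 1.0) * z + np.log(1.0 + np.exp(z))
        return s

    fval = _nll(a, b)
    for _ in range(100):
        h11 = eps
        h22 = eps
        h21 = 0.0
        g1 = 0.0
        g2 = 0.0
        for i in range(n):
            z = a * f[i] + b
            if z >= 0.0:
                p = np.exp(-z) / (1.0 + np.exp(-z))
            else:
                p = 1.0 / (1.0 + np.exp(z))
            d1 = t[i] - p
            d2 = p * (1.0 - p)
            g1 += f[i] * d1
            g2 += d1
            h11 += f[i] * f[i] * d2
            h22 += d2
            h21 += f[i] * d2
        if abs(g1) < 1e-5 and abs(g2) < 1e-5:
            break
        det = h11 * h22 - h21 * h21
        da = -(h22 * g1 - h21 * g2) / det
        db = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * da + g2 * db
        step = 1.0
        improved = False
        while step >= 1e-10:
            na, nb = a + step * da, b + step * db
            nf = _nll(na, nb)
            if nf < fval + 1e-4 * step * gd:
                a, b, fval = na, nb, nf
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    return a, b


@njit(cache=True)
def platt_apply(f, a, b):
    n = f.shape[0]
    out = np.empty(n)
    for i in range(n):
        z = a * f[i] + b
        if z >= 0.0:
            out[i] = np.exp(-z) / (1.0 + np.exp(-z))
        else:
            out[i] = 1.0 / (1.0 + np.exp(z))
    return out


@njit(cache=True)
def rank_auc(scores, labels):
    """Mann-Whitney AUC with average-rank tie handling.

    Equals (number of (pos, neg) pairs with s_pos > s_neg plus half the
    tied pairs) / (n_pos * n_neg).
    """
    n = scores.shape[0]
    order = np.argsort(scores)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[order[j + 1]] == scores[order[i]]:
            j += 1
        avg = 0.5 * (i + j) + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    npos = 0.0
    rpos = 0.0
    for i in range(n):
        if labels[i] > 0:
            npos += 1.0
            rpos += ranks[i]
    nneg = n - npos
    if npos == 0.0 or nneg == 0.0:
        return np.nan
    return (rpos - npos * (npos + 1.0) / 2.0) / (npos * nneg)


@njit(cache=True)
def _subset_repeat_probs(Xtr, ytr, Xte, fold_id, fallback, C):
    """Calibrated test probabilities for one (subset, repeat) pair.

    Xtr/Xte are already restricted to the subset's columns and min-max
    scaled with this repeat's training parameters.  ``fold_id`` assigns
    each training row to one of 3 stratified calibration folds;
    ``fallback`` switches to in-sample calibration when a class is too
    small to stratify.
    """
    ntr = Xtr.shape[0]
    ysig = np.empty(ntr)
    for i in range(ntr):
        ysig[i] = 1.0 if ytr[i] > 0 else -1.0

    if fallback:
        w, b = svm_dual_cd(Xtr, ysig, C)
        fcal = decision_values(Xtr, w, b)
        a, bb = platt_fit(fcal, ytr)
        fte = decision_values(Xte, w, b)
        return platt_apply(fte, a, bb)

    fcal = np.empty(ntr)
    for fold in range(3):
        nin = 0
        for i in range(ntr):
            if fold_id[i] != fold:
                nin += 1
        Xin = np.empty((nin, Xtr.shape[1]))
        yin = np.empty(nin)
        k = 0
        for i in range(ntr):
            if fold_id[i] != fold:
                Xin[k] = Xtr[i]
                yin[k] = ysig[i]
                k += 1
        w, b = svm_dual_cd(Xin, yin, C)
        for i in range(ntr):
            if fold_id[i] == fold:
                s = b
                for j in range(Xtr.shape[1]):
                    s += w[j] * Xtr[i, j]
                fcal[i] = s
    a, bb = platt_fit(fcal, ytr)
    w, b = svm_dual_cd(Xtr, ysig, C)
    fte = decision_values(Xte, w, b)
    return platt_apply(fte, a, bb)


@njit(cache=True)
def evaluate_mask_probs(Xtr, ytr, Xte, fold_id, fallback, mask, C):
    """Pooled calibrated probabilities for one subset over all repeats.

    Xtr: (R, ntr, D) scaled training features per repeat; Xte: (R, nte, D);
    mask: (D,) boolean subset flags.  Returns (R, nte) probabilities.
    """
    R, ntr, D = Xtr.shape
    nte = Xte.shape[1]
    k = 0
    for j in range(D):
        if mask[j]:
            k += 1
    cols = np.empty(k, dtype=np.int64)
    k = 0
    for j in range(D):
        if mask[j]:
            cols[k] = j
            k += 1
    probs = np.empty((R, nte))
    Xs = np.empty((ntr, k))
    Xt = np.empty((nte, k))
    for r in range(R):
        for i in range(ntr):
            for j in range(k):
                Xs[i, j] = Xtr[r, i, cols[j]]
        for i in range(nte):
            for j in range(k):
                Xt[i, j] = Xte[r, i, cols[j]]
        probs[r] = _subset_repeat_probs(Xs, ytr[r], Xt, fold_id[r], fallback[r], C)
    return probs


@njit(cache=True, parallel=True)
def search_masks_auc(Xtr, ytr, Xte, yte, fold_id, fallback, masks, C):
    """Pooled AUC for every subset mask; the exhaustive-search hot loop.

    masks: (M, D) boolean.  Returns (M,) pooled AUCs.  Each subset is
    evaluated independently on the shared splits, so the result is
    identical whether run serially or in parallel.
    """
    M = masks.shape[0]
    R, nte = yte.shape
    ylab = np.empty(R * nte)
    for r in range(R):
        for i in range(nte):
            ylab[r * nte + i] = yte[r, i]
    out = np.empty(M)
    for m in prange(M):
        probs = evaluate_mask_probs(Xtr, ytr, Xte, fold_id, fallback, masks[m], C)
        out[m] = rank_auc(probs.ravel(), ylab)
    return out
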