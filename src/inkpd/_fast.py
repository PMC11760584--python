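"""Numba kernels: weighted CART building, SAMME boosting, sample entropy.

The hyperparameter search fits on the order of a million small boosted
ensembles (population 50, 10 iterations, 3 inner folds, per family, per
outer fold), so the tree builder and boosting loop are compiled. The tree
is a standard exhaustive-search CART with weighted Gini impurity; split
choice matches scikit-learn's ``DecisionTreeClassifier`` (midpoint
thresholds, splits only between distinct values), which the test suite
verifies on random weighted problems.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["build_tree", "predict_tree", "fit_samme", "predict_samme", "sample_entropy"]


@njit(cache=True)
def build_tree(X, y, sw, n_classes, max_depth, min_samples_split,
               feat, thr, left, right, value):
    """Grow one weighted-Gini CART into the preallocated node arrays.

    ``X`` is (n, f) float32, ``y`` int64 class codes, ``sw`` float64 sample
    weights. ``min_samples_split`` is an absolute sample count. Returns the
    number of nodes used; internal nodes have ``feat >= 0``.
    """
    n, f = X.shape
    max_nodes = feat.shape[0]
    idx = np.arange(n)
    node_lo = np.empty(max_nodes, np.int64)
    node_hi = np.empty(max_nodes, np.int64)
    node_depth = np.empty(max_nodes, np.int64)
    stack = np.empty(max_nodes, np.int64)
    node_lo[0] = 0
    node_hi[0] = n
    node_depth[0] = 0
    n_nodes = 1
    stack[0] = 0
    sp = 1
    while sp > 0:
        sp -= 1
        nid = stack[sp]
        lo, hi, depth = node_lo[nid], node_hi[nid], node_depth[nid]
        tot = np.zeros(n_classes)
        wsum = 0.0
        for ii in range(lo, hi):
            i = idx[ii]
            tot[y[i]] += sw[i]
            wsum += sw[i]
        for k in range(n_classes):
            value[nid, k] = tot[k]
        feat[nid] = -1
        n_pos = 0
        for k in range(n_classes):
            if tot[k] > 0.0:
                n_pos += 1
        if (depth >= max_depth or hi - lo < min_samples_split
                or n_pos <= 1 or hi - lo < 2):
            continue
        sq = 0.0
        for k in range(n_classes):
            sq += tot[k] * tot[k]
        best_gain = 1e-12
        best_f = -1
        best_thr = 0.0
        for j in range(f):
            vals = np.empty(hi - lo, np.float32)
            for ii in range(lo, hi):
                vals[ii - lo] = X[idx[ii], j]
            order = np.argsort(vals, kind="mergesort")
            lcw = np.zeros(n_classes)
            lw = 0.0
            lsq = 0.0
            rsq = sq
            for p in range(hi - lo - 1):
                i = idx[lo + order[p]]
                c = y[i]
                w = sw[i]
                lsq += w * (2.0 * lcw[c] + w)
                rsq += w * (w - 2.0 * tot[c] + 2.0 * lcw[c])
                lcw[c] += w
                lw += w
                v_here = vals[order[p]]
                v_next = vals[order[p + 1]]
                if v_next <= v_here:
                    continue
                rw = wsum - lw
                if lw <= 0.0 or rw <= 0.0:
                    continue
                # Gini decrease up to the constant sq/wsum
                gain = lsq / lw + rsq / rw - sq / wsum
                if gain > best_gain:
                    best_gain = gain
                    best_f = j
                    best_thr = 0.5 * (v_here + v_next)
        if best_f < 0 or n_nodes + 2 > max_nodes:
            continue
        tmp = np.empty(hi - lo, np.int64)
        a = 0
        for ii in range(lo, hi):
            i = idx[ii]
            if X[i, best_f] <= best_thr:
                tmp[a] = i
                a += 1
        b = a
        for ii in range(lo, hi):
            i = idx[ii]
            if X[i, best_f] > best_thr:
                tmp[b] = i
                b += 1
        for ii in range(hi - lo):
            idx[lo + ii] = tmp[ii]
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feat[nid] = best_f
        thr[nid] = best_thr
        left[nid] = lid
        right[nid] = rid
        node_lo[lid] = lo
        node_hi[lid] = lo + a
        node_depth[lid] = depth + 1
        node_lo[rid] = lo + a
        node_hi[rid] = hi
        node_depth[rid] = depth + 1
        stack[sp] = lid
        sp += 1
        stack[sp] = rid
        sp += 1
    return n_nodes


@njit(cache=True)
def predict_tree(X, feat, thr, left, right, value, n_classes):
    """Leaf class-weight distributions, normalised to probabilities."""
    n = X.shape[0]
    out = np.empty((n, n_classes))
    for i in range(n):
        nid = 0
        while feat[nid] >= 0:
            if X[i, feat[nid]] <= thr[nid]:
                nid = left[nid]
            else:
                nid = right[nid]
        s = 0.0
        for k in range(n_classes):
            s += value[nid, k]
        if s <= 0.0:
            # zero-weight leaf (boosting weights underflowed): uninformative
            for k in range(n_classes):
                out[i, k] = 1.0 / n_classes
        else:
            for k in range(n_classes):
                out[i, k] = value[nid, k] / s
    return out


@njit(cache=True)
def fit_samme(X, y, n_classes, max_depth, min_split_frac, n_estimators,
              learning_rate):
    """Discrete SAMME boosting of weighted CARTs.

    Stops early when a round's weighted error is 0 (that tree alone is a
    perfect committee member) or >= 1 - 1/K (worse than random; the round
    is discarded unless it is the first). Returns the per-tree node arrays,
    the estimator weights alpha and the number of trees kept.
    """
    n = X.shape[0]
    max_nodes = 2 * n + 1
    min_split = int(np.ceil(min_split_frac * n))
    if min_split < 2:
        min_split = 2
    feats = np.empty((n_estimators, max_nodes), np.int64)
    thrs = np.empty((n_estimators, max_nodes))
    lefts = np.empty((n_estimators, max_nodes), np.int64)
    rights = np.empty((n_estimators, max_nodes), np.int64)
    values = np.empty((n_estimators, max_nodes, n_classes))
    alphas = np.zeros(n_estimators)
    sw = np.full(n, 1.0 / n)
    n_used = 0
    for b in range(n_estimators):
        build_tree(X, y, sw, n_classes, max_depth, min_split,
                   feats[b], thrs[b], lefts[b], rights[b], values[b])
        proba = predict_tree(X, feats[b], thrs[b], lefts[b], rights[b],
                             values[b], n_classes)
        err = 0.0
        miss = np.empty(n, np.bool_)
        for i in range(n):
            best_k = 0
            best_p = proba[i, 0]
            for k in range(1, n_classes):
                if proba[i, k] > best_p:
                    best_p = proba[i, k]
                    best_k = k
            miss[i] = best_k != y[i]
            if miss[i]:
                err += sw[i]
        if err <= 1e-12:
            alphas[b] = 1.0
            n_used = b + 1
            break
        if err >= 1.0 - 1.0 / n_classes:
            if b == 0:
                alphas[b] = 1e-10
                n_used = 1
            break
        alpha = learning_rate * (np.log((1.0 - err) / err) + np.log(n_classes - 1.0))
        alphas[b] = alpha
        n_used = b + 1
        tot = 0.0
        for i in range(n):
            if miss[i]:
                sw[i] *= np.exp(min(alpha, 500.0))
            tot += sw[i]
        for i in range(n):
            sw[i] /= tot
    return feats, thrs, lefts, rights, values, alphas, n_used


@njit(cache=True)
def predict_samme(X, feats, thrs, lefts, rights, values, alphas, n_used,
                  n_classes):
    """Alpha-weighted mean of the trees' leaf class distributions."""
    n = X.shape[0]
    out = np.zeros((n, n_classes))
    asum = 0.0
    for b in range(n_used):
        proba = predict_tree(X, feats[b], thrs[b], lefts[b], rights[b],
                             values[b], n_classes)
        for i in range(n):
            for k in range(n_classes):
                out[i, k] += alphas[b] * proba[i, k]
        asum += alphas[b]
    if asum > 0.0:
        for i in range(n):
            for k in range(n_classes):
                out[i, k] /= asum
    return out


@njit(cache=True)
def sample_entropy(x, m, r):
    """Sample entropy SampEn(m, r): -ln(A/B) over Chebyshev template matches.

    A degenerate signal (no matches at either length) returns 0 so that
    downstream feature tables stay finite.
    """
    n = x.shape[0]
    if n <= m + 1 or r <= 0.0:
        return 0.0
    b_count = 0
    a_count = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d <= r:
                b_count += 1
                diff = abs(x[i + m] - x[j + m])
                if diff > d:
                    d = diff
                if d <= r:
                    a_count += 1
    if b_count == 0 or a_count == 0:
        return 0.0
    return -np.log(a_count / b_count)
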