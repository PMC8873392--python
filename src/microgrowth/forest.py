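"""A compact random-forest regressor engine.

CART regression trees (variance-reduction splits, ``mtry`` features drawn
per node, bootstrap resampling with a configurable per-tree sample
fraction, out-of-bag error) implemented with numba so that the permutation
machinery in :mod:`microgrowth.rf` — thousands of refits on small cohort
tables — stays cheap.  Semantics follow the classic algorithm (Breiman
bagging + random feature subspace; ranger-style ``sample.fraction`` with
replacement); tests compare its accuracy and OOB error against an
independent reference forest implementation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["RandomForest"]


@njit(cache=True)
def _build_tree(X, y, samples, mtry, min_leaf, feature, threshold, left, right, value):
    """Depth-first CART build over ``samples`` (in-place partitioned).

    Node arrays are pre-allocated by the caller; returns the node count.
    """
    n_total = samples.shape[0]
    p = X.shape[1]
    # explicit stack of (node_id, start, end)
    stack = np.empty((2 * n_total + 2, 3), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n_total
    top = 1
    n_nodes = 1
    feat_pool = np.empty(p, np.int64)
    buf = np.empty(n_total, np.int64)
    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        m = end - start
        tot = 0.0
        totsq = 0.0
        for i in range(start, end):
            v = y[samples[i]]
            tot += v
            totsq += v * v
        mean = tot / m
        value[node] = mean
        if m < 2 * min_leaf or totsq - tot * mean < 1e-12:
            feature[node] = -1
            continue
        # draw mtry features without replacement (partial Fisher-Yates)
        for j in range(p):
            feat_pool[j] = j
        best_gain = 1e-12
        best_f = -1
        best_thr = 0.0
        base = tot * tot / m
        for k in range(mtry):
            r = k + np.random.randint(0, p - k)
            f = feat_pool[r]
            feat_pool[r] = feat_pool[k]
            feat_pool[k] = f
            vals = np.empty(m)
            for i in range(m):
                vals[i] = X[samples[start + i], f]
            order = np.argsort(vals, kind="mergesort")
            cum = 0.0
            for i in range(m - 1):
                cum += y[samples[start + order[i]]]
                if vals[order[i]] == vals[order[i + 1]]:
                    continue
                nl = i + 1
                nr = m - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                gain = cum * cum / nl + (tot - cum) * (tot - cum) / nr - base
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (vals[order[i]] + vals[order[i + 1]])
        if best_f < 0:
            feature[node] = -1
            continue
        # stable partition into buf: left block then right block
        nl = 0
        for i in range(start, end):
            if X[samples[i], best_f] <= best_thr:
                buf[nl] = samples[i]
                nl += 1
        nr = nl
        for i in range(start, end):
            if X[samples[i], best_f] > best_thr:
                buf[nr] = samples[i]
                nr += 1
        for i in range(m):
            samples[start + i] = buf[i]
        feature[node] = best_f
        threshold[node] = best_thr
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        left[node] = lid
        right[node] = rid
        stack[top, 0] = lid
        stack[top, 1] = start
        stack[top, 2] = start + nl
        top += 1
        stack[top, 0] = rid
        stack[top, 1] = start + nl
        stack[top, 2] = end
        top += 1
    return n_nodes


@njit(cache=True)
def _predict_tree(X, out, feature, threshold, left, right, value):
    for i in range(X.shape[0]):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] += value[node]


@njit(cache=True)
def _fit_forest(X, y, n_trees, mtry, n_boot, min_leaf, seed, compute_oob):
    np.random.seed(seed)
    n = X.shape[0]
    cap = 2 * n_boot + 2
    feature = np.empty((n_trees, cap), np.int64)
    threshold = np.zeros((n_trees, cap))
    left = np.zeros((n_trees, cap), np.int64)
    right = np.zeros((n_trees, cap), np.int64)
    value = np.zeros((n_trees, cap))
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, np.int64)
    inbag = np.zeros(n, np.bool_)
    pred1 = np.zeros(1)
    for t in range(n_trees):
        boot = np.random.randint(0, n, n_boot)
        _build_tree(
            X, y, boot.copy(), mtry, min_leaf,
            feature[t], threshold[t], left[t], right[t], value[t],
        )
        if compute_oob:
            for i in range(n):
                inbag[i] = False
            for i in range(n_boot):
                inbag[boot[i]] = True
            for i in range(n):
                if not inbag[i]:
                    pred1[0] = 0.0
                    _predict_tree(
                        X[i : i + 1], pred1,
                        feature[t], threshold[t], left[t], right[t], value[t],
                    )
                    oob_sum[i] += pred1[0]
                    oob_cnt[i] += 1
    oob_mse = -1.0
    if compute_oob:
        sse = 0.0
        k = 0
        for i in range(n):
            if oob_cnt[i] > 0:
                d = oob_sum[i] / oob_cnt[i] - y[i]
                sse += d * d
                k += 1
        if k > 0:
            oob_mse = sse / k
    return feature, threshold, left, right, value, oob_mse


@njit(cache=True)
def _predict_forest(X, feature, threshold, left, right, value):
    n_trees = feature.shape[0]
    out = np.zeros(X.shape[0])
    for t in range(n_trees):
        _predict_tree(X, out, feature[t], threshold[t], left[t], right[t], value[t])
    return out / n_trees


class RandomForest:
    """Regression random forest.

    Parameters
    ----------
    n_trees : int
        Ensemble size.
    mtry : int
        Features considered per split.
    sample_fraction : float
        Per-tree bootstrap size as a fraction of n (drawn with replacement).
    min_samples_leaf : int
        Minimum samples per leaf (5, the common regression-forest default).
    seed : int
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry: int | None = None,
        sample_fraction: float = 1.0,
        min_samples_leaf: int = 5,
        seed: int = 0,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.sample_fraction = sample_fraction
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed

    def fit(self, X, y, compute_oob: bool = False):
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        n, p = X.shape
        mtry = self.mtry if self.mtry is not None else max(1, p // 3)
        mtry = min(mtry, p)
        n_boot = max(2 * self.min_samples_leaf, int(round(self.sample_fraction * n)))
        (self._feature, self._threshold, self._left, self._right, self._value,
         oob) = _fit_forest(
            X, y, self.n_trees, mtry, n_boot, self.min_samples_leaf,
            self.seed % 2**31, compute_oob,
        )
        self.oob_mse_ = float(oob) if oob >= 0 else float("nan")
        return self

    def predict(self, X) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        return _predict_forest(
            X, self._feature, self._threshold, self._left, self._right, self._value
        )
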