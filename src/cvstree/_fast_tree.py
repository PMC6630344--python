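"""Compiled kernel for least-squares tree growth.

Grows the whole tree in one machine-code pass and returns it as flat
arrays; ``tree.fit_tree`` rebuilds node objects from them.  Each predictor
column is sorted once up front and the per-column sorted orders are
maintained through every split by stable partitioning, so finding a
node's best split is a single linear scan per column with no re-sorting
(the classic presorted CART layout).

The split rule is identical to the reference ``tree.best_split``:
candidate thresholds are midpoints between consecutive distinct sorted
values, a split must strictly reduce the residual sum of squares, and
ties break to the lowest column index then the smallest threshold
(guaranteed by scanning columns and thresholds in ascending order and
accepting only strict improvements).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SSE_RTOL = 1e-9


@njit(cache=True)
def _grow_arrays(X, y, min_node_size, max_depth):  # pragma: no cover - compiled
    """Returns (feature, threshold, left, right, value, count).

    ``feature[i] < 0`` marks a leaf.  X is the (n x k) matrix of the
    allowed columns only; feature indices are local to that matrix.
    """
    n, k = X.shape
    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, -1, dtype=np.int64)
    threshold = np.zeros(max_nodes, dtype=np.float64)
    left = np.full(max_nodes, -1, dtype=np.int64)
    right = np.full(max_nodes, -1, dtype=np.int64)
    value = np.zeros(max_nodes, dtype=np.float64)
    count = np.zeros(max_nodes, dtype=np.int64)

    # per-column row orders, kept sorted within every node's segment
    sidx = np.empty((k, n), dtype=np.int64)
    for c in range(k):
        sidx[c] = np.argsort(X[:, c])
    goes_left = np.empty(n, dtype=np.uint8)
    buf_left = np.empty(n, dtype=np.int64)
    buf_right = np.empty(n, dtype=np.int64)

    # stack of (start, end, depth, node_id)
    stack = np.empty((max_nodes, 4), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = n
    stack[0, 2] = 0
    stack[0, 3] = 0
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        start = stack[top, 0]
        end = stack[top, 1]
        depth = stack[top, 2]
        node = stack[top, 3]
        m = end - start

        sy = 0.0
        syy = 0.0
        for pos in range(start, end):
            yi = y[sidx[0, pos]]
            sy += yi
            syy += yi * yi
        value[node] = sy / m
        count[node] = m
        parent_sse = syy - sy * sy / m
        tol = _SSE_RTOL * max(1.0, parent_sse)

        if m < min_node_size or depth >= max_depth:
            continue
        if parent_sse <= _SSE_RTOL * max(1.0, syy):
            continue  # residual error is zero

        best_sse = np.inf
        best_col = -1
        best_thr = 0.0
        for c in range(k):
            s = 0.0
            ss = 0.0
            for pos in range(m - 1):
                r = sidx[c, start + pos]
                yi = y[r]
                s += yi
                ss += yi * yi
                xa = X[r, c]
                xb = X[sidx[c, start + pos + 1], c]
                if xb <= xa:
                    continue
                nl = pos + 1
                nr = m - nl
                sse = (ss - s * s / nl) + (syy - ss - (sy - s) ** 2 / nr)
                if sse < best_sse - tol:
                    best_sse = sse
                    best_col = c
                    best_thr = (xa + xb) / 2.0

        if best_col < 0 or parent_sse - best_sse <= tol:
            continue

        n_left = 0
        for pos in range(start, end):
            r = sidx[best_col, pos]
            if X[r, best_col] <= best_thr:
                goes_left[r] = 1
                n_left += 1
            else:
                goes_left[r] = 0

        # stable partition of every column's segment
        for c in range(k):
            nl = 0
            nr = 0
            for pos in range(start, end):
                r = sidx[c, pos]
                if goes_left[r] == 1:
                    buf_left[nl] = r
                    nl += 1
                else:
                    buf_right[nr] = r
                    nr += 1
            for i in range(nl):
                sidx[c, start + i] = buf_left[i]
            for i in range(nr):
                sidx[c, start + nl + i] = buf_right[i]

        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        feature[node] = best_col
        threshold[node] = best_thr
        left[node] = lchild
        right[node] = rchild
        stack[top, 0] = start
        stack[top, 1] = start + n_left
        stack[top, 2] = depth + 1
        stack[top, 3] = lchild
        top += 1
        stack[top, 0] = start + n_left
        stack[top, 1] = end
        stack[top, 2] = depth + 1
        stack[top, 3] = rchild
        top += 1

    return feature[:n_nodes], threshold[:n_nodes], left[:n_nodes], right[:n_nodes], value[:n_nodes], count[:n_nodes]


def grow_tree_arrays(X: np.ndarray, y: np.ndarray, min_node_size: int, max_depth: int):
    """Compiled growth on a contiguous column-restricted matrix."""
    return _grow_arrays(
        np.ascontiguousarray(X), np.ascontiguousarray(y, dtype=np.float64),
        min_node_size, max_depth,
    )


@njit(cache=True)
def _predict_arrays(feature, threshold, left, right, value, X):  # pragma: no cover
    n = X.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]
    return out


def fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    min_node_size: int,
    max_depth: int,
) -> np.ndarray:
    """Grow on (X_train, y_train) and predict X_eval, all in compiled code.

    Both matrices must already be restricted to the same allowed columns.
    """
    feature, threshold, left, right, value, _ = grow_tree_arrays(
        X_train, y_train, min_node_size, max_depth
    )
    return _predict_arrays(feature, threshold, left, right, value,
                           np.ascontiguousarray(X_eval))
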