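"""Exact path-dependent Shapley attribution for decision-tree ensembles.

Computes, for each instance and feature, the Shapley value of the feature
under the conditional-expectation value function encoded by the tree itself:
when a coalition excludes a split feature, both children are taken weighted by
their training cover.  The algorithm tracks all subset-extension paths down
the tree in a single pass per (instance, tree), giving per-tree cost
O(leaves x depth^2) instead of 2^features, and is deterministic.

Local accuracy holds exactly: ``base_value + sum(phi) == raw prediction``.
The kernels are written in a flat, array-based style so numba can compile
them; without numba they run as plain Python (identical results, slower).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _extend(pf, pz, po, pw, off, u, pzf, pof, pfi):
    pf[off + u] = pfi
    pz[off + u] = pzf
    po[off + u] = pof
    pw[off + u] = 1.0 if u == 0 else 0.0
    for i in range(u - 1, -1, -1):
        pw[off + i + 1] += pof * pw[off + i] * (i + 1.0) / (u + 1.0)
        pw[off + i] = pzf * pw[off + i] * (u - i) / (u + 1.0)


@njit(cache=False)
def _unwind(pf, pz, po, pw, off, u, k):
    oo = po[off + k]
    zz = pz[off + k]
    nxt = pw[off + u]
    if oo != 0.0:
        for i in range(u - 1, -1, -1):
            tmp = pw[off + i]
            pw[off + i] = nxt * (u + 1.0) / ((i + 1.0) * oo)
            nxt = tmp - pw[off + i] * zz * (u - i) / (u + 1.0)
    else:
        for i in range(u - 1, -1, -1):
            pw[off + i] = pw[off + i] * (u + 1.0) / (zz * (u - i))
    for i in range(k, u):
        pf[off + i] = pf[off + i + 1]
        pz[off + i] = pz[off + i + 1]
        po[off + i] = po[off + i + 1]


@njit(cache=False)
def _unwound_sum(pf, pz, po, pw, off, u, k):
    oo = po[off + k]
    zz = pz[off + k]
    nxt = pw[off + u]
    total = 0.0
    if oo != 0.0:
        for i in range(u - 1, -1, -1):
            tmp = nxt / ((i + 1.0) * oo)
            total += tmp
            nxt = pw[off + i] - tmp * zz * (u - i)
    else:
        for i in range(u - 1, -1, -1):
            total += pw[off + i] / (zz * (u - i))
    return total * (u + 1.0)


@njit(cache=False)
def _shap_one(cl, cr, feat, thresh, value, weight, x, phi,
              pf, pz, po, pw, stack):
    """Accumulate one tree's attributions for one instance into ``phi``.

    ``stack`` rows: node, unique_depth, parent_offset (ints) and pzf, pof,
    pfi packed in parallel float arrays is avoided by storing floats in a
    separate array; here stack is (n, 6) float64 and ints are round-tripped.
    """
    top = 0
    stack[top, 0] = 0.0  # node
    stack[top, 1] = 0.0  # unique_depth on entry
    stack[top, 2] = 0.0  # parent path offset
    stack[top, 3] = 1.0  # parent zero fraction
    stack[top, 4] = 1.0  # parent one fraction
    stack[top, 5] = -1.0  # parent feature index
    top += 1
    while top > 0:
        top -= 1
        node = int(stack[top, 0])
        u = int(stack[top, 1])
        poff = int(stack[top, 2])
        pzf = stack[top, 3]
        pof = stack[top, 4]
        pfi = int(stack[top, 5])

        off = poff + u
        for i in range(u):  # copy parent's path, then extend with our edge
            pf[off + i] = pf[poff + i]
            pz[off + i] = pz[poff + i]
            po[off + i] = po[poff + i]
            pw[off + i] = pw[poff + i]
        _extend(pf, pz, po, pw, off, u, pzf, pof, pfi)

        if cl[node] < 0:  # leaf
            leaf_v = value[node]
            for i in range(1, u + 1):
                w = _unwound_sum(pf, pz, po, pw, off, u, i)
                phi[pf[off + i]] += w * (po[off + i] - pz[off + i]) * leaf_v
            continue

        f = feat[node]
        if x[f] <= thresh[node]:
            hot, cold = cl[node], cr[node]
        else:
            hot, cold = cr[node], cl[node]
        hot_zf = weight[hot] / weight[node]
        cold_zf = weight[cold] / weight[node]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(u + 1):  # have we split on this feature above?
            if pf[off + i] == f:
                k = i
                break
        u2 = u
        if k >= 0:
            iz = pz[off + k]
            io = po[off + k]
            _unwind(pf, pz, po, pw, off, u, k)
            u2 = u - 1

        stack[top, 0] = cold
        stack[top, 1] = u2 + 1
        stack[top, 2] = off
        stack[top, 3] = cold_zf * iz
        stack[top, 4] = 0.0
        stack[top, 5] = f
        top += 1
        stack[top, 0] = hot
        stack[top, 1] = u2 + 1
        stack[top, 2] = off
        stack[top, 3] = hot_zf * iz
        stack[top, 4] = io
        stack[top, 5] = f
        top += 1


@njit(cache=False)
def _shap_tree_batch(cl, cr, feat, thresh, value, weight, X, phi, scale):
    depth = _max_depth(cl, cr)
    size = (depth + 2) * (depth + 3) // 2
    pf = np.zeros(size, dtype=np.int64)
    pz = np.zeros(size, dtype=np.float64)
    po = np.zeros(size, dtype=np.float64)
    pw = np.zeros(size, dtype=np.float64)
    stack = np.zeros((2 * (depth + 2), 6), dtype=np.float64)
    tmp = np.zeros(X.shape[1], dtype=np.float64)
    for r in range(X.shape[0]):
        for j in range(X.shape[1]):
            tmp[j] = 0.0
        _shap_one(cl, cr, feat, thresh, value, weight, X[r], tmp,
                  pf, pz, po, pw, stack)
        for j in range(X.shape[1]):
            phi[r, j] += scale * tmp[j]


@njit(cache=False)
def _max_depth(cl, cr):
    n = cl.shape[0]
    depth = np.zeros(n, dtype=np.int64)
    best = 0
    for node in range(n):  # parents precede children in sklearn's arrays
        if cl[node] >= 0:
            depth[cl[node]] = depth[node] + 1
            depth[cr[node]] = depth[node] + 1
    for node in range(n):
        if depth[node] > best:
            best = depth[node]
    return best


def tree_expected_value(value: np.ndarray, weight: np.ndarray,
                        cl: np.ndarray) -> float:
    """Cover-weighted mean of leaf values (the tree's base value)."""
    leaves = cl < 0
    return float(np.sum(value[leaves] * weight[leaves]) / np.sum(weight[leaves]))


def shap_values_trees(trees, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Attributions for an additive ensemble of trees.

    ``trees`` is a sequence of dicts with keys ``children_left``,
    ``children_right``, ``feature``, ``threshold``, ``value`` (per-node scalar
    output), ``weight`` (per-node training cover) and ``scale``.  Returns
    ``(phi[n, p], base_value)`` where base_value excludes any fixed intercept.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros(X.shape, dtype=np.float64)
    base = 0.0
    for t in trees:
        cl = np.ascontiguousarray(t["children_left"], dtype=np.int64)
        cr = np.ascontiguousarray(t["children_right"], dtype=np.int64)
        feat = np.ascontiguousarray(t["feature"], dtype=np.int64)
        thresh = np.ascontiguousarray(t["threshold"], dtype=np.float64)
        value = np.ascontiguousarray(t["value"], dtype=np.float64)
        weight = np.ascontiguousarray(t["weight"], dtype=np.float64)
        scale = float(t.get("scale", 1.0))
        _shap_tree_batch(cl, cr, feat, thresh, value, weight, X, phi, scale)
        base += scale * tree_expected_value(value, weight, cl)
    return phi, base
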