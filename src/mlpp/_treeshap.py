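"""Exact path-dependent TreeSHAP for sklearn decision trees.

Implements the polynomial-time Shapley-value algorithm for tree
ensembles (EXTEND / UNWIND over the unique feature path), vectorized
over samples: the sequence of path features is the same for every
sample at a given tree node, so the per-element fractions and weights
are carried as (n_samples, path_len) arrays and the whole batch is
attributed in one recursion over the tree.

For a tree whose leaves hold conditional expectations (class-1
fractions), the attributions satisfy local accuracy exactly:
base + sum(phi) == tree prediction, and averaging over a forest's
trees gives the forest probability decomposition.
"""

from __future__ import annotations

import sys

import numpy as np

__all__ = ["tree_shap", "forest_shap", "tree_expected_value"]


def _leaf_values_proba(tree) -> np.ndarray:
    """Per-node class-1 probability of an sklearn ClassifierTree."""
    value = tree.value  # (n_nodes, 1, n_classes); normalized in sklearn >= 1.3
    v = value[:, 0, :]
    totals = v.sum(axis=1)
    out = np.zeros(len(v))
    ok = totals > 0
    if v.shape[1] == 1:   # single-class tree (degenerate)
        out[ok] = v[ok, 0]
    else:
        out[ok] = v[ok, 1] / totals[ok]
    return out


def tree_expected_value(tree) -> float:
    """Cover-weighted mean prediction (the attribution bias term)."""
    return float(_leaf_values_proba(tree)[0])


def _extend(z, o, w, pz, po):
    """Append an element with fractions (pz, po) to every sample's path.

    z, o, w: (n, l) arrays; pz, po: (n,) arrays.  Returns (n, l+1).
    """
    n, l = w.shape
    z2 = np.concatenate([z, pz[:, None]], axis=1)
    o2 = np.concatenate([o, po[:, None]], axis=1)
    w2 = np.concatenate([w, np.zeros((n, 1))], axis=1)
    if l == 0:
        w2[:, 0] = 1.0
        return z2, o2, w2
    for i in range(l - 1, -1, -1):
        w2[:, i + 1] += po * w2[:, i] * (i + 1) / (l + 1)
        w2[:, i] = pz * w2[:, i] * (l - i) / (l + 1)
    return z2, o2, w2


def _unwound_sum(z, o, w, i):
    """Sum of path weights had element i never been extended in.

    Vectorized port of the UNWIND loop; o[:, i] may be zero for a
    subset of samples, handled by masking.  Returns (n,) sums.
    """
    n, l = w.shape
    oi = o[:, i]
    zi = z[:, i]
    nxt = w[:, l - 1].copy()
    total = np.zeros(n)
    hot = oi != 0
    oi_safe = np.where(hot, oi, 1.0)
    for j in range(l - 2, -1, -1):
        # hot samples: invert the one_fraction contribution
        tmp_hot = nxt * l / ((j + 1) * oi_safe)
        nxt = w[:, j] - tmp_hot * zi * (l - (j + 1)) / l
        # cold samples: one_fraction is 0, only zero_fraction contributed
        denom = zi * (l - (j + 1))
        tmp_cold = np.where(denom != 0, w[:, j] * l / np.where(denom != 0, denom, 1.0), 0.0)
        total += np.where(hot, tmp_hot, tmp_cold)
    return total


def _unwind(z, o, w, i):
    """Remove element i from every sample's path; returns (n, l-1) arrays."""
    n, l = w.shape
    oi = o[:, i]
    zi = z[:, i]
    hot = oi != 0
    oi_safe = np.where(hot, oi, 1.0)
    w_new = np.empty((n, l - 1))
    nxt = w[:, l - 1].copy()
    for j in range(l - 2, -1, -1):
        tmp_hot = nxt * l / ((j + 1) * oi_safe)
        nxt = w[:, j] - tmp_hot * zi * (l - (j + 1)) / l
        denom = zi * (l - (j + 1))
        tmp_cold = np.where(denom != 0, w[:, j] * l / np.where(denom != 0, denom, 1.0), 0.0)
        w_new[:, j] = np.where(hot, tmp_hot, tmp_cold)
    keep = [k for k in range(l) if k != i]
    return z[:, keep], o[:, keep], w_new


def tree_shap(tree, X: np.ndarray) -> np.ndarray:
    """Per-sample feature attributions phi (n_samples, n_features).

    ``tree`` is an sklearn ``Tree`` object (``estimator.tree_``) of a
    classifier; leaf values are class-1 fractions so the additivity
    identity base + phi.sum() == predict_proba[:, 1] holds exactly.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    phi = np.zeros((n, m))
    left, right = tree.children_left, tree.children_right
    feature, threshold = tree.feature, tree.threshold
    cover = tree.weighted_n_node_samples
    leaf_val = _leaf_values_proba(tree)

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, int(tree.max_depth) * 4 + 1000))
    try:
        _recurse(
            0, X, phi, left, right, feature, threshold, cover, leaf_val,
            np.empty((n, 0)), np.empty((n, 0)), np.empty((n, 0)),
            np.ones(n), np.ones(n), -1, [],
        )
    finally:
        sys.setrecursionlimit(old_limit)
    return phi


def _recurse(node, X, phi, left, right, feature, threshold, cover, leaf_val,
             z, o, w, pz, po, pfeat, path_feats):
    z, o, w = _extend(z, o, w, pz, po)
    path_feats = path_feats + [pfeat]
    l = w.shape[1]
    if left[node] == -1:  # leaf
        v = leaf_val[node]
        for i in range(1, l):
            s = _unwound_sum(z, o, w, i)
            phi[:, path_feats[i]] += s * (o[:, i] - z[:, i]) * v
        return
    f = int(feature[node])
    goes_left = X[:, f] <= threshold[node]
    iz = np.ones(X.shape[0])
    io = np.ones(X.shape[0])
    k = next((i for i in range(1, l) if path_feats[i] == f), None)
    if k is not None:
        iz, io = z[:, k].copy(), o[:, k].copy()
        z, o, w = _unwind(z, o, w, k)
        path_feats = [pf for i, pf in enumerate(path_feats) if i != k]
    rl = cover[left[node]] / cover[node]
    rr = cover[right[node]] / cover[node]
    # one_fraction goes to the child the sample actually takes
    _recurse(left[node], X, phi, left, right, feature, threshold, cover,
             leaf_val, z, o, w, iz * rl, np.where(goes_left, io, 0.0), f,
             path_feats)
    _recurse(right[node], X, phi, left, right, feature, threshold, cover,
             leaf_val, z, o, w, iz * rr, np.where(goes_left, 0.0, io), f,
             path_feats)


def forest_shap(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Average per-tree attributions and bias over a fitted forest.

    Returns (phi, base) with phi of shape (n_samples, n_features);
    base + phi.sum(axis=1) equals ``forest.predict_proba(X)[:, 1]``.
    """
    X = np.asarray(X, dtype=float)
    phi = np.zeros((X.shape[0], X.shape[1]))
    base = 0.0
    trees = [est.tree_ for est in forest.estimators_]
    for t in trees:
        phi += tree_shap(t, X)
        base += tree_expected_value(t)
    k = len(trees)
    return phi / k, base / k
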