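"""Exact path-dependent Shapley attribution for decision trees.

For a tree, the value function of the Shapley game is the cover-weighted
conditional expectation of the tree output: descending from the root, a
split on a feature in the coalition follows the sample's branch, a split on
an absent feature averages both branches weighted by their training cover.
The polynomial-time algorithm below carries, along each root-to-leaf path,
the permutation weights of every subset size simultaneously (the
EXTEND/UNWIND bookkeeping), so each leaf contributes its exact Shapley share
in O(depth²) instead of enumerating coalitions.  Attributions satisfy local
accuracy: they sum to the tree output at x minus the root expectation.

The traversal is an explicit-stack DFS over a flat path buffer: a node's
buffer segment sits ``unique_depth+1`` slots past its parent's, and LIFO
ordering guarantees a sibling only reuses a segment after the other
sibling's subtree has finished.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _extend(pf, pz, po, pw, off, ud, zero_fraction, one_fraction, feature_index):
    pf[off + ud] = feature_index
    pz[off + ud] = zero_fraction
    po[off + ud] = one_fraction
    pw[off + ud] = 1.0 if ud == 0 else 0.0
    for i in range(ud - 1, -1, -1):
        pw[off + i + 1] += one_fraction * pw[off + i] * (i + 1.0) / (ud + 1.0)
        pw[off + i] = zero_fraction * pw[off + i] * (ud - i) / (ud + 1.0)


@njit(cache=True)
def _unwind(pf, pz, po, pw, off, ud, path_index):
    one_fraction = po[off + path_index]
    zero_fraction = pz[off + path_index]
    next_one_portion = pw[off + ud]
    for i in range(ud - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[off + i]
            pw[off + i] = next_one_portion * (ud + 1.0) / ((i + 1.0) * one_fraction)
            next_one_portion = tmp - pw[off + i] * zero_fraction * (ud - i) / (ud + 1.0)
        else:
            pw[off + i] = pw[off + i] * (ud + 1.0) / (zero_fraction * (ud - i))
    for i in range(path_index, ud):
        pf[off + i] = pf[off + i + 1]
        pz[off + i] = pz[off + i + 1]
        po[off + i] = po[off + i + 1]


@njit(cache=True)
def _unwound_sum(pf, pz, po, pw, off, ud, path_index):
    one_fraction = po[off + path_index]
    zero_fraction = pz[off + path_index]
    next_one_portion = pw[off + ud]
    total = 0.0
    if one_fraction != 0.0:
        for i in range(ud - 1, -1, -1):
            tmp = next_one_portion * (ud + 1.0) / ((i + 1.0) * one_fraction)
            total += tmp
            next_one_portion = pw[off + i] - tmp * zero_fraction * (ud - i) / (ud + 1.0)
    else:
        for i in range(ud - 1, -1, -1):
            total += pw[off + i] * (ud + 1.0) / (zero_fraction * (ud - i))
    return total


@njit(cache=True)
def _tree_shap_sample(
    children_left,
    children_right,
    feature,
    threshold,
    cover,
    leaf_value,
    x,
    phi,
    pf,
    pz,
    po,
    pw,
    stack_node,
    stack_ud,
    stack_poff,
    stack_pz,
    stack_po,
    stack_pi,
):
    # stack frames: (node, unique_depth, parent_offset, parent_zero, parent_one, parent_feature)
    top = 0
    stack_node[0] = 0
    stack_ud[0] = 0
    stack_poff[0] = 0
    stack_pz[0] = 1.0
    stack_po[0] = 1.0
    stack_pi[0] = -1
    while top >= 0:
        node = stack_node[top]
        ud = stack_ud[top]
        poff = stack_poff[top]
        parent_zero = stack_pz[top]
        parent_one = stack_po[top]
        parent_feat = stack_pi[top]
        top -= 1

        off = poff + ud + 1
        for i in range(ud):
            pf[off + i] = pf[poff + i]
            pz[off + i] = pz[poff + i]
            po[off + i] = po[poff + i]
            pw[off + i] = pw[poff + i]
        _extend(pf, pz, po, pw, off, ud, parent_zero, parent_one, parent_feat)

        if children_left[node] < 0:  # leaf
            v = leaf_value[node]
            for i in range(1, ud + 1):
                w = _unwound_sum(pf, pz, po, pw, off, ud, i)
                phi[pf[off + i]] += w * (po[off + i] - pz[off + i]) * v
            continue

        split = feature[node]
        left = children_left[node]
        right = children_right[node]
        if x[split] <= threshold[node]:
            hot, cold = left, right
        else:
            hot, cold = right, left
        hot_zero = cover[hot] / cover[node]
        cold_zero = cover[cold] / cover[node]

        incoming_zero = 1.0
        incoming_one = 1.0
        found = -1
        for i in range(ud + 1):
            if pf[off + i] == split:
                found = i
                break
        if found >= 0:
            incoming_zero = pz[off + found]
            incoming_one = po[off + found]
            _unwind(pf, pz, po, pw, off, ud, found)
            ud -= 1

        # push cold first so hot's subtree completes before cold reuses its segment
        top += 1
        stack_node[top] = cold
        stack_ud[top] = ud + 1
        stack_poff[top] = off
        stack_pz[top] = cold_zero * incoming_zero
        stack_po[top] = 0.0
        stack_pi[top] = split
        top += 1
        stack_node[top] = hot
        stack_ud[top] = ud + 1
        stack_poff[top] = off
        stack_pz[top] = hot_zero * incoming_zero
        stack_po[top] = incoming_one
        stack_pi[top] = split
    return phi


@njit(cache=True)
def _tree_shap_matrix(
    children_left,
    children_right,
    feature,
    threshold,
    cover,
    leaf_value,
    X,
    max_depth,
):
    n, m = X.shape
    phi = np.zeros((n, m))
    buf = (max_depth + 3) * (max_depth + 4) // 2 + 8
    pf = np.empty(buf, dtype=np.int64)
    pz = np.empty(buf)
    po = np.empty(buf)
    pw = np.empty(buf)
    stack_cap = 2 * (max_depth + 2) + 4
    stack_node = np.empty(stack_cap, dtype=np.int64)
    stack_ud = np.empty(stack_cap, dtype=np.int64)
    stack_poff = np.empty(stack_cap, dtype=np.int64)
    stack_pz = np.empty(stack_cap)
    stack_po = np.empty(stack_cap)
    stack_pi = np.empty(stack_cap, dtype=np.int64)
    for s in range(n):
        _tree_shap_sample(
            children_left,
            children_right,
            feature,
            threshold,
            cover,
            leaf_value,
            X[s],
            phi[s],
            pf,
            pz,
            po,
            pw,
            stack_node,
            stack_ud,
            stack_poff,
            stack_pz,
            stack_po,
            stack_pi,
        )
    return phi


def _tree_arrays(tree, positive_class_index: int | None):
    """Flat arrays for one fitted sklearn tree; leaf values are scalars.

    For classifiers the leaf value is the probability of the positive class
    (per-node class counts normalized to proportions).
    """
    t = tree.tree_
    values = t.value.reshape(t.node_count, -1).astype(float)
    if positive_class_index is None:
        leaf_value = values[:, 0].copy()
    else:
        totals = values.sum(axis=1)
        totals[totals == 0] = 1.0
        leaf_value = values[:, positive_class_index] / totals
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(float),
        t.weighted_n_node_samples.astype(float),
        leaf_value,
        int(t.max_depth),
    )


def tree_shap(tree, X: np.ndarray, positive_class_index: int | None = None):
    """Shapley values and base value for one decision tree.

    Returns ``(phi, expected_value)`` with ``phi`` of shape (n_samples,
    n_features); ``phi.sum(1) + expected_value`` equals the tree output.
    """
    cl, cr, feat, thr, cover, leaf_value, max_depth = _tree_arrays(tree, positive_class_index)
    X = np.ascontiguousarray(X, dtype=float)
    phi = _tree_shap_matrix(cl, cr, feat, thr, cover, leaf_value, X, max_depth)
    # cover-weighted expectation over leaves == root value for sklearn trees
    expected = float(leaf_value[0])
    return phi, expected


def forest_shap(forest, X: np.ndarray, positive_class_index: int | None = None):
    """Shapley values for a random forest: the mean of per-tree attributions.

    A forest prediction is the mean of tree outputs (probabilities for
    classifiers), so additivity carries through the average.
    """
    X = np.ascontiguousarray(X, dtype=float)
    phi = np.zeros_like(X, dtype=float)
    expected = 0.0
    for tree in forest.estimators_:
        p, e = tree_shap(tree, X, positive_class_index)
        phi += p
        expected += e
    k = len(forest.estimators_)
    return phi / k, expected / k
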