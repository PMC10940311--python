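"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles — coalition enumeration,
pairwise rank counting, subset enumeration, hand-rolled cross-validation —
and never calls the library code paths it is used to check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, factorial

import numpy as np


# ---------------------------------------------------------------- Shapley

def tree_expected_value(tree, x, coalition: set) -> float:
    """Cover-weighted conditional expectation of a sklearn tree output.

    Splits on coalition features follow the sample; splits on absent
    features average both branches weighted by training cover.
    """
    t = tree.tree_
    vals = t.value.reshape(t.node_count, -1)[:, 0]

    def rec(node):
        if t.children_left[node] < 0:
            return vals[node]
        f = t.feature[node]
        left, right = t.children_left[node], t.children_right[node]
        if f in coalition:
            return rec(left) if x[f] <= t.threshold[node] else rec(right)
        w = t.weighted_n_node_samples
        return (w[left] * rec(left) + w[right] * rec(right)) / w[node]

    return rec(0)


def brute_force_tree_shap(tree, x, n_features: int) -> np.ndarray:
    """Exact Shapley values by enumerating all coalitions of used features."""
    used = sorted(set(int(f) for f in tree.tree_.feature if f >= 0))
    phi = np.zeros(n_features)
    u = len(used)
    for i in used:
        others = [j for j in used if j != i]
        for r in range(u):
            for subset in combinations(others, r):
                weight = factorial(r) * factorial(u - r - 1) / factorial(u)
                s = set(subset)
                phi[i] += weight * (
                    tree_expected_value(tree, x, s | {i}) - tree_expected_value(tree, x, s)
                )
    return phi


# ---------------------------------------------------------------- metrics

def auc_mann_whitney(truth, scores) -> float:
    """ROC-AUC as the fraction of (positive, negative) pairs ranked correctly,
    ties counted half."""
    y = np.asarray(truth, dtype=bool)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def confusion_counts(truth, predicted):
    y = np.asarray(truth, dtype=bool)
    yhat = np.asarray(predicted, dtype=bool)
    tp = int(np.sum(y & yhat))
    tn = int(np.sum(~y & ~yhat))
    fp = int(np.sum(~y & yhat))
    fn = int(np.sum(y & ~yhat))
    return tp, tn, fp, fn


def f1_from_counts(truth, predicted) -> float:
    tp, _, fp, fn = confusion_counts(truth, predicted)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def balanced_accuracy_from_counts(truth, predicted) -> float:
    tp, tn, fp, fn = confusion_counts(truth, predicted)
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def mse_direct(actual, predicted) -> float:
    y = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    return float(sum((fi - yi) ** 2 for fi, yi in zip(f, y)) / len(y))


def pearson_direct(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


# ------------------------------------------------------------- enrichment

def hypergeom_tail_by_enumeration(M: int, K: int, n: int, k: int, universe=None) -> float:
    """P(overlap >= k) by enumerating every n-subset of an M-gene universe."""
    universe = list(range(M)) if universe is None else list(universe)
    in_set = set(universe[:K])
    hits = sum(1 for draw in combinations(universe, n) if len(in_set & set(draw)) >= k)
    return hits / comb(M, n)


def bh_adjust_direct(pvalues) -> np.ndarray:
    """Benjamini–Hochberg: p*(m/rank), cumulative min from the largest p."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        adjusted[i] = running
    return adjusted


# ------------------------------------------------------------------- CV

def manual_grid_search(make_estimator, grid_points, X, y, cv, score_fn):
    """Exhaustive CV loop: for each grid point, mean score over shared folds.

    ``cv`` must use the same fold assignment as the implementation under
    test; the winner is the first grid point with the maximal mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    means = []
    for params in grid_points:
        scores = []
        for train_idx, test_idx in cv.split(X):
            est = make_estimator(**params)
            est.fit(X[train_idx], y[train_idx])
            scores.append(score_fn(est, X[test_idx], y[test_idx]))
        means.append(float(np.mean(scores)))
    best = 0
    for i in range(1, len(means)):
        if means[i] > means[best]:
            best = i
    return grid_points[best], means
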