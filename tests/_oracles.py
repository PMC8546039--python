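"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reusing the package's own
code paths: naive O(n^2) counting for curve metrics, explicit subset
enumeration for Shapley interaction values (with a cover-weighted tree
evaluator reading the booster's JSON dump), and direct re-enumeration of
moving windows and selector windows.
"""

from __future__ import annotations

import json
import math
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------- curve metrics

def brute_force_auprc(scores, labels) -> float:
    """Average precision by direct counting at every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        predicted = scores >= t
        tp = int((predicted & (labels == 1)).sum())
        fp = int((predicted & (labels == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def brute_force_auroc(scores, labels) -> float:
    """Pairwise-comparison count with half credit for score ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def monte_carlo_balanced_precision(precision, prior, n=100_000, seed=0):
    """Prior-rebalancing simulation: redraws a balanced test population with
    the classifier's class-conditional prediction rates held fixed, and
    returns (empirical balanced precision, standard error)."""
    lr = precision * (1 - prior) / ((1 - precision) * prior)
    p_pred_neg = 0.01  # free choice; fixes p_pred_pos via the likelihood ratio
    p_pred_pos = lr * p_pred_neg
    assert p_pred_pos <= 1.0
    rng = np.random.default_rng(seed)
    pos_hits = rng.uniform(size=n // 2) < p_pred_pos
    neg_hits = rng.uniform(size=n // 2) < p_pred_neg
    tp, fp = pos_hits.sum(), neg_hits.sum()
    bp = tp / (tp + fp)
    se = math.sqrt(bp * (1 - bp) / (tp + fp))
    return bp, se


# ------------------------------------------------------------------ windows

def brute_force_windows(X: int, n_windows: int, fraction: float):
    """Re-enumerate the moving windows directly from the definition."""
    size = int(math.floor(X * fraction + 0.5))
    step = max(1, int(math.floor(X * (1.0 - fraction) / (n_windows - 1))))
    out = []
    for j in range(n_windows):
        start = j * step
        end = min(start + size, X)
        if start < end:
            out.append((start, end))
    return out


# ------------------------------------------------------------------ selector

def brute_force_select(trials, window: int):
    """Recompute every moving-average window explicitly and apply the
    early-stopping rule; returns the chosen trial."""
    ordered = sorted(trials, key=lambda t: t.mean_train_aubprc)
    vals = [t.mean_val_aubprc for t in ordered]
    if len(ordered) <= window:
        candidates = ordered
    else:
        means = []
        for i in range(len(ordered) - window + 1):
            means.append(sum(vals[i : i + window]) / window)
        chosen = len(means) - 1
        for i in range(1, len(means)):
            if means[i] < means[i - 1]:
                chosen = i
                break
        candidates = ordered[chosen : chosen + window]
    best = candidates[0]
    for t in candidates[1:]:
        if t.mean_val_aubprc > best.mean_val_aubprc:
            best = t
    return best


# ----------------------------------------------------- Shapley interactions

def _parse_trees(booster):
    return [json.loads(s) for s in booster.get_dump(with_stats=True, dump_format="json")]


def _tree_expectation(node, x: dict, active: frozenset) -> float:
    """Cover-weighted conditional expectation of one tree: active features
    follow their split; inactive features average the children by cover."""
    if "leaf" in node:
        return node["leaf"]
    feat = node["split"]
    children = {c["nodeid"]: c for c in node["children"]}
    if feat in active:
        branch = node["yes"] if x[feat] < node["split_condition"] else node["no"]
        return _tree_expectation(children[branch], x, active)
    covers = {cid: children[cid]["cover"] for cid in children}
    total = sum(covers.values())
    return sum(
        covers[cid] / total * _tree_expectation(children[cid], x, active)
        for cid in children
    )


def coalition_value(trees, x: dict, subset, base_margin: float = 0.0) -> float:
    active = frozenset(subset)
    return base_margin + sum(_tree_expectation(t, x, active) for t in trees)


def exhaustive_shapley_interactions(booster, x: dict, feature_names):
    """Exact Shapley interaction matrix by subset enumeration.

    Returns (base_value, matrix) with the convention used by tree ensembles:
    off-diagonal cells carry half the pairwise interaction, the diagonal
    carries the main effect minus the off-diagonal row sum, and
    base + sum(matrix) equals the full prediction.
    """
    trees = _parse_trees(booster)
    names = list(feature_names)
    M = len(names)
    values = {}
    for r in range(M + 1):
        for subset in combinations(range(M), r):
            values[frozenset(subset)] = coalition_value(
                trees, x, (names[i] for i in subset)
            )
    base = values[frozenset()]

    def shapley_value(i: int) -> float:
        others = [j for j in range(M) if j != i]
        total = 0.0
        for r in range(M):
            w = math.factorial(r) * math.factorial(M - r - 1) / math.factorial(M)
            for subset in combinations(others, r):
                s = frozenset(subset)
                total += w * (values[s | {i}] - values[s])
        return total

    def interaction(i: int, j: int) -> float:
        others = [k for k in range(M) if k not in (i, j)]
        total = 0.0
        for r in range(M - 1):
            w = (
                math.factorial(r)
                * math.factorial(M - r - 2)
                / math.factorial(M - 1)
            )
            for subset in combinations(others, r):
                s = frozenset(subset)
                total += w * (
                    values[s | {i, j}]
                    - values[s | {i}]
                    - values[s | {j}]
                    + values[s]
                )
        return total

    matrix = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            half = interaction(i, j) / 2.0
            matrix[i, j] = matrix[j, i] = half
    for i in range(M):
        matrix[i, i] = shapley_value(i) - (matrix[i].sum() - matrix[i, i])
    return base, matrix
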