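"""Independent brute-force oracles used to cross-check the similarity and
metric implementations.  Each oracle is deliberately naive (path enumeration,
recursive memoized DP, explicit loops, exhaustive pair counting) and shares
no code with the implementation it checks."""

from functools import lru_cache

import networkx as nx
import numpy as np


def ds_by_path_enumeration(dag, disease, xi):
    """DS_d(t) = max over directed child->parent paths d..t of xi^len(path)."""
    graph = dag.graph
    if disease not in graph:
        return {}
    contrib = {disease: 1.0}
    for term in nx.descendants(graph, disease):
        best = 0.0
        for path in nx.all_simple_paths(graph, disease, term):
            best = max(best, xi ** (len(path) - 1))
        contrib[term] = best
    return contrib


def dss_pair(dag, d1, d2, xi):
    c1 = ds_by_path_enumeration(dag, d1, xi)
    c2 = ds_by_path_enumeration(dag, d2, xi)
    if d1 == d2:
        return 1.0
    shared = c1.keys() & c2.keys()
    if not shared or not c1 or not c2:
        return 0.0
    return sum(c1[t] + c2[t] for t in shared) / (sum(c1.values()) + sum(c2.values()))


def lfs_pair(ld_values, dss_values, i, j):
    """Naive max-sum evaluation of the functional-similarity formula."""
    if i == j:
        return 1.0
    di = np.flatnonzero(ld_values[i])
    dj = np.flatnonzero(ld_values[j])
    if len(di) == 0 or len(dj) == 0:
        return 0.0
    s_ij = sum(max(dss_values[d, dp] for dp in di) for d in dj)
    s_ji = sum(max(dss_values[d, dp] for dp in dj) for d in di)
    return (s_ij + s_ji) / (len(di) + len(dj))


def edit_distance_recursive(s1, s2, sub, ins, dele):
    """Top-down memoized edit distance, independent of the iterative kernel."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j * ins
        if j == 0:
            return i * dele
        match = rec(i - 1, j - 1) + (0.0 if s1[i - 1] == s2[j - 1] else sub)
        return min(match, rec(i - 1, j) + dele, rec(i, j - 1) + ins)

    return rec(len(s1), len(s2))


def gip_direct(profiles):
    """Direct elementwise evaluation of the Gaussian profile kernel."""
    n = len(profiles)
    eta = 1.0 / np.mean([np.dot(p, p) for p in profiles])
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = profiles[i] - profiles[j]
            out[i, j] = np.exp(-eta * np.dot(d, d))
    return out


def auc_pair_counting(labels, scores):
    """Mann-Whitney AUC by exhaustive pair enumeration, ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_step_integral(labels, scores):
    """Precision-recall step integral: sum of precision at each recall jump."""
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="mergesort")
    labels = labels[order]
    scores = np.asarray(scores)[order]
    tp = fp = 0
    n_pos = labels.sum()
    area = 0.0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:
            j += 1
        tp_new = tp + labels[i:j].sum()
        fp_new = fp + (j - i) - labels[i:j].sum()
        precision = tp_new / (tp_new + fp_new)
        area += precision * (tp_new - tp) / n_pos
        tp, fp = tp_new, fp_new
        i = j
    return area


def confusion_from_vectors(labels, predicted):
    """Recount the confusion table and metrics straight from raw vectors."""
    labels = np.asarray(labels).astype(bool)
    predicted = np.asarray(predicted).astype(bool)
    tp = int((labels & predicted).sum())
    fp = int((~labels & predicted).sum())
    tn = int((~labels & ~predicted).sum())
    fn = int((labels & ~predicted).sum())
    out = {}
    out["accuracy"] = (tp + tn) / (tp + tn + fp + fn)
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    out["precision"] = tp / (tp + fp) if tp + fp else None
    if out["precision"] is None or out["sensitivity"] is None or (
        out["precision"] + out["sensitivity"] == 0
    ):
        out["f1"] = None
    else:
        out["f1"] = (
            2 * out["precision"] * out["sensitivity"] / (out["precision"] + out["sensitivity"])
        )
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    out["mcc"] = (tp * tn - fp * fn) / np.sqrt(denom) if denom else None
    return out


def random_dag(rng, n_terms):
    """A random rooted DAG over n_terms nodes (edges child -> parent)."""
    names = [f"t{i}" for i in range(n_terms)]
    edges = set()
    for i in range(1, n_terms):
        n_parents = rng.integers(1, min(i, 3) + 1)
        for p in rng.choice(i, size=n_parents, replace=False):
            edges.add((names[i], names[int(p)]))
    return names, edges
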