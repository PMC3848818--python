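"""Independent brute-force oracles used to cross-check the package.

Deliberately slow and literal: networkx graphs, python sets and explicit
loops, sharing no code with the implementation under test.
"""
from __future__ import annotations

import math

import networkx as nx
import numpy as np
from scipy.stats import norm


def naive_pearson(x, y) -> float:
    """Two-pass covariance / sigma Pearson correlation."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def bfs_components(nodes, edges):
    """Connected components via explicit breadth-first flood fill."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            node = queue.pop(0)
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def _graph(z: np.ndarray, t: float) -> nx.Graph:
    g = nx.Graph()
    n = z.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if z[i, j] > t:
                g.add_edge(i, j)
    return g


def _min3_nodes(g: nx.Graph) -> set:
    out = set()
    for comp in nx.connected_components(g):
        if len(comp) >= 3:
            out |= comp
    return out


def naive_exclusive(z_a: np.ndarray, z_b: np.ndarray, t: float):
    """Literal remove-then-recompute set algebra at one threshold."""
    ga, gb = _graph(z_a, t), _graph(z_b, t)
    removed = _min3_nodes(ga) & _min3_nodes(gb)
    keep = set(range(z_a.shape[0])) - removed
    a_tilde = _min3_nodes(ga.subgraph(keep))
    b_tilde = _min3_nodes(gb.subgraph(keep))
    return removed, a_tilde, b_tilde


def naive_dcglob(z_a: np.ndarray, z_b: np.ndarray, thresholds, n_a: int, n_b: int):
    """Per-gene (direction, run_length, p) by materializing every network."""
    n_genes = z_a.shape[0]
    k = len(thresholds)
    i_a = np.zeros((n_genes, k), dtype=bool)
    i_b = np.zeros((n_genes, k), dtype=bool)
    for m, t in enumerate(thresholds):
        _, a_tilde, b_tilde = naive_exclusive(z_a, z_b, t)
        for g in a_tilde:
            i_a[g, m] = True
        for g in b_tilde:
            i_b[g, m] = True
    se = math.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    out = []
    for g in range(n_genes):
        best = None  # (length_idx, mean_idx, pref, start, end, cond)
        for cond, row in (("A", i_a[g]), ("B", i_b[g])):
            start = None
            for m in range(k + 1):
                on = m < k and row[m]
                if on and start is None:
                    start = m
                elif not on and start is not None:
                    end = m - 1
                    pref = 1 if cond == "A" else 0
                    cand = (end - start, start + end, pref, start, end, cond)
                    if best is None or cand > best:
                        best = cand
                    start = None
        if best is None:
            out.append(("none", 0.0, 1.0))
        else:
            length = thresholds[best[4]] - thresholds[best[3]]
            out.append((best[5], length, float(norm.sf(length / se))))
    return out


def naive_dcloc(z_a: np.ndarray, z_b: np.ndarray, thresholds):
    """Per-gene mean Jaccard dissimilarity with python sets per threshold."""
    n_genes = z_a.shape[0]
    total = np.zeros(n_genes)
    for t in thresholds:
        for g in range(n_genes):
            v_a = {j for j in range(n_genes) if j != g and z_a[g, j] > t}
            v_b = {j for j in range(n_genes) if j != g and z_b[g, j] > t}
            union = v_a | v_b
            if len(union) >= 3:
                total[g] += 1.0 - len(v_a & v_b) / len(union)
    return total / len(thresholds)


def naive_bh_reject(pvals, alpha: float) -> np.ndarray:
    """Step-up rule: reject the smallest k p-values for the largest k
    with p_(k) <= k * alpha / m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def auroc(labels, scores) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[labels], scores[~labels]
    ranks = np.argsort(np.argsort(np.concatenate([pos, neg]), kind="mergesort")) + 1.0
    # midranks for ties
    order = np.argsort(np.concatenate([pos, neg]), kind="mergesort")
    allscores = np.concatenate([pos, neg])
    sorted_scores = allscores[order]
    midrank = np.empty_like(ranks)
    i = 0
    while i < len(sorted_scores):
        j = i
        while j + 1 < len(sorted_scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        midrank[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r_pos = midrank[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return u / (len(pos) * len(neg))
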