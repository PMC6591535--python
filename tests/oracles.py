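"""Brute-force reference implementations used only to check the package.

Every oracle here is deliberately naive — exhaustive enumeration, dense
linear algebra, pair counting — and independent of the code paths it
verifies.  They are only feasible at tiny problem sizes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# shortest paths / centrality by exhaustive simple-path enumeration
# ---------------------------------------------------------------------------

def all_simple_paths(n: int, edges: dict[tuple[int, int], float],
                     src: int, dst: int):
    """Yield (length, path) over every simple src→dst path."""
    adjacency: dict[int, list[int]] = {i: [] for i in range(n)}
    for (a, b) in edges:
        adjacency[a].append(b)
        adjacency[b].append(a)

    def walk(node, visited, length, path):
        if node == dst:
            yield length, tuple(path)
            return
        for nxt in adjacency[node]:
            if nxt in visited:
                continue
            key = (node, nxt) if node < nxt else (nxt, node)
            yield from walk(nxt, visited | {nxt}, length + edges[key],
                            path + [nxt])

    yield from walk(src, {src}, 0.0, [src])


def brute_shortest(n, edges, src, dst, rel_tol=1e-9):
    """(min length, list of shortest paths) by enumeration."""
    best = math.inf
    paths = []
    for length, path in all_simple_paths(n, edges, src, dst):
        if length < best * (1 - rel_tol):
            best = length
            paths = [(length, path)]
        elif length <= best * (1 + rel_tol):
            paths.append((length, path))
            best = min(best, length)
    shortest = [p for (length, p) in paths
                if length <= best * (1 + rel_tol)]
    return best, shortest


def brute_closeness(n, edges):
    """Closeness (|V_c|-1)/sum of shortest path lengths, per component."""
    comp = _components(n, edges)
    values = []
    for u in range(n):
        members = [v for v in range(n) if comp[v] == comp[u]]
        if len(members) == 1:
            values.append(0.0)
            continue
        total = 0.0
        for v in members:
            if v == u:
                continue
            best, _ = brute_shortest(n, edges, u, v)
            total += best
        values.append((len(members) - 1) / total)
    return np.array(values)


def brute_betweenness(n, edges):
    """Unnormalized node and edge betweenness by path enumeration."""
    node_bt = np.zeros(n)
    edge_bt = {e: 0.0 for e in edges}
    comp = _components(n, edges)
    for j in range(n):
        for k in range(j + 1, n):
            if comp[j] != comp[k]:
                continue
            _, shortest = brute_shortest(n, edges, j, k)
            g = len(shortest)
            if g == 0:
                continue
            for path in shortest:
                for u in path[1:-1]:
                    node_bt[u] += 1.0 / g
                for a, b in zip(path, path[1:]):
                    key = (a, b) if a < b else (b, a)
                    edge_bt[key] += 1.0 / g
    return node_bt, edge_bt


def _components(n, edges):
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b) in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    return [find(i) for i in range(n)]


def dense_leading_eigenpair(w: np.ndarray):
    """Leading eigenpair of a symmetric matrix by full decomposition."""
    vals, vecs = np.linalg.eigh(w)
    lam = vals[-1]
    vec = vecs[:, -1]
    if vec.sum() < 0:
        vec = -vec
    return np.abs(vec), float(lam)


# ---------------------------------------------------------------------------
# spanning trees by exhaustive enumeration
# ---------------------------------------------------------------------------

def min_spanning_weight(values: np.ndarray) -> float:
    """Minimum total weight over all labeled spanning trees (n <= 8)."""
    n = values.shape[0]
    if n <= 1:
        return 0.0
    all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = math.inf
    for combo in itertools.combinations(all_edges, n - 1):
        comp = _components(n, {e: 0.0 for e in combo})
        if len(set(comp)) != 1:
            continue  # not spanning
        best = min(best, sum(values[i, j] for i, j in combo))
    return best


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def nn_components(values: np.ndarray, ids) -> list[set[str]]:
    """Nearest-neighbor-link components with lexicographic tie-break."""
    n = values.shape[0]
    links = set()
    for i in range(n):
        best = math.inf
        for j in range(n):
            if j != i and values[i, j] < best:
                best = values[i, j]
        candidates = sorted(
            ids[j] for j in range(n) if j != i and values[i, j] == best
        )
        links.add(frozenset((ids[i], candidates[0])))
    edges = {}
    index = {name: i for i, name in enumerate(ids)}
    for pair in links:
        a, b = sorted(pair)
        edges[(index[a], index[b])] = 0.0
    comp = _components(n, edges)
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(comp[i], set()).add(ids[i])
    return list(groups.values())


# ---------------------------------------------------------------------------
# classifier evaluation
# ---------------------------------------------------------------------------

def pair_counting_auc(d_mins, labels) -> float:
    """Mann-Whitney AUC: fraction of pos/neg pairs ranked correctly,
    half credit for ties (smaller distance = more member-like)."""
    pos = [d for d, lab in zip(d_mins, labels) if lab == "positive"]
    neg = [d for d, lab in zip(d_mins, labels) if lab == "negative"]
    total = 0.0
    for p in pos:
        for q in neg:
            if p < q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_f_sweep(d_mins, labels):
    """Best (tau, F1) over a dense sweep of all plausible thresholds."""
    d = np.asarray(d_mins, dtype=float)
    pos = np.array([lab == "positive" for lab in labels])
    values = np.unique(d)
    candidates = []
    for lo, hi in zip(values[:-1], values[1:]):
        candidates.append(hi / 2 if lo == 0 else math.sqrt(lo * hi))
    candidates.append(10 * values[-1] if values[-1] > 0 else 1.0)
    best = (None, -1.0)
    for tau in candidates:
        predicted = d < tau
        tp = np.sum(predicted & pos)
        fp = np.sum(predicted & ~pos)
        fn = np.sum(~predicted & pos)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = (2 * precision * recall / (precision + recall)
             if precision + recall else 0.0)
        if f > best[1]:
            best = (tau, f)
    return best
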