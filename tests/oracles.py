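"""Independent brute-force oracles used across the test suite.

These are deliberately naive implementations (explicit loops, path
enumeration, dense power iteration, combinatorial arithmetic) kept separate
from the library code paths they check.
"""

import math
from collections import deque

import numpy as np


# -- correlation coefficients ------------------------------------------------

def pearson_brute(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def ranks_brute(x):
    """Average ranks, handling ties by explicit grouping."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(x, y):
    return pearson_brute(ranks_brute(x), ranks_brute(y))


def cosine_brute(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float((x * y).sum() / np.sqrt((x ** 2).sum() * (y ** 2).sum()))


# -- graph centralities ------------------------------------------------------

def bfs_distances(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def closeness_brute(graph):
    """(n_component - 1) / sum of distances, per node."""
    adj = {n: list(graph.neighbors(n)) for n in graph.nodes}
    out = {}
    for n in graph.nodes:
        dist = bfs_distances(adj, n)
        total = sum(dist.values())
        out[n] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def _all_shortest_paths(adj, dist, s, t):
    """Enumerate all shortest s->t paths by walking the predecessor DAG."""
    if t not in dist:
        return []
    paths = []

    def back(node, acc):
        if node == s:
            paths.append([s] + acc[::-1])
            return
        for p in adj[node]:
            if dist.get(p, -1) == dist[node] - 1:
                back(p, acc + [node])

    back(t, [])
    return paths


def betweenness_brute(graph):
    """Normalized betweenness by explicit shortest-path enumeration."""
    nodes = list(graph.nodes)
    n = len(nodes)
    adj = {u: list(graph.neighbors(u)) for u in nodes}
    score = {u: 0.0 for u in nodes}
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            paths = _all_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    if n > 2:
        scale = 1.0 / ((n - 1) * (n - 2) / 2.0)
    else:
        scale = 1.0
    return {u: v * scale for u, v in score.items()}


def pagerank_brute(graph, d=0.85, n_iter=2000):
    """Dense power iteration with uniform dangling redistribution."""
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    deg = np.array([graph.degree(u) for u in nodes], float)
    p = np.full(n, 1.0 / n)
    for _ in range(n_iter):
        new = np.full(n, (1.0 - d) / n)
        dangling = p[deg == 0].sum()
        new += d * dangling / n
        for u in nodes:
            if graph.degree(u) == 0:
                continue
            share = d * p[idx[u]] / graph.degree(u)
            for v in graph.neighbors(u):
                new[idx[v]] += share
        if np.abs(new - p).sum() < 1e-14:
            p = new
            break
        p = new
    return {u: p[idx[u]] for u in nodes}


def eigenvector_brute(graph):
    """Principal adjacency eigenvector (largest component convention)."""
    import networkx as nx
    comp = max(nx.connected_components(graph), key=len)
    sub = sorted(comp)
    pos = {u: i for i, u in enumerate(sub)}
    A = np.zeros((len(sub), len(sub)))
    for u, v in graph.edges:
        if u in pos and v in pos:
            A[pos[u], pos[v]] = A[pos[v], pos[u]] = 1.0
    w, V = np.linalg.eigh(A)
    vec = np.abs(V[:, np.argmax(w)])
    vec = vec / np.linalg.norm(vec)
    out = {u: 0.0 for u in graph.nodes}
    out.update({u: float(vec[pos[u]]) for u in sub})
    return out


# -- combinatorics -----------------------------------------------------------

def hypergeom_upper_tail(a, S, n1, n2):
    """P(X >= a) for X ~ Hypergeometric(S, n1, n2), by explicit summation."""
    total = 0
    denom = math.comb(S, n2)
    for k in range(a, min(n1, n2) + 1):
        total += math.comb(n1, k) * math.comb(S - n1, n2 - k)
    return total / denom
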