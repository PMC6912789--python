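"""Independent brute-force oracles used to cross-check the implementation.

Deliberately different algorithms from the package: Floyd-Warshall distances
instead of BFS, explicit enumeration of all shortest paths instead of
Brandes' accumulation, and hand ranking + Pearson-on-ranks for Spearman.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

INF = math.inf


def floyd_warshall(nodes, edges):
    dist = {(u, v): (0 if u == v else INF) for u in nodes for v in nodes}
    for u, v in edges:
        dist[(u, v)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                alt = dist[(i, k)] + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return dist


def enumerate_geodesics(nodes, edges, s, t, dist):
    """All shortest s->t paths, by DFS pruned with exact remaining distance."""
    if dist[(s, t)] is INF or s == t:
        return []
    succ = {u: [] for u in nodes}
    for u, v in edges:
        succ[u].append(v)
    target_len = dist[(s, t)]
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for w in succ[last]:
            if len(path) + dist[(w, t)] == target_len and w not in path:
                path.append(w)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_betweenness(nodes, edges):
    """Directed betweenness, endpoints excluded, normalized by (n-1)(n-2)."""
    dist = floyd_warshall(nodes, edges)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t or dist[(s, t)] is INF:
                continue
            paths = enumerate_geodesics(nodes, edges, s, t, dist)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(v in p for p in paths)
                bc[v] += through / len(paths)
    if n > 2:
        for v in bc:
            bc[v] /= (n - 1) * (n - 2)
    return bc


def brute_closeness(nodes, edges, direction):
    """Wasserman-Faust closeness from the Floyd-Warshall distance matrix."""
    dist = floyd_warshall(nodes, edges)
    n = len(nodes)
    out = {}
    for v in nodes:
        if direction == "in":
            ds = [dist[(w, v)] for w in nodes if w != v and dist[(w, v)] is not INF]
        else:
            ds = [dist[(v, w)] for w in nodes if w != v and dist[(v, w)] is not INF]
        if not ds:
            out[v] = 0.0
        else:
            out[v] = (len(ds) / sum(ds)) * (len(ds) / (n - 1))
    return out


def brute_degrees(nodes, edges):
    n = len(nodes)
    indeg = {v: sum(e[1] == v for e in edges) for v in nodes}
    outdeg = {v: sum(e[0] == v for e in edges) for v in nodes}
    return (
        indeg,
        outdeg,
        {v: indeg[v] / (n - 1) for v in nodes},
        {v: outdeg[v] / (n - 1) for v in nodes},
    )


def hand_ranks(values):
    """Average ranks (1-based) with ties, no library calls."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y):
    """Rank-then-Pearson rs and the t-approximation p-value."""
    rx = np.array(hand_ranks(list(x)))
    ry = np.array(hand_ranks(list(y)))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return math.nan, math.nan
    rs = float(rx @ ry) / denom
    n = len(rx)
    if abs(rs) == 1.0:
        return rs, 0.0
    t = rs * math.sqrt((n - 2) / (1 - rs * rs))
    from scipy.stats import t as tdist

    return rs, float(2 * tdist.sf(abs(t), n - 2))


def random_digraph(rng, n_max=7):
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"v{i}" for i in range(n)]
    p = rng.uniform(0.1, 0.9)
    edges = [
        (u, v) for u in nodes for v in nodes if u != v and rng.random() < p
    ]
    return nodes, edges


def all_digraphs(n):
    """Every labeled simple digraph on n nodes (2^(n(n-1)) of them)."""
    nodes = [f"v{i}" for i in range(n)]
    slots = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in range(1 << len(slots)):
        yield nodes, [slots[i] for i in range(len(slots)) if mask >> i & 1]
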