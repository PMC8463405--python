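"""Independent brute-force reference implementations used only by tests.

Everything here works from first definitions (flood fill, all-pairs BFS,
exhaustive triple enumeration, direct formula evaluation) and never calls
the package's own metric code, so agreement is a real cross-check.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def components_floodfill(nodes, edges):
    """Connected components by explicit flood fill."""
    adj = adjacency(nodes, edges)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def bfs_levels(adj, source):
    """Distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def all_pairs_paths(nodes, edges):
    adj = adjacency(nodes, edges)
    dist, sigma = {}, {}
    for s in nodes:
        dist[s], sigma[s] = bfs_levels(adj, s)
    return dist, sigma


def diameter_bfs(nodes, edges):
    dist, _ = all_pairs_paths(nodes, edges)
    return max(dist[s][t] for s in nodes for t in dist[s])


def average_path_length_bfs(nodes, edges):
    dist, _ = all_pairs_paths(nodes, edges)
    nodes = list(nodes)
    total, pairs = 0, 0
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            total += dist[s][t]
            pairs += 1
    return total / pairs


def transitivity_triples(nodes, edges):
    """3 x triangles / connected triples by exhaustive enumeration."""
    adj = adjacency(nodes, edges)
    triangles = sum(
        1 for a, b, c in combinations(sorted(nodes, key=str), 3)
        if b in adj[a] and c in adj[a] and c in adj[b]
    )
    triples = sum(
        len(adj[v]) * (len(adj[v]) - 1) // 2 for v in nodes
    )
    return 3.0 * triangles / triples if triples else 0.0


def modularity_direct(nodes, edges, partition):
    """Q = sum_c [e_c/m - (d_c/(2m))^2] evaluated straight from the formula."""
    m = len(edges)
    if m == 0:
        return float("nan")
    adj = adjacency(nodes, edges)
    q = 0.0
    for comm in partition:
        e_c = sum(1 for u, v in edges if u in comm and v in comm)
        d_c = sum(len(adj[v]) for v in comm)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def assortativity_mixing(nodes, edges, labels):
    """Newman's nominal coefficient from the edge-end mixing matrix."""
    cats = sorted({labels[n] for n in nodes})
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v in edges:
        i, j = idx[labels[u]], idx[labels[v]]
        e[i, j] += 1
        e[j, i] += 1
    e /= e.sum()
    a = e.sum(axis=1)
    trace = np.trace(e)
    norm = float(a @ a)
    if norm == 1.0:  # one label owns every edge endpoint: undefined
        return float("nan")
    return (trace - norm) / (1.0 - norm)


def articulation_by_removal(nodes, edges):
    """Nodes whose removal increases the component count of their graph."""
    base = len(components_floodfill(nodes, edges))
    adj = adjacency(nodes, edges)
    out = set()
    for v in nodes:
        if not adj[v]:  # removing an isolated node only deletes its component
            continue
        rest = [n for n in nodes if n != v]
        redges = [(a, b) for a, b in edges if v not in (a, b)]
        if len(components_floodfill(rest, redges)) > base:
            out.add(v)
    return out


def betweenness_pairsum(nodes, edges):
    """Unnormalized betweenness: per unordered pair, the fraction of shortest
    paths through each interior node, summed pair by pair."""
    dist, sigma = all_pairs_paths(nodes, edges)
    bc = {n: 0.0 for n in nodes}
    nodes = list(nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s] or sigma[s][t] == 0:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    bc[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    return bc


def spearman_naive(x, y):
    """Spearman rho as the Pearson correlation of mid-ranks, computed from
    the definition with an explicit tie-aware ranking."""

    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx) ** 0.5
    dy = sum((b - my) ** 2 for b in ry) ** 0.5
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)
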