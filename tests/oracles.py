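"""Independent brute-force oracles for the network statistics.

Deliberately naive: explicit enumeration, plain-Python arithmetic, no
shared code with the implementations they check.
"""

from __future__ import annotations

import math
from collections import deque


def pearson(pairs: list[tuple[float, float]]) -> float | None:
    """Textbook Pearson correlation over a list of (x, y) pairs."""
    n = len(pairs)
    if n == 0:
        return None
    mx = sum(x for x, _ in pairs) / n
    my = sum(y for _, y in pairs) / n
    sxx = sum((x - mx) ** 2 for x, _ in pairs)
    syy = sum((y - my) ** 2 for _, y in pairs)
    sxy = sum((x - mx) * (y - my) for x, y in pairs)
    if sxx <= 0 or syy <= 0:
        return None
    return sxy / math.sqrt(sxx * syy)


def edge_assortativity(edges: set[tuple[str, str]], values: dict[str, float]) -> float | None:
    """Endpoint-value correlation by explicit edge enumeration."""
    return pearson([(values[s], values[r]) for s, r in edges])


def in_degrees(nodes: tuple[str, ...], edges: set[tuple[str, str]]) -> dict[str, int]:
    deg = {n: 0 for n in nodes}
    for _, r in edges:
        deg[r] += 1
    return deg


def out_degrees(nodes: tuple[str, ...], edges: set[tuple[str, str]]) -> dict[str, int]:
    deg = {n: 0 for n in nodes}
    for s, _ in edges:
        deg[s] += 1
    return deg


def bfs_distances(nodes, adjacency: dict[str, list[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adjacency.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_pairs_in_eccentricity(
    nodes: tuple[str, ...], edges: set[tuple[str, str]]
) -> dict[str, int]:
    """In-eccentricity by all-pairs BFS: per-node max over reaching sources."""
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for s, r in edges:
        adj[s].append(r)
    ecc = {n: 0 for n in nodes}
    for u in nodes:
        for v, d in bfs_distances(nodes, adj, u).items():
            if d > ecc[v]:
                ecc[v] = d
    return ecc


def _all_shortest_paths(adj, dist_from_s, s, t):
    """Every shortest s→t path, by DFS backwards over the BFS distances."""
    if t not in dist_from_s:
        return []
    rev: dict[str, list[str]] = {}
    for u, nbrs in adj.items():
        for v in nbrs:
            rev.setdefault(v, []).append(u)
    paths = []

    def back(v, tail):
        if v == s:
            paths.append([s] + tail)
            return
        for u in rev.get(v, ()):
            if dist_from_s.get(u, -2) == dist_from_s[v] - 1:
                back(u, [v] + tail)

    back(t, [])
    return paths


def betweenness_by_path_enumeration(
    nodes: tuple[str, ...], edges: set[tuple[str, str]]
) -> dict[str, float]:
    """Unnormalized directed betweenness by enumerating all shortest paths."""
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for s, r in edges:
        adj[s].append(r)
    bc = {n: 0.0 for n in nodes}
    for s in nodes:
        dist = bfs_distances(nodes, adj, s)
        for t in nodes:
            if t == s:
                continue
            paths = _all_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc


def phi_by_contingency(
    nodes: tuple[str, ...],
    edges_a: set[tuple[str, str]],
    edges_b: set[tuple[str, str]],
) -> float | None:
    """Phi of two adjacency matrices by explicit off-diagonal tabulation."""
    n11 = n10 = n01 = n00 = 0
    for s in nodes:
        for r in nodes:
            if s == r:
                continue
            a = (s, r) in edges_a
            b = (s, r) in edges_b
            if a and b:
                n11 += 1
            elif a:
                n10 += 1
            elif b:
                n01 += 1
            else:
                n00 += 1
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return None
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def sample_variance(values: list[float]) -> float:
    n = len(values)
    mean = sum(values) / n
    return sum((v - mean) ** 2 for v in values) / (n - 1)
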