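"""Independent brute-force oracles for small graphs and exact statistics.

Everything here is pure Python over adjacency dicts (no networkx) so the
oracles stay independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from fractions import Fraction


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_shortest_paths(adj, s, t, d):
    """Every simple path from s to t of length exactly d, by exhaustive DFS."""
    paths = []

    def dfs(path):
        u = path[-1]
        if len(path) - 1 > d:
            return
        if u == t and len(path) - 1 == d:
            paths.append(list(path))
            return
        for v in adj[u]:
            if v not in path:
                path.append(v)
                dfs(path)
                path.pop()

    dfs([s])
    return paths


def oracle_centralities(nodes, edges):
    """Degree, normalized betweenness and reachable-average closeness by
    exhaustive shortest-path enumeration."""
    nodes = list(nodes)
    adj = adjacency(nodes, edges)
    n = len(nodes)
    degree = {v: len(adj[v]) for v in nodes}

    closeness = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        reach = [d for u, d in dist.items() if u != v]
        closeness[v] = len(reach) / sum(reach) if reach and sum(reach) else 0.0

    betweenness = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist = bfs_distances(adj, s)
        if t not in dist:
            continue
        paths = all_shortest_paths(adj, s, t, dist[t])
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            betweenness[v] += through / sigma
    scale = (n - 1) * (n - 2) / 2
    if scale > 0:
        betweenness = {v: b / scale for v, b in betweenness.items()}
    return degree, betweenness, closeness


def oracle_path_length_counts(nodes, edges):
    """Ordered finite-distance pair counts per distance, via per-source BFS."""
    adj = adjacency(nodes, edges)
    counts: dict[int, int] = {}
    for s in nodes:
        for u, d in bfs_distances(adj, s).items():
            if u != s:
                counts[d] = counts.get(d, 0) + 1
    return counts


def oracle_kcore(nodes, edges, k):
    """Maximal subgraph with all internal degrees >= k, by repeated pruning."""
    adj = {v: set(nb) for v, nb in adjacency(nodes, edges).items()}
    alive = set(nodes)
    changed = True
    while changed:
        changed = False
        for v in sorted(alive):
            if len(adj[v] & alive) < k:
                alive.discard(v)
                changed = True
    return alive


def oracle_vertex_weight(nodes, edges, v, degree_cutoff=2):
    """MCODE vertex weight by enumerating k-cores of the closed neighborhood."""
    adj = adjacency(nodes, edges)
    if len(adj[v]) < degree_cutoff:
        return 0.0
    hood = adj[v] | {v}
    h_edges = [(a, b) for a, b in edges if a in hood and b in hood]
    k = 0
    core = set(hood)
    while True:
        nxt = oracle_kcore(hood, h_edges, k + 1)
        if not nxt:
            break
        k += 1
        core = nxt
    m = sum(1 for a, b in h_edges if a in core and b in core)
    nc = len(core)
    density = 2 * m / (nc * (nc - 1)) if nc > 1 else 0.0
    return k * density


def oracle_mcode_complexes(nodes, edges, weights, node_score_cutoff=0.2):
    """Step-by-step reference trace of the greedy complex expansion."""
    adj = adjacency(nodes, edges)
    visited = set()
    complexes = []
    for seed in sorted(nodes, key=lambda u: (-weights[u], u)):
        if seed in visited:
            continue
        threshold = weights[seed] * (1 - node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = deque([seed])
        while frontier:
            u = frontier.popleft()
            for nb in sorted(adj[u]):
                if nb not in visited and weights[nb] >= threshold:
                    visited.add(nb)
                    members.add(nb)
                    frontier.append(nb)
        if len(members) >= 2:
            complexes.append(frozenset(members))
    return complexes


def oracle_hypergeom_upper(k, K, n, N):
    """Exact rational P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc


def oracle_bh(pvalues):
    """Benjamini–Hochberg adjusted p-values by the textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        adj[idx] = running
    return adj
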