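"""Independent brute-force oracles, deliberately naive.

These reimplement, from first principles and without networkx/statsmodels
shortcuts, the quantities the package computes, so tests can compare two
independent routes.
"""

from itertools import combinations

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def count_shortest_paths(adj: dict, s, t, dist_s: dict):
    """Number of shortest s-t paths, and how many pass through each node."""
    if t not in dist_s:
        return 0, {}
    d = dist_s[t]
    paths = []

    def extend(path):
        u = path[-1]
        if len(path) - 1 == d:
            if u == t:
                paths.append(path)
            return
        for v in adj[u]:
            if dist_s.get(v) == len(path):  # stay on a shortest path
                extend(path + [v])

    extend([s])
    through = {}
    for p in paths:
        for node in p[1:-1]:
            through[node] = through.get(node, 0) + 1
    return len(paths), through


def brute_force_metrics(nodes: list, edges: list) -> dict:
    """All eight topological parameters, by enumeration."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    n = len(nodes)
    deg = {v: len(adj[v]) for v in nodes}
    dists = {v: bfs_distances(adj, v) for v in nodes}

    betw = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        total, through = count_shortest_paths(adj, s, t, dists[s])
        if total:
            for v, c in through.items():
                betw[v] += c / total

    out = {}
    for v in nodes:
        d = dists[v]
        closeness = sum(1.0 / l for u, l in d.items() if u != v)
        comp_ecc = max((l for u, l in d.items()), default=0)
        ecc_cent = 1.0 / comp_ecc if comp_ecc > 0 else 0.0
        if deg[v] >= 2:
            links = sum(
                1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a]
            )
            cc = 2.0 * links / (deg[v] * (deg[v] - 1))
        else:
            cc = 0.0
        if deg[v] > 0:
            bc = (1.0 / deg[v]) / sum(1.0 / deg[u] for u in adj[v])
            nbrs = sorted(adj[v])
            lac = sum(
                sum(1 for u in nbrs if u in adj[w] and u != w) for w in nbrs
            ) / len(nbrs)
        else:
            bc, lac = 0.0, 0.0
        out[v] = {
            "degree": float(deg[v]),
            "betweenness": betw[v],
            "bridging_centrality": betw[v] * bc,
            "closeness": closeness,
            "eccentricity_centrality": ecc_cent,
            "clustering": cc,
            "brokering": (1.0 - cc) * deg[v] / (n - 1),
            "lac": lac,
        }
    return out


def bh_step_up(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adj[i] = running_min
    return adj
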