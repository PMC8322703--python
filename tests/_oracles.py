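"""Independent brute-force oracles used by the tests.

Everything here works from a plain adjacency dict and explicit enumeration
(subsets, simple paths, BFS written out by hand) so it shares no code path
with the implementations it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def adjacency(edges, nodes) -> dict:
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_dist(adj, s) -> dict:
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def components(adj, nodes=None) -> list[set]:
    nodes = set(adj if nodes is None else nodes)
    comps = []
    while nodes:
        s = nodes.pop()
        comp = set(_bfs_restricted(adj, s, nodes | {s}))
        nodes -= comp
        comps.append(comp)
    return comps


def _bfs_restricted(adj, s, allowed):
    seen = {s}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w in allowed and w not in seen:
                seen.add(w)
                q.append(w)
    return seen


def is_clique(adj, subset) -> bool:
    return all(b in adj[a] for a, b in itertools.combinations(subset, 2))


def maximal_cliques(adj, nodes) -> list[set]:
    """All maximal cliques of size >= 2 by exhaustive subset enumeration."""
    nodes = list(nodes)
    cliques = [set(c) for r in range(2, len(nodes) + 1)
               for c in itertools.combinations(nodes, r)
               if is_clique(adj, c)]
    return [c for c in cliques
            if not any(c < d for d in cliques)]


def mcc(adj, nodes) -> dict:
    scores = {v: 0.0 for v in nodes}
    for c in maximal_cliques(adj, nodes):
        for v in c:
            scores[v] += math.factorial(len(c) - 1)
    return scores


def _nbhd_largest_component(adj, v):
    nbrs = adj[v]
    if not nbrs:
        return set(), 0
    sub = {u: adj[u] & nbrs for u in nbrs}
    comps = []
    remaining = set(nbrs)
    while remaining:
        s = remaining.pop()
        comp = _bfs_restricted(sub, s, remaining | {s})
        remaining -= comp
        comps.append(comp)
    best = max(comps, key=lambda c: (len(c),
               sum(len(sub[u] & c) for u in c) // 2))
    edges = sum(len(sub[u] & best) for u in best) // 2
    return best, edges


def mnc(adj, nodes) -> dict:
    return {v: float(len(_nbhd_largest_component(adj, v)[0])) for v in nodes}


def dmnc(adj, nodes) -> dict:
    out = {}
    for v in nodes:
        comp, edges = _nbhd_largest_component(adj, v)
        out[v] = edges / len(comp) ** 1.7 if comp else 0.0
    return out


def harmonic_closeness(adj, nodes) -> dict:
    return {v: sum(1.0 / d for w, d in bfs_dist(adj, v).items() if w != v)
            for v in nodes}


def inv_eccentricity(adj, nodes) -> dict:
    out = {}
    for v in nodes:
        dist = bfs_dist(adj, v)
        ecc = max(dist.values())
        out[v] = 1.0 / ecc if ecc > 0 else 0.0
    return out


def radiality(adj, nodes) -> dict:
    n = len(list(nodes))
    out = {v: 0.0 for v in nodes}
    if n < 2:
        return out
    for comp in components(adj, nodes):
        if len(comp) == 1:
            continue
        dists = {v: bfs_dist({u: adj[u] & comp for u in comp}, v) for v in comp}
        diam = max(max(d.values()) for d in dists.values())
        for v in comp:
            out[v] = sum(diam + 1 - d for w, d in dists[v].items() if w != v) \
                / (n - 1)
    return out


def betweenness(adj, nodes) -> dict:
    """Unnormalized betweenness by explicit simple-path enumeration."""
    nodes = list(nodes)
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist = bfs_dist(adj, s)
        if t not in dist:
            continue
        shortest = [p for p in _all_simple_paths(adj, s, t, dist[t])]
        if not shortest:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            out[v] += through / len(shortest)
    return out


def _all_simple_paths(adj, s, t, length):
    """All simple paths from s to t with exactly ``length`` edges."""
    paths = []

    def extend(path):
        u = path[-1]
        if len(path) - 1 == length:
            if u == t:
                paths.append(list(path))
            return
        for w in adj[u]:
            if w not in path:
                path.append(w)
                extend(path)
                path.pop()

    extend([s])
    return paths


def bottleneck(adj, nodes) -> dict:
    """One BFS tree per root, lexicographically smallest parent; a node
    scores a point per tree whose proper descendants exceed tree size / 4."""
    out = {v: 0.0 for v in nodes}
    for s in nodes:
        dist = bfs_dist(adj, s)
        n_tree = len(dist)
        if n_tree == 1:
            continue
        parent = {v: min((u for u in adj[v] if dist.get(u) == dist[v] - 1),
                         key=str)
                  for v in dist if v != s}
        desc = {v: 0 for v in dist}
        for v in sorted(dist, key=lambda x: -dist[x]):
            if v != s:
                desc[parent[v]] += desc[v] + 1
        for v in dist:
            if desc[v] > n_tree / 4.0:
                out[v] += 1.0
    return out


def epc_exact(edges, nodes, keep_p: float):
    """Exact EPC expectation and variance by enumerating all edge subsets.

    Returns (mean, var) dicts: for each node, moments of the number of
    other nodes in its component when each edge survives with prob keep_p.
    """
    edges = list(edges)
    nodes = list(nodes)
    mean = {v: 0.0 for v in nodes}
    second = {v: 0.0 for v in nodes}
    for mask in range(2 ** len(edges)):
        kept = [e for i, e in enumerate(edges) if mask >> i & 1]
        prob = keep_p ** len(kept) * (1 - keep_p) ** (len(edges) - len(kept))
        adj = adjacency(kept, nodes)
        for comp in components(adj, nodes):
            for v in comp:
                x = len(comp) - 1
                mean[v] += prob * x
                second[v] += prob * x * x
    var = {v: second[v] - mean[v] ** 2 for v in nodes}
    return mean, var


def order_stat_tail_mc(r, m, n_draws, rng):
    """Monte-Carlo P(U_(k) <= r_k) for sorted uniforms, per k."""
    import numpy as np
    draws = np.sort(rng.random((n_draws, m)), axis=1)
    r = np.asarray(r)
    return (draws <= r).mean(axis=0)
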