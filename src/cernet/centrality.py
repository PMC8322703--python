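"""Topological centrality ensemble for hub-gene identification.

Implements the ten node-ranking methods popularised by the cytoHubba
Cytoscape plugin — MCC, DMNC, MNC, Degree, EPC, BottleNeck, EcCentricity,
Closeness, Radiality and Betweenness — plus helpers to take per-method
top-k lists and re-aggregate them with Robust Rank Aggregation into a
single hub table.  Exact normalisations vary between tools; the
definitions used here are documented per method and pinned by oracle
tests, and all are deterministic given the graph (EPC given its seed).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import rra

METHODS = ("MCC", "DMNC", "MNC", "Degree", "EPC", "BottleNeck",
           "EcCentricity", "Closeness", "Radiality", "Betweenness")


def _mcc(net: nx.Graph) -> dict:
    """Maximal Clique Centrality: sum of (|C|-1)! over maximal cliques
    containing the node (cliques of size >= 2; isolated nodes score 0)."""
    scores = {v: 0.0 for v in net.nodes}
    for clique in nx.find_cliques(net):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def _neighborhood_component(net: nx.Graph, v) -> nx.Graph:
    """Largest connected component of the open-neighborhood subgraph."""
    nbhd = net.subgraph(list(net.neighbors(v)))
    if nbhd.number_of_nodes() == 0:
        return nbhd
    comp = max(nx.connected_components(nbhd),
               key=lambda c: (len(c), nbhd.subgraph(c).number_of_edges()))
    return nbhd.subgraph(comp)


def _mnc(net: nx.Graph) -> dict:
    return {v: float(_neighborhood_component(net, v).number_of_nodes())
            for v in net.nodes}


def _dmnc(net: nx.Graph) -> dict:
    scores = {}
    for v in net.nodes:
        comp = _neighborhood_component(net, v)
        n = comp.number_of_nodes()
        scores[v] = comp.number_of_edges() / n ** 1.7 if n > 0 else 0.0
    return scores


def _closeness(net: nx.Graph) -> dict:
    """Harmonic closeness: sum of reciprocal distances (1/inf = 0)."""
    return {v: sum(1.0 / d for w, d in
                   nx.single_source_shortest_path_length(net, v).items()
                   if w != v)
            for v in net.nodes}


def _eccentricity(net: nx.Graph) -> dict:
    scores = {}
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        if len(comp) == 1:
            scores.update({v: 0.0 for v in comp})
            continue
        ecc = nx.eccentricity(sub)
        scores.update({v: 1.0 / e for v, e in ecc.items()})
    return scores


def _radiality(net: nx.Graph) -> dict:
    """Radiality: sum over same-component nodes of (diam + 1 - d(v, w)),
    divided by (|V| - 1) with |V| the whole graph's node count."""
    n = net.number_of_nodes()
    scores = {v: 0.0 for v in net.nodes}
    if n < 2:
        return scores
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        if len(comp) == 1:
            continue
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(dd.values()) for dd in dist.values())
        for v in comp:
            scores[v] = sum(diam + 1 - d for w, d in dist[v].items()
                            if w != v) / (n - 1)
    return scores


def _betweenness(net: nx.Graph) -> dict:
    return nx.betweenness_centrality(net, normalized=False)


def _bottleneck(net: nx.Graph) -> dict:
    """BottleNeck: for each root, one BFS shortest-path tree is built with
    ties broken toward the lexicographically smaller parent; a node gains a
    point per tree in which its proper descendants exceed a quarter of the
    tree (the root's descendant count is the tree size minus one)."""
    scores = {v: 0.0 for v in net.nodes}
    order = {v: i for i, v in enumerate(sorted(net.nodes, key=str))}
    for s in net.nodes:
        depth = nx.single_source_shortest_path_length(net, s)
        tree_nodes = sorted(depth, key=lambda v: (depth[v], order[v]))
        n_tree = len(tree_nodes)
        if n_tree == 1:
            continue
        parent = {}
        for v in tree_nodes:
            if v == s:
                continue
            preds = [u for u in net.neighbors(v) if depth.get(u) == depth[v] - 1]
            parent[v] = min(preds, key=lambda u: order[u])
        desc = {v: 0 for v in tree_nodes}
        for v in sorted(tree_nodes, key=lambda v: -depth[v]):
            if v == s:
                continue
            p = parent[v]
            desc[p] += desc[v] + 1
        for v in tree_nodes:
            if desc[v] > n_tree / 4.0:
                scores[v] += 1.0
    return scores


def _epc(net: nx.Graph, seed: int, iters: int, keep_p: float) -> dict:
    """Edge Percolated Component: expected number of other nodes connected
    to v when each edge survives independently with probability keep_p,
    estimated over ``iters`` seeded realizations."""
    rng = np.random.default_rng(seed)
    nodes = list(net.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = [(idx[a], idx[b]) for a, b in net.edges]
    totals = np.zeros(len(nodes))
    n = len(nodes)
    if n == 0 or iters <= 0:
        return {v: 0.0 for v in nodes}
    keep_masks = rng.random((iters, len(edges))) < keep_p if edges else \
        np.zeros((iters, 0), dtype=bool)
    parent = np.empty(n, dtype=np.int64)
    for it in range(iters):
        parent[:] = np.arange(n)

        def find(x: int) -> int:
            root = x
            while parent[root] != root:
                root = parent[root]
            while parent[x] != root:
                parent[x], x = root, parent[x]
            return root

        for e, (a, b) in enumerate(edges):
            if keep_masks[it, e]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        roots = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
        sizes = np.bincount(roots, minlength=n)
        totals += sizes[roots] - 1
    return {v: totals[idx[v]] / iters for v in nodes}


def centrality(net: nx.Graph, method: str, seed: int = 0,
               epc_iters: int = 1000, epc_keep_p: float = 0.5) -> dict:
    """Compute one of the ten centralities; returns node -> score."""
    if method == "Degree":
        return {v: float(d) for v, d in net.degree()}
    if method == "MCC":
        return _mcc(net)
    if method == "MNC":
        return _mnc(net)
    if method == "DMNC":
        return _dmnc(net)
    if method == "Closeness":
        return _closeness(net)
    if method == "EcCentricity":
        return _eccentricity(net)
    if method == "Radiality":
        return _radiality(net)
    if method == "Betweenness":
        return _betweenness(net)
    if method == "BottleNeck":
        return _bottleneck(net)
    if method == "EPC":
        return _epc(net, seed=seed, iters=epc_iters, keep_p=epc_keep_p)
    raise ValueError(f"unknown centrality method {method!r}; "
                     f"choose from {METHODS}")


def centrality_table(net: nx.Graph, seed: int = 0, epc_iters: int = 1000,
                     epc_keep_p: float = 0.5) -> pd.DataFrame:
    """All ten centralities as a nodes x methods DataFrame."""
    cols = {m: centrality(net, m, seed=seed, epc_iters=epc_iters,
                          epc_keep_p=epc_keep_p) for m in METHODS}
    return pd.DataFrame(cols).reindex(sorted(net.nodes, key=str))


def top_k_list(scores: Mapping, k: int = 50) -> list:
    """Top-k nodes by score descending, ties broken by node id ascending."""
    ranked = sorted(scores, key=lambda v: (-scores[v], str(v)))
    return ranked[:min(k, len(ranked))]


def aggregate_hubs(lists: Sequence[Sequence], n_nodes: int,
                   score_cut: float = 0.05) -> pd.DataFrame:
    """RRA-aggregate per-method top-k lists into a hub table.

    Every list shares the same universe (all ``n_nodes`` network nodes);
    nodes missing from a method's list get the worst rank.  Returns the
    aggregated rows with corrected score < ``score_cut``, ascending.
    """
    table = rra.aggregate(lists, [n_nodes] * len(lists))
    return table[table["score"] < score_cut].drop(columns="mean_lfc")
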