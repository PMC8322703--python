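"""Protein-protein interaction networks: loading, gene induction, MCODE.

Networks are plain undirected :class:`networkx.Graph` objects with gene
symbols as node ids, an optional ``confidence`` edge attribute in [0, 1]
and an optional ``direction`` node attribute.

MCODE finds densely connected complexes: every node is weighted by the
density of the highest k-core of its open neighborhood, clusters grow
greedily from high-weight seeds, and a 2-core "haircut" trims loosely
attached tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MCODECluster:
    """A dense cluster: its node set, seed, and score = density * size."""

    nodes: frozenset
    seed: str
    score: float

    def __len__(self) -> int:
        return len(self.nodes)


def load_edge_list(path, min_conf: float = 0.4) -> nx.Graph:
    """Load a (protein1, protein2, combined_score) TSV into a Graph.

    Scores on a 0-1000 scale (max > 1) are rescaled to [0, 1].  Edges are
    kept when confidence is strictly greater than ``min_conf``; self-loops
    are dropped and duplicate edges collapse to the maximum confidence.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str,
                     skip_blank_lines=True)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need (id, id, score) columns")
    if len(df) and not _is_number(df.iat[0, 2]):
        df = df.iloc[1:].reset_index(drop=True)  # header row
    bad = [i for i, v in enumerate(df.iloc[:, 2]) if not _is_number(v)]
    if bad:
        raise ValueError(f"{path}: malformed score on line {bad[0] + 1}")
    scores = df.iloc[:, 2].astype(float)
    if scores.max() > 1.0:
        scores = scores / 1000.0
    net = nx.Graph()
    n_dup = n_self = 0
    for (a, b), conf in zip(df.iloc[:, :2].itertuples(index=False), scores):
        a, b = str(a), str(b)
        if a == b:
            n_self += 1
            continue
        if conf <= min_conf:
            continue
        if net.has_edge(a, b):
            n_dup += 1
            net[a][b]["confidence"] = max(net[a][b]["confidence"], conf)
        else:
            net.add_edge(a, b, confidence=float(conf))
    if n_dup or n_self:
        logger.info("dropped %d self-loops, merged %d duplicate edges",
                    n_self, n_dup)
    return net


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def induce_on_genes(net: nx.Graph, genes, drop_isolated: bool = True) -> nx.Graph:
    """Subgraph on ``genes``; isolated nodes removed unless kept explicitly."""
    sub = nx.Graph(net.subgraph(set(genes) & set(net.nodes)))
    if drop_isolated:
        sub.remove_nodes_from([v for v, d in dict(sub.degree()).items() if d == 0])
    if sub.number_of_nodes() == 0:
        logger.warning("induced subgraph is empty")
    return sub


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def mcode_node_weights(net: nx.Graph, degree_cut: int = 2) -> dict:
    """MCODE vertex weights: highest-k-core density of the open neighborhood.

    For node v, take the subgraph induced on v's neighbors (v excluded),
    find its maximum core number k and the corresponding k-core K; the
    weight is k * density(K).  Nodes with fewer than ``degree_cut``
    neighbors weigh 0.
    """
    weights = {}
    for v in net.nodes:
        nbrs = list(net.neighbors(v))
        if len(nbrs) < degree_cut:
            weights[v] = 0.0
            continue
        nbhd = net.subgraph(nbrs)
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_num = nx.core_number(nbhd)
        k = max(core_num.values())
        core = nbhd.subgraph([u for u, c in core_num.items() if c >= k])
        weights[v] = k * _density(core)
    return weights


def mcode_find_clusters(net: nx.Graph, node_score_cut: float = 0.2,
                        degree_cut: int = 2, k_core: int = 2,
                        haircut: bool = True,
                        max_depth: int = 100) -> list[MCODECluster]:
    """Greedy seeded complex detection (MCODE).

    Unvisited nodes are seeded in decreasing weight order (ties by node
    id); a cluster grows breadth-first from the seed, admitting unvisited
    neighbors whose weight is at least (1 - node_score_cut) times the seed
    weight, to at most ``max_depth`` hops.  A 2-core haircut trims degree-1
    tails, clusters without a ``k_core``-core are discarded, and surviving
    clusters (score = density * size, descending) have disjoint node sets.
    """
    weights = mcode_node_weights(net, degree_cut=degree_cut)
    visited: set = set()
    clusters: list[MCODECluster] = []
    for seed in sorted(net.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in visited:
            continue
        threshold = (1.0 - node_score_cut) * weights[seed]
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for u in frontier:
                for w in net.neighbors(u):
                    if w in members or w in visited:
                        continue
                    if weights[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        visited |= members
        sub = nx.Graph(net.subgraph(members))
        if haircut:
            sub = nx.k_core(sub, 2)
        if sub.number_of_nodes() == 0 or nx.k_core(sub, k_core).number_of_nodes() == 0:
            continue
        if not nx.is_connected(sub):
            # keep the component containing the seed (or the largest one)
            comps = list(nx.connected_components(sub))
            keep = next((c for c in comps if seed in c),
                        max(comps, key=len))
            sub = nx.Graph(sub.subgraph(keep))
            if nx.k_core(sub, k_core).number_of_nodes() == 0:
                continue
        score = _density(sub) * sub.number_of_nodes()
        if score <= 0:
            continue
        cl = MCODECluster(nodes=frozenset(sub.nodes), seed=seed, score=score)
        assert nx.is_connected(net.subgraph(cl.nodes))
        clusters.append(cl)
    return sorted(clusters, key=lambda c: (-c.score, sorted(map(str, c.nodes))))
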