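"""Competing-endogenous-RNA (ceRNA) network assembly.

A circRNA acts as a miRNA sponge: it sequesters miRNAs away from their
mRNA targets, so a functional circRNA-miRNA-mRNA axis needs (i) the
miRNA-mRNA pair predicted by all three target databases, (ii) the miRNA
differentially expressed in the opposite direction to the mRNA, and
(iii) a circRNA interacting with the miRNA.  After attaching circRNAs,
only circRNAs whose miRNA partners collectively reach every remaining
mRNA are retained, giving a small tripartite network whose nodes are then
ranked by Maximal Clique Centrality.
"""

from __future__ import annotations

import importlib.resources
import logging
from collections.abc import Iterable, Mapping

import networkx as nx
import pandas as pd

from .centrality import centrality, top_k_list

logger = logging.getLogger(__name__)

Pair = tuple[str, str]  # (mirna_id, mrna_symbol)


def load_target_table(path) -> pd.DataFrame:
    """Read a (mirna_id, mrna_symbol, source) TSV of predicted targets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    need = {"mirna", "mrna", "source"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    if df.duplicated(["mirna", "mrna", "source"]).any():
        raise ValueError(f"{path}: duplicate (mirna, mrna, source) rows")
    return df


def intersect_three_dbs(targets: pd.DataFrame) -> set[Pair]:
    """Pairs predicted by all three sources.

    ``targets`` holds rows (mirna, mrna, source) pooled over exactly three
    distinct prediction databases.
    """
    sources = sorted(targets["source"].unique())
    if len(sources) != 3:
        raise ValueError(f"need exactly 3 target sources, got {sources}")
    per_source = [set(zip(g["mirna"], g["mrna"]))
                  for _, g in targets.groupby("source")]
    return set.intersection(*per_source)


def validate_directions(pairs: Iterable[Pair],
                        demis: pd.DataFrame | Mapping[str, str],
                        mrna_dirs: Mapping[str, str]) -> set[Pair]:
    """Keep pairs whose miRNA moves opposite to its target mRNA.

    miRNAs repress their targets, so a pair is biologically consistent only
    when the differentially expressed miRNA and the mRNA have opposite
    directions.  miRNAs absent from the DE-miRNA table are dropped.
    """
    if isinstance(demis, pd.DataFrame):
        mi_dir = {str(i): str(d).lower()
                  for i, d in demis["direction"].items()}
    else:
        mi_dir = {k: str(v).lower() for k, v in demis.items()}
    opposite = {"up": "down", "down": "up"}
    kept = set()
    for mi, g in pairs:
        gdir = str(mrna_dirs[g]).lower()
        if gdir not in opposite:
            raise ValueError(f"mRNA {g} has unknown direction {gdir!r}")
        if mi_dir.get(mi) == opposite[gdir]:
            kept.add((mi, g))
    return kept


def attach_circrnas(pairs: Iterable[Pair], circ: pd.DataFrame | Iterable[Pair]
                    ) -> tuple[set[str], set[str], set[str]]:
    """Drop mRNAs none of whose validated miRNAs has a circRNA partner.

    ``circ`` holds (circrna_id, mirna_id) interaction rows.  Returns
    (kept_mrnas, candidate_circs, dropped_mrnas) where candidate circRNAs
    are those linked to at least one miRNA of a surviving mRNA.
    """
    circ_pairs = _as_circ_pairs(circ)
    mirnas_with_circ = {mi for _, mi in circ_pairs}
    by_mrna: dict[str, set[str]] = {}
    for mi, g in pairs:
        by_mrna.setdefault(g, set()).add(mi)
    kept = {g for g, mis in by_mrna.items() if mis & mirnas_with_circ}
    dropped = set(by_mrna) - kept
    if dropped:
        logger.info("mRNAs without circRNA support dropped: %s", sorted(dropped))
    surviving_mis = {mi for mi, g in pairs if g in kept}
    candidates = {c for c, mi in circ_pairs if mi in surviving_mis}
    if not kept:
        logger.warning("every mRNA lost circRNA support; network will be empty")
    return kept, candidates, dropped


def coverage_filter(candidate_circs: Iterable[str], kept_mrnas: Iterable[str],
                    pairs: Iterable[Pair],
                    circ: pd.DataFrame | Iterable[Pair]) -> set[str]:
    """Retain circRNAs that can regulate *every* remaining mRNA.

    circRNA c covers mRNA g when some miRNA m has both an interaction
    (c, m) and a validated pair (m, g); only circRNAs covering all kept
    mRNAs survive.
    """
    circ_pairs = _as_circ_pairs(circ)
    kept_mrnas = set(kept_mrnas)
    pair_set = set(pairs)
    mis_of_circ: dict[str, set[str]] = {}
    for c, mi in circ_pairs:
        mis_of_circ.setdefault(c, set()).add(mi)
    retained = set()
    for c in candidate_circs:
        mis = mis_of_circ.get(c, set())
        if all(any((mi, g) in pair_set for mi in mis) for g in kept_mrnas):
            retained.add(c)
    return retained


def build_network(retained_circs: Iterable[str], kept_mrnas: Iterable[str],
                  pairs: Iterable[Pair], circ: pd.DataFrame | Iterable[Pair],
                  dirs: Mapping[str, str] | None = None) -> nx.Graph:
    """Assemble the tripartite circRNA-miRNA-mRNA graph.

    Nodes: retained circRNAs, kept mRNAs, and miRNAs linked to at least one
    retained circRNA *and* one kept mRNA.  Edges are the circ-miRNA and
    miRNA-mRNA interactions restricted to those nodes; node attributes
    ``kind`` (circRNA/miRNA/mRNA) and optional ``direction`` are set.
    """
    circ_pairs = _as_circ_pairs(circ)
    retained_circs, kept_mrnas = set(retained_circs), set(kept_mrnas)
    pair_set = {(mi, g) for mi, g in pairs if g in kept_mrnas}
    mis_to_mrna = {mi for mi, _ in pair_set}
    mis_to_circ = {mi for c, mi in circ_pairs if c in retained_circs}
    mirnas = mis_to_mrna & mis_to_circ
    net = nx.Graph()
    for c in sorted(retained_circs):
        net.add_node(c, kind="circRNA")
    for mi in sorted(mirnas):
        net.add_node(mi, kind="miRNA")
    for g in sorted(kept_mrnas):
        net.add_node(g, kind="mRNA")
    for c, mi in circ_pairs:
        if c in retained_circs and mi in mirnas:
            net.add_edge(c, mi)
    for mi, g in pair_set:
        if mi in mirnas:
            net.add_edge(mi, g)
    if dirs:
        for v, d in dirs.items():
            if v in net:
                net.nodes[v]["direction"] = str(d).lower()
    _check_invariants(net)
    return net


def _check_invariants(net: nx.Graph) -> None:
    kinds = nx.get_node_attributes(net, "kind")
    assert set(kinds) == set(net.nodes), "every node needs a kind"
    allowed = {frozenset({"circRNA", "miRNA"}), frozenset({"miRNA", "mRNA"})}
    for a, b in net.edges:
        assert frozenset({kinds[a], kinds[b]}) in allowed, \
            f"forbidden edge class {kinds[a]}-{kinds[b]} ({a}, {b})"
    circs = {v for v, k in kinds.items() if k == "circRNA"}
    for v, k in kinds.items():
        if k == "mRNA" and circs:
            assert any(nx.has_path(net, c, v) for c in circs), \
                f"mRNA {v} unreachable from every circRNA"


def rank_cerna_mcc(net: nx.Graph, top: int = 10) -> list[str]:
    """Rank ceRNA nodes by Maximal Clique Centrality on the plain graph."""
    return top_k_list(centrality(net, "MCC"), k=top)


def _as_circ_pairs(circ) -> set[Pair]:
    if isinstance(circ, pd.DataFrame):
        df = circ.copy()
        df.columns = [c.lower() for c in df.columns]
        if not {"circrna", "mirna"} <= set(df.columns):
            raise ValueError("circRNA table needs columns (circrna, mirna)")
        return set(zip(df["circrna"].astype(str), df["mirna"].astype(str)))
    return {(str(c), str(mi)) for c, mi in circ}


def load_table3() -> pd.DataFrame:
    """The published 45 miRNA-mRNA relationships of the asthma hub genes.

    Returns one row per (mirna, mrna) pair with the mRNA direction; used as
    a worked example and fixture for the network-assembly rules.
    """
    path = importlib.resources.files("cernet.data") / "table3.tsv"
    raw = pd.read_csv(path, sep="\t")
    rows = []
    for _, r in raw.iterrows():
        for mi in str(r["miRNAs"]).split("/"):
            rows.append({"mirna": mi, "mrna": r["mRNA"],
                         "direction": str(r["direction"]).lower()})
    return pd.DataFrame(rows)
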