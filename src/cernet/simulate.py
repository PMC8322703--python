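"""Seeded synthetic-data generators with planted ground truth.

Every pipeline input — multi-cohort case/control expression matrices, a
confidence-scored interaction network, miRNA target tables from three
prediction sources, a differential-miRNA table and circRNA-miRNA links —
can be generated here with known planted signal, so each stage and the
end-to-end run are testable without any database downloads.

The expression generator emulates a five-cohort microarray meta-analysis
design: a shared gene space, independent cohorts with Gaussian log2 noise,
concordant case shifts for the planted genes, and a fraction of genes
missing per cohort (platform differences).  The interaction generator
plants cliques in an Erdos-Renyi background; the ceRNA generator plants
consistent circRNA-miRNA-mRNA triplets next to decoys that each violate
exactly one assembly rule, so a failure is attributable to a single filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside every generated artifact."""

    de_genes_up: dict[str, float] = field(default_factory=dict)
    de_genes_down: dict[str, float] = field(default_factory=dict)
    hub_nodes: set[str] = field(default_factory=set)
    clusters: list[set[str]] = field(default_factory=list)
    cerna_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "de_genes_up": self.de_genes_up,
            "de_genes_down": self.de_genes_down,
            "hub_nodes": sorted(self.hub_nodes),
            "clusters": [sorted(c) for c in self.clusters],
            "cerna_triplets": [list(t) for t in self.cerna_triplets],
            "params": self.params,
        }, indent=2)


def simulate_expression_datasets(n_datasets: int = 5, n_genes: int = 1000,
                                 n_case: int = 20, n_control: int = 20,
                                 n_up: int = 50, n_down: int = 50,
                                 effect: float = 1.0, sigma: float = 1.0,
                                 missing_frac: float = 0.1,
                                 seed: int = 0) -> tuple[list[ExpressionMatrix], PlantedTruth]:
    """Independent case/control cohorts with shared planted DE genes.

    Gene g in cohort d is N(baseline_g, sigma^2); planted up/down genes are
    shifted by +/-``effect`` in every cohort's cases.  ``missing_frac`` of
    genes are absent from each cohort at random, emulating platform
    coverage differences.
    """
    if n_up + n_down >= n_genes:
        raise ValueError("planted genes must number fewer than n_genes")
    if min(n_datasets, n_case, n_control) < 1 or n_genes < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(7.0, 1.0, size=n_genes)
    planted = rng.choice(n_genes, size=n_up + n_down, replace=False)
    up_idx, down_idx = planted[:n_up], planted[n_up:]
    shift = np.zeros(n_genes)
    shift[up_idx] = effect
    shift[down_idx] = -effect
    matrices = []
    for d in range(n_datasets):
        present = np.sort(rng.choice(
            n_genes, size=max(1, int(round(n_genes * (1 - missing_frac)))),
            replace=False))
        n_s = n_case + n_control
        vals = rng.normal(baseline[present, None], sigma,
                          size=(present.size, n_s))
        vals[:, :n_case] += shift[present, None]
        samples = [f"D{d}_case{j:02d}" for j in range(n_case)] + \
                  [f"D{d}_ctrl{j:02d}" for j in range(n_control)]
        groups = {s: ("case" if j < n_case else "control")
                  for j, s in enumerate(samples)}
        df = pd.DataFrame(vals, index=[genes[i] for i in present],
                          columns=samples)
        matrices.append(ExpressionMatrix(df, groups))
    truth = PlantedTruth(
        de_genes_up={genes[i]: effect for i in up_idx},
        de_genes_down={genes[i]: -effect for i in down_idx},
        params=dict(n_datasets=n_datasets, n_genes=n_genes, n_case=n_case,
                    n_control=n_control, n_up=n_up, n_down=n_down,
                    effect=effect, sigma=sigma, missing_frac=missing_frac,
                    seed=seed),
    )
    return matrices, truth


def simulate_ppi(n_background: int = 60, p_edge: float = 0.05,
                 clique_sizes: tuple[int, ...] = (6, 5),
                 seed: int = 0,
                 node_names: list[str] | None = None) -> tuple[nx.Graph, PlantedTruth]:
    """Erdos-Renyi background with planted cliques sparsely wired in.

    Planted (within-clique) edges get confidence ~ U(0.7, 1); background
    and attachment edges ~ U(0.2, 0.9).  Each clique node is attached to
    four distinct random background nodes, making the planted complexes
    both dense and central — like disease hub genes, they dominate the
    local-density centralities through the clique and the distance-based
    centralities through their background connectivity.  ``node_names``
    optionally names the nodes (cliques first, then background), letting
    the network share a gene space with the expression generator.
    """
    rng = np.random.default_rng(seed)
    n_clique = sum(clique_sizes)
    if node_names is not None and len(node_names) < n_clique + n_background:
        raise ValueError(f"need >= {n_clique + n_background} node names")
    net = nx.Graph()
    if node_names is not None:
        bg = list(node_names[n_clique:n_clique + n_background])
    else:
        bg = [f"BG{i:03d}" for i in range(n_background)]
    net.add_nodes_from(bg)
    for i in range(n_background):
        for j in range(i + 1, n_background):
            if rng.random() < p_edge:
                net.add_edge(bg[i], bg[j],
                             confidence=float(rng.uniform(0.2, 0.9)))
    clusters: list[set[str]] = []
    offset = 0
    for c, size in enumerate(clique_sizes):
        if node_names is not None:
            members = list(node_names[offset:offset + size])
            offset += size
        else:
            members = [f"CLQ{c}_{k}" for k in range(size)]
        for i in range(size):
            for j in range(i + 1, size):
                net.add_edge(members[i], members[j],
                             confidence=float(rng.uniform(0.7, 1.0)))
        n_attach = min(4, n_background)
        for v in members:
            if n_attach:
                for t in rng.choice(n_background, size=n_attach,
                                    replace=False):
                    net.add_edge(v, bg[int(t)],
                                 confidence=float(rng.uniform(0.2, 0.9)))
        clusters.append(set(members))
    truth = PlantedTruth(
        hub_nodes=set().union(*clusters) if clusters else set(),
        clusters=clusters,
        params=dict(n_background=n_background, p_edge=p_edge,
                    clique_sizes=list(clique_sizes), seed=seed),
    )
    return net, truth


def simulate_cerna_tables(n_mirnas: int = 100, n_circ: int = 20,
                          n_planted_triplets: int = 5,
                          decoy_frac: float = 0.5, seed: int = 0,
                          mrna_names: list[str] | None = None,
                          mrna_dirs: dict[str, str] | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Target tables, DE-miRNA table and circRNA links with planted axes.

    Plants ``n_planted_triplets`` miRNA-mRNA pairs (alternating mRNA
    direction, miRNA opposite) present in all three target sources, and two
    planted circRNAs linked to every planted miRNA (hence covering every
    planted mRNA).  Decoys, ``decoy_frac`` of the planted count per rule,
    each violate exactly one assembly rule: absent from one target source,
    same-direction miRNA, or a circRNA covering only a strict subset of the
    mRNAs.  Returns (targets, demis, circ, truth).

    ``mrna_names`` (with optional ``mrna_dirs``) names the planted mRNAs,
    e.g. with hub genes from the expression/network generators so the whole
    synthetic study shares one gene space.
    """
    if n_planted_triplets < 1:
        raise ValueError("need at least one planted triplet")
    rng = np.random.default_rng(seed)
    mirna_pool = [f"hsa-miR-SYN-{i:03d}" for i in range(n_mirnas)]
    circ_pool = [f"hsa_circ_SYN{i:04d}" for i in range(n_circ)]
    sources = ("targetscan", "mirdb", "mirwalk")

    target_rows: list[dict] = []
    demi_rows: dict[str, dict] = {}
    circ_rows: list[dict] = []
    dir_of_mrna: dict[str, str] = {}

    def add_pair(mi: str, g: str, dbs) -> None:
        for s in dbs:
            target_rows.append({"mirna": mi, "mrna": g, "source": s})

    def add_demi(mi: str, direction: str) -> None:
        lfc = float(rng.uniform(0.8, 2.0)) * (1 if direction == "up" else -1)
        demi_rows[mi] = {"mirna": mi, "log2fc": lfc,
                         "p": float(rng.uniform(1e-6, 0.01)),
                         "direction": direction}

    # --- planted triplets -------------------------------------------------
    planted_mis = mirna_pool[:n_planted_triplets]
    if mrna_names is not None:
        if len(mrna_names) < n_planted_triplets:
            raise ValueError(f"need >= {n_planted_triplets} mRNA names")
        planted_genes = list(mrna_names[:n_planted_triplets])
    else:
        planted_genes = [f"PGENE{i:02d}" for i in range(n_planted_triplets)]
    planted_circs = circ_pool[:2]
    for i, (mi, g) in enumerate(zip(planted_mis, planted_genes)):
        gdir = (mrna_dirs or {}).get(g, "up" if i % 2 == 0 else "down")
        dir_of_mrna[g] = gdir
        add_pair(mi, g, sources)
        add_demi(mi, "down" if gdir == "up" else "up")
        for c in planted_circs:
            circ_rows.append({"circrna": c, "mirna": mi})
    triplets = [(c, mi, g) for c in planted_circs
                for mi, g in zip(planted_mis, planted_genes)]

    # --- decoys: one rule violation each ---------------------------------
    n_decoy = max(1, int(round(decoy_frac * n_planted_triplets)))
    free_mis = mirna_pool[n_planted_triplets:]
    decoy_idx = 0

    # (a) pair missing from one target source
    for i in range(n_decoy):
        mi, g = free_mis[decoy_idx], f"DB_DECOY{i:02d}"
        decoy_idx += 1
        dir_of_mrna[g] = "up"
        add_pair(mi, g, sources[: 2])
        add_demi(mi, "down")
        circ_rows.append({"circrna": planted_circs[0], "mirna": mi})
    # (b) same-direction miRNA (fails direction validation)
    for i in range(n_decoy):
        mi, g = free_mis[decoy_idx], f"DIR_DECOY{i:02d}"
        decoy_idx += 1
        dir_of_mrna[g] = "up"
        add_pair(mi, g, sources)
        add_demi(mi, "up")
        circ_rows.append({"circrna": planted_circs[0], "mirna": mi})
    # (c) circRNA covering only a strict subset of planted mRNAs
    decoy_circs = circ_pool[2: 2 + n_decoy]
    for c in decoy_circs:
        for mi in planted_mis[: max(1, n_planted_triplets - 1)]:
            circ_rows.append({"circrna": c, "mirna": mi})

    targets = pd.DataFrame(target_rows).drop_duplicates()
    demis = pd.DataFrame(list(demi_rows.values())).set_index("mirna")
    circ = pd.DataFrame(circ_rows).drop_duplicates()
    planted_set = set(planted_genes)
    truth = PlantedTruth(
        de_genes_up={g: 1.0 for g, d in dir_of_mrna.items()
                     if d == "up" and g in planted_set},
        de_genes_down={g: -1.0 for g, d in dir_of_mrna.items()
                       if d == "down" and g in planted_set},
        cerna_triplets=triplets,
        params=dict(n_mirnas=n_mirnas, n_circ=n_circ,
                    n_planted_triplets=n_planted_triplets,
                    decoy_frac=decoy_frac, seed=seed,
                    planted_circs=planted_circs,
                    planted_mirnas=planted_mis,
                    planted_mrnas=planted_genes,
                    mrna_dirs=dir_of_mrna),
    )
    return targets, demis, circ, truth


def write_edge_list(net: nx.Graph, path) -> None:
    """Write a (protein1, protein2, combined_score) TSV on the 0-1 scale."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, data in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{a}\t{b}\t{data.get('confidence', 1.0)!r}\n")


def write_expression(m: ExpressionMatrix, expr_path, groups_path) -> None:
    """Write a matrix and its group map in the dialect the readers consume."""
    m.values.to_csv(expr_path, sep="\t", index_label="gene")
    with open(groups_path, "w") as fh:
        for s in m.sample_ids:
            fh.write(f"{s}\t{m.groups[s]}\n")


def write_synthetic_inputs(outdir, seed: int = 0, **expr_kwargs) -> dict:
    """Generate and write every pipeline input under ``outdir``.

    Returns a manifest dict (also written as ``manifest.json``) listing the
    file paths, the seed and the planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrices, expr_truth = simulate_expression_datasets(seed=seed, **expr_kwargs)
    files: dict[str, object] = {"datasets": []}
    for i, m in enumerate(matrices):
        expr, grp = outdir / f"expr_{i}.tsv", outdir / f"groups_{i}.tsv"
        write_expression(m, expr, grp)
        files["datasets"].append({"expression": str(expr), "groups": str(grp)})
    # One shared gene space: planted DE genes become the network cliques
    # (and thus the expected hubs), and a subset of the up/down clique
    # genes become the planted ceRNA mRNAs with their true directions.
    up_genes = sorted(expr_truth.de_genes_up)
    down_genes = sorted(expr_truth.de_genes_down)
    null_genes = sorted(set(f"G{i:05d}" for i in
                            range(expr_truth.params["n_genes"]))
                        - set(up_genes) - set(down_genes))
    clique_sizes = (6, 5)
    if len(up_genes) < 6 or len(down_genes) < 5:
        raise ValueError("need >= 6 planted up and >= 5 planted down genes")
    clique_genes = up_genes[:6] + down_genes[:5]
    net, ppi_truth = simulate_ppi(
        seed=seed + 1, clique_sizes=clique_sizes,
        n_background=min(60, len(null_genes)),
        node_names=clique_genes + null_genes)
    edge_path = outdir / "ppi_edges.tsv"
    write_edge_list(net, edge_path)
    files["ppi_edges"] = str(edge_path)
    cerna_mrnas = up_genes[:3] + down_genes[:2]
    targets, demis, circ, cerna_truth = simulate_cerna_tables(
        seed=seed + 2, mrna_names=cerna_mrnas,
        mrna_dirs={**{g: "up" for g in up_genes[:3]},
                   **{g: "down" for g in down_genes[:2]}})
    for name, df in (("targets", targets), ("circ", circ)):
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        files[name] = str(p)
    demi_path = outdir / "demis.tsv"
    demis.to_csv(demi_path, sep="\t")
    files["demis"] = str(demi_path)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps({
        "expression": json.loads(expr_truth.to_json()),
        "ppi": json.loads(ppi_truth.to_json()),
        "cerna": json.loads(cerna_truth.to_json()),
    }, indent=2))
    files["truth"] = str(truth_path)
    manifest = {"seed": seed, "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
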