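"""Pipeline orchestration: a validated config, staged execution, manifest.

The stages mirror the analysis workflow: per-cohort differential
expression, robust rank aggregation across cohorts, interaction-network
construction with MCODE clusters, centrality-ensemble hub genes, ceRNA
network assembly, and optional gene-set enrichment.  Every stage writes
plain TSV/JSON artifacts; the manifest records paths and content hashes so
a rerun with the same config and seed is byte-checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import cerna, diffexpr, enrich, ppi, rra
from .centrality import METHODS, aggregate_hubs, centrality_table, top_k_list
from .expression import detect_outlier_samples, ensure_log2, read_expression_table

logger = logging.getLogger(__name__)

STAGES = ("de", "rra", "network", "hubs", "cerna", "enrich")


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass
class PipelineConfig:
    """All inputs, thresholds and the seed for one pipeline run.

    ``datasets`` is a list of ``{"expression": path, "groups": path}``
    entries; the remaining inputs are single files.  Thresholds default to
    the conventional cutoffs used throughout this package.
    """

    datasets: list[dict] = field(default_factory=list)
    ppi_edges: str | None = None
    targets: str | None = None
    demis: str | None = None
    circ: str | None = None
    gene_sets: str | None = None
    outdir: str = "cernet_out"
    seed: int = 0
    lfc_cut: float = 0.5
    p_cut: float = 0.05
    rra_score_cut: float = 0.05
    hub_score_cut: float = 0.05
    min_confidence: float = 0.4
    top_k: int = 50
    outlier_k_mads: float = 3.0
    drop_outliers: bool = True
    mcode_node_score_cut: float = 0.2
    mcode_k_core: int = 2
    epc_iters: int = 1000
    epc_keep_p: float = 0.5

    _RANGES = {
        "lfc_cut": (0.0, 10.0), "p_cut": (0.0, 1.0),
        "rra_score_cut": (0.0, 1.0), "hub_score_cut": (0.0, 1.0),
        "min_confidence": (0.0, 1.0), "mcode_node_score_cut": (0.0, 1.0),
        "epc_keep_p": (0.0, 1.0),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name} = {v} outside [{lo}, {hi}]")
        if self.top_k < 1 or self.epc_iters < 1 or self.mcode_k_core < 1:
            raise ConfigError("top_k, epc_iters and mcode_k_core must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)
                 if not f.name.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", **kw)
    return path


def run(config: PipelineConfig) -> dict:
    """Execute all applicable stages in order; returns the output manifest."""
    for entry in config.datasets:
        for key in ("expression", "groups"):
            if not Path(entry[key]).exists():
                raise FileNotFoundError(entry[key])
    for path in (config.ppi_edges, config.targets, config.demis,
                 config.circ, config.gene_sets):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(path)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    artifacts: dict[str, Path] = {}
    state: dict = {}
    try:
        _stage_de(config, outdir, artifacts, state)
        _stage_rra(config, outdir, artifacts, state)
        if config.ppi_edges:
            _stage_network(config, outdir, artifacts, state)
            _stage_hubs(config, outdir, artifacts, state)
        if config.targets and config.demis and config.circ:
            _stage_cerna(config, outdir, artifacts, state)
        if config.gene_sets:
            _stage_enrich(config, outdir, artifacts, state)
    except Exception as exc:  # record partial progress before re-raising
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        for name, path in artifacts.items():
            stage = name.split("/")[0]
            manifest["stages"].setdefault(stage, {})[name.split("/", 1)[1]] = {
                "path": str(path), "sha256": _sha256(path)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_de(config, outdir, artifacts, state) -> None:
    if not config.datasets:
        return
    tables = []
    for i, entry in enumerate(config.datasets):
        m = read_expression_table(entry["expression"], entry["groups"])
        m = ensure_log2(m)
        if m.values.shape[1] >= 4:
            outliers = detect_outlier_samples(m, k_mads=config.outlier_k_mads)
            if outliers and config.drop_outliers:
                logger.info("dataset %d: dropping outlier samples %s", i, outliers)
                m = m.drop_samples(outliers)
        table = diffexpr.moderated_t_test(m)
        up, down = diffexpr.filter_degs(table, lfc=config.lfc_cut,
                                        alpha=config.p_cut)
        table["direction"] = "ns"
        table.loc[up, "direction"] = "up"
        table.loc[down, "direction"] = "down"
        path = _write(table, outdir / f"de_{i}.tsv")
        artifacts[f"de/dataset_{i}"] = path
        tables.append({"table": table, "up": up, "down": down,
                       "universe": len(table)})
    state["de"] = tables


def _stage_rra(config, outdir, artifacts, state) -> None:
    if "de" not in state:
        return
    de = state["de"]
    lfc = pd.DataFrame({i: d["table"]["log2fc"] for i, d in enumerate(de)})
    results = {}
    for direction in ("up", "down"):
        lists = [d[direction] for d in de]
        universes = [d["universe"] for d in de]
        results[direction] = rra.aggregate(lists, universes, lfc)
        artifacts[f"rra/{direction}"] = _write(
            results[direction], outdir / f"rra_{direction}.tsv")
    robust = rra.select_robust(results["up"], results["down"],
                               score_cut=config.rra_score_cut,
                               lfc_cut=config.lfc_cut)
    artifacts["rra/robust"] = _write(robust, outdir / "robust_degs.tsv")
    state["robust"] = robust
    state["universe_genes"] = sorted(set().union(
        *[set(d["table"].index) for d in de]))


def _stage_network(config, outdir, artifacts, state) -> None:
    net = ppi.load_edge_list(config.ppi_edges, min_conf=config.min_confidence)
    genes = set(state["robust"].index) if "robust" in state else set(net.nodes)
    sub = ppi.induce_on_genes(net, genes)
    if "robust" in state:
        nx.set_node_attributes(
            sub, state["robust"]["direction"].to_dict(), "direction")
    artifacts["network/edges"] = _write(
        nx.to_pandas_edgelist(sub), outdir / "network_edges.tsv", index=False)
    (outdir / "network.json").write_text(
        json.dumps(nx.node_link_data(sub, edges="links"), indent=2))
    artifacts["network/json"] = outdir / "network.json"
    clusters = ppi.mcode_find_clusters(
        sub, node_score_cut=config.mcode_node_score_cut,
        k_core=config.mcode_k_core)
    (outdir / "clusters.json").write_text(json.dumps(
        [{"nodes": sorted(map(str, c.nodes)), "seed": str(c.seed),
          "score": c.score} for c in clusters], indent=2))
    artifacts["network/clusters"] = outdir / "clusters.json"
    state["network"] = sub


def _stage_hubs(config, outdir, artifacts, state) -> None:
    net = state.get("network")
    if net is None or net.number_of_nodes() == 0:
        logger.warning("empty network; skipping hub stage")
        return
    table = centrality_table(
        net, seed=config.seed + 10, epc_iters=config.epc_iters,
        epc_keep_p=config.epc_keep_p)
    artifacts["hubs/centrality"] = _write(table, outdir / "centrality.tsv",
                                          index_label="node")
    lists = [top_k_list(table[m].to_dict(), k=config.top_k)
             for m in METHODS]
    hubs = aggregate_hubs(lists, net.number_of_nodes(),
                          score_cut=config.hub_score_cut)
    artifacts["hubs/hubs"] = _write(hubs, outdir / "hubs.tsv")
    state["hubs"] = hubs


def _stage_cerna(config, outdir, artifacts, state) -> None:
    targets = cerna.load_target_table(config.targets)
    demis = pd.read_csv(config.demis, sep="\t", index_col=0)
    circ = pd.read_csv(config.circ, sep="\t", dtype=str)
    if "hubs" in state and "robust" in state and len(state["hubs"]):
        hub_genes = set(state["hubs"].index)
        dirs = state["robust"]["direction"].reindex(
            sorted(hub_genes)).dropna().to_dict()
        targets = targets[targets["mrna"].isin(dirs)]
    else:
        # standalone mode: directions must come from the DE-miRNA-style
        # table of mRNA directions embedded in the target table
        if "direction" not in targets.columns:
            raise ConfigError("cerna stage without hub stage needs a "
                              "'direction' column in the target table")
        dirs = dict(zip(targets["mrna"], targets["direction"].str.lower()))
    pairs = cerna.intersect_three_dbs(targets)
    validated = cerna.validate_directions(pairs, demis, dirs)
    kept, candidates, dropped = cerna.attach_circrnas(validated, circ)
    retained = cerna.coverage_filter(candidates, kept, validated, circ)
    mi_dirs = {str(i): str(d).lower() for i, d in demis["direction"].items()}
    net = cerna.build_network(retained, kept, validated, circ,
                              dirs={**dirs, **mi_dirs})
    (outdir / "cerna_network.json").write_text(
        json.dumps(nx.node_link_data(net, edges="links"), indent=2))
    artifacts["cerna/network"] = outdir / "cerna_network.json"
    top = cerna.rank_cerna_mcc(net, top=10)
    summary = pd.DataFrame({
        "top_mcc": pd.Series(top, dtype=str),
    })
    artifacts["cerna/top"] = _write(summary, outdir / "cerna_top.tsv",
                                    index=False)
    artifacts["cerna/dropped"] = _write(
        pd.DataFrame({"dropped_mrna": sorted(dropped)}),
        outdir / "cerna_dropped.tsv", index=False)
    state["cerna"] = net


def _stage_enrich(config, outdir, artifacts, state) -> None:
    sets = enrich.read_gmt(config.gene_sets)
    universe = set(state.get("universe_genes", []))
    query = set(state["robust"].index) if "robust" in state else set()
    if not query or not universe:
        logger.warning("no robust DEGs or universe; skipping enrichment")
        return
    table = enrich.ora(query, sets, universe, alpha=config.p_cut)
    artifacts["enrich/ora"] = _write(table, outdir / "enrichment.tsv",
                                     index=False)
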