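"""End-to-end orchestration: mapping -> enrichment -> network -> selection -> overlays.

The run mirrors the study cascade: a raw identifier list is mapped to a
deduplicated query, pathways are ranked by over-representation, proteins
of the top pathways form the network universe, a confidence-thresholded
interaction graph yields degree/betweenness, the dual above-mean rule
selects key proteins, and regulator/drug layers are projected onto them.
Every intermediate table is materialized in the output directory and the
stage counts are collected in a JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import DomainError, KeynetError
from .id_mapping import map_identifiers, read_gene_list, read_mapping_table, write_unmapped
from .enrichment import (
    enrich,
    pathway_protein_union,
    read_background,
    read_gmt,
    top_pathways,
    write_enrichment,
)
from .keynode import KeyNodeResult, SelectionThresholds, compute_thresholds, select_key_nodes
from .network import (
    build_graph,
    centrality_table,
    graph_to_graphml,
    read_centrality_table,
    read_edge_table,
    write_centrality_table,
    write_sif,
)
from .overlays import (
    combine_layers,
    export_multilayer,
    overlay_drugs,
    overlay_regulators,
    read_drug_table,
    read_regulator_tables,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = f"keynet-report/{__version__}"


@dataclass
class RunConfig:
    gene_list: str
    mapping_table: str
    gmt: str
    edge_table: str
    out_dir: str
    background: str | None = None
    mirna_targets: str | None = None
    dysregulation: str | None = None
    lncrna_targets: str | None = None
    drug_table: str | None = None
    gene_list_dialect: str = "plain"
    edge_dialect: str = "string_export"
    min_score: float = 0.7
    top_k_pathways: int = 10
    enrichment_p_cutoff: float = 0.05
    require_dysregulation: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_score <= 1.0):
            raise DomainError(f"min_score {self.min_score} outside [0,1]")
        if self.top_k_pathways < 1:
            raise DomainError("top_k_pathways must be >= 1")


def _stage(name: str):
    """Re-raise any stage failure with the stage name attached."""

    class _StageContext:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            self.elapsed = time.perf_counter() - self.t0
            if exc is not None:
                raise KeynetError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _StageContext()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema": REPORT_SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
        "timings_s": {},
    }
    timings = report["timings_s"]

    with _stage("mapping") as ctx:
        raw_ids = read_gene_list(config.gene_list, dialect=config.gene_list_dialect)
        mapping = read_mapping_table(config.mapping_table)
        query, unmapped = map_identifiers(raw_ids, mapping)
        query.write_tsv(out / "query_gene_set.tsv")
        write_unmapped(unmapped, out / "unmapped.txt")
    timings["mapping"] = ctx.elapsed
    report["n_query"] = len(raw_ids)
    report["n_mapped"] = len(query)
    report["n_unmapped"] = len(unmapped)

    with _stage("enrichment") as ctx:
        background = read_background(config.background) if config.background else None
        collection = read_gmt(config.gmt, background=background)
        rows = enrich(query, collection)
        write_enrichment(rows, out / "enrichment.tsv")
        top = top_pathways(rows, config.top_k_pathways)
        union = pathway_protein_union(top, collection, query)
        union.write_tsv(out / "union_proteins.tsv")
    timings["enrichment"] = ctx.elapsed
    report["n_pathways_tested"] = len(rows)
    report["n_top_pathways"] = len(top)
    report["n_significant_pathways"] = sum(
        1 for r in rows if r.p_value < config.enrichment_p_cutoff
    )
    report["n_union_proteins"] = len(union)

    with _stage("network") as ctx:
        edges = read_edge_table(config.edge_table, dialect=config.edge_dialect)
        graph = build_graph(edges, union, min_score=config.min_score)
        table = centrality_table(graph)
        write_centrality_table(table, out / "centrality.tsv")
        write_sif(graph, out / "network.sif")
        graph_to_graphml(graph, out / "network.graphml")
    timings["network"] = ctx.elapsed
    connected = {v for pair in graph.edges for v in pair}
    report["n_nodes_connected"] = len(connected)
    report["n_edges"] = graph.n_edges

    with _stage("selection") as ctx:
        thresholds = compute_thresholds(table)
        key = select_key_nodes(table, thresholds)
        key.write(out / "key_nodes.tsv", out / "key_nodes.json")
    timings["selection"] = ctx.elapsed
    report["mean_degree"] = thresholds.mean_degree
    report["mean_betweenness"] = thresholds.mean_betweenness
    report["universe_size"] = thresholds.universe_size
    report["n_key_proteins"] = len(key.selected)

    overlay_inputs = (
        config.mirna_targets,
        config.dysregulation,
        config.lncrna_targets,
        config.drug_table,
    )
    if all(p is not None for p in overlay_inputs) and key.selected:
        with _stage("overlays") as ctx:
            regulators = read_regulator_tables(
                config.mirna_targets, config.dysregulation, config.lncrna_targets
            )
            drugs = read_drug_table(config.drug_table)
            reg_net = overlay_regulators(
                key, regulators, require_dysregulation=config.require_dysregulation
            )
            drug_net = overlay_drugs(key, drugs)
            net = combine_layers(reg_net, drug_net)
            export_multilayer(net, out)
        timings["overlays"] = ctx.elapsed
        report.update(net.summary)
    elif not key.selected:
        logger.warning("empty key-protein set; overlay stages skipped")

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
    return report


def selection_only(
    centrality_table_path: str | Path,
    thresholds: tuple[float, float] | None = None,
) -> KeyNodeResult:
    """Run only the key-node selection on an externally produced table.

    When ``thresholds`` is omitted the degree/betweenness means are
    computed from the table itself; otherwise the given (mean_degree,
    mean_betweenness) pair is applied as-is.
    """
    table = read_centrality_table(centrality_table_path)
    if not table:
        raise DomainError(f"empty centrality table: {centrality_table_path}")
    if thresholds is None:
        sel = compute_thresholds(table)
    else:
        sel = SelectionThresholds(
            mean_degree=thresholds[0],
            mean_betweenness=thresholds[1],
            universe_size=len(table),
        )
    return select_key_nodes(table, sel)
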