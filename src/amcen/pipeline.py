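"""End-to-end orchestration: screens -> integration -> ceRNA -> topology.

The full run mirrors the study design: expression and methylation screens
with |t| > 2 and p < 0.05, intersection into hyper_low / hypo_high aberrant
classes, two fully separate ceRNA inference runs (one per class, each with
its own miRNA universe), curated-miRNA restriction, network assembly with
degree/betweenness, optional PPI hub matching into a biomarker report, and
optional over-representation analysis of the aberrant classes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import cerna, enrichment, integration, network
from .differential import classify_differential, two_group_t, write_records_tsv
from .interactions import read_interactions_tsv
from .matrix import read_matrix_tsv

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    expression: str
    methylation: str
    lnc_expression: str
    groups: str
    mrna_mirna: str
    mirna_lncrna: str
    curated_mirnas: str | None = None
    ppi: str | None = None
    gmt: str | None = None
    outdir: str = "amcen_out"
    p_threshold: float = 0.05
    t_threshold: float = 2.0
    t_method: str = "student"
    hypergeom_p: float = 0.05
    tail: str = "ge"
    pcc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    hub_degree: int = 10
    enrich_p: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "hypergeom_p", "fdr_threshold", "enrich_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.t_threshold <= 0 or not -1.0 <= self.pcc_threshold <= 1.0:
            raise ValueError("invalid t/pcc threshold")
        if self.hub_degree < 0:
            raise ValueError("hub_degree must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def require_inputs(self) -> None:
        for name in ("expression", "methylation", "lnc_expression", "groups",
                     "mrna_mirna", "mirna_lncrna", "curated_mirnas", "ppi", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; writes all stage outputs under
    config.outdir and returns the machine-readable summary dict."""
    config.require_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    state = {"stage": "setup"}

    def _stage(name: str) -> float:
        state["stage"] = name
        log.info("stage %s", name)
        return time.perf_counter()

    def finish(name: str, t0: float) -> None:
        summary["stages"][name] = round(time.perf_counter() - t0, 3)

    try:
        t0 = _stage("differential_screen")
        expr = read_matrix_tsv(config.expression, config.groups)
        meth = read_matrix_tsv(config.methylation, config.groups)
        expr_calls = classify_differential(
            two_group_t(expr, method=config.t_method),
            config.p_threshold, config.t_threshold, mode="expression")
        meth_calls = classify_differential(
            two_group_t(meth, method=config.t_method),
            config.p_threshold, config.t_threshold, mode="methylation")
        write_records_tsv(expr_calls, outdir / "expression_differential.tsv")
        write_records_tsv(meth_calls, outdir / "methylation_differential.tsv")
        summary["degs_up"] = sum(r.direction == "up" for r in expr_calls)
        summary["degs_down"] = sum(r.direction == "down" for r in expr_calls)
        summary["dmgs_hyper"] = sum(r.direction == "hyper" for r in meth_calls)
        summary["dmgs_hypo"] = sum(r.direction == "hypo" for r in meth_calls)
        finish("differential_screen", t0)

        t0 = _stage("integration")
        aberrant = integration.intersect_aberrant(expr_calls, meth_calls)
        integration.write_aberrant_sets(aberrant, outdir)
        summary["hyper_low"] = len(aberrant.hyper_low)
        summary["hypo_high"] = len(aberrant.hypo_high)
        finish("integration", t0)

        t0 = _stage("cerna_inference")
        mrna_mirna = read_interactions_tsv(config.mrna_mirna, "mrna-mirna")
        mirna_lncrna = read_interactions_tsv(config.mirna_lncrna, "mirna-lncrna")
        lnc_expr = read_matrix_tsv(config.lnc_expression, config.groups)
        all_triples: list[cerna.CeRNATriple] = []
        for cls_name, genes in (("hyper_low", aberrant.hyper_low),
                                ("hypo_high", aberrant.hypo_high)):
            sub = cerna.match_dmg_mirna(set(genes), mrna_mirna)
            pairs = cerna.enumerate_pairs(sub, mirna_lncrna, tail=config.tail)
            pairs = [p for p in pairs if p.p_hyper < config.hypergeom_p]
            pairs = cerna.coexpression_filter(
                pairs, expr, lnc_expr,
                pcc_threshold=config.pcc_threshold,
                fdr_threshold=config.fdr_threshold)
            triples = cerna.expand_triples(pairs)
            cerna.write_pairs_tsv(pairs, outdir / f"{cls_name}_pairs.tsv")
            cerna.write_triples(triples, outdir / f"{cls_name}_triples.tsv",
                                outdir / f"{cls_name}_triples.json")
            summary[f"{cls_name}_universe_N"] = len(sub.targets())
            summary[f"{cls_name}_pairs"] = len(pairs)
            summary[f"{cls_name}_triples"] = len(triples)
            all_triples.extend(triples)
        finish("cerna_inference", t0)

        if config.curated_mirnas:
            t0 = _stage("curated_restriction")
            curated = [ln.strip() for ln in
                       Path(config.curated_mirnas).read_text().splitlines() if ln.strip()]
            all_triples = cerna.restrict_to_curated(all_triples, curated)
            finish("curated_restriction", t0)
        summary["triples_total"] = len(all_triples)
        cerna.write_triples(all_triples, outdir / "triples.tsv", outdir / "triples.json")

        t0 = _stage("network_topology")
        report = {"critical_genes": [], "rows": [], "ranked_lncrnas": [], "ties": []}
        if all_triples:
            net = network.build_network(all_triples)
            metrics = network.degree_and_betweenness(net)
            network.write_sif(net, outdir / "amcen.sif")
            network.write_graphml(net, outdir / "amcen.graphml")
            network.write_metrics_tsv(metrics, outdir / "node_metrics.tsv")
            summary["nodes_mrna"] = len(net.nodes_of_type("mrna"))
            summary["nodes_mirna"] = len(net.nodes_of_type("mirna"))
            summary["nodes_lncrna"] = len(net.nodes_of_type("lncrna"))
            summary["edges"] = net.n_edges
            if config.ppi:
                ppi = read_interactions_tsv(config.ppi, "ppi")
                hubs = network.select_hubs(ppi, config.hub_degree)
                summary["hubs"] = len(hubs)
                report = network.biomarker_candidates(hubs, net, metrics)
                network.write_biomarker_report(report, outdir / "biomarkers.tsv",
                                               outdir / "biomarkers.json")
        else:
            log.warning("no triples survived; network stage skipped")
            summary.update({"nodes_mrna": 0, "nodes_mirna": 0,
                            "nodes_lncrna": 0, "edges": 0})
        summary["critical_genes"] = report["critical_genes"]
        summary["top_lncrnas"] = report["ranked_lncrnas"][:10]
        finish("network_topology", t0)

        if config.gmt:
            t0 = _stage("enrichment")
            collection = enrichment.read_gmt(config.gmt)
            expr_genes = {r.feature_id for r in expr_calls}
            for cls_name, genes in (("hyper_low", aberrant.hyper_low),
                                    ("hypo_high", aberrant.hypo_high)):
                table = enrichment.ora(set(genes) & expr_genes, expr_genes,
                                       collection, p_threshold=config.enrich_p)
                enrichment.write_enrichment_tsv(
                    table, outdir / f"{cls_name}_enrichment.tsv")
                summary[f"{cls_name}_enriched_terms"] = len(table)
            finish("enrichment", t0)
    except Exception as err:
        raise RuntimeError(
            f"pipeline aborted in stage {state['stage']!r} "
            f"(partial outputs under {outdir}): {err}") from err

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
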