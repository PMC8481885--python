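"""Tripartite ceRNA network assembly, topology, and biomarker ranking.

The aberrantly-methylated ceRNA network is a tripartite graph: mRNA and
lncRNA nodes connect only through miRNA nodes (each triple contributes an
mRNA-miRNA and a miRNA-lncRNA edge). Candidate biomarkers are the hub
genes of a user-supplied PPI network that also appear as mRNA nodes here,
together with their partner lncRNAs ranked by network degree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .cerna import CeRNATriple
from .interactions import InteractionTable

log = logging.getLogger(__name__)

NODE_TYPES = ("mrna", "mirna", "lncrna")
# edges may only join adjacent layers
_ALLOWED = {frozenset(("mrna", "mirna")), frozenset(("mirna", "lncrna"))}


@dataclass(frozen=True)
class NodeMetrics:
    node: str
    type: str
    degree: int
    betweenness: float


class TripartiteNetwork:
    """Undirected typed graph over mRNA/miRNA/lncRNA nodes.

    Wraps a networkx.Graph; the constructor enforces that every edge joins
    an mRNA to a miRNA or a miRNA to an lncRNA, so mRNA-lncRNA shortcuts,
    same-type edges, and triangles are impossible.
    """

    def __init__(self, graph: nx.Graph):
        for v, data in graph.nodes(data=True):
            if data.get("type") not in NODE_TYPES:
                raise ValueError(f"node {v!r} missing a valid type attribute")
        for u, v in graph.edges():
            kinds = frozenset((graph.nodes[u]["type"], graph.nodes[v]["type"]))
            if kinds not in _ALLOWED:
                raise ValueError(
                    f"edge ({u}, {v}) joins types {sorted(kinds)}; only "
                    "mrna-mirna and mirna-lncrna edges are allowed")
        self.graph = graph

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(v for v, d in self.graph.nodes(data=True) if d["type"] == node_type)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(triples: list[CeRNATriple]) -> TripartiteNetwork:
    """Assemble the network from triples; duplicate edges collapse. An ID
    appearing in two molecular roles is a hard error."""
    roles: dict[str, str] = {}
    g = nx.Graph()
    for t in triples:
        for node, role in ((t.mrna, "mrna"), (t.mirna, "mirna"), (t.lncrna, "lncrna")):
            prev = roles.get(node)
            if prev is not None and prev != role:
                raise ValueError(f"ID {node!r} appears as both {prev} and {role}")
            roles[node] = role
            g.add_node(node, type=role)
        g.add_edge(t.mrna, t.mirna)
        g.add_edge(t.mirna, t.lncrna)
    return TripartiteNetwork(g)


def degree_and_betweenness(net: TripartiteNetwork) -> list[NodeMetrics]:
    """Per-node degree and unnormalized betweenness (sum over unordered
    source/target pairs of the fraction of shortest paths through the node;
    unweighted, undirected; disconnected pairs contribute 0)."""
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    bc = nx.betweenness_centrality(net.graph, normalized=False)
    return [NodeMetrics(node=v, type=net.graph.nodes[v]["type"],
                        degree=net.graph.degree[v], betweenness=float(bc[v]))
            for v in sorted(net.graph.nodes())]


def select_hubs(ppi_edges: InteractionTable, degree_threshold: int = 10) -> list[str]:
    """Genes with PPI degree strictly above the threshold, ranked by degree
    descending, ties broken lexicographically."""
    if ppi_edges.kind != "ppi":
        raise ValueError(f"expected a ppi table, got {ppi_edges.kind!r}")
    g = nx.Graph()
    g.add_edges_from(ppi_edges.edges)
    hubs = [(d, v) for v, d in g.degree() if d > degree_threshold]
    return [v for d, v in sorted(hubs, key=lambda dv: (-dv[0], dv[1]))]


def biomarker_candidates(hubs: list[str], net: TripartiteNetwork,
                         metrics: list[NodeMetrics]) -> dict:
    """Match PPI hub genes against the ceRNA network and rank lncRNAs.

    Returns a report with (i) ``critical_genes``: hubs present as mRNA
    nodes; (ii) ``rows``: one (gene, miRNA, lncRNA) row per triple path
    from a critical gene through a shared miRNA to a partner lncRNA; and
    (iii) ``ranked_lncrnas``: partner lncRNAs ordered by network degree,
    then betweenness, then name, with ties flagged.
    """
    mdict = {m.node: m for m in metrics}
    mrnas = set(net.nodes_of_type("mrna"))
    critical = [h for h in hubs if h in mrnas]
    if not critical:
        log.warning("no hub gene present in the ceRNA network; empty report")
        return {"critical_genes": [], "rows": [], "ranked_lncrnas": [], "ties": []}
    rows = []
    partner_lncs: set[str] = set()
    for gene in critical:
        for mirna in sorted(net.graph.neighbors(gene)):
            for lnc in sorted(net.graph.neighbors(mirna)):
                if net.graph.nodes[lnc]["type"] != "lncrna":
                    continue
                rows.append({"gene": gene, "mirna": mirna, "lncrna": lnc})
                partner_lncs.add(lnc)
    ranked = sorted(partner_lncs,
                    key=lambda v: (-mdict[v].degree, -mdict[v].betweenness, v))
    keyed = {v: (mdict[v].degree, mdict[v].betweenness) for v in ranked}
    ties = sorted({v for v in ranked
                   if sum(1 for u in ranked if keyed[u] == keyed[v]) > 1})
    return {"critical_genes": critical, "rows": rows,
            "ranked_lncrnas": ranked, "ties": ties}


# ---------------------------------------------------------------------------
# persistence

def write_sif(net: TripartiteNetwork, path: str | Path) -> None:
    lines = [f"{u}\tinteracts\t{v}" for u, v in sorted(net.graph.edges())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(net: TripartiteNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_metrics_tsv(metrics: list[NodeMetrics], path: str | Path) -> None:
    pd.DataFrame([(m.node, m.type, m.degree, m.betweenness) for m in metrics],
                 columns=["node", "type", "degree", "betweenness"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_biomarker_report(report: dict, tsv_path: str | Path,
                           json_path: str | Path | None = None) -> None:
    pd.DataFrame(report["rows"], columns=["gene", "mirna", "lncrna"]
                 ).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report, indent=2) + "\n")
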