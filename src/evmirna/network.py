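"""Thresholded tripartite miRNA–gene–pathway network construction.

Nodes enter by strict statistical thresholds: miRNAs with nominal
p < 0.05, pathways with permutation FDR q < 0.2, and genes that are both
validated targets of an included miRNA and leading-edge members of an
included pathway (an independent conjunction — the target and the
leading edge need not come from the same miRNA/pathway pair).  Edges are
typed: miRNA—gene "targets", gene—pathway "leading_edge_member".
Rendering (the published view used a Kamada-Kawai layout) is
presentation, not part of the contract; exports are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .gsea import EnrichmentResult
from .targets import TargetMap, normalize_mirna_id

logger = logging.getLogger(__name__)

__all__ = [
    "TripartiteNetwork",
    "build_network",
    "degree_summary",
    "export_network",
    "import_network",
]

NODE_KINDS = ("mirna", "gene", "pathway")


@dataclass
class TripartiteNetwork:
    """A typed tripartite graph plus the thresholds that built it."""

    graph: nx.Graph
    mirna_p_threshold: float
    pathway_q_threshold: float

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind
        )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        g = self.graph
        for node, data in g.nodes(data=True):
            if data.get("kind") not in NODE_KINDS:
                raise ValueError(f"node {node!r} has unknown kind {data.get('kind')!r}")
            if data["kind"] == "gene":
                kinds = {g.nodes[nb]["kind"] for nb in g.neighbors(node)}
                if not {"mirna", "pathway"} <= kinds:
                    raise ValueError(
                        f"gene {node!r} lacks a miRNA or pathway neighbour"
                    )
        for u, v, data in g.edges(data=True):
            pair = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
            if data.get("etype") == "targets" and pair != {"mirna", "gene"}:
                raise ValueError(f"bad 'targets' edge {u!r}-{v!r}")
            if data.get("etype") == "leading_edge_member" and pair != {"gene", "pathway"}:
                raise ValueError(f"bad 'leading_edge_member' edge {u!r}-{v!r}")


def build_network(
    de: pd.DataFrame,
    targets: TargetMap,
    enrich: list[EnrichmentResult],
    mirna_p: float = 0.05,
    pathway_q: float = 0.2,
) -> TripartiteNetwork:
    """Assemble the tripartite network under strict inclusion thresholds.

    An empty network is a legal outcome (logged), e.g. when no miRNA
    clears the nominal-p bar.
    """
    g = nx.Graph()

    included_mirnas: dict[str, str] = {}  # canonical key -> de row label
    for label, row in de.iterrows():
        p = row["p_value"]
        if pd.notna(p) and p < mirna_p:
            key = normalize_mirna_id(str(label)).key
            included_mirnas[key] = label
            g.add_node(
                key, kind="mirna", log2fc=float(row["log2fc"]), p=float(p),
                display=normalize_mirna_id(str(label)).display,
            )

    included_pathways: dict[str, EnrichmentResult] = {}
    for r in enrich:
        if np.isfinite(r.q_fdr) and r.q_fdr < pathway_q:
            included_pathways[r.set_name] = r
            g.add_node(r.set_name, kind="pathway", nes=float(r.nes), q=float(r.q_fdr))

    target_union: dict[str, set[str]] = {}
    for key in included_mirnas:
        for gene in targets.targets_of(key):
            target_union.setdefault(gene, set()).add(key)
    leading_union: dict[str, set[str]] = {}
    for name, r in included_pathways.items():
        for gene in r.leading_edge:
            leading_union.setdefault(gene, set()).add(name)

    genes = sorted(set(target_union) & set(leading_union))
    for gene in genes:
        g.add_node(gene, kind="gene")
        for key in sorted(target_union[gene]):
            g.add_edge(key, gene, etype="targets")
        for name in sorted(leading_union[gene]):
            g.add_edge(gene, name, etype="leading_edge_member")

    # prune included miRNAs/pathways with no qualifying gene? No: they met
    # their own thresholds and remain as isolated nodes only if they have
    # neither targets nor leading-edge genes in the intersection. The
    # published construction draws only connected entities, so drop them.
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    if isolated:
        logger.info("dropped %d isolated nodes from the network", len(isolated))
    if g.number_of_nodes() == 0:
        logger.info("network is empty under p<%s, q<%s", mirna_p, pathway_q)

    net = TripartiteNetwork(
        graph=g, mirna_p_threshold=mirna_p, pathway_q_threshold=pathway_q
    )
    net.validate()
    return net


def degree_summary(net: TripartiteNetwork) -> pd.DataFrame:
    """Per-miRNA count of incident target-gene edges, descending."""
    rows = []
    for m in net.nodes_of_kind("mirna"):
        count = sum(
            1 for _, _, d in net.graph.edges(m, data=True) if d["etype"] == "targets"
        )
        rows.append((m, count))
    frame = pd.DataFrame(rows, columns=["mirna", "n_target_genes"])
    return frame.sort_values(
        by=["n_target_genes", "mirna"], ascending=[False, True]
    ).reset_index(drop=True)


def _sorted_copy(net: TripartiteNetwork) -> nx.Graph:
    """Rebuild the graph with nodes/edges in (kind, label) order so exports
    are byte-stable."""
    g = nx.Graph()
    order = {k: i for i, k in enumerate(NODE_KINDS)}
    nodes = sorted(
        net.graph.nodes(data=True), key=lambda nd: (order[nd[1]["kind"]], nd[0])
    )
    for n, d in nodes:
        g.add_node(n, **d)
    edges = sorted(
        net.graph.edges(data=True), key=lambda e: tuple(sorted((e[0], e[1])))
    )
    for u, v, d in edges:
        g.add_edge(*sorted((u, v)), **d)
    return g


def export_network(
    net: TripartiteNetwork, path: str | Path, format: str = "graphml"
) -> Path:
    """Write the network as GraphML (with node attributes) or an edge TSV."""
    path = Path(path)
    g = _sorted_copy(net)
    if format == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif format == "edge_tsv":
        rows = [(u, d["etype"], v) for u, v, d in g.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "type", "target"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def import_network(path: str | Path) -> TripartiteNetwork:
    """Read a GraphML export back into a TripartiteNetwork (round-trip)."""
    g = nx.read_graphml(Path(path))
    clean = nx.Graph()
    for n, d in g.nodes(data=True):
        clean.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        clean.add_edge(u, v, **d)
    net = TripartiteNetwork(
        graph=clean, mirna_p_threshold=float("nan"), pathway_q_threshold=float("nan")
    )
    net.validate()
    return net
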