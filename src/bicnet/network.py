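"""Gene set networks from overlapping biclusters.

Every gene occurring in at least one bicluster carries a *membership
signature*: the exact set of biclusters containing it.  Genes with identical
signatures form one node (so nodes partition the biclustered genes), and two
nodes are joined by an edge weighted by the number of biclusters they share:
``weight(u, v) = |signature(u) & signature(v)|``.  Consequently the nodes of
any single bicluster induce a clique.  A node is annotated with the union of
its signature biclusters' condition sets.

Gene set networks are compact: there are never more nodes than genes, and
usually far fewer, which is the point of summarizing biclusters this way.

Node identifiers are assigned by sorting signatures (as tuples of bicluster
indices), so outputs are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "GeneSetNode",
    "GeneSetNetwork",
    "build_network",
    "filter_by_edge_weight",
    "node_stats",
    "extract_hub_subnetwork",
    "write_graphml",
    "write_network_tables",
]


@dataclass(frozen=True)
class GeneSetNode:
    node_id: int
    genes: frozenset
    signature: frozenset  # bicluster indices (into the input sequence)
    conditions: frozenset

    def sorted_genes(self) -> list:
        return sorted(self.genes)


@dataclass
class GeneSetNetwork:
    """One connected component: nodes plus a weighted networkx graph."""

    nodes: dict  # node_id -> GeneSetNode
    graph: nx.Graph  # nodes are node_ids; edges carry 'weight'

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def is_singleton(self) -> bool:
        return self.n_nodes == 1

    def node_by_signature(self, signature) -> GeneSetNode:
        signature = frozenset(signature)
        for node in self.nodes.values():
            if node.signature == signature:
                return node
        raise KeyError(f"no node with signature {sorted(signature)}")

    def genes(self) -> list:
        out = set()
        for node in self.nodes.values():
            out |= node.genes
        return sorted(out)


def build_network(biclusters) -> list:
    """Decompose biclustered genes into signature nodes and connect them.

    Returns the connected components as separate networks, largest (by node
    count, then gene count) first.  Bicluster indices in signatures refer to
    positions in the input sequence.
    """
    biclusters = list(biclusters)
    if not biclusters:
        return []
    signature_of: dict = {}
    for idx, b in enumerate(biclusters):
        for g in b.genes:
            signature_of.setdefault(g, set()).add(idx)
    by_signature: dict = {}
    for g, sig in signature_of.items():
        by_signature.setdefault(frozenset(sig), set()).add(g)

    nodes: dict = {}
    for node_id, sig in enumerate(sorted(by_signature, key=lambda s: tuple(sorted(s)))):
        conditions = frozenset()
        for idx in sig:
            conditions |= biclusters[idx].conditions
        nodes[node_id] = GeneSetNode(
            node_id=node_id,
            genes=frozenset(by_signature[sig]),
            signature=sig,
            conditions=conditions,
        )

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    ids = sorted(nodes)
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            w = len(nodes[u].signature & nodes[v].signature)
            if w >= 1:
                graph.add_edge(u, v, weight=w)

    return _components(nodes, graph)


def _components(nodes: dict, graph: nx.Graph) -> list:
    comps = []
    for comp in nx.connected_components(graph):
        comp_ids = sorted(comp)
        sub = graph.subgraph(comp_ids).copy()
        comp_nodes = {i: nodes[i] for i in comp_ids}
        comps.append(GeneSetNetwork(nodes=comp_nodes, graph=sub))
    comps.sort(
        key=lambda net: (
            -net.n_nodes,
            -len(net.genes()),
            min(net.nodes),
        )
    )
    return comps


def filter_by_edge_weight(net: GeneSetNetwork, min_weight: int) -> list:
    """Drop edges below ``min_weight`` and isolated nodes; return the
    surviving connected components."""
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    graph = net.graph.copy()
    light = [(u, v) for u, v, w in graph.edges(data="weight") if w < min_weight]
    graph.remove_edges_from(light)
    graph.remove_nodes_from(list(nx.isolates(graph)))
    nodes = {i: net.nodes[i] for i in graph.nodes}
    return _components(nodes, graph)


def node_stats(net: GeneSetNetwork) -> pd.DataFrame:
    """Per-node degree, weighted degree and gene count, degree-descending."""
    rows = []
    for i in sorted(net.nodes):
        deg = net.graph.degree(i)
        wdeg = sum(w for _, _, w in net.graph.edges(i, data="weight"))
        rows.append({
            "node_id": i,
            "degree": int(deg),
            "weighted_degree": int(wdeg),
            "n_genes": len(net.nodes[i].genes),
        })
    df = pd.DataFrame(rows, columns=["node_id", "degree", "weighted_degree", "n_genes"])
    return df.sort_values(
        ["degree", "node_id"], ascending=[False, True], ignore_index=True
    )


def extract_hub_subnetwork(net: GeneSetNetwork, min_weight: int = 2):
    """The maximum-degree node, its heavy-edge neighbourhood and gene list.

    Ties on degree break to the node with the lexicographically smallest
    signature (= smallest node id).  Neighbours are those adjacent to the hub
    through edges of weight >= ``min_weight``.  The gene list (hub plus
    neighbours, sorted) is what one pastes into an external GO-enrichment
    tool.
    """
    if not net.nodes:
        raise ValueError("empty network")
    hub_id = min(sorted(net.nodes), key=lambda i: (-net.graph.degree(i), i))
    neighbors = sorted(
        v
        for v in net.graph.neighbors(hub_id)
        if net.graph.edges[hub_id, v]["weight"] >= min_weight
    )
    genes = set(net.nodes[hub_id].genes)
    for v in neighbors:
        genes |= net.nodes[v].genes
    return net.nodes[hub_id], [net.nodes[v] for v in neighbors], sorted(genes)


def write_graphml(networks, path) -> None:
    """All components in one GraphML file (attributes flattened to text)."""
    merged = nx.Graph()
    for net in networks:
        for i in sorted(net.nodes):
            node = net.nodes[i]
            merged.add_node(
                i,
                genes=",".join(node.sorted_genes()),
                n_genes=len(node.genes),
                signature=",".join(str(s) for s in sorted(node.signature)),
                conditions=",".join(sorted(node.conditions)),
                connected=not net.is_singleton,
            )
        for u, v, w in net.graph.edges(data="weight"):
            merged.add_edge(u, v, weight=int(w))
    nx.write_graphml(merged, path)


def write_network_tables(networks, out_dir) -> None:
    """Flat nodes.tsv / edges.tsv plus one gene-list text file per node."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    node_rows, edge_rows = [], []
    for comp_idx, net in enumerate(networks):
        for i in sorted(net.nodes):
            node = net.nodes[i]
            node_rows.append({
                "component": comp_idx,
                "node_id": i,
                "n_genes": len(node.genes),
                "genes": ",".join(node.sorted_genes()),
                "signature": ",".join(str(s) for s in sorted(node.signature)),
                "conditions": ",".join(sorted(node.conditions)),
                "connected": not net.is_singleton,
            })
            gene_file = out_dir / f"node_{i:04d}_genes.txt"
            gene_file.write_text("\n".join(node.sorted_genes()) + "\n")
        for u, v, w in sorted(net.graph.edges(data="weight")):
            edge_rows.append({
                "component": comp_idx,
                "source": u,
                "target": v,
                "weight": int(w),
            })
    pd.DataFrame(
        node_rows,
        columns=["component", "node_id", "n_genes", "genes", "signature",
                 "conditions", "connected"],
    ).to_csv(out_dir / "nodes.tsv", sep="\t", index=False)
    pd.DataFrame(
        edge_rows, columns=["component", "source", "target", "weight"]
    ).to_csv(out_dir / "edges.tsv", sep="\t", index=False)
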