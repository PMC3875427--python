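"""Gene set network construction, filtering and hub extraction."""

import numpy as np
import pytest

from bicnet.core import Bicluster
from bicnet.fixtures import three_overlapping_biclusters
from bicnet.network import (
    build_network,
    extract_hub_subnetwork,
    filter_by_edge_weight,
    node_stats,
    write_graphml,
    write_network_tables,
)

from _oracles import network_from_signatures


def _random_bicluster_collection(rng):
    n_bics = int(rng.integers(1, 7))
    gene_pool = [f"g{i:02d}" for i in range(30)]
    cond_pool = [f"c{j}" for j in range(8)]
    bics = []
    for _ in range(n_bics):
        genes = rng.choice(gene_pool, size=int(rng.integers(2, 12)), replace=False)
        conds = rng.choice(cond_pool, size=int(rng.integers(2, 5)), replace=False)
        bics.append(Bicluster(frozenset(genes), frozenset(conds)))
    return bics


class TestBuildNetwork:
    def test_three_overlapping_biclusters_give_five_node_network(self):
        nets = build_network(three_overlapping_biclusters())
        assert len(nets) == 1
        net = nets[0]
        assert net.n_nodes == 5
        assert net.n_edges == 7
        u = net.node_by_signature({0, 1})
        v = net.node_by_signature({0, 1, 2})
        assert net.graph.edges[u.node_id, v.node_id]["weight"] == 2

    def test_single_bicluster_is_one_isolated_node(self):
        b = Bicluster(frozenset({"a", "b", "c"}), frozenset({"x", "y"}))
        nets = build_network([b])
        assert len(nets) == 1 and nets[0].n_nodes == 1 and nets[0].n_edges == 0
        assert nets[0].is_singleton

    def test_partition_clique_and_weights_match_oracle(self, rng):
        for _ in range(25):
            bics = _random_bicluster_collection(rng)
            nets = build_network(bics)
            all_nodes = {}
            for net in nets:
                all_nodes.update(net.nodes)
            # partition of biclustered genes
            covered = set()
            for node in all_nodes.values():
                assert not (node.genes & covered)
                covered |= node.genes
            assert covered == set().union(*(b.genes for b in bics))
            # oracle comparison
            oracle_nodes, oracle_edges = network_from_signatures(bics)
            assert {n.genes for n in all_nodes.values()} == oracle_nodes
            got_edges = {}
            for net in nets:
                for u, v, w in net.graph.edges(data="weight"):
                    got_edges[frozenset((net.nodes[u].genes, net.nodes[v].genes))] = w
            assert got_edges == oracle_edges
            # clique property per bicluster
            for idx in range(len(bics)):
                members = [i for i, n in all_nodes.items() if idx in n.signature]
                for a in range(len(members)):
                    for b2 in range(a + 1, len(members)):
                        found = False
                        for net in nets:
                            if net.graph.has_edge(members[a], members[b2]):
                                found = True
                        assert found

    def test_node_count_never_exceeds_gene_count(self, rng):
        for _ in range(10):
            bics = _random_bicluster_collection(rng)
            nets = build_network(bics)
            n_nodes = sum(net.n_nodes for net in nets)
            assert n_nodes <= len(set().union(*(b.genes for b in bics)))

    def test_conditions_are_union_over_signature(self):
        nets = build_network(three_overlapping_biclusters())
        node = nets[0].node_by_signature({0, 1})
        b1, b2, _ = three_overlapping_biclusters()
        assert node.conditions == b1.conditions | b2.conditions


class TestFilterByEdgeWeight:
    def test_min_weight_one_is_identity(self):
        nets = build_network(three_overlapping_biclusters())
        filtered = filter_by_edge_weight(nets[0], 1)
        assert len(filtered) == 1 and filtered[0].n_edges == nets[0].n_edges

    def test_heavy_edges_only_leaves_three_node_path(self):
        nets = build_network(three_overlapping_biclusters())
        comps = filter_by_edge_weight(nets[0], 2)
        assert len(comps) == 1
        comp = comps[0]
        assert comp.n_nodes == 3 and comp.n_edges == 2
        sigs = {tuple(sorted(n.signature)) for n in comp.nodes.values()}
        assert sigs == {(0, 1), (0, 1, 2), (1, 2)}
        degrees = sorted(d for _, d in comp.graph.degree())
        assert degrees == [1, 1, 2]  # a path, centered on {B1,B2,B3}

    def test_threshold_above_max_weight_empties_network(self):
        nets = build_network(three_overlapping_biclusters())
        assert filter_by_edge_weight(nets[0], 10) == []


class TestNodeStats:
    def test_isolated_node_stats(self):
        b = Bicluster(frozenset({"a", "b"}), frozenset({"x", "y"}))
        net = build_network([b])[0]
        df = node_stats(net)
        assert df.loc[0, ["degree", "weighted_degree", "n_genes"]].tolist() == [0, 0, 2]

    def test_fully_shared_node_has_highest_degree(self):
        net = build_network(three_overlapping_biclusters())[0]
        df = node_stats(net)
        top = net.nodes[df.loc[0, "node_id"]]
        assert top.signature == frozenset({0, 1, 2})
        assert df.loc[0, "degree"] == 4


class TestHubExtraction:
    def test_single_node_network(self):
        b = Bicluster(frozenset({"a", "b"}), frozenset({"x", "y"}))
        net = build_network([b])[0]
        hub, neighbors, genes = extract_hub_subnetwork(net, min_weight=2)
        assert neighbors == [] and genes == ["a", "b"]

    def test_hub_and_heavy_neighbors(self):
        net = build_network(three_overlapping_biclusters())[0]
        hub, neighbors, genes = extract_hub_subnetwork(net, min_weight=2)
        assert hub.signature == frozenset({0, 1, 2})
        assert {frozenset(n.signature) for n in neighbors} == {
            frozenset({0, 1}), frozenset({1, 2}),
        }
        assert set(genes) == hub.genes | set().union(*(n.genes for n in neighbors))


class TestExports:
    def test_graphml_and_tables(self, tmp_path):
        nets = build_network(three_overlapping_biclusters())
        write_graphml(nets, tmp_path / "net.graphml")
        assert (tmp_path / "net.graphml").stat().st_size > 0
        write_network_tables(nets, tmp_path / "tables")
        nodes = (tmp_path / "tables" / "nodes.tsv").read_text().strip().splitlines()
        edges = (tmp_path / "tables" / "edges.tsv").read_text().strip().splitlines()
        assert len(nodes) == 6 and len(edges) == 8  # header + 5 nodes / 7 edges
        gene_lists = list((tmp_path / "tables").glob("node_*_genes.txt"))
        assert len(gene_lists) == 5
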