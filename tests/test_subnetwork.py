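"""Seed mapping, shortest-path extraction and the layered network."""

import numpy as np
import pandas as pd
import pytest

from phytonet import (
    KGEdge,
    KnowledgeGraph,
    SyntheticSpec,
    build_layered_network,
    degree_table,
    generate_kg,
    map_seeds,
    shortest_paths,
    write_sif,
)
from phytonet.curated import SIGNATURE_PHYTOCHEMICALS, curated_mini_network
from phytonet.subnetwork import NO_PATH, SeedMappingError, SeedSet

from conftest import random_typed_graph


def brute_force_shortest_paths(graph, source, target, max_len):
    """Oracle: enumerate every simple path up to max_len by DFS, keep minimal."""
    adjacency = {nid: sorted(graph.neighbors(nid)) for nid in graph.node_ids}
    found = []

    def walk(node, path):
        if len(path) - 1 > max_len:
            return
        if node == target:
            found.append(list(path))
            return
        for nxt in adjacency[node]:
            if nxt not in path:
                path.append(nxt)
                walk(nxt, path)
                path.pop()

    walk(source, [source])
    if not found:
        return [], NO_PATH
    best = min(len(p) for p in found) - 1
    return sorted(p for p in found if len(p) - 1 == best), best


def chain_graph(*node_specs):
    """Linear graph from (label, type) pairs, edges along the chain."""
    g = KnowledgeGraph()
    ids = [g.ensure_node(lbl, t).id for lbl, t in node_specs]
    for a, b in zip(ids, ids[1:]):
        g.add_edge(KGEdge(a, b, "regulates"))
    return g, ids


class TestMapSeeds:
    def test_unmapped_labels_reported_not_dropped(self, mini_network):
        labels = [lbl for lbl, _ in SIGNATURE_PHYTOCHEMICALS]
        mini_network.ensure_node("TG", "marker")
        seeds = map_seeds(mini_network, labels, ["TG"])
        # hispidin, danshensu, rosmarinic acid, tanshinone I have no curated target
        assert len(seeds.compounds) == 8
        assert sorted(seeds.unmapped) == [
            "danshensu",
            "hispidin",
            "rosmarinic acid",
            "tanshinone I",
        ]

    def test_empty_marker_list_is_error(self, mini_network):
        with pytest.raises(SeedMappingError):
            map_seeds(mini_network, ["ellagic acid"], [])

    def test_nothing_mapped_is_hard_error(self, mini_network):
        with pytest.raises(SeedMappingError, match="no seed label mapped"):
            map_seeds(mini_network, ["unobtainium"], ["NOPE"])

    def test_synonym_table_resolves(self, mini_network):
        mini_network.ensure_node("TG", "marker")
        seeds = map_seeds(
            mini_network,
            ["E. acid"],
            ["TG"],
            synonyms={"E. acid": "ellagic acid"},
        )
        assert seeds.compounds == ["compound:ellagic acid"] and not seeds.unmapped


class TestShortestPaths:
    def test_direct_edge_single_path(self):
        g, ids = chain_graph(("c", "compound"), ("M", "marker"))
        res = shortest_paths(g, ids[0], ids[1])
        assert res.length == 1 and res.paths == [[ids[0], ids[1]]]

    def test_disconnected_pair_sentinel(self):
        g = KnowledgeGraph()
        a = g.ensure_node("c", "compound").id
        b = g.ensure_node("M", "marker").id
        res = shortest_paths(g, a, b)
        assert res.paths == [] and res.length == NO_PATH

    def test_beyond_max_len_is_no_path(self):
        g, ids = chain_graph(
            ("c", "compound"), ("p1", "protein"), ("p2", "protein"),
            ("p3", "protein"), ("M", "marker"),
        )
        assert shortest_paths(g, ids[0], ids[-1], max_len=3).length == NO_PATH
        assert shortest_paths(g, ids[0], ids[-1], max_len=4).length == 4

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_brute_force_enumeration(self, seed):
        """Path sets agree with exhaustive simple-path enumeration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        graph, ids = random_typed_graph(rng, n_nodes=n, p=float(rng.uniform(0.05, 0.25)))
        src, dst = rng.choice(ids, size=2, replace=False)
        max_len = int(rng.integers(1, 5))
        res = shortest_paths(graph, src, dst, max_len=max_len)
        expected_paths, expected_len = brute_force_shortest_paths(graph, src, dst, max_len)
        assert res.paths == expected_paths
        assert res.length == expected_len


class TestLayeredNetwork:
    def test_three_node_star(self):
        g, ids = chain_graph(("c", "compound"), ("p", "protein"), ("M", "marker"))
        seeds = SeedSet(compounds=[ids[0]], markers=[ids[2]])
        net = build_layered_network(g, seeds)
        assert (net.n_nodes, net.n_edges) == (3, 2)
        assert net.layer_of == {
            ids[0]: "component",
            ids[1]: "target",
            ids[2]: "marker",
        }

    def test_planted_chains_recovered_exactly(self):
        spec = SyntheticSpec(seed=7)
        spec.kg.distractor_edge_prob = 0.0
        graph, chains = generate_kg(spec)
        seeds = SeedSet(
            compounds=sorted({c[0] for c in chains}),
            markers=sorted({c[-1] for c in chains}),
        )
        net = build_layered_network(graph, seeds)
        expected_nodes = {n for chain in chains for n in chain}
        assert set(net.graph.node_ids) == expected_nodes
        expected_edges = set()
        for chain in chains:
            for a, b in zip(chain, chain[1:]):
                expected_edges.add(frozenset((a, b)))
        assert {frozenset((e.source, e.target)) for e in net.graph.edges} == expected_edges
        assert set(net.nodes_in_layer("component")) == set(seeds.compounds)

    def test_curated_network_degrees(self, mini_network):
        """The worked example: CASP3 fans in 6 compounds, cryptotanshinone 2 targets."""
        g = mini_network
        pheno = g.ensure_node("vascular dysfunction", "phenotype")
        tg = g.ensure_node("TG", "marker")
        g.add_edge(KGEdge(tg.id, pheno.id, "marker_of_phenotype"))
        for prot in [n.id for n in g.nodes if n.node_type == "protein"]:
            g.add_edge(KGEdge(prot, pheno.id, "regulates"))
        seeds = map_seeds(
            g, [lbl for lbl, _ in SIGNATURE_PHYTOCHEMICALS], ["TG"]
        )
        net = build_layered_network(g, seeds)
        table = degree_table(net)
        degree = dict(zip(table["node_id"], table["degree"]))
        assert degree["protein:CASP3"] == 6
        assert degree["compound:cryptotanshinone"] == 2

    def test_event_map_annotates_targets(self, mini_network):
        from phytonet.curated import curated_event_map

        g = curated_mini_network()
        pheno = g.ensure_node("vascular dysfunction", "phenotype")
        tg = g.ensure_node("TG", "marker")
        g.add_edge(KGEdge(tg.id, pheno.id, "marker_of_phenotype"))
        g.add_edge(KGEdge("protein:CASP3", pheno.id, "regulates"))
        seeds = map_seeds(g, ["ellagic acid"], ["TG"])
        net = build_layered_network(g, seeds, event_map=curated_event_map())
        assert net.event_of.get("protein:CASP3") == "endothelial_inflammation"

    def test_disconnected_seeds_warn_not_error(self, caplog):
        g = KnowledgeGraph()
        c = g.ensure_node("c", "compound").id
        m = g.ensure_node("M", "marker").id
        with caplog.at_level("WARNING"):
            net = build_layered_network(g, SeedSet(compounds=[c], markers=[m]))
        assert net.n_nodes == 0
        assert any("no (compound, marker) pair" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(10))
    def test_max_len_monotonicity(self, seed):
        """Raising the hop cap never removes nodes from the layered network."""
        spec = SyntheticSpec(seed=200 + seed)
        spec.kg.distractor_edge_prob = 0.05
        graph, chains = generate_kg(spec)
        seeds = SeedSet(
            compounds=sorted({c[0] for c in chains}),
            markers=sorted({c[-1] for c in chains}),
        )
        previous: set[str] = set()
        for max_len in (1, 2, 3, 4, 5):
            net = build_layered_network(graph, seeds, max_len=max_len)
            assert previous <= set(net.graph.node_ids)
            previous = set(net.graph.node_ids)

    def test_rerun_sif_export_byte_identical(self, tmp_path):
        spec = SyntheticSpec(seed=11)
        outputs = []
        for name in ("a.sif", "b.sif"):
            graph, chains = generate_kg(spec)
            seeds = SeedSet(
                compounds=sorted({c[0] for c in chains}),
                markers=sorted({c[-1] for c in chains}),
            )
            net = build_layered_network(graph, seeds)
            write_sif(net.graph, tmp_path / name)
            outputs.append((tmp_path / name).read_bytes())
        assert outputs[0] == outputs[1]


class TestDegreeTable:
    def test_complete_bipartite_all_threes(self):
        g = KnowledgeGraph()
        comps = [g.ensure_node(f"c{i}", "compound").id for i in range(3)]
        prots = [g.ensure_node(f"p{i}", "protein").id for i in range(3)]
        for c in comps:
            for p in prots:
                g.add_edge(KGEdge(c, p, "targets"))
        layer_of = {c: "component" for c in comps} | {p: "target" for p in prots}
        from phytonet.subnetwork import LayeredNetwork

        table = degree_table(LayeredNetwork(graph=g, layer_of=layer_of))
        assert (table["degree"] == 3).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_random_bipartite_matches_recount(self, seed):
        rng = np.random.default_rng(300 + seed)
        g = KnowledgeGraph()
        comps = [g.ensure_node(f"c{i}", "compound").id for i in range(6)]
        prots = [g.ensure_node(f"p{i}", "protein").id for i in range(8)]
        adjacency = {n: set() for n in comps + prots}
        for c in comps:
            for p in prots:
                if rng.random() < 0.4:
                    g.add_edge(KGEdge(c, p, "targets"))
                    adjacency[c].add(p)
                    adjacency[p].add(c)
        layer_of = {c: "component" for c in comps} | {p: "target" for p in prots}
        from phytonet.subnetwork import LayeredNetwork

        table = degree_table(LayeredNetwork(graph=g, layer_of=layer_of))
        for row in table.itertuples(index=False):
            assert row.degree == len(adjacency[row.node_id])
        # sorted descending, ties lexicographic
        key = list(zip(-table["degree"], table["node_id"]))
        assert key == sorted(key)
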