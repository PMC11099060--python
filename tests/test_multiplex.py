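"""Multiplex assembly, aggregation, components, centrality and export."""

import networkx as nx
import numpy as np
import pytest

from conftest import agg_from_graph
from onsetnet.multiplex import (
    Layer,
    aggregate,
    build_multiplex,
    closeness_centrality,
    induced_subnetwork,
    largest_connected_component,
    read_layer,
    split_layers,
    summarize_network,
    write_graphml,
    write_sif,
)
from oracle_utils import brute_force_closeness


class TestReadLayer:
    def test_dedupes_and_drops_self_loops(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\nB\tA\nC\tC\n")
        layer = read_layer(p, "ppi")
        assert layer.edges == frozenset({("A", "B")})

    def test_empty_file(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("")
        assert read_layer(p, "ppi").edges == frozenset()

    def test_triangle(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\nB\tC\nA\tC\n")
        assert len(read_layer(p, "ppi").edges) == 3

    def test_short_row_is_hard_error_naming_line(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\nJUSTONE\n")
        with pytest.raises(ValueError, match="line 2"):
            read_layer(p, "ppi")

    def test_extra_columns_ignored_with_warning(self, tmp_path, caplog):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t0.9\n")
        with caplog.at_level("WARNING"):
            layer = read_layer(p, "ppi")
        assert layer.edges == frozenset({("A", "B")})
        assert any("unweighted" in m for m in caplog.messages)


class TestBuildMultiplex:
    def test_union_node_set_with_per_layer_isolates(self):
        mx = build_multiplex(
            [Layer("l1", frozenset({("A", "B")})), Layer("l2", frozenset({("B", "C")}))]
        )
        assert mx.nodes == {"A", "B", "C"}
        g1, g2 = mx.layer_graphs()
        assert g1.degree["C"] == 0 and g2.degree["A"] == 0

    def test_single_layer_identity(self):
        layer = Layer("l1", frozenset({("A", "B"), ("B", "C")}))
        mx = build_multiplex([layer])
        assert mx.nodes == layer.endpoints and mx.layers == (layer,)

    def test_disjoint_layers_union(self):
        layers = [
            Layer("l1", frozenset({("A", "B")})),
            Layer("l2", frozenset({("C", "D")})),
            Layer("l3", frozenset({("E", "F")})),
        ]
        assert build_multiplex(layers).nodes == set("ABCDEF")

    def test_zero_layers_error(self):
        with pytest.raises(ValueError):
            build_multiplex([])


class TestLargestConnectedComponent:
    def test_keeps_larger_component(self):
        mx = build_multiplex(
            [Layer("l1", frozenset({("A", "B"), ("B", "C"), ("A", "C"), ("D", "E")}))]
        )
        assert largest_connected_component(mx).nodes == {"A", "B", "C"}

    def test_connected_input_unchanged(self, toy_multiplex):
        assert largest_connected_component(toy_multiplex).nodes == toy_multiplex.nodes

    def test_tie_broken_toward_smallest_member(self):
        mx = build_multiplex([Layer("l1", frozenset({("C", "D"), ("A", "B")}))])
        assert largest_connected_component(mx).nodes == {"A", "B"}

    def test_idempotent(self, toy_multiplex):
        once = largest_connected_component(toy_multiplex)
        assert largest_connected_component(once) == once

    def test_connectivity_is_cross_layer(self):
        # A-B only in layer 1, B-C only in layer 2: connected for a layer-switching walker
        mx = build_multiplex(
            [Layer("l1", frozenset({("A", "B")})), Layer("l2", frozenset({("B", "C")}))]
        )
        assert largest_connected_component(mx).nodes == {"A", "B", "C"}


class TestAggregate:
    def test_shared_edge_carries_both_tags(self):
        mx = build_multiplex(
            [Layer("l1", frozenset({("A", "B")})), Layer("l2", frozenset({("A", "B")}))]
        )
        net = aggregate(mx)
        assert net.n_edges == 1 and set(net.edge_layers("A", "B")) == {"l1", "l2"}

    def test_disjoint_layers_sum_edges(self):
        mx = build_multiplex(
            [Layer("l1", frozenset({("A", "B")})), Layer("l2", frozenset({("C", "D")}))]
        )
        assert aggregate(mx).n_edges == 2

    def test_round_trip_by_tags(self):
        rng = np.random.default_rng(5)
        names = [f"N{i:02d}" for i in range(12)]
        layers = []
        for li in range(3):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            edges = frozenset(
                (names[min(a, b)], names[max(a, b)]) for a, b in g.edges
            )
            layers.append(Layer(f"l{li}", edges))
        mx = build_multiplex(layers)
        recovered = split_layers(aggregate(mx), mx.layer_names)
        for layer in layers:
            assert recovered[layer.name] == layer.edges


class TestInducedSubnetwork:
    def test_drops_internal_edges_only(self):
        net = agg_from_graph(nx.path_graph(["A", "B", "C"]))
        sub = induced_subnetwork(net, {"A", "C"})
        assert sub.network.nodes == {"A", "C"} and sub.network.n_edges == 0

    def test_identity_on_full_node_set(self):
        net = agg_from_graph(nx.path_graph(["A", "B", "C"]))
        sub = induced_subnetwork(net, {"A", "B", "C"})
        assert sub.network.n_edges == 2 and sub.absent == ()

    def test_absent_genes_reported_not_dropped_silently(self):
        net = agg_from_graph(nx.path_graph(["A", "B"]))
        sub = induced_subnetwork(net, {"A", "ANO5"})
        assert sub.absent == ("ANO5",)
        assert sub.network.nodes == {"A"}


class TestCloseness:
    def test_path_of_three(self):
        vals = closeness_centrality(agg_from_graph(nx.path_graph(["A", "B", "C"])))
        assert vals["B"] == pytest.approx(1.0)
        assert vals["A"] == vals["C"] == pytest.approx(2 / 3)

    def test_complete_graph_all_ones(self):
        vals = closeness_centrality(agg_from_graph(nx.complete_graph(5)))
        assert all(v == pytest.approx(1.0) for v in vals.values())

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("Z")
        assert closeness_centrality(agg_from_graph(g))["Z"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        g = nx.gnp_random_graph(n, 0.15, seed=seed)
        vals = closeness_centrality(agg_from_graph(g))
        oracle = brute_force_closeness(g)
        for v in g.nodes:
            assert vals[v] == pytest.approx(oracle[v], abs=1e-12)


class TestSummary:
    def test_triangle(self):
        s = summarize_network(agg_from_graph(nx.complete_graph(["A", "B", "C"])))
        assert (s.n_nodes, s.n_edges, s.component_diameters, s.density) == (3, 3, (1,), 1.0)

    def test_path_diameter(self):
        s = summarize_network(agg_from_graph(nx.path_graph(4)))
        assert s.component_diameters == (3,)

    def test_empty_graph(self):
        s = summarize_network(agg_from_graph(nx.Graph()))
        assert s.n_nodes == 0 and s.n_edges == 0 and s.density == 0.0


class TestExport:
    def test_graphml_round_trip_with_attributes(self, toy_multiplex, tmp_path):
        net = aggregate(toy_multiplex)
        path = tmp_path / "net.graphml"
        write_graphml(net, path, node_groups={"A": "DoGs"})
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.nodes)
        assert back.nodes["A"]["group"] == "DoGs"
        assert back.edges["A", "B"]["layers"] == "ppi"

    def test_sif_lists_isolated_nodes(self, tmp_path):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("Z")
        path = tmp_path / "net.sif"
        write_sif(agg_from_graph(g), path)
        lines = path.read_text().splitlines()
        assert "A\tppi\tB" in lines and "Z" in lines
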