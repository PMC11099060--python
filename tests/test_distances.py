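"""Group distance statistics and their random-gene-set nulls."""

import networkx as nx
import numpy as np
import pytest

from conftest import agg_from_graph
from onsetnet.distances import (
    NullConfig,
    avg_shortest_distance,
    distance_table,
    empirical_p,
    random_baseline,
)
from oracle_utils import brute_force_avg_distance


def random_net_and_sets(seed, n=40, p=0.15):
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=seed)
    lcc = max(nx.connected_components(g), key=len)
    g = g.subgraph(lcc).copy()
    nodes = sorted(g.nodes)
    a = set(rng.choice(nodes, size=min(6, len(nodes)), replace=False).tolist())
    b = set(rng.choice(nodes, size=min(8, len(nodes)), replace=False).tolist())
    return agg_from_graph(g), g, a, b


class TestAvgShortestDistance:
    def test_star_leaves_intra(self):
        g = nx.star_graph(["c", "l1", "l2", "l3"])
        net = agg_from_graph(g)
        assert avg_shortest_distance(net, {"l1", "l2", "l3"}, {"l1", "l2", "l3"}) == 2.0

    def test_single_edge(self):
        net = agg_from_graph(nx.path_graph(["a", "b"]))
        assert avg_shortest_distance(net, {"a"}, {"b"}) == 1.0

    def test_complete_graph_disjoint_sets(self):
        net = agg_from_graph(nx.complete_graph(8))
        assert avg_shortest_distance(net, {0, 1, 2}, {5, 6}) == 1.0

    def test_singleton_intra_is_error(self):
        net = agg_from_graph(nx.path_graph(["a", "b"]))
        with pytest.raises(ValueError):
            avg_shortest_distance(net, {"a"}, {"a"})

    def test_gene_outside_network_is_error(self):
        net = agg_from_graph(nx.path_graph(["a", "b"]))
        with pytest.raises(ValueError, match="not in network"):
            avg_shortest_distance(net, {"a"}, {"zz"})

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bfs_oracle_and_is_symmetric(self, seed):
        net, g, a, b = random_net_and_sets(seed)
        d_ab = avg_shortest_distance(net, a, b)
        assert d_ab == pytest.approx(brute_force_avg_distance(g, a, b), abs=1e-12)
        assert d_ab == pytest.approx(avg_shortest_distance(net, b, a), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_bounded_by_one_and_diameter(self, seed):
        net, g, a, b = random_net_and_sets(seed)
        d = avg_shortest_distance(net, a, b)
        assert 1.0 <= d <= nx.diameter(g)


class TestEmpiricalP:
    def test_complete_graph_p_zero(self):
        net = agg_from_graph(nx.complete_graph(12))
        res = empirical_p(net, {0, 1, 2}, {5, 6, 7}, NullConfig(n_random=100, rng_seed=0))
        assert res.p == 0.0 and res.real_distance == 1.0

    def test_adjacent_pair_on_long_path_is_extreme(self):
        net = agg_from_graph(nx.path_graph(30))
        res = empirical_p(net, {0}, {1}, NullConfig(n_random=300, rng_seed=0))
        assert res.p <= 0.05

    def test_reproducible_given_seed(self):
        net, _, a, b = random_net_and_sets(3)
        cfg = NullConfig(n_random=50, rng_seed=123)
        r1, r2 = empirical_p(net, a, b, cfg), empirical_p(net, a, b, cfg)
        assert r1.p == r2.p
        assert np.array_equal(r1.null_distances, r2.null_distances)

    def test_oversized_random_set_is_error(self):
        net = agg_from_graph(nx.path_graph(4))
        with pytest.raises(ValueError, match="exceeds"):
            random_baseline(net, {0}, size=5, cfg=NullConfig(n_random=1, rng_seed=0))

    def test_null_p_roughly_uniform(self):
        # small-scale calibration; the full KS check lives in the acceptance suite
        g = nx.gnp_random_graph(60, 0.1, seed=9)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        net = agg_from_graph(g)
        rng = np.random.default_rng(9)
        nodes = sorted(g.nodes)
        ps = []
        for i in range(40):
            a = set(rng.choice(nodes, size=5, replace=False).tolist())
            b = set(rng.choice(nodes, size=5, replace=False).tolist())
            ps.append(empirical_p(net, a, b, NullConfig(n_random=60, rng_seed=i)).p)
        assert 0.15 < np.mean(ps) < 0.85


class TestRandomBaseline:
    def test_complete_graph_exactly_one(self):
        net = agg_from_graph(nx.complete_graph(10))
        assert random_baseline(net, {0, 1}, cfg=NullConfig(n_random=50, rng_seed=0)) == 1.0

    def test_star_center_singleton(self):
        net = agg_from_graph(nx.star_graph(6))
        val = random_baseline(net, {0}, size=1, cfg=NullConfig(n_random=100, rng_seed=0))
        assert val == 1.0  # every other node sits at distance 1 from the hub

    def test_path_end_node_expectation(self):
        # exact expectation under the self-pair-exclusion rule:
        # mean distance from an end of P10 to a uniform *other* node = 45/9 = 5
        net = agg_from_graph(nx.path_graph(10))
        val = random_baseline(net, {0}, size=1, cfg=NullConfig(n_random=4000, rng_seed=1))
        assert val == pytest.approx(5.0, rel=0.05)

    def test_random_vs_random_requires_sizes(self):
        net = agg_from_graph(nx.complete_graph(5))
        with pytest.raises(ValueError):
            random_baseline(net, cfg=NullConfig(n_random=5))


class TestDistanceTable:
    def test_singleton_groups_on_triangle(self):
        net = agg_from_graph(nx.complete_graph(["x", "y", "z"]))
        groups = {"ga": {"x"}, "gb": {"y"}, "gc": {"z"}}
        table = distance_table(net, groups, NullConfig(n_random=20, rng_seed=0))
        for i, la in enumerate(("ga", "gb", "gc")):
            for lb in ("ga", "gb", "gc")[i + 1 :]:
                assert table.mean_distance[frozenset({la, lb})] == 1.0

    def test_identical_groups_intra_equals_inter(self):
        net, _, a, _ = random_net_and_sets(2)
        table = distance_table(net, {"g1": a, "g2": set(a)}, NullConfig(n_random=10, rng_seed=0))
        assert table.mean_distance[frozenset({"g1"})] == pytest.approx(
            table.mean_distance[frozenset({"g1", "g2"})]
        )

    def test_directional_pvalues_present_for_all_ordered_pairs(self):
        net, _, a, b = random_net_and_sets(4)
        table = distance_table(net, {"g1": a, "g2": b}, NullConfig(n_random=25, rng_seed=0))
        assert set(table.p_empirical) == {("g1", "g1"), ("g1", "g2"), ("g2", "g1"), ("g2", "g2")}

    def test_matrix_shape_includes_random_row(self):
        net, _, a, b = random_net_and_sets(5)
        table = distance_table(net, {"g1": a, "g2": b}, NullConfig(n_random=25, rng_seed=0))
        mat = table.to_matrix()
        assert list(mat.index) == ["g1", "g2", "Random"]
        assert np.isfinite(mat.loc["Random", "Random"])

    def test_planted_groups_sit_below_their_random_baseline(self, default_bundle):
        from onsetnet.multiplex import aggregate, largest_connected_component

        mx = largest_connected_component(default_bundle.multiplex())
        net = aggregate(mx)
        groups = {lab: set(g) & set(mx.nodes) for lab, g in default_bundle.groups.items()}
        table = distance_table(net, groups, NullConfig(n_random=100, rng_seed=0))
        for lab in groups:
            intra = table.mean_distance[frozenset({lab})]
            baseline = table.mean_distance[frozenset({lab, "Random"})]
            assert intra < baseline
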