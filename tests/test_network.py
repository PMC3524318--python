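import itertools
import warnings

import networkx as nx
import numpy as np
import pytest

from dton.network import (
    TimeOrderNetwork,
    build_adjacency,
    classify_trend,
    export_network,
    find_incoming_edge_hubs,
    import_network_tsv,
    maximum_weight_spanning_tree,
    remove_redundant_edges,
    threshold_network,
)
from dton.spline import fit_spline
from dton.time_order import PairScore


def ps(a, b, delta):
    """A PairScore with the requested delta (finite log-likelihoods)."""
    return PairScore(a, b, loglik_a_to_b=delta, loglik_b_to_a=0.0)


def net_from_edges(edges, variant="full"):
    g = nx.DiGraph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return TimeOrderNetwork(g, variant)


class TestBuildAdjacency:
    def test_positive_delta_direction_kept(self):
        net = build_adjacency([ps("A", "B", 2.0)])
        assert net.edges() == [("A", "B", 2.0)]

    def test_negative_delta_flips_direction(self):
        net = build_adjacency([ps("A", "B", -1.5)])
        assert net.edges() == [("B", "A", 1.5)]

    def test_tie_produces_no_edge(self):
        net = build_adjacency([ps("A", "B", 0.0)])
        assert net.n_edges == 0
        assert set(net.graph.nodes) == {"A", "B"}

    def test_edge_count_without_ties(self, rng):
        genes = [f"g{i}" for i in range(12)]
        scores = [
            ps(a, b, float(rng.normal()) or 0.1)
            for a, b in itertools.combinations(genes, 2)
        ]
        assert build_adjacency(scores).n_edges == 66

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_adjacency([ps("A", "B", 1.0), ps("B", "A", 2.0)])

    def test_exactly_one_direction_per_pair(self, rng):
        genes = [f"g{i}" for i in range(8)]
        scores = [ps(a, b, float(rng.normal()))
                  for a, b in itertools.combinations(genes, 2)]
        net = build_adjacency(scores)
        for u, v in net.graph.edges:
            assert not net.graph.has_edge(v, u)


class TestThreshold:
    def test_median_rule(self):
        net = net_from_edges(
            [("a", "b", 1.0), ("c", "d", 2.0), ("e", "f", 3.0), ("g", "h", 4.0)]
        )
        kept = threshold_network(net, 0.5)
        assert sorted(w for *_, w in kept.edges()) == [3.0, 4.0]

    def test_quantile_zero_keeps_all(self):
        net = net_from_edges([("a", "b", 1.0), ("b", "c", 0.5)])
        assert threshold_network(net, 0.0).n_edges == 2

    def test_matches_bruteforce_filter(self, rng):
        edges = [(f"u{i}", f"v{i}", float(w)) for i, w in
                 enumerate(rng.uniform(0.1, 5, 20))]
        net = net_from_edges(edges)
        q = 0.37
        kept = threshold_network(net, q)
        cut = np.quantile([w for *_, w in edges], q)
        expect = sorted((u, v, w) for u, v, w in edges if w >= cut)
        assert kept.edges() == expect

    def test_monotone_in_quantile(self, rng):
        edges = [(f"u{i}", f"v{i}", float(w)) for i, w in
                 enumerate(rng.uniform(0.1, 5, 15))]
        net = net_from_edges(edges)
        prev = None
        for q in (0.0, 0.25, 0.5, 0.75, 0.99):
            cur = {(u, v) for u, v, _ in threshold_network(net, q).edges()}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_bad_quantile_rejected(self):
        with pytest.raises(ValueError):
            threshold_network(net_from_edges([("a", "b", 1.0)]), 1.0)


def random_dag(rng, n=10, p=0.35):
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    order = rng.permutation(n)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(int(order[i]), int(order[j]), weight=float(rng.uniform(0.1, 2)))
    return g


class TestRedundantEdges:
    def test_length_two_shortcut_removed(self):
        net = net_from_edges(
            [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)], "thresholded"
        )
        reduced = remove_redundant_edges(net)
        assert {(u, v) for u, v, _ in reduced.edges()} == {("A", "B"), ("B", "C")}

    def test_pure_chain_unchanged(self):
        net = net_from_edges([("A", "B", 1.0), ("B", "C", 2.0)], "thresholded")
        assert remove_redundant_edges(net).edges() == net.edges()

    def test_matches_networkx_transitive_reduction(self, rng):
        for _ in range(15):
            g = random_dag(rng)
            net = TimeOrderNetwork(g, "thresholded")
            mine = {(u, v) for u, v, _ in remove_redundant_edges(net).edges()}
            expect = set(nx.transitive_reduction(g).edges)
            assert mine == expect

    def test_reachability_preserved(self, rng):
        for _ in range(10):
            g = random_dag(rng, n=8)
            reduced = remove_redundant_edges(TimeOrderNetwork(g, "thresholded")).graph
            for u in g.nodes:
                assert nx.descendants(g, u) == nx.descendants(reduced, u)

    def test_cycle_emits_warning_and_keeps_cycle(self):
        net = net_from_edges(
            [("A", "B", 1.0), ("B", "A", 1.0)], "thresholded"
        )
        with pytest.warns(UserWarning, match="cycle"):
            reduced = remove_redundant_edges(net)
        assert reduced.n_edges == 2


def bruteforce_max_spanning_weight(g):
    """Max total weight over all spanning trees, by edge-subset enumeration."""
    n = g.number_of_nodes()
    best = -np.inf
    edges = list(g.edges(data="weight"))
    for combo in itertools.combinations(edges, n - 1):
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        h.add_weighted_edges_from(combo)
        if nx.is_connected(h):
            best = max(best, sum(w for *_, w in combo))
    return best


class TestMaximumWeightSpanningTree:
    def test_triangle(self):
        net = net_from_edges([("a", "b", 3.0), ("b", "c", 2.0), ("a", "c", 1.0)])
        tree = maximum_weight_spanning_tree(net)
        assert sorted(w for *_, w in tree.edges()) == [2.0, 3.0]

    def test_path_graph_forced(self):
        net = net_from_edges([("a", "b", 1.0), ("b", "c", 1.0)])
        tree = maximum_weight_spanning_tree(net)
        assert {(u, v) for u, v, _ in tree.edges()} == {("a", "b"), ("b", "c")}

    def test_directions_preserved(self, rng):
        edges = [("c", "a", 5.0), ("b", "a", 4.0), ("c", "b", 3.0)]
        tree = maximum_weight_spanning_tree(net_from_edges(edges))
        assert {(u, v) for u, v, _ in tree.edges()} == {("c", "a"), ("b", "a")}

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(8):
            n = int(rng.integers(4, 7))
            g = nx.DiGraph()
            for a, b in itertools.combinations(range(n), 2):
                u, v = (a, b) if rng.random() < 0.5 else (b, a)
                g.add_edge(str(u), str(v), weight=float(rng.uniform(0.1, 5)))
            net = TimeOrderNetwork(g, "full")
            tree = maximum_weight_spanning_tree(net)
            got = sum(w for *_, w in tree.edges())
            expect = bruteforce_max_spanning_weight(g.to_undirected())
            assert got == pytest.approx(expect, abs=1e-9)

    def test_forest_on_disconnected_input(self):
        net = net_from_edges([("a", "b", 1.0), ("c", "d", 2.0)])
        tree = maximum_weight_spanning_tree(net)
        assert tree.n_edges == 2
        assert not list(nx.cycle_basis(tree.graph.to_undirected()))

    def test_acyclic_ignoring_direction(self, rng):
        g = nx.DiGraph()
        for a, b in itertools.combinations(range(7), 2):
            g.add_edge(str(a), str(b), weight=float(rng.uniform(0.1, 5)))
        tree = maximum_weight_spanning_tree(TimeOrderNetwork(g, "full"))
        und = tree.graph.to_undirected()
        assert nx.is_tree(und)


class TestHubs:
    def test_star_graph(self):
        edges = [(f"leaf{i}", "center", 1.0) for i in range(5)]
        hubs = find_incoming_edge_hubs(net_from_edges(edges), 10)
        assert len(hubs) == 1
        assert hubs[0].gene_id == "center"
        assert hubs[0].in_degree == 5

    def test_node_with_outgoing_edge_excluded(self):
        edges = [(f"x{i}", "m", 1.0) for i in range(5)] + [("m", "z", 1.0)]
        hubs = find_incoming_edge_hubs(net_from_edges(edges), 10)
        assert "m" not in [h.gene_id for h in hubs]

    def test_empty_network(self):
        assert find_incoming_edge_hubs(TimeOrderNetwork(nx.DiGraph()), 5) == []

    def test_sorted_by_in_degree_then_id(self):
        edges = [("a", "z", 1.0), ("b", "z", 1.0), ("c", "y", 1.0)]
        hubs = find_incoming_edge_hubs(net_from_edges(edges), 10)
        assert [h.gene_id for h in hubs] == ["z", "y"]


class TestClassifyTrend:
    def test_increasing_curve_overexpressed(self, grid, knots):
        fit = fit_spline(np.linspace(0, 2, 12), grid, knots)
        call = classify_trend(fit)
        assert call.trend == "overexpressed"
        assert not call.boundary

    def test_zero_gene_is_boundary(self, grid, knots):
        fit = fit_spline(np.zeros(12), grid, knots)
        call = classify_trend(fit)
        assert call.late_mean == 0
        assert call.boundary

    def test_sign_matches_numeric_average(self, grid, knots, rng):
        from dton.spline import evaluate_spline

        for _ in range(5):
            fit = fit_spline(rng.normal(size=12), grid, knots)
            call = classify_trend(fit)
            ts = np.linspace(knots.k2, 32, 100)
            numeric = float(np.mean(evaluate_spline(fit, ts)))
            assert call.late_mean == pytest.approx(numeric, abs=2e-2)
            if abs(numeric) > 1e-3:
                assert np.sign(call.late_mean) == np.sign(numeric)


class TestExport:
    def test_tsv_has_header_and_rows(self, tmp_path):
        net = net_from_edges([("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 3.0)])
        export_network(net, "tsv", tmp_path / "n.tsv")
        lines = (tmp_path / "n.tsv").read_text().splitlines()
        assert lines[0] == "source\ttarget\tweight"
        assert len(lines) == 4

    def test_tsv_round_trip(self, tmp_path, rng):
        edges = [(f"u{i}", f"v{i}", float(w)) for i, w in
                 enumerate(rng.uniform(0.1, 5, 10))]
        net = net_from_edges(edges)
        export_network(net, "tsv", tmp_path / "n.tsv")
        back = import_network_tsv(tmp_path / "n.tsv")
        assert [(u, v) for u, v, _ in back.edges()] == [(u, v) for u, v, _ in net.edges()]
        np.testing.assert_allclose(
            [w for *_, w in back.edges()], [w for *_, w in net.edges()], rtol=1e-10
        )

    def test_graphml_is_well_formed_xml(self, tmp_path):
        import xml.etree.ElementTree as ET

        net = net_from_edges([("a", "b", 1.5)])
        export_network(net, "graphml", tmp_path / "n.graphml")
        ET.parse(tmp_path / "n.graphml")

    def test_dot_contains_edges(self, tmp_path):
        net = net_from_edges([("a", "b", 1.5)])
        export_network(net, "dot", tmp_path / "n.dot")
        assert '"a" -> "b"' in (tmp_path / "n.dot").read_text()
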