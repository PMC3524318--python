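"""Directed time-order network construction and analysis.

From pairwise delta log-likelihoods we build a complete directed graph
(one edge per pair, pointing toward the later-responding gene, weighted
by the positive delta). Two reductions make the graph readable:

* small networks (tens of genes): drop edges below a weight quantile,
  then remove transitively redundant edges (A->C is redundant given
  A->B->C);
* genome-scale networks: keep a maximum-weight spanning tree (Prim),
  which connects every gene through the strongest order evidence.

Nodes with only incoming edges ("incoming-edge hubs") are the
late-response candidates; more incoming edges means a later response.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .spline import SplineFit
from .time_order import PairScore, evaluate_cumulative, integrate_spline

__all__ = [
    "TimeOrderNetwork",
    "HubReport",
    "TrendCall",
    "build_adjacency",
    "threshold_network",
    "remove_redundant_edges",
    "maximum_weight_spanning_tree",
    "find_incoming_edge_hubs",
    "classify_trend",
    "export_network",
    "import_network_tsv",
]

VARIANTS = ("full", "thresholded", "reduced", "mwst")


@dataclass
class TimeOrderNetwork:
    """A weighted directed graph over genes; edge u->v means v responds later.

    ``variant`` tracks provenance: "full" (one edge per scored pair),
    "thresholded", "reduced" (redundant edges removed) or "mwst".
    """

    graph: nx.DiGraph
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for u, v, w in self.graph.edges(data="weight"):
            if w is None or w <= 0:
                raise ValueError(f"edge {u}->{v} must carry a positive weight")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weights(self) -> np.ndarray:
        return np.array([w for *_, w in self.graph.edges(data="weight")], dtype=float)

    def edges(self) -> list[tuple[str, str, float]]:
        return sorted((u, v, w) for u, v, w in self.graph.edges(data="weight"))


@dataclass(frozen=True)
class HubReport:
    """An incoming-edge hub: a node with no outgoing edges."""

    gene_id: str
    in_degree: int
    out_degree: int

    def __post_init__(self) -> None:
        if self.out_degree != 0 or self.in_degree < 1:
            raise ValueError("a hub has out_degree 0 and in_degree >= 1")


def build_adjacency(scores: Iterable[PairScore]) -> TimeOrderNetwork:
    """Keep, per pair, the single directed edge of the supported ordering.

    Of the two symmetric delta values only the positive one is kept as
    the edge weight; a pair with delta exactly 0 (neither direction
    supported) contributes no edge, but both genes appear as nodes.
    """
    g = nx.DiGraph()
    seen: set[frozenset[str]] = set()
    for s in scores:
        key = frozenset((s.gene_a, s.gene_b))
        if key in seen:
            raise ValueError(f"duplicate pair record for {s.gene_a}, {s.gene_b}")
        seen.add(key)
        g.add_node(s.gene_a)
        g.add_node(s.gene_b)
        ordered = s.ordered
        if ordered is not None:
            g.add_edge(*ordered, weight=abs(s.delta))
    return TimeOrderNetwork(g, "full")


def threshold_network(net: TimeOrderNetwork, quantile: float = 0.5) -> TimeOrderNetwork:
    """Drop edges below the given quantile of the kept positive edge weights.

    The quantile uses the same linear-interpolation rule as knot
    placement; zeroed symmetric entries are bookkeeping, not evidence,
    so they are excluded from the distribution.
    """
    if net.variant != "full":
        raise ValueError("thresholding applies to the full network")
    if not (0 <= quantile < 1):
        raise ValueError("quantile must be in [0, 1)")
    g = nx.DiGraph()
    g.add_nodes_from(net.graph.nodes)
    weights = net.edge_weights()
    if weights.size:
        cut = np.quantile(weights, quantile, method="linear")
        for u, v, w in net.graph.edges(data="weight"):
            if w >= cut:
                g.add_edge(u, v, weight=w)
    return TimeOrderNetwork(g, "thresholded")


def remove_redundant_edges(net: TimeOrderNetwork) -> TimeOrderNetwork:
    """Transitive reduction: drop edges explained by a longer directed path.

    An edge (u, v) is redundant iff v remains reachable from u through a
    directed path of length >= 2 after deleting (u, v); on a DAG this
    yields the unique minimal reachability-preserving subgraph. Edges
    inside directed cycles are never removed by this rule; a warning is
    emitted if cycles are present.
    """
    if net.variant != "thresholded":
        raise ValueError("redundancy removal applies to a thresholded network")
    g = net.graph
    if not nx.is_directed_acyclic_graph(g):
        warnings.warn("network contains directed cycles; cycle edges are kept")
    reduced = g.copy()
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        if nx.has_path(h, u, v):
            reduced.remove_edge(u, v)
    return TimeOrderNetwork(reduced, "reduced")


def maximum_weight_spanning_tree(net: TimeOrderNetwork) -> TimeOrderNetwork:
    """Maximum-weight spanning tree (forest) via Prim's algorithm.

    Weights are symmetrized as the pair's positive delta — the strength
    of the ordering evidence irrespective of direction — and each
    selected edge keeps its original direction. Disconnected inputs
    yield a maximum spanning forest; weight ties break lexicographically
    on the sorted node pair for reproducibility.
    """
    if net.variant != "full":
        raise ValueError("the spanning tree is built from the full network")
    und: dict[frozenset[str], tuple[float, str, str]] = {}
    for u, v, w in net.graph.edges(data="weight"):
        und[frozenset((u, v))] = (w, u, v)
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in net.graph.nodes}
    for (w, u, v) in und.values():
        adj[u].append((v, w))
        adj[v].append((u, w))

    tree = nx.DiGraph()
    tree.add_nodes_from(net.graph.nodes)
    visited: set[str] = set()
    for start in sorted(net.graph.nodes):
        if start in visited:
            continue
        visited.add(start)
        # heap keyed by (-weight, sorted endpoint pair) => max weight,
        # lexicographic tie-break
        heap: list[tuple[float, tuple[str, str], str, str]] = []

        def push(u: str) -> None:
            for v, w in adj[u]:
                if v not in visited:
                    heapq.heappush(heap, (-w, tuple(sorted((u, v))), u, v))

        push(start)
        while heap:
            negw, _, u, v = heapq.heappop(heap)
            if v in visited:
                continue
            visited.add(v)
            src, dst = (u, v) if net.graph.has_edge(u, v) else (v, u)
            tree.add_edge(src, dst, weight=-negw)
            push(v)
    return TimeOrderNetwork(tree, "mwst")


def find_incoming_edge_hubs(net: TimeOrderNetwork, top: int = 10) -> list[HubReport]:
    """Nodes with only incoming edges, sorted by in-degree descending.

    The more incoming edges such a node has, the later its inferred
    response; ties break alphabetically on gene id.
    """
    g = net.graph
    hubs = [
        HubReport(n, g.in_degree(n), 0)
        for n in g.nodes
        if g.out_degree(n) == 0 and g.in_degree(n) >= 1
    ]
    hubs.sort(key=lambda h: (-h.in_degree, h.gene_id))
    return hubs[:top]


@dataclass(frozen=True)
class TrendCall:
    """Late-window expression trend of a fitted gene.

    ``late_mean`` is the average fitted LCR over [K2, t_max]; its sign
    sets the label. ``boundary`` flags an exactly-zero mean, where the
    label defaults to "underexpressed" but carries no evidence.
    """

    trend: str
    late_mean: float
    boundary: bool = False


def classify_trend(fit: SplineFit) -> TrendCall:
    """Label a gene over- or underexpressed from its late-interval mean LCR."""
    k = fit.knots
    curve = integrate_spline(fit)
    area = evaluate_cumulative(curve, k.t_max) - evaluate_cumulative(curve, k.k2)
    mean = float(area) / (k.t_max - k.k2)
    if mean > 0:
        return TrendCall("overexpressed", mean)
    if mean < 0:
        return TrendCall("underexpressed", mean)
    return TrendCall("underexpressed", 0.0, boundary=True)


def export_network(net: TimeOrderNetwork, fmt: str, path: str | Path) -> None:
    """Write the network as an edge-list TSV, GraphML, or DOT digraph."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in net.edges():
                fh.write(f"{u}\t{v}\t{w:.12g}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("digraph dton {\n")
            for n in sorted(net.graph.nodes):
                fh.write(f'  "{n}";\n')
            for u, v, w in net.edges():
                fh.write(f'  "{u}" -> "{v}" [weight={w:.12g}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (expected tsv, graphml or dot)")


def import_network_tsv(path: str | Path, variant: str = "full") -> TimeOrderNetwork:
    """Read an edge-list TSV written by :func:`export_network`."""
    g = nx.DiGraph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source", "target", "weight"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            g.add_edge(u, v, weight=float(w))
    return TimeOrderNetwork(g, variant)
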