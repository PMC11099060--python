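"""Multiplex network assembly and basic topology.

A multiplex network is a set of interaction layers (e.g. protein-protein
binary interactions, molecular complexes, pathway co-membership) sharing one
node universe; a gene may be isolated within any single layer.  Connectivity
is evaluated on the aggregated graph — the union of all layer edge sets — so
that the largest connected component matches the reachability of a walker
allowed to switch layer at any node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .gene_sets import canonical_symbol

log = logging.getLogger(__name__)


def _edge(a: str, b: str) -> tuple:
    """Canonical undirected edge representation (sorted 2-tuple)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Layer:
    """One interaction layer: a named simple undirected edge set."""

    name: str
    edges: frozenset

    @property
    def endpoints(self) -> frozenset:
        return frozenset(n for e in self.edges for n in e)

    def graph(self, nodes: Iterable[str] = ()) -> nx.Graph:
        g = nx.Graph(name=self.name)
        g.add_nodes_from(nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class MultiplexNetwork:
    """Ordered layers over a shared node universe."""

    nodes: frozenset
    layers: tuple

    @property
    def layer_names(self) -> tuple:
        return tuple(layer.name for layer in self.layers)

    def layer_graphs(self) -> list:
        return [layer.graph(self.nodes) for layer in self.layers]


@dataclass(frozen=True)
class AggregatedNetwork:
    """Union of the layers as a single graph; each edge tagged with the layers supporting it."""

    graph: nx.Graph

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_layers(self, a: str, b: str) -> tuple:
        return self.graph.edges[a, b]["layers"]


@dataclass(frozen=True)
class InducedSubnetwork:
    """Induced subgraph plus the query members absent from the parent network."""

    network: AggregatedNetwork
    absent: tuple


def read_layer(path, name: str) -> Layer:
    """Read a TSV edge list into a layer.

    The first two columns are gene symbols; extra columns (e.g. weights) are
    ignored with a warning; self-loops are dropped; duplicate rows collapse.
    A row with fewer than two columns is a hard error naming the line.
    """
    edges = set()
    extra_cols = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"{path}: line {lineno} has fewer than 2 columns")
        if len(fields) > 2:
            extra_cols = True
        a, b = canonical_symbol(fields[0]), canonical_symbol(fields[1])
        if a == b:
            continue
        edges.add(_edge(a, b))
    if extra_cols:
        log.warning("%s: extra columns ignored (graphs are unweighted)", path)
    return Layer(name=name, edges=frozenset(edges))


def build_multiplex(layers: Iterable[Layer]) -> MultiplexNetwork:
    """Assemble layers over the union of their endpoints as shared node set."""
    layers = tuple(layers)
    if not layers:
        raise ValueError("a multiplex network needs at least one layer")
    nodes = frozenset().union(*(layer.endpoints for layer in layers))
    return MultiplexNetwork(nodes=nodes, layers=layers)


def aggregate(mx: MultiplexNetwork) -> AggregatedNetwork:
    """Merge the layers into one graph, recording edge provenance."""
    g = nx.Graph()
    g.add_nodes_from(mx.nodes)
    for layer in mx.layers:
        for a, b in layer.edges:
            if g.has_edge(a, b):
                g.edges[a, b]["layers"] = g.edges[a, b]["layers"] + (layer.name,)
            else:
                g.add_edge(a, b, layers=(layer.name,))
    return AggregatedNetwork(graph=g)


def split_layers(net: AggregatedNetwork, layer_names: Iterable[str]) -> dict:
    """Re-split an aggregated network by its provenance tags (inverse of aggregate)."""
    out = {name: set() for name in layer_names}
    for a, b, data in net.graph.edges(data=True):
        for name in data["layers"]:
            out[name].add(_edge(a, b))
    return {name: frozenset(edges) for name, edges in out.items()}


def largest_connected_component(mx: MultiplexNetwork) -> MultiplexNetwork:
    """Restrict the multiplex to the largest component of its aggregated graph.

    Ties between equally sized components are broken toward the component
    containing the lexicographically smallest node.
    """
    if not mx.nodes:
        raise ValueError("empty multiplex network")
    agg = aggregate(mx).graph
    keep = None
    for comp in nx.connected_components(agg):
        comp = set(comp)
        if keep is None or len(comp) > len(keep) or (
            len(comp) == len(keep) and min(comp) < min(keep)
        ):
            keep = comp
    layers = tuple(
        Layer(
            name=layer.name,
            edges=frozenset(e for e in layer.edges if e[0] in keep and e[1] in keep),
        )
        for layer in mx.layers
    )
    return MultiplexNetwork(nodes=frozenset(keep), layers=layers)


def induced_subnetwork(net: AggregatedNetwork, genes: Iterable[str]) -> InducedSubnetwork:
    """Induce the subgraph on ``genes``; isolated members stay as disconnected nodes.

    Query members absent from the parent network are not dropped silently:
    they are returned in ``absent`` (sorted).
    """
    genes = {canonical_symbol(g) for g in genes}
    present = genes & set(net.graph.nodes)
    absent = tuple(sorted(genes - present))
    if absent:
        log.warning("%d gene(s) not in network: %s", len(absent), ", ".join(absent))
    sub = nx.Graph(net.graph.subgraph(present))
    sub.add_nodes_from(present)
    return InducedSubnetwork(network=AggregatedNetwork(graph=sub), absent=absent)


def closeness_centrality(net: AggregatedNetwork) -> dict:
    """Per-component closeness: 1 / mean shortest-path distance to the component.

    Matches the NetworkAnalyzer convention: values are not rescaled by
    component size relative to the whole graph, and isolated nodes score 0.
    """
    return nx.closeness_centrality(net.graph, wf_improved=False)


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_components: int
    component_sizes: tuple
    component_diameters: tuple
    density: float
    degree_min: int
    degree_mean: float
    degree_max: int


def summarize_network(net: AggregatedNetwork) -> NetworkSummary:
    """Node/edge counts, per-component diameters, density and degree statistics."""
    g = net.graph
    n = g.number_of_nodes()
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c))) if n else []
    diameters = tuple(nx.diameter(g.subgraph(c)) if len(c) > 1 else 0 for c in comps)
    degrees = [d for _, d in g.degree()]
    return NetworkSummary(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        n_components=len(comps),
        component_sizes=tuple(len(c) for c in comps),
        component_diameters=diameters,
        density=nx.density(g) if n else 0.0,
        degree_min=min(degrees) if degrees else 0,
        degree_mean=(sum(degrees) / n) if n else 0.0,
        degree_max=max(degrees) if degrees else 0,
    )


# ---------------------------------------------------------------------------
# Export (Cytoscape-compatible)

def write_graphml(net: AggregatedNetwork, path, node_groups: dict = None) -> None:
    """GraphML export; edge attribute = supporting layers, node attribute = group."""
    g = nx.Graph()
    for node in net.graph.nodes:
        g.add_node(node, group=(node_groups or {}).get(node, ""))
    for a, b, data in net.graph.edges(data=True):
        g.add_edge(a, b, layers=",".join(data.get("layers", ())))
    nx.write_graphml(g, path)


def write_sif(net: AggregatedNetwork, path) -> None:
    """SIF export; the interaction type column carries the supporting layers."""
    lines = []
    connected = set()
    for a, b, data in sorted(net.graph.edges(data=True)):
        rel = "|".join(data.get("layers", ("interacts",)))
        lines.append(f"{a}\t{rel}\t{b}")
        connected.update((a, b))
    for node in sorted(set(net.graph.nodes) - connected):
        lines.append(node)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
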