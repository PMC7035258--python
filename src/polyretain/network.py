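"""Ortholog projection of a reference interaction network and its statistics.

"Equivalent replacement": a reference interaction (a, b) induces a projected
edge (x, y) for every x orthologous to a and y orthologous to b — the
ortholog map may be many-to-many, so a gene retained in multiple copies
after polyploidy multiplies its interactions.  Edges are undirected, simple
(deduplicated, no self-loops); nodes are the genes incident to at least one
projected edge, optionally annotated with the polyploidy events they derive
from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Network",
    "NetworkStats",
    "project_network",
    "network_stats",
    "event_specific_nodes",
]


@dataclass
class Network:
    """Undirected simple graph with per-node annotations."""

    edges: set[tuple[str, str]] = field(default_factory=set)
    annotations: dict[str, dict] = field(default_factory=dict)

    @staticmethod
    def from_edges(edges: Iterable[tuple[str, str]]) -> "Network":
        net = Network()
        for a, b in edges:
            net.add_edge(a, b)
        return net

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            return
        self.edges.add((a, b) if a < b else (b, a))

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    max_degree: int
    max_degree_node: str | None
    edge_node_ratio: float  # 0 for an empty network


def project_network(
    reference_edges: Iterable[tuple[str, str]],
    ortholog_map: Mapping[str, Iterable[str]],
    annotations: Mapping[str, Mapping] | None = None,
) -> Network:
    """Expand each reference edge over the ortholog sets of its endpoints.

    Symmetric in edge endpoints and independent of input edge order; genes
    with an empty (or missing) ortholog set contribute nothing.
    """
    net = Network()
    orth = {k: sorted(set(v)) for k, v in ortholog_map.items()}
    for a, b in reference_edges:
        for x in orth.get(a, ()):
            for y in orth.get(b, ()):
                net.add_edge(x, y)
    if annotations:
        for node in net.nodes:
            if node in annotations:
                net.annotations[node] = dict(annotations[node])
    return net


def network_stats(net: Network) -> NetworkStats:
    nodes = net.nodes
    if not nodes:
        return NetworkStats(0, 0, 0, None, 0.0)
    deg = net.degree()
    max_node = min((n for n in deg if deg[n] == max(deg.values())))
    return NetworkStats(
        n_nodes=len(nodes),
        n_edges=len(net.edges),
        max_degree=deg[max_node],
        max_degree_node=max_node,
        edge_node_ratio=round(len(net.edges) / len(nodes), 2),
    )


def event_specific_nodes(net: Network) -> dict[frozenset[str], int]:
    """Partition event-annotated nodes by their exact event set (Venn regions).

    Region counts sum to the number of nodes carrying a non-empty
    ``event_set`` annotation.
    """
    venn: dict[frozenset[str], int] = {}
    for node in net.nodes:
        evs = frozenset(net.annotations.get(node, {}).get("event_set", ()))
        if evs:
            venn[evs] = venn.get(evs, 0) + 1
    return venn
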