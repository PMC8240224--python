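"""Local descriptors of a protein-interaction edge list.

Node count, edge count, average node degree (2E/N over the declared
node set, isolated nodes counting with degree 0) and average local
clustering coefficient (degree-<2 nodes contribute 0).  Edge lists are
user-supplied files; no interaction service is queried.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .model import ValidationError


@dataclass(frozen=True)
class GraphSummary:
    nodes: int
    edges: int
    average_degree: float
    average_local_clustering: float


def _build_graph(
    edge_list: Iterable[tuple[str, str]], node_list: Sequence[str] | None = None
) -> nx.Graph:
    g = nx.Graph()
    declared = set(node_list) if node_list is not None else None
    if declared is not None:
        g.add_nodes_from(declared)
    for u, v in edge_list:
        if u == v:
            raise ValidationError(f"self-loop on node {u!r}")
        if declared is not None and (u not in declared or v not in declared):
            raise ValidationError(
                f"edge ({u!r}, {v!r}) names a node outside the declared node list"
            )
        g.add_edge(u, v)  # duplicates collapse in a simple graph
    return g


def graph_summary(
    edge_list: Iterable[tuple[str, str]], node_list: Sequence[str] | None = None
) -> GraphSummary:
    """Summarize an undirected simple graph.

    ``average_degree * N == 2 * E`` exactly before rounding; an empty
    graph reports all zeros.
    """
    g = _build_graph(edge_list, node_list)
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        return GraphSummary(0, 0, 0.0, 0.0)
    clustering = nx.clustering(g)  # degree < 2 -> 0.0
    # fsum over sorted node names: insertion-order independent
    total_c = math.fsum(clustering[v] for v in sorted(g.nodes()))
    return GraphSummary(
        nodes=n,
        edges=e,
        average_degree=2.0 * e / n,
        average_local_clustering=total_c / n,
    )


def subnetwork_by_selection(
    edge_list: Iterable[tuple[str, str]], selected_symbols: Iterable[str]
) -> list[tuple[str, str]]:
    """Edge list of the subgraph induced on the selected symbols."""
    keep = set(selected_symbols)
    g = _build_graph(edge_list)
    sub = g.subgraph(keep)
    return sorted(tuple(sorted(e)) for e in sub.edges())
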