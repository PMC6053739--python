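"""Phase-specific co-expression graphs, topology metrics, and degree
weights.

Each phase's network has an edge wherever the pair classifier found a
significant signed correlation; isolated genes from the node universe are
kept as degree-0 nodes so cross-phase topology is computed over a common
vertex set.  Gene importance is the sigmoid of the degree,
w = 1 / (1 + exp(-degree)), mapping connectivity into (0, 1); genes
outside the network inherit the minimum in-network weight.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "TopologySummary",
    "topology_metrics",
    "degree_weight",
    "degree_weights",
    "network_edges",
]


def build_network(
    pairs: pd.DataFrame,
    phase: str | None = None,
    node_universe: Iterable[str] | None = None,
) -> nx.Graph:
    """Build an undirected signed graph from a classified pair table.

    Edges are exactly the rows classed positive/negative (attributes
    ``r`` and ``sign``); duplicate rows collapse to one edge.  Universe
    genes without any edge are retained as isolated nodes.
    """
    g = nx.Graph(phase=phase)
    if node_universe is not None:
        g.add_nodes_from(node_universe)
    sig = pairs[pairs["class"].isin(("positive", "negative"))]
    for a, b, r, cls in zip(sig["gene_a"], sig["gene_b"], sig["r"], sig["class"]):
        if a == b:
            continue
        g.add_edge(a, b, r=float(r), sign=cls)
    return g


@dataclasses.dataclass
class TopologySummary:
    """The four topology metrics of one phase network.

    avg_shortest_path averages unweighted distances over ordered reachable
    node pairs (components of size >= 2 only).  Closeness uses the
    Wasserman–Faust component scaling, closeness(v) =
    ((reachable_v - 1) / sum of distances) * ((reachable_v - 1) / (n - 1)),
    so fragmented graphs stay comparable.  Clustering is the usual local
    transitivity, 0 for degree < 2.
    """
    phase: str | None
    n_nodes: int
    n_edges: int
    avg_shortest_path: float
    degree: dict[str, int]
    closeness: dict[str, float]
    clustering: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        nodes = sorted(self.degree)
        return pd.DataFrame({
            "gene": nodes,
            "degree": [self.degree[n] for n in nodes],
            "closeness": [self.closeness[n] for n in nodes],
            "clustering": [self.clustering[n] for n in nodes],
        })


def topology_metrics(net: nx.Graph) -> TopologySummary:
    """Degree, closeness, clustering and average shortest path of a graph."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network: no nodes")
    total_dist = 0
    n_pairs = 0
    for _, lengths in nx.all_pairs_shortest_path_length(net):
        total_dist += sum(lengths.values())   # self distance contributes 0
        n_pairs += len(lengths) - 1
    aslp = total_dist / n_pairs if n_pairs else float("nan")
    if n_pairs == 0:
        logger.warning("edgeless network: average shortest path undefined")
    return TopologySummary(
        phase=net.graph.get("phase"),
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        avg_shortest_path=aslp,
        degree=dict(net.degree()),
        closeness=nx.closeness_centrality(net, wf_improved=True),
        clustering=nx.clustering(net),
    )


def degree_weight(degree: int | np.ndarray) -> float | np.ndarray:
    """Sigmoid degree weight, 1 / (1 + e^-degree)."""
    return expit(degree)


def degree_weights(
    net: nx.Graph, universe: Iterable[str]
) -> pd.DataFrame:
    """Map every universe gene to a (0,1) weight from its network degree.

    In-network genes get sigmoid(degree); universe genes absent from the
    network get the minimum weight observed in the network (0.5 whenever
    any node is isolated).  An empty network weights everything at
    sigmoid(0) = 0.5.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty gene universe")
    degrees = dict(net.degree())
    if not degrees:
        logger.warning("empty network: all %d genes weighted 0.5", len(universe))
        floor = 0.5
    else:
        floor = float(expit(min(degrees.values())))
    rows = []
    for gene in universe:
        if gene in degrees:
            d = degrees[gene]
            rows.append((gene, d, float(expit(d))))
        else:
            rows.append((gene, pd.NA, floor))
    return pd.DataFrame(rows, columns=["gene", "degree", "weight"]) \
        .set_index("gene")


def network_edges(net: nx.Graph) -> pd.DataFrame:
    """Export the edge set as a sorted (gene_a, gene_b, r, sign) table."""
    rows = sorted(
        (min(a, b), max(a, b), d.get("r", np.nan), d.get("sign", ""))
        for a, b, d in net.edges(data=True)
    )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign"])
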