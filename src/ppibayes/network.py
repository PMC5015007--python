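"""High-confidence weighted interaction network from posterior scores."""

from __future__ import annotations

from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .types import PosteriorScores

__all__ = ["WeightedNetwork", "threshold_network", "degree"]


class WeightedNetwork:
    """Simple undirected graph whose edge weights are posterior probabilities."""

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted((min(u, v), max(u, v), d["weight"])
                      for u, v, d in self.graph.edges(data=True))
        return pd.DataFrame(rows, columns=["protein_a", "protein_b",
                                           "posterior"])

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "WeightedNetwork":
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.protein_a, row.protein_b,
                       weight=float(row.posterior))
        return WeightedNetwork(g)


def threshold_network(scores: PosteriorScores, tau: float = 0.8,
                      keep_isolated: bool = False,
                      universe: Optional[Iterable[str]] = None
                      ) -> WeightedNetwork:
    """Keep pairs whose posterior strictly exceeds ``tau``.

    A pair scoring exactly ``tau`` is excluded.  By default only proteins
    incident to a kept edge become nodes; with ``keep_isolated`` the full
    ``universe`` (or every scored protein) is retained as isolated nodes.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must lie in [0, 1]")
    g = nx.Graph()
    if keep_isolated:
        if universe is not None:
            g.add_nodes_from(universe)
        else:
            for (a, b) in scores.scores:
                g.add_node(a)
                g.add_node(b)
    for (a, b), s in scores.items():
        if s > tau:
            g.add_edge(a, b, weight=s)
    return WeightedNetwork(g)


def degree(network: WeightedNetwork, protein: str) -> int:
    """Number of incident edges (unweighted)."""
    if protein not in network.graph:
        raise KeyError(f"protein {protein!r} not in network")
    return int(network.graph.degree[protein])
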