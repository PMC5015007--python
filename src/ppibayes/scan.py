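"""SCAN structural clustering and modularity-based epsilon selection.

SCAN grows clusters from core vertices whose neighbourhoods are
structurally similar, and classifies the remaining vertices as hubs
(bridging two or more clusters) or outliers.  The clustering threshold
epsilon is chosen by sweeping a grid and maximizing the similarity-based
modularity Q_S; the plain modularity Q_N is computed alongside for the
diagnostic curve.  Clustering is purely topological: posterior edge weights
play no role in the structural similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .network import WeightedNetwork

__all__ = ["ModulePartition", "structural_similarity", "scan_cluster",
           "modularity_QN", "modularity_QS", "select_epsilon"]


@dataclass
class ModulePartition:
    """SCAN output: module labels plus hub/outlier classification."""

    labels: Dict[str, int]          # clustered node -> 1..n_modules
    hubs: Set[str]
    outliers: Set[str]
    epsilon: float
    mu: int
    q_n: float = float("nan")
    q_s: float = float("nan")

    def n_modules(self) -> int:
        return max(self.labels.values()) if self.labels else 0

    def modules(self) -> Dict[int, Set[str]]:
        out: Dict[int, Set[str]] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, set()).add(node)
        return out

    def all_nodes(self) -> Set[str]:
        return set(self.labels) | self.hubs | self.outliers

    def communities(self) -> List[Set[str]]:
        """Modules plus singleton communities for hubs and outliers."""
        comms = [m for _, m in sorted(self.modules().items())]
        comms += [{v} for v in sorted(self.hubs | self.outliers)]
        return comms


def structural_similarity(network: WeightedNetwork, u: str, v: str) -> float:
    """Normalized overlap of closed neighbourhoods,
    ``|G(u) & G(v)| / sqrt(|G(u)| |G(v)|)`` with ``G(x) = {x} + neighbours(x)``.
    """
    g = network.graph
    for w in (u, v):
        if w not in g:
            raise KeyError(f"protein {w!r} not in network")
    gu = set(g.neighbors(u)) | {u}
    gv = set(g.neighbors(v)) | {v}
    return len(gu & gv) / math.sqrt(len(gu) * len(gv))


def _edge_similarities(network: WeightedNetwork) -> Dict[Tuple[str, str], float]:
    g = network.graph
    closed = {x: set(g.neighbors(x)) | {x} for x in g.nodes}
    sig = {}
    for u, v in g.edges:
        a, b = (u, v) if u <= v else (v, u)
        sig[(a, b)] = len(closed[u] & closed[v]) / math.sqrt(
            len(closed[u]) * len(closed[v]))
    return sig


def scan_cluster(network: WeightedNetwork, epsilon: float,
                 mu: int = 2) -> ModulePartition:
    """Partition a network into structure-connected clusters.

    A node is a core if at least ``mu`` of its neighbours have structural
    similarity >= ``epsilon``; clusters are grown from cores through
    epsilon-similar neighbour links (deterministic given sorted node
    order).  Unclustered nodes adjacent to two or more clusters are hubs,
    the rest outliers.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if mu < 2:
        raise ValueError("mu must be >= 2")
    g = network.graph
    sig = _edge_similarities(network)

    def s(u, v):
        return sig[(u, v) if u <= v else (v, u)]

    nodes = sorted(g.nodes)
    eps_nb = {u: [v for v in sorted(g.neighbors(u)) if s(u, v) >= epsilon]
              for u in nodes}
    core = {u for u in nodes if len(eps_nb[u]) >= mu}

    labels: Dict[str, int] = {}
    next_label = 1
    for seed in nodes:
        if seed not in core or seed in labels:
            continue
        lab = next_label
        next_label += 1
        labels[seed] = lab
        queue = [seed]
        while queue:
            w = queue.pop(0)
            if w not in core:
                continue
            for v in eps_nb[w]:
                if v not in labels:
                    labels[v] = lab
                    queue.append(v)

    hubs: Set[str] = set()
    outliers: Set[str] = set()
    for u in nodes:
        if u in labels:
            continue
        seen = {labels[v] for v in g.neighbors(u) if v in labels}
        (hubs if len(seen) >= 2 else outliers).add(u)
    return ModulePartition(labels=labels, hubs=hubs, outliers=outliers,
                           epsilon=epsilon, mu=mu)


def _check_cover(network: WeightedNetwork, partition: ModulePartition) -> None:
    if network.number_of_nodes() == 0:
        raise ValueError("modularity of an empty network is undefined")
    missing = set(network.nodes) - partition.all_nodes()
    if missing:
        raise ValueError(f"partition does not cover nodes {sorted(missing)[:3]}")


def modularity_QN(network: WeightedNetwork,
                  partition: ModulePartition) -> float:
    """Newman modularity: within-module edge fraction minus the degree-based
    expectation, summed over modules (hubs/outliers enter as singletons)."""
    _check_cover(network, partition)
    g = network.graph
    L = g.number_of_edges()
    if L == 0:
        return 0.0
    q = 0.0
    for comm in partition.communities():
        ls = sum(1 for u, v in g.edges(comm) if u in comm and v in comm)
        ds = sum(g.degree[u] for u in comm if u in g)
        q += ls / L - (ds / (2.0 * L)) ** 2
    return q


def modularity_QS(network: WeightedNetwork,
                  partition: ModulePartition) -> float:
    """Similarity-based modularity: the analogue of Q_N with every edge
    weighted by its structural similarity."""
    _check_cover(network, partition)
    g = network.graph
    sig = _edge_similarities(network)
    ts = sum(sig.values())
    if ts == 0.0:
        return 0.0
    wdeg: Dict[str, float] = {u: 0.0 for u in g.nodes}
    for (a, b), w in sig.items():
        wdeg[a] += w
        wdeg[b] += w
    q = 0.0
    for comm in partition.communities():
        is_s = sum(w for (a, b), w in sig.items()
                   if a in comm and b in comm)
        ds_s = sum(wdeg[u] for u in comm if u in wdeg)
        q += is_s / ts - (ds_s / (2.0 * ts)) ** 2
    return q


def select_epsilon(network: WeightedNetwork,
                   grid: Sequence[float] = tuple(
                       round(0.05 + 0.01 * k, 2) for k in range(91)),
                   mu: int = 2):
    """Cluster at every epsilon on the grid and pick the Q_S maximizer.

    Returns ``(best_epsilon, partitions, qn_curve, qs_curve)`` where the
    curves are lists aligned with the grid and ties break toward the
    smallest epsilon.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("epsilon grid must be non-empty")
    partitions: List[ModulePartition] = []
    qn_curve: List[float] = []
    qs_curve: List[float] = []
    best_eps, best_qs = None, -math.inf
    for eps in grid:
        part = scan_cluster(network, eps, mu)
        part.q_n = modularity_QN(network, part)
        part.q_s = modularity_QS(network, part)
        partitions.append(part)
        qn_curve.append(part.q_n)
        qs_curve.append(part.q_s)
        if part.q_s > best_qs:
            best_eps, best_qs = eps, part.q_s
    return best_eps, partitions, qn_curve, qs_curve
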