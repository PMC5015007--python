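"""Hypergeometric association of modules with intrinsically disordered
proteins (IDPs) and hub-composition analysis.

An IDP is a protein whose longest continuous disordered region exceeds
40 amino acids.  Each module of size n containing m IDPs is tested against
the network background (N proteins, M IDPs) with the hypergeometric upper
tail; the raw p-values are compared with the significance level directly
(no multiplicity correction by default, Benjamini-Hochberg behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Set

import pandas as pd
from scipy import stats as sps

from .network import WeightedNetwork
from .scan import ModulePartition

logger = logging.getLogger(__name__)

__all__ = ["DisorderAnnotation", "EnrichmentResult", "hypergeom_pvalue",
           "test_modules", "hub_idp_fraction", "IDP_LENGTH_CUTOFF",
           "HUB_DEGREE_CUTOFF"]

IDP_LENGTH_CUTOFF = 40   # strict: disordered region must exceed 40 aa
HUB_DEGREE_CUTOFF = 5    # strict: a hub has more than 5 neighbours


@dataclass
class DisorderAnnotation:
    """Longest continuous intrinsically disordered region per protein (aa)."""

    lengths: Dict[str, int]

    def __post_init__(self) -> None:
        for p, ln in self.lengths.items():
            if ln < 0:
                raise ValueError(f"negative disorder length for {p}")

    def is_idp(self, protein: str) -> bool:
        return self.lengths.get(protein, 0) > IDP_LENGTH_CUTOFF

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "DisorderAnnotation":
        return DisorderAnnotation(dict(zip(
            df["protein_id"], df["longest_disorder_length"].astype(int))))


@dataclass
class EnrichmentResult:
    module: int
    n: int            # module size
    m: int            # IDPs in the module
    p_value: float
    significant: bool


def hypergeom_pvalue(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric probability of drawing >= m successes.

    ``p = sum_{i=m}^{min(n, M)} C(M, i) C(N-M, n-i) / C(N, n)`` — the
    chance that n draws without replacement from a population of N with M
    successes contain at least m successes.
    """
    if not (0 <= m <= n <= N) or not (0 <= M <= N):
        raise ValueError(f"invalid hypergeometric arguments "
                         f"N={N} M={M} n={n} m={m}")
    if m == 0:
        return 1.0
    return float(sps.hypergeom.sf(m - 1, N, M, n))


def test_modules(partition: ModulePartition,
                 annotation: DisorderAnnotation,
                 alpha: float = 0.05,
                 correction: Optional[str] = None) -> List[EnrichmentResult]:
    """One hypergeometric test per module against the network background.

    The background is the clustered network itself (all partitioned nodes,
    including hubs and outliers).  Unannotated proteins are treated as
    non-IDPs with a warning.  ``correction="bh"`` applies Benjamini-
    Hochberg to the p-values before the significance call.
    """
    nodes = sorted(partition.all_nodes())
    missing = [p for p in nodes if p not in annotation.lengths]
    if missing:
        logger.warning("%d proteins lack disorder annotation; treated as "
                       "non-IDP (e.g. %s)", len(missing), missing[:3])
    N = len(nodes)
    M = sum(1 for p in nodes if annotation.is_idp(p))
    results: List[EnrichmentResult] = []
    for label, members in sorted(partition.modules().items()):
        n = len(members)
        m = sum(1 for p in members if annotation.is_idp(p))
        p = hypergeom_pvalue(N, M, n, m)
        results.append(EnrichmentResult(module=label, n=n, m=m, p_value=p,
                                        significant=False))
    pvals = [r.p_value for r in results]
    if correction == "bh" and pvals:
        adjusted = sps.false_discovery_control(pvals, method="bh")
        for r, q in zip(results, adjusted):
            r.significant = bool(q < alpha)
    elif correction is None:
        for r in results:
            r.significant = bool(r.p_value < alpha)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return results


def hub_idp_fraction(network: WeightedNetwork, module_nodes: Iterable[str],
                     annotation: DisorderAnnotation,
                     hub_degree: int = HUB_DEGREE_CUTOFF) -> float:
    """Fraction of hub nodes of a module-induced subgraph that are IDPs.

    Hubs are nodes whose degree in the induced subgraph strictly exceeds
    ``hub_degree``; raises if the subgraph has no hubs.
    """
    module_nodes = set(module_nodes)
    missing = module_nodes - set(network.nodes)
    if missing:
        raise KeyError(f"module nodes not in network: {sorted(missing)[:3]}")
    sub = network.graph.subgraph(module_nodes)
    hubs = [u for u in sub.nodes if sub.degree[u] > hub_degree]
    if not hubs:
        raise ValueError("no hubs: no node exceeds the degree cutoff")
    return sum(1 for u in hubs if annotation.is_idp(u)) / len(hubs)


def results_to_frame(results: List[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {"module": [r.module for r in results],
         "n": [r.n for r in results],
         "m": [r.m for r in results],
         "p_value": [r.p_value for r in results],
         "significant": [r.significant for r in results]})
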