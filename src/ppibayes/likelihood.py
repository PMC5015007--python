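"""Per-source probability models and the complete log likelihood.

This is the reference implementation of the generative model: every factor
is written out directly, one evidence record at a time.  The Monte Carlo EM
machinery in :mod:`ppibayes.mcem` uses a vectorized sampler instead; the two
routes are cross-checked against each other in the test suite.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Dict, FrozenSet, Iterable, Set, Tuple

import pandas as pd

from .types import (HUMAN, EvidenceError, EvidenceSet, LatentState, Pair,
                    ParameterVector, canonical_pair)

__all__ = [
    "y2h_response_prob", "complex_log_likelihood", "literature_log_prob",
    "transfer_prob", "prior_log_prob", "complete_log_likelihood",
    "joint_identity", "transfer_links",
]

_LOG_EPS = 1e-300  # guard for log(0) on degenerate parameters


def _log(p: float) -> float:
    return math.log(p) if p > 0.0 else math.log(_LOG_EPS)


def _expit(t: float) -> float:
    if t >= 0:
        return 1.0 / (1.0 + math.exp(-t))
    e = math.exp(t)
    return e / (1.0 + e)


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return math.log(p / (1.0 - p))


def y2h_response_prob(z: int, x_i: int, x_j: int,
                      theta: ParameterVector,
                      self_activation: str = "exponent") -> float:
    """Probability that a single Y2H replicate reports positive.

    Three mechanisms can fire the reporter: (a) a true interaction, with
    probability ``alpha_I`` when ``z=1``; (b) self-activation, with
    probability ``alpha_S`` per self-activating partner (``exponent`` mode
    uses the literal exponent ``x_i + x_j``; ``indicator`` mode collapses it
    to ``1[x_i + x_j > 0]``); (c) an unknown process, ``alpha_U``.  The
    replicate is positive if at least one mechanism fires.
    """
    xs = x_i + x_j
    if self_activation == "indicator":
        xs = min(xs, 1)
    elif self_activation != "exponent":
        raise ValueError(f"unknown self_activation mode {self_activation!r}")
    return 1.0 - ((1.0 - theta.alpha_I) ** z
                  * (1.0 - theta.alpha_S) ** xs
                  * (1.0 - theta.alpha_U))


def neighbourhoods(adjacency: Dict[str, Set[str]],
                   bait: str) -> Tuple[Set[str], Set[str]]:
    """1-step and 2-step neighbour sets of a bait (self excluded)."""
    n1 = set(adjacency.get(bait, ()))
    n2: Set[str] = set()
    for v in n1:
        n2.update(adjacency.get(v, ()))
    n2 -= n1
    n2.discard(bait)
    return n1, n2


def _adjacency(zmap: Dict[Pair, int]) -> Dict[str, Set[str]]:
    adj: Dict[str, Set[str]] = {}
    for (a, b), v in zmap.items():
        if v:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    return adj


def complex_log_likelihood(bait: str, observed: Iterable[str],
                           state: LatentState, theta: ParameterVector,
                           organism: str = HUMAN) -> float:
    """Log probability of one pulled-down complex given the latent graph.

    Each 1-step neighbour of the bait is captured independently with
    probability ``psi1``, each 2-step neighbour with ``psi2``.  An observed
    member at distance >= 3 (or unreachable) contributes a fixed background
    factor ``psi_bg``; unobserved distant proteins contribute no factor.
    """
    zmap = state.z_of(organism)
    if bait not in state.x_of(organism):
        raise EvidenceError(f"bait {bait!r} not in the {organism} universe")
    observed = set(observed) - {bait}
    adj = _adjacency(zmap)
    n1, n2 = neighbourhoods(adj, bait)
    ll = 0.0
    ll += len(n1 & observed) * _log(theta.psi1)
    ll += len(n1 - observed) * _log(1.0 - theta.psi1)
    ll += len(n2 & observed) * _log(theta.psi2)
    ll += len(n2 - observed) * _log(1.0 - theta.psi2)
    ll += len(observed - n1 - n2) * _log(theta.psi_bg)
    return ll


def literature_log_prob(observed: int, z: int,
                        rate_pos: float, rate_neg: float) -> float:
    """Log probability of a literature report indicator.

    ``Pr[report = 1 | z] = rate_pos^z * rate_neg^(1-z)``; channel H uses
    (gamma1, gamma0) and channel L uses (beta1, beta0).
    """
    p1 = rate_pos if z else rate_neg
    return _log(p1) if observed else _log(1.0 - p1)


def transfer_prob(z_human: int, identity_arg: float, mode: str,
                  theta: ParameterVector,
                  parameterization: str = "constant") -> float:
    """Probability that a latent status transfers to an orthologous unit.

    ``mode="interaction"`` gives ``Pr[Z*=1 | Z=z]`` using (phi1, phi0) and a
    joint identity argument; ``mode="self_activation"`` gives
    ``Pr[X*=1 | X=x]`` using (lambda1, lambda0) and a single identity.

    Parameterizations: ``constant`` ignores the identity (the form the
    complete likelihood uses); ``logistic`` makes the rate a monotone
    increasing function of identity,
    ``expit(logit(rate) + transfer_slope * (identity - 0.5))``.
    """
    if mode == "interaction":
        rate = theta.phi1 if z_human else theta.phi0
    elif mode == "self_activation":
        rate = theta.lambda1 if z_human else theta.lambda0
    else:
        raise ValueError(f"unknown transfer mode {mode!r}")
    if parameterization == "constant":
        return rate
    if parameterization == "logistic":
        if not (0.0 <= identity_arg <= 1.0):
            raise ValueError("identity must lie in [0, 1]")
        return _expit(_logit(rate) + theta.transfer_slope * (identity_arg - 0.5))
    raise ValueError(f"unknown parameterization {parameterization!r}")


def joint_identity(identity_a: float, identity_b: float) -> float:
    """Joint sequence identity of a pair of ortholog pairs (geometric mean)."""
    return math.sqrt(identity_a * identity_b)


def prior_log_prob(state: LatentState, theta: ParameterVector) -> float:
    """Log prior of the human latent state: independent Bernoulli factors."""
    lr, l1r = _log(theta.rho), _log(1.0 - theta.rho)
    ls, l1s = _log(theta.r), _log(1.0 - theta.r)
    ll = 0.0
    for v in state.z.values():
        ll += lr if v else l1r
    for v in state.x.values():
        ll += ls if v else l1s
    return ll


def transfer_links(homology: pd.DataFrame):
    """Enumerate pair-of-pair transfer factors implied by a homology map.

    Yields ``(organism, human_pair, star_pair, joint_identity)`` for every
    combination of two homology rows of the same organism with distinct
    human proteins and distinct orthologs.
    """
    if homology is None or not len(homology):
        return
    for org, grp in homology.groupby("organism", sort=True):
        rows = sorted(zip(grp["human"], grp["ortholog"],
                          grp["identity"].astype(float)))
        for i in range(len(rows)):
            hi, oi, ii = rows[i]
            for j in range(i + 1, len(rows)):
                hj, oj, ij = rows[j]
                if hi == hj or oi == oj:
                    continue
                yield (str(org), canonical_pair(hi, hj),
                       canonical_pair(oi, oj), joint_identity(ii, ij))


def complete_log_likelihood(state: LatentState, evidence: EvidenceSet,
                            theta: ParameterVector,
                            self_activation: str = "exponent",
                            transfer_parameterization: str = "constant") -> float:
    """Complete log likelihood of latent state plus all observed evidence.

    Sums the log factors of every Y2H replicate (human and starred), every
    pulled-down complex, both literature channels, the cross-organism
    transfer factors for Z* and X*, and the Bernoulli priors on (Z, X).
    """
    uni = evidence.universe
    ll = prior_log_prob(state, theta)

    # Y2H replicates, any organism
    for row in evidence.y2h.itertuples(index=False):
        org = uni.organism[row.a]
        pair = canonical_pair(row.a, row.b)
        z = state.z_of(org)[pair]
        xmap = state.x_of(org)
        th = theta.for_source(str(row.source_id))
        p = y2h_response_prob(z, xmap[row.a], xmap[row.b], th,
                              self_activation)
        ll += _log(p) if row.observed else _log(1.0 - p)

    # pulled-down complexes, any organism
    for rec in evidence.complexes:
        org = uni.organism[rec.bait]
        th = theta.for_source(rec.experiment_id)
        ll += complex_log_likelihood(rec.bait, rec.members, state, th, org)

    # literature channels (human only)
    for row in evidence.literature.itertuples(index=False):
        z = state.z[canonical_pair(row.a, row.b)]
        if row.channel == "H":
            ll += literature_log_prob(int(row.observed), z,
                                      theta.gamma1, theta.gamma0)
        else:
            ll += literature_log_prob(int(row.observed), z,
                                      theta.beta1, theta.beta0)

    # cross-organism transfer factors
    for org, hpair, spair, jid in transfer_links(evidence.homology):
        zs = state.star[org].z.get(spair)
        if zs is None:
            continue
        p = transfer_prob(state.z[hpair], jid, "interaction", theta,
                          transfer_parameterization)
        ll += _log(p) if zs else _log(1.0 - p)
    if len(evidence.homology):
        for row in evidence.homology.itertuples(index=False):
            org = str(row.organism)
            xs = state.star[org].x.get(row.ortholog)
            if xs is None:
                continue
            p = transfer_prob(state.x[row.human], float(row.identity),
                              "self_activation", theta,
                              transfer_parameterization)
            ll += _log(p) if xs else _log(1.0 - p)
    return ll
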