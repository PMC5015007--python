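"""Forward simulation of ground truth and all four evidence types.

The generator follows the same generative model the inference machinery
assumes: latent interactions are independent Bernoulli draws (optionally
with planted dense communities), Y2H replicates fire through the
true-interaction / self-activation / unknown mechanisms, pull-down
complexes capture 1- and 2-step neighbours of a bait, literature channels
report with separate true/false positive rates, and starred organisms are
obtained by identity-annotated ortholog transfer.  Disorder annotations can
be planted at an elevated rate inside chosen communities so that the
enrichment stage has a known positive control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (HUMAN, ComplexRecord, EvidenceSet, LatentState,
                    OrganismState, ParameterVector, ProteinUniverse,
                    canonical_pair)

__all__ = ["SimulationConfig", "SimulatedData", "default_true_theta",
           "sample_ground_truth", "sample_evidence", "sample_disorder",
           "simulate_dataset", "universe_for"]


def default_true_theta() -> ParameterVector:
    """Default generating parameters.

    Assay parameters follow published estimates for an integrated human PPI
    corpus (rho=0.014, r=8.9e-5, alpha_I=0.933, alpha_S=0.852,
    alpha_U=0.007, psi1=0.809, psi2=0.788); report and transfer rates, which
    no table prints, are set to plausible interior values.
    """
    return ParameterVector(
        rho=0.014, r=8.9e-5,
        alpha_I=0.933, alpha_S=0.852, alpha_U=0.007,
        psi1=0.809, psi2=0.788,
        gamma1=0.8, gamma0=0.01,
        beta1=0.7, beta0=0.02,
        phi1=0.7, phi0=0.05,
        lambda1=0.7, lambda0=0.05,
    )


@dataclass
class SimulationConfig:
    """Study conditions for one simulated data set."""

    n_proteins: int = 300
    theta_true: ParameterVector = field(default_factory=default_true_theta)
    n_y2h_replicates: int = 2
    y2h_coverage: float = 1.0
    n_baits: Optional[int] = None          # default: n_proteins // 5
    lit_coverage: float = 1.0
    n_homolog_organisms: int = 1
    homolog_fraction: float = 0.5
    identity_range: Tuple[float, float] = (0.3, 1.0)
    community_sizes: Tuple[int, ...] = ()
    rho_within: float = 0.6
    n_idp_communities: int = 0
    idp_rate_planted: float = 0.9
    idp_rate_background: float = 0.375
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.y2h_coverage <= 1.0):
            raise ValueError("y2h_coverage must lie in [0, 1]")
        if not (0.0 <= self.lit_coverage <= 1.0):
            raise ValueError("lit_coverage must lie in [0, 1]")
        if self.n_proteins <= 0 or self.n_y2h_replicates <= 0:
            raise ValueError("counts must be positive")
        if sum(self.community_sizes) > self.n_proteins:
            raise ValueError("community sizes exceed n_proteins")
        if self.n_idp_communities > len(self.community_sizes):
            raise ValueError("n_idp_communities exceeds number of communities")

    @property
    def effective_n_baits(self) -> int:
        return self.n_baits if self.n_baits is not None \
            else max(1, self.n_proteins // 5)


@dataclass
class SimulatedData:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    universe: ProteinUniverse
    truth: LatentState
    evidence: EvidenceSet
    disorder: pd.DataFrame
    communities: List[List[str]]


# ---------------------------------------------------------------------------
# deterministic naming and homology layout
# ---------------------------------------------------------------------------

def _human_ids(n: int) -> List[str]:
    width = max(4, len(str(n - 1)))
    return [f"H{i:0{width}d}" for i in range(n)]


def _organisms(config: SimulationConfig) -> List[str]:
    return [f"org{k + 1}" for k in range(config.n_homolog_organisms)]


def _homology_map(config: SimulationConfig) -> pd.DataFrame:
    """One ortholog per mapped human protein, per organism (deterministic)."""
    humans = _human_ids(config.n_proteins)
    lo, hi = config.identity_range
    rows = []
    for k, org in enumerate(_organisms(config)):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1, k]))
        mapped = rng.random(config.n_proteins) < config.homolog_fraction
        idents = rng.uniform(lo, hi, size=config.n_proteins)
        for i in np.flatnonzero(mapped):
            rows.append((humans[i], f"{org}:{humans[i]}", org,
                         float(idents[i])))
    return pd.DataFrame(rows, columns=["human", "ortholog", "organism",
                                       "identity"])


def universe_for(config: SimulationConfig) -> ProteinUniverse:
    humans = _human_ids(config.n_proteins)
    proteins = list(humans)
    organisms = [HUMAN] * len(humans)
    hom = _homology_map(config)
    for row in hom.itertuples(index=False):
        proteins.append(row.ortholog)
        organisms.append(row.organism)
    return ProteinUniverse(proteins, organisms)


def _community_members(config: SimulationConfig) -> List[List[str]]:
    humans = _human_ids(config.n_proteins)
    out, start = [], 0
    for size in config.community_sizes:
        out.append(humans[start:start + size])
        start += size
    return out


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def sample_ground_truth(config: SimulationConfig) -> LatentState:
    """Draw (Z, X) and, via ortholog transfer, every (Z*, X*)."""
    theta = config.theta_true
    n = config.n_proteins
    humans = _human_ids(n)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    iu, ju = np.triu_indices(n, 1)
    prob = np.full(iu.shape, theta.rho)
    comm_label = np.full(n, -1)
    start = 0
    for c, size in enumerate(config.community_sizes):
        comm_label[start:start + size] = c
        start += size
    same = (comm_label[iu] >= 0) & (comm_label[iu] == comm_label[ju])
    prob[same] = config.rho_within
    zvec = (rng.random(iu.shape) < prob).astype(np.int8)
    xvec = (rng.random(n) < theta.r).astype(np.int8)

    z = {(humans[i], humans[j]): int(v)
         for i, j, v in zip(iu, ju, zvec)}
    x = {humans[i]: int(xvec[i]) for i in range(n)}

    hom = _homology_map(config)
    star: Dict[str, OrganismState] = {}
    for k, (org, grp) in enumerate(hom.groupby("organism", sort=True)):
        rng_o = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2, k]))
        h2o = dict(zip(grp["human"], grp["ortholog"]))
        mapped = sorted(h2o)
        zs: Dict[Tuple[str, str], int] = {}
        for a_idx in range(len(mapped)):
            for b_idx in range(a_idx + 1, len(mapped)):
                hp = canonical_pair(mapped[a_idx], mapped[b_idx])
                rate = theta.phi1 if z[hp] else theta.phi0
                sp = canonical_pair(h2o[hp[0]], h2o[hp[1]])
                zs[sp] = int(rng_o.random() < rate)
        xs = {h2o[h]: int(rng_o.random() < (theta.lambda1 if x[h]
                                            else theta.lambda0))
              for h in mapped}
        star[str(org)] = OrganismState(zs, xs)
    return LatentState(z, x, star)


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def _zmap_arrays(zmap: Dict[Tuple[str, str], int],
                 proteins: Sequence[str]) -> Tuple[np.ndarray, np.ndarray,
                                                   np.ndarray, np.ndarray]:
    """Vectorize a pair->z dict over sorted proteins (triu order)."""
    n = len(proteins)
    iu, ju = np.triu_indices(n, 1)
    z = np.fromiter((zmap[canonical_pair(proteins[i], proteins[j])]
                     for i, j in zip(iu, ju)),
                    dtype=np.int8, count=len(iu))
    return iu, ju, z, np.asarray(proteins, dtype=object)


def _y2h_frame(rng, proteins, iu, ju, z, xvec, theta, config, source_id,
               rows_out):
    cov = rng.random(len(iu)) < config.y2h_coverage
    if not cov.any():
        return
    ii, jj, zz = iu[cov], ju[cov], z[cov]
    xs = xvec[ii] + xvec[jj]
    p = 1.0 - ((1.0 - theta.alpha_I) ** zz
               * (1.0 - theta.alpha_S) ** xs
               * (1.0 - theta.alpha_U))
    for t in range(1, config.n_y2h_replicates + 1):
        obs = (rng.random(len(ii)) < p).astype(int)
        rows_out.append(pd.DataFrame({
            "a": proteins[ii], "b": proteins[jj],
            "source_id": source_id, "replicate": t, "observed": obs}))


def _mpc_complexes(rng, proteins, iu, ju, z, theta, n_baits, tag, out):
    n = len(proteins)
    adj = np.zeros((n, n), dtype=bool)
    adj[iu, ju] = z.astype(bool)
    adj |= adj.T
    deg = adj.sum(axis=1)
    candidates = np.flatnonzero(deg > 0)
    if len(candidates) == 0 or n_baits <= 0:
        return
    baits = rng.choice(candidates, size=min(n_baits, len(candidates)),
                       replace=False)
    two = (adj @ adj) > 0
    for b_no, b in enumerate(sorted(baits)):
        n1 = adj[b]
        n2 = two[b] & ~adj[b]
        n2[b] = False
        take = (n1 & (rng.random(n) < theta.psi1)) \
            | (n2 & (rng.random(n) < theta.psi2))
        members = frozenset(proteins[m] for m in np.flatnonzero(take))
        out.append(ComplexRecord(bait=str(proteins[b]), members=members,
                                 experiment_id=f"mpc_{tag}_{b_no}"))


def sample_evidence(truth: LatentState, config: SimulationConfig) -> EvidenceSet:
    """Draw every evidence type from a ground-truth latent state.

    A fixed config seed gives byte-identical output.  Baits are drawn
    uniformly from proteins with at least one true neighbour.
    """
    theta = config.theta_true
    uni = universe_for(config)
    humans = _human_ids(config.n_proteins)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    iu, ju, z, parr = _zmap_arrays(truth.z, humans)
    xvec = np.array([truth.x[p] for p in humans], dtype=np.int8)

    y2h_rows: List[pd.DataFrame] = []
    complexes: List[ComplexRecord] = []
    _y2h_frame(rng, parr, iu, ju, z, xvec, theta, config, "y2h_human",
               y2h_rows)
    _mpc_complexes(rng, parr, iu, ju, z, theta, config.effective_n_baits,
                   HUMAN, complexes)

    # literature channels over covered human pairs
    lit_rows = []
    for channel, pos, neg in (("H", theta.gamma1, theta.gamma0),
                              ("L", theta.beta1, theta.beta0)):
        cov = rng.random(len(iu)) < config.lit_coverage
        if cov.any():
            zz = z[cov]
            obs = (rng.random(int(cov.sum()))
                   < np.where(zz == 1, pos, neg)).astype(int)
            lit_rows.append(pd.DataFrame({
                "a": parr[iu[cov]], "b": parr[ju[cov]],
                "channel": channel, "observed": obs}))
    literature = pd.concat(lit_rows, ignore_index=True) if lit_rows else None

    # starred organisms: Y2H and MPC from the starred truth
    for org in sorted(truth.star):
        ostate = truth.star[org]
        sprots = sorted(ostate.x)
        if len(sprots) < 2:
            continue
        siu, sju, sz, sparr = _zmap_arrays(ostate.z, sprots)
        sx = np.array([ostate.x[p] for p in sprots], dtype=np.int8)
        _y2h_frame(rng, sparr, siu, sju, sz, sx, theta, config,
                   f"y2h_{org}", y2h_rows)
        nb = max(1, round(config.effective_n_baits * len(sprots)
                          / config.n_proteins))
        _mpc_complexes(rng, sparr, siu, sju, sz, theta, nb, org, complexes)

    y2h = pd.concat(y2h_rows, ignore_index=True) if y2h_rows else None
    return EvidenceSet.build(uni, y2h=y2h, literature=literature,
                             complexes=complexes,
                             homology=_homology_map(config))


def sample_disorder(config: SimulationConfig) -> pd.DataFrame:
    """Longest-continuous-disordered-region lengths per human protein.

    Proteins in the first ``n_idp_communities`` planted communities are
    intrinsically disordered (region > 40 aa) at rate ``idp_rate_planted``;
    everything else at ``idp_rate_background``.  IDP lengths are uniform on
    41..300 aa, non-IDP lengths uniform on 0..40 aa.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    humans = _human_ids(config.n_proteins)
    rate = np.full(config.n_proteins, config.idp_rate_background)
    start = 0
    for c, size in enumerate(config.community_sizes):
        if c < config.n_idp_communities:
            rate[start:start + size] = config.idp_rate_planted
        start += size
    is_idp = rng.random(config.n_proteins) < rate
    length = np.where(is_idp, rng.integers(41, 301, config.n_proteins),
                      rng.integers(0, 41, config.n_proteins))
    return pd.DataFrame({"protein_id": humans,
                         "longest_disorder_length": length.astype(int)})


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Ground truth, evidence and disorder annotation in one call."""
    truth = sample_ground_truth(config)
    evidence = sample_evidence(truth, config)
    disorder = sample_disorder(config)
    return SimulatedData(config=config, universe=evidence.universe,
                         truth=truth, evidence=evidence, disorder=disorder,
                         communities=_community_members(config))
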