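"""Domain types for the evidence-integration model.

The model treats the true pairwise interaction status ``Z_ij`` of human
proteins and the self-activation status ``X_i`` of each protein as latent
Bernoulli variables.  Observed evidence — yeast two-hybrid (Y2H) replicates,
mass-spec pull-down complexes (MPC), literature reports, and evidence on
orthologous proteins in other organisms — is modelled conditionally on the
latent state with the parameter vector defined in :class:`ParameterVector`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HUMAN = "human"

Pair = Tuple[str, str]

#: components of theta that are re-estimated by the M-step (psi_bg is fixed)
ESTIMATED_COMPONENTS = (
    "rho", "r",
    "alpha_I", "alpha_S", "alpha_U",
    "psi1", "psi2",
    "gamma1", "gamma0",
    "beta1", "beta0",
    "phi1", "phi0",
    "lambda1", "lambda0",
)

#: (positive-rate, negative-rate) pairs whose ordering is enforced after
#: estimation to resolve label switching
RATE_PAIRS = (("gamma1", "gamma0"), ("beta1", "beta0"),
              ("phi1", "phi0"), ("lambda1", "lambda0"))


class EvidenceError(ValueError):
    """Raised when evidence records are inconsistent with the universe."""


def canonical_pair(a: str, b: str) -> Pair:
    """Canonical (sorted) ordering of an unordered protein pair."""
    if a == b:
        raise EvidenceError(f"self-pair ({a},{a}) is not a valid pair")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ParameterVector:
    """The model parameter vector theta.

    Defaults are the weakly informative interior values used to initialize
    the Monte Carlo EM fit.

    Attributes
    ----------
    rho : prior probability that a human pair truly interacts.
    r : prior probability that a protein is a self-activator.
    alpha_I, alpha_S, alpha_U : probabilities that a single Y2H replicate
        fires through the true-interaction / self-activation / unknown
        mechanism.  The reporter is positive if at least one mechanism fires:
        ``Pr[Y=1|z, x_i, x_j] = 1 - (1-alpha_I)^z (1-alpha_S)^(x_i+x_j) (1-alpha_U)``.
    psi1, psi2 : probability that a 1-step / 2-step neighbour of an MPC bait
        is captured in the pulled-down complex.
    psi_bg : fixed background capture probability for observed complex
        members at graph distance >= 3 from the bait (not estimated).
    gamma1, gamma0 : literature true/false positive report rates, channel H.
    beta1, beta0 : same for channel L.
    phi1, phi0 : cross-organism interaction transfer rates
        (``Pr[Z*=1 | Z=z]`` in the constant parameterization).
    lambda1, lambda0 : cross-organism self-activation transfer rates.
    transfer_slope : slope of the optional logistic transfer parameterization
        (monotone dependence on sequence identity); unused in constant mode.
    overrides : optional per-source parameter table, ``{source_id: {name: value}}``;
        honoured by the reference likelihood only.
    """

    rho: float = 0.005
    r: float = 1e-4
    alpha_I: float = 0.5
    alpha_S: float = 0.3
    alpha_U: float = 0.01
    psi1: float = 0.7
    psi2: float = 0.3
    psi_bg: float = 1e-3
    gamma1: float = 0.7
    gamma0: float = 0.05
    beta1: float = 0.7
    beta0: float = 0.05
    phi1: float = 0.7
    phi0: float = 0.05
    lambda1: float = 0.7
    lambda0: float = 0.05
    transfer_slope: float = 2.0
    overrides: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ESTIMATED_COMPONENTS + ("psi_bg",):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"parameter {name}={v} outside [0, 1]")
        if self.transfer_slope < 0:
            raise ValueError("transfer_slope must be >= 0")

    def for_source(self, source_id: Optional[str]) -> "ParameterVector":
        """Effective parameters for one data source (per-source overrides)."""
        if source_id is None or source_id not in self.overrides:
            return self
        return replace(self, overrides={}, **self.overrides[source_id])

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in ESTIMATED_COMPONENTS])

    def to_dict(self) -> Dict[str, float]:
        return {c: float(getattr(self, c)) for c in ESTIMATED_COMPONENTS}

    def diff(self, other: "ParameterVector") -> float:
        """Maximum absolute componentwise change (the MCEM ``diff``)."""
        return float(np.max(np.abs(self.as_array() - other.as_array())))

    def clipped(self, eps: float = 1e-6) -> "ParameterVector":
        """Clip every estimated component into [eps, 1-eps]."""
        kw = {c: float(min(max(getattr(self, c), eps), 1.0 - eps))
              for c in ESTIMATED_COMPONENTS}
        return replace(self, **kw)

    def with_rate_ordering(self) -> "ParameterVector":
        """Swap (pos, neg) rate pairs violating pos > neg (identifiability)."""
        kw = {}
        for pos, neg in RATE_PAIRS:
            p, q = getattr(self, pos), getattr(self, neg)
            if p < q:
                kw[pos], kw[neg] = q, p
        return replace(self, **kw) if kw else self


# ---------------------------------------------------------------------------
# universe and latent state
# ---------------------------------------------------------------------------

class ProteinUniverse:
    """Ordered collection of protein identifiers with an organism tag each."""

    def __init__(self, proteins: Iterable[str], organisms: Iterable[str]):
        self.proteins: List[str] = list(proteins)
        self.organism: Dict[str, str] = dict(zip(self.proteins, organisms))
        if len(self.organism) != len(self.proteins):
            raise EvidenceError("protein identifiers must be unique")
        self.index: Dict[str, int] = {p: i for i, p in enumerate(self.proteins)}

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, protein: str) -> bool:
        return protein in self.index

    def organisms(self) -> List[str]:
        seen: Dict[str, None] = {}
        for p in self.proteins:
            seen.setdefault(self.organism[p], None)
        return list(seen)

    def proteins_of(self, organism: str) -> List[str]:
        return [p for p in self.proteins if self.organism[p] == organism]

    def require(self, protein: str) -> None:
        if protein not in self.index:
            raise EvidenceError(f"unknown protein identifier {protein!r}")


@dataclass
class OrganismState:
    """Latent state restricted to one non-human organism."""

    z: Dict[Pair, int]
    x: Dict[str, int]


@dataclass
class LatentState:
    """The unobserved interaction matrix Z and self-activation vector X.

    ``z`` maps canonical human pairs to {0,1}; ``x`` maps human proteins to
    {0,1}.  ``star`` holds the analogous maps for each non-human organism,
    defined only on proteins/pairs covered by the homology mapping.
    """

    z: Dict[Pair, int]
    x: Dict[str, int]
    star: Dict[str, OrganismState] = field(default_factory=dict)

    @staticmethod
    def zeros(universe: ProteinUniverse,
              homology: Optional[pd.DataFrame] = None) -> "LatentState":
        """All-zero latent state over a universe (star domains from homology)."""
        humans = universe.proteins_of(HUMAN)
        z = {canonical_pair(a, b): 0
             for i, a in enumerate(humans) for b in humans[i + 1:]}
        x = {p: 0 for p in humans}
        star: Dict[str, OrganismState] = {}
        if homology is not None and len(homology):
            for org, grp in homology.groupby("organism", sort=True):
                prots = sorted(set(grp["ortholog"]))
                zs = {canonical_pair(a, b): 0
                      for i, a in enumerate(prots) for b in prots[i + 1:]}
                xs = {p: 0 for p in prots}
                star[str(org)] = OrganismState(zs, xs)
        return LatentState(z, x, star)

    def z_of(self, organism: str) -> Dict[Pair, int]:
        return self.z if organism == HUMAN else self.star[organism].z

    def x_of(self, organism: str) -> Dict[str, int]:
        return self.x if organism == HUMAN else self.star[organism].x

    def neighbours(self, organism: str, protein: str) -> FrozenSet[str]:
        """1-step neighbours of a protein under this state's Z."""
        zmap = self.z_of(organism)
        out = set()
        for (a, b), v in zmap.items():
            if v:
                if a == protein:
                    out.add(b)
                elif b == protein:
                    out.add(a)
        return frozenset(out)


# ---------------------------------------------------------------------------
# evidence records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Y2HRecord:
    pair: Pair
    source_id: str
    replicate: int
    observed: int


@dataclass(frozen=True)
class ComplexRecord:
    bait: str
    members: FrozenSet[str]
    experiment_id: str

    def __post_init__(self) -> None:
        if self.bait in self.members:
            object.__setattr__(self, "members",
                               frozenset(self.members) - {self.bait})


@dataclass(frozen=True)
class LiteratureRecord:
    pair: Pair
    channel: str  # "H" or "L"
    observed: int


@dataclass
class EvidenceSet:
    """All observed evidence, indexed against a protein universe.

    Frames
    ------
    y2h : columns ``a, b, source_id, replicate, observed`` (any organism;
        both endpoints of a pair must share an organism).
    literature : columns ``a, b, channel, observed`` (human pairs only).
    complexes : list of :class:`ComplexRecord` (bait's organism implied).
    homology : columns ``human, ortholog, organism, identity``.
    """

    universe: ProteinUniverse
    y2h: pd.DataFrame
    literature: pd.DataFrame
    complexes: List[ComplexRecord]
    homology: pd.DataFrame

    @staticmethod
    def build(universe: ProteinUniverse,
              y2h: Optional[pd.DataFrame] = None,
              literature: Optional[pd.DataFrame] = None,
              complexes: Optional[List[ComplexRecord]] = None,
              homology: Optional[pd.DataFrame] = None) -> "EvidenceSet":
        y2h = _empty_frame(y2h, ["a", "b", "source_id", "replicate", "observed"])
        literature = _empty_frame(literature, ["a", "b", "channel", "observed"])
        homology = _empty_frame(homology, ["human", "ortholog", "organism",
                                           "identity"])
        complexes = list(complexes or [])
        ev = EvidenceSet(universe, y2h, literature, complexes, homology)
        ev._validate()
        return ev

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        uni = self.universe
        self.y2h = _canonicalize_pairs(self.y2h, "y2h")
        self.literature = _canonicalize_pairs(self.literature, "literature")
        for df, what in ((self.y2h, "y2h"), (self.literature, "literature")):
            for col in ("a", "b"):
                for p in df[col].unique():
                    uni.require(p)
            if len(df) and not df["observed"].isin((0, 1)).all():
                raise EvidenceError(f"{what} observed values must be 0/1")
        if len(self.y2h):
            orgs_a = self.y2h["a"].map(uni.organism)
            orgs_b = self.y2h["b"].map(uni.organism)
            if not (orgs_a == orgs_b).all():
                raise EvidenceError("y2h pair endpoints span organisms")
            for (_, _, _), grp in self.y2h.groupby(["a", "b", "source_id"]):
                reps = sorted(grp["replicate"])
                if reps != list(range(1, len(reps) + 1)):
                    raise EvidenceError(
                        f"y2h replicate indices not contiguous from 1: {reps}")
        if len(self.literature):
            if not self.literature["channel"].isin(("H", "L")).all():
                raise EvidenceError("literature channel must be 'H' or 'L'")
            bad = self.literature.duplicated(["a", "b", "channel"])
            if bad.any():
                raise EvidenceError("duplicate literature record per (pair, channel)")
            non_human = [p for p in pd.concat([self.literature["a"],
                                               self.literature["b"]]).unique()
                         if uni.organism[p] != HUMAN]
            if non_human:
                raise EvidenceError(f"literature records on non-human proteins: "
                                    f"{non_human[:3]}")
        for rec in self.complexes:
            uni.require(rec.bait)
            org = uni.organism[rec.bait]
            for m in rec.members:
                uni.require(m)
                if uni.organism[m] != org:
                    raise EvidenceError(
                        f"complex member {m} not from bait organism {org}")
        if len(self.homology):
            for p in self.homology["human"].unique():
                uni.require(p)
                if uni.organism[p] != HUMAN:
                    raise EvidenceError(f"homology 'human' column has {p}")
            for p in self.homology["ortholog"].unique():
                uni.require(p)
            ident = self.homology["identity"].astype(float)
            if ((ident < 0) | (ident > 1)).any():
                raise EvidenceError("sequence identities must lie in [0, 1]")
        self._check_star_mapped()

    def _check_star_mapped(self) -> None:
        """Starred evidence must live on proteins covered by the homology map."""
        mapped = set(self.homology["ortholog"]) if len(self.homology) else set()
        orgs = self.universe.organism
        for df in (self.y2h,):
            for p in pd.concat([df["a"], df["b"]]).unique() if len(df) else []:
                if orgs[p] != HUMAN and p not in mapped:
                    raise EvidenceError(
                        f"starred protein {p} has no homology mapping")
        for rec in self.complexes:
            if orgs[rec.bait] != HUMAN:
                for p in {rec.bait} | set(rec.members):
                    if p not in mapped:
                        raise EvidenceError(
                            f"starred protein {p} has no homology mapping")

    # -- views -------------------------------------------------------------

    def star_organisms(self) -> List[str]:
        if not len(self.homology):
            return []
        return sorted(set(self.homology["organism"]))

    def restrict(self, kinds: Iterable[str]) -> "EvidenceSet":
        """Keep only the named evidence kinds.

        Kinds: ``y2h`` (human Y2H), ``mpc`` (human complexes), ``literature``
        (channels H and L), ``homolog`` (homology map plus all starred
        evidence).
        """
        kinds = set(kinds)
        unknown = kinds - {"y2h", "mpc", "literature", "homolog"}
        if unknown:
            raise ValueError(f"unknown evidence kinds: {sorted(unknown)}")
        orgs = self.universe.organism
        y2h = self.y2h
        human_mask = y2h["a"].map(orgs).eq(HUMAN) if len(y2h) else None
        parts = []
        if len(y2h):
            if "y2h" in kinds:
                parts.append(y2h[human_mask])
            if "homolog" in kinds:
                parts.append(y2h[~human_mask])
        new_y2h = pd.concat(parts, ignore_index=True) if parts else None
        new_lit = self.literature if "literature" in kinds else None
        new_cpx = [c for c in self.complexes
                   if (orgs[c.bait] == HUMAN and "mpc" in kinds)
                   or (orgs[c.bait] != HUMAN and "homolog" in kinds)]
        new_hom = self.homology if "homolog" in kinds else None
        return EvidenceSet.build(self.universe, new_y2h, new_lit, new_cpx,
                                 new_hom)


def _empty_frame(df: Optional[pd.DataFrame], cols: List[str]) -> pd.DataFrame:
    if df is None or not len(df):
        return pd.DataFrame({c: [] for c in cols})
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise EvidenceError(f"evidence frame missing columns {missing}")
    return df[cols].reset_index(drop=True)


def _canonicalize_pairs(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Order each pair canonically; drop self-pairs with a warning."""
    if not len(df):
        return df
    selfp = df["a"] == df["b"]
    if selfp.any():
        logger.warning("dropping %d self-pair %s record(s) (homodimers are "
                       "excluded from the model)", int(selfp.sum()), what)
        df = df[~selfp].reset_index(drop=True)
    a = df["a"].where(df["a"] < df["b"], df["b"])
    b = df["b"].where(df["a"] < df["b"], df["a"])
    out = df.copy()
    out["a"], out["b"] = a, b
    return out


# ---------------------------------------------------------------------------
# posterior scores
# ---------------------------------------------------------------------------

@dataclass
class PosteriorScores:
    """Per-pair estimates of Pr[Z_ij = 1 | all evidence]."""

    scores: Dict[Pair, float]

    def __post_init__(self) -> None:
        for pair, s in self.scores.items():
            if not (0.0 <= s <= 1.0) or math.isnan(s):
                raise ValueError(f"posterior for {pair} outside [0,1]: {s}")

    def __len__(self) -> int:
        return len(self.scores)

    def get(self, a: str, b: str) -> float:
        return self.scores[canonical_pair(a, b)]

    def items(self):
        return self.scores.items()

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.scores.items())
        return pd.DataFrame(
            {"protein_a": [p[0] for p, _ in rows],
             "protein_b": [p[1] for p, _ in rows],
             "posterior": [s for _, s in rows]})
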