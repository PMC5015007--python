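"""Flat-array representation of an evidence set for the Gibbs sampler.

Pairs of each organism are laid out in upper-triangular order over that
organism's (lexicographically sorted) proteins, matching the canonical pair
ordering used by :class:`ppibayes.types.LatentState`.  Starred pair/protein
variables of all organisms are concatenated into flat vectors so the human
sweep can read its transfer children through one CSR index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .likelihood import transfer_links
from .types import (HUMAN, EvidenceSet, LatentState, OrganismState,
                    ParameterVector, canonical_pair)

_EMPTY_PTR = np.zeros(1, dtype=np.int64)
_EMPTY_IDX = np.zeros(0, dtype=np.int64)
_EMPTY_I8 = np.zeros(0, dtype=np.int8)


def pair_index(i: int, j: int, n: int) -> int:
    """Triangular index of pair (i < j) among C(n,2) pairs."""
    return i * (2 * n - i - 1) // 2 + (j - i - 1)


def _csr(keys: np.ndarray, values: np.ndarray, n: int):
    keys = np.asarray(keys, dtype=np.int64)
    values = np.asarray(values, dtype=np.int64)
    order = np.argsort(keys, kind="stable")
    counts = np.bincount(keys, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, values[order]


@dataclass
class OrgBlock:
    """Static (theta-independent) structure of one organism's evidence."""

    name: str
    proteins: List[str]
    ypos: np.ndarray
    ytot: np.ndarray
    hobs: np.ndarray         # int8 per pair, -1 = absent (human only)
    lobs: np.ndarray
    cplx_bait: np.ndarray    # int64[nc]
    obs: np.ndarray          # bool[nc, n]
    crow_indptr: np.ndarray  # protein -> complex rows where it is bait
    crow_idx: np.ndarray
    xp_indptr: np.ndarray    # protein -> (partner, pair) with Y2H evidence
    xp_j: np.ndarray
    xp_p: np.ndarray
    par_indptr: np.ndarray   # star only: local pair -> human pair indices
    par_idx: np.ndarray
    xpar_indptr: np.ndarray  # star only: local protein -> human protein idx
    xpar_idx: np.ndarray
    offset: int = 0          # slice start in the flat starred arrays
    xoffset: int = 0

    @property
    def n(self) -> int:
        return len(self.proteins)

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2


@dataclass
class PackedState:
    """Mutable Gibbs state: latent vectors plus derived graph matrices."""

    z_h: np.ndarray
    X_h: np.ndarray
    zs_flat: np.ndarray
    xs_flat: np.ndarray
    adj: List[np.ndarray]
    cn: List[np.ndarray]


@dataclass
class PackedProblem:
    human: OrgBlock
    stars: List[OrgBlock]
    child_indptr: np.ndarray   # human pair -> flat star pair indices
    child_idx: np.ndarray
    xchild_indptr: np.ndarray  # human protein -> flat star protein indices
    xchild_idx: np.ndarray
    link_par: np.ndarray       # flat transfer links (pair level)
    link_child: np.ndarray
    xlink_par: np.ndarray      # flat transfer links (protein level)
    xlink_child: np.ndarray
    iu: np.ndarray             # human triu indices (convenience)
    ju: np.ndarray

    @property
    def n_star_pairs(self) -> int:
        return sum(b.n_pairs for b in self.stars)

    @property
    def n_star_prot(self) -> int:
        return sum(b.n for b in self.stars)

    def new_state(self) -> PackedState:
        blocks = [self.human] + self.stars
        return PackedState(
            z_h=np.zeros(self.human.n_pairs, dtype=np.int8),
            X_h=np.zeros(self.human.n, dtype=np.int8),
            zs_flat=np.zeros(self.n_star_pairs, dtype=np.int8),
            xs_flat=np.zeros(self.n_star_prot, dtype=np.int8),
            adj=[np.zeros((b.n, b.n), dtype=np.bool_) for b in blocks],
            cn=[np.zeros((b.n, b.n), dtype=np.int16) for b in blocks],
        )

    def star_slices(self, state: PackedState):
        for k, b in enumerate(self.stars):
            yield (b,
                   state.zs_flat[b.offset:b.offset + b.n_pairs],
                   state.xs_flat[b.xoffset:b.xoffset + b.n],
                   state.adj[k + 1], state.cn[k + 1])

    def export_state(self, state: PackedState) -> LatentState:
        hp = self.human.proteins
        z = {}
        p = 0
        for i in range(len(hp) - 1):
            for j in range(i + 1, len(hp)):
                z[(hp[i], hp[j])] = int(state.z_h[p])
                p += 1
        x = {hp[i]: int(state.X_h[i]) for i in range(len(hp))}
        star = {}
        for b, zs, xs, _, _ in self.star_slices(state):
            sz = {}
            p = 0
            for i in range(b.n - 1):
                for j in range(i + 1, b.n):
                    sz[(b.proteins[i], b.proteins[j])] = int(zs[p])
                    p += 1
            star[b.name] = OrganismState(
                sz, {b.proteins[i]: int(xs[i]) for i in range(b.n)})
        return LatentState(z, x, star)


def _aggregate_pairwise(block_proteins, idx, df, n):
    """ypos/ytot per pair from a y2h frame restricted to one organism."""
    n_pairs = n * (n - 1) // 2
    ypos = np.zeros(n_pairs, dtype=np.int32)
    ytot = np.zeros(n_pairs, dtype=np.int32)
    if df is None or not len(df):
        return ypos, ytot
    ai = df["a"].map(idx).to_numpy(dtype=np.int64)
    bi = df["b"].map(idx).to_numpy(dtype=np.int64)
    p = ai * (2 * n - ai - 1) // 2 + (bi - ai - 1)
    np.add.at(ytot, p, 1)
    np.add.at(ypos, p, df["observed"].to_numpy(dtype=np.int32))
    return ypos, ytot


def _partner_csr(ypos, ytot, n):
    pmask = np.flatnonzero(ytot > 0)
    if len(pmask) == 0:
        return (np.zeros(n + 1, dtype=np.int64), _EMPTY_IDX, _EMPTY_IDX)
    iu, ju = np.triu_indices(n, 1)
    ii, jj = iu[pmask], ju[pmask]
    keys = np.concatenate([ii, jj])
    partners = np.concatenate([jj, ii])
    pidx = np.concatenate([pmask, pmask])
    order = np.argsort(keys, kind="stable")
    counts = np.bincount(keys, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, partners[order].astype(np.int64), pidx[order].astype(np.int64)


def _build_block(name, proteins, idx, y2h_df, lit_df, complexes) -> OrgBlock:
    n = len(proteins)
    n_pairs = n * (n - 1) // 2
    ypos, ytot = _aggregate_pairwise(proteins, idx, y2h_df, n)

    if lit_df is not None and len(lit_df):
        hobs = np.full(n_pairs, -1, dtype=np.int8)
        lobs = np.full(n_pairs, -1, dtype=np.int8)
        for chan, arr in (("H", hobs), ("L", lobs)):
            sub = lit_df[lit_df["channel"] == chan]
            if len(sub):
                ai = sub["a"].map(idx).to_numpy(dtype=np.int64)
                bi = sub["b"].map(idx).to_numpy(dtype=np.int64)
                p = ai * (2 * n - ai - 1) // 2 + (bi - ai - 1)
                arr[p] = sub["observed"].to_numpy(dtype=np.int8)
    elif name == HUMAN:
        hobs = np.full(n_pairs, -1, dtype=np.int8)
        lobs = np.full(n_pairs, -1, dtype=np.int8)
    else:
        hobs, lobs = _EMPTY_I8, _EMPTY_I8

    nc = len(complexes)
    cplx_bait = np.zeros(nc, dtype=np.int64)
    obs = np.zeros((nc, n), dtype=np.bool_)
    for r, rec in enumerate(complexes):
        cplx_bait[r] = idx[rec.bait]
        for m in rec.members:
            obs[r, idx[m]] = True
    crow_indptr, crow_idx = _csr(cplx_bait, np.arange(nc), n)

    xp_indptr, xp_j, xp_p = _partner_csr(ypos, ytot, n)
    return OrgBlock(name=name, proteins=list(proteins),
                    ypos=ypos, ytot=ytot, hobs=hobs, lobs=lobs,
                    cplx_bait=cplx_bait, obs=obs,
                    crow_indptr=crow_indptr, crow_idx=crow_idx,
                    xp_indptr=xp_indptr, xp_j=xp_j, xp_p=xp_p,
                    par_indptr=_EMPTY_PTR, par_idx=_EMPTY_IDX,
                    xpar_indptr=_EMPTY_PTR, xpar_idx=_EMPTY_IDX)


def build_packed(evidence: EvidenceSet) -> PackedProblem:
    uni = evidence.universe
    humans = sorted(uni.proteins_of(HUMAN))
    h_idx = {p: i for i, p in enumerate(humans)}
    nh = len(humans)

    orgs = evidence.star_organisms()
    y2h = evidence.y2h
    y2h_org = y2h["a"].map(uni.organism) if len(y2h) else None
    human_block = _build_block(
        HUMAN, humans, h_idx,
        y2h[y2h_org == HUMAN] if len(y2h) else None,
        evidence.literature,
        [c for c in evidence.complexes if uni.organism[c.bait] == HUMAN])

    stars: List[OrgBlock] = []
    star_prots: Dict[str, List[str]] = {}
    for org in orgs:
        grp = evidence.homology[evidence.homology["organism"] == org]
        prots = sorted(set(grp["ortholog"]))
        star_prots[org] = prots
        s_idx = {p: i for i, p in enumerate(prots)}
        blk = _build_block(
            org, prots, s_idx,
            y2h[y2h_org == org] if len(y2h) else None,
            None,
            [c for c in evidence.complexes if uni.organism[c.bait] == org])
        stars.append(blk)

    # flat offsets
    off = xoff = 0
    for blk in stars:
        blk.offset, blk.xoffset = off, xoff
        off += blk.n_pairs
        xoff += blk.n

    # pair-level transfer links
    s_index = {blk.name: {p: i for i, p in enumerate(blk.proteins)}
               for blk in stars}
    s_block = {blk.name: blk for blk in stars}
    link_par, link_child = [], []
    for org, hpair, spair, _jid in transfer_links(evidence.homology):
        blk = s_block[org]
        sidx = s_index[org]
        hi, hj = h_idx[hpair[0]], h_idx[hpair[1]]
        si, sj = sidx[spair[0]], sidx[spair[1]]
        link_par.append(pair_index(min(hi, hj), max(hi, hj), nh))
        link_child.append(blk.offset
                          + pair_index(min(si, sj), max(si, sj), blk.n))
    link_par = np.asarray(link_par, dtype=np.int64)
    link_child = np.asarray(link_child, dtype=np.int64)

    # protein-level transfer links
    xlink_par, xlink_child = [], []
    if len(evidence.homology):
        for row in evidence.homology.itertuples(index=False):
            org = str(row.organism)
            blk = s_block[org]
            xlink_par.append(h_idx[row.human])
            xlink_child.append(blk.xoffset + s_index[org][row.ortholog])
    xlink_par = np.asarray(xlink_par, dtype=np.int64)
    xlink_child = np.asarray(xlink_child, dtype=np.int64)

    # CSRs: human -> children; star-local -> parents
    n_pairs_h = nh * (nh - 1) // 2
    if len(link_par):
        child_indptr, child_idx = _csr(link_par, link_child, n_pairs_h)
        for blk in stars:
            sel = (link_child >= blk.offset) \
                & (link_child < blk.offset + blk.n_pairs)
            blk.par_indptr, blk.par_idx = _csr(
                link_child[sel] - blk.offset, link_par[sel], blk.n_pairs)
    else:
        child_indptr, child_idx = _EMPTY_PTR, _EMPTY_IDX
    if len(xlink_par):
        xchild_indptr, xchild_idx = _csr(xlink_par, xlink_child, nh)
        for blk in stars:
            sel = (xlink_child >= blk.xoffset) \
                & (xlink_child < blk.xoffset + blk.n)
            blk.xpar_indptr, blk.xpar_idx = _csr(
                xlink_child[sel] - blk.xoffset, xlink_par[sel], blk.n)
    else:
        xchild_indptr, xchild_idx = _EMPTY_PTR, _EMPTY_IDX

    iu, ju = np.triu_indices(nh, 1)
    return PackedProblem(human=human_block, stars=stars,
                         child_indptr=child_indptr, child_idx=child_idx,
                         xchild_indptr=xchild_indptr, xchild_idx=xchild_idx,
                         link_par=link_par, link_child=link_child,
                         xlink_par=xlink_par, xlink_child=xlink_child,
                         iu=iu, ju=ju)


# ---------------------------------------------------------------------------
# theta-dependent log tables
# ---------------------------------------------------------------------------

def _clip(p: float, eps: float = 1e-12) -> float:
    return min(max(p, eps), 1.0 - eps)


def _logit(p: float) -> float:
    p = _clip(p)
    return math.log(p / (1.0 - p))


@dataclass
class LogTables:
    ylog: np.ndarray
    lrh: np.ndarray
    lrl: np.ndarray
    lchild: np.ndarray
    lpar: np.ndarray
    lxchild: np.ndarray
    lxpar: np.ndarray
    mlog: np.ndarray
    base_z: float
    base_x: float


def build_tables(theta: ParameterVector,
                 self_activation: str = "exponent") -> LogTables:
    ylog = np.zeros((2, 3, 2))
    for z in (0, 1):
        for xs in (0, 1, 2):
            xe = min(xs, 1) if self_activation == "indicator" else xs
            p = _clip(1.0 - (1.0 - theta.alpha_I) ** z
                      * (1.0 - theta.alpha_S) ** xe
                      * (1.0 - theta.alpha_U))
            ylog[z, xs, 1] = math.log(p)
            ylog[z, xs, 0] = math.log(1.0 - p)

    def ratio(pos, neg):
        pos, neg = _clip(pos), _clip(neg)
        return np.array([math.log(pos / neg),
                         math.log((1.0 - pos) / (1.0 - neg))])

    mlog = np.array([math.log(_clip(theta.psi1)),
                     math.log(_clip(1.0 - theta.psi1)),
                     math.log(_clip(theta.psi2)),
                     math.log(_clip(1.0 - theta.psi2)),
                     math.log(_clip(theta.psi_bg))])
    return LogTables(
        ylog=ylog,
        lrh=ratio(theta.gamma1, theta.gamma0),
        lrl=ratio(theta.beta1, theta.beta0),
        lchild=ratio(theta.phi1, theta.phi0),
        lpar=np.array([_logit(theta.phi1), _logit(theta.phi0)]),
        lxchild=ratio(theta.lambda1, theta.lambda0),
        lxpar=np.array([_logit(theta.lambda1), _logit(theta.lambda0)]),
        mlog=mlog,
        base_z=_logit(theta.rho),
        base_x=_logit(theta.r),
    )
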