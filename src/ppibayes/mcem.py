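"""Monte Carlo EM: Gibbs E-step, M-step, fitting and posterior scoring.

The E-step draws the latent interaction/self-activation variables from
their joint posterior at the current parameters by systematic-scan Gibbs
sampling and accumulates Monte Carlo estimates of the expected sufficient
statistics.  The M-step maximizes the Monte Carlo Q-function: components
with conjugate Bernoulli structure (rho, r, the report and transfer rates)
have closed-form ratio updates; the Y2H mechanism probabilities are
maximized jointly and the complex capture probabilities coordinate-wise by
greedy hill climbing with step halving.  Iteration stops when the maximum
absolute parameter change falls below ``tol``.

``exact_posterior`` enumerates all latent configurations through the
reference likelihood and is the brute-force oracle used in tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import logsumexp

from . import _kernels
from ._pack import (LogTables, PackedProblem, PackedState, build_packed,
                    build_tables)
from .likelihood import complete_log_likelihood
from .types import (ESTIMATED_COMPONENTS, EvidenceSet, LatentState, Pair,
                    ParameterVector, PosteriorScores)

logger = logging.getLogger(__name__)

__all__ = ["MCEMSchedule", "GibbsState", "SuffStats", "FitResult",
           "gibbs_sweep", "e_step", "m_step", "fit", "score_posteriors",
           "exact_posterior", "expected_complete_ll"]


def _check_shared(theta: ParameterVector) -> None:
    if theta.overrides:
        raise ValueError("the sampler assumes shared parameters; per-source "
                         "overrides are honoured by the reference "
                         "likelihood only")


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass
class MCEMSchedule:
    """Sampling schedule: per-iteration burn-in and retained sweep counts.

    Retained samples grow linearly with the EM iteration (increasing-
    precision MCEM); scoring of the final posterior uses its own chain.
    """

    burnin: int = 50
    base: int = 100
    step: int = 100
    cap: int = 1_000_000
    score_burnin: int = 50
    score_samples: int = 500

    def samples(self, iteration: int) -> int:
        return min(self.base + self.step * iteration, self.cap)


# ---------------------------------------------------------------------------
# Gibbs machinery
# ---------------------------------------------------------------------------

@dataclass
class GibbsState:
    """Current latent state of the sampler plus running pair sums."""

    packed: PackedProblem
    state: PackedState
    z_sums: np.ndarray
    sweeps: int
    rng: np.random.Generator

    @classmethod
    def from_evidence(cls, evidence: EvidenceSet, seed: int = 0) -> "GibbsState":
        packed = build_packed(evidence)
        return cls(packed=packed, state=packed.new_state(),
                   z_sums=np.zeros(packed.human.n_pairs),
                   sweeps=0, rng=np.random.default_rng(seed))

    @property
    def latent(self) -> LatentState:
        return self.packed.export_state(self.state)

    def mean_z(self) -> np.ndarray:
        if self.sweeps == 0:
            raise ValueError("no retained sweeps yet")
        return self.z_sums / self.sweeps


def _one_sweep(packed: PackedProblem, st: PackedState, tables: LogTables,
               rng: np.random.Generator) -> None:
    seeds = rng.integers(0, 2 ** 31 - 1, size=2 + 2 * len(packed.stars))
    hb = packed.human
    _kernels.sweep_pairs(
        seeds[0], st.z_h, st.adj[0], st.cn[0], st.X_h,
        hb.ypos, hb.ytot, tables.ylog,
        hb.hobs, hb.lobs, tables.lrh, tables.lrl,
        tables.base_z,
        hb.par_indptr, hb.par_idx, st.z_h, tables.lpar,
        packed.child_indptr, packed.child_idx, st.zs_flat, tables.lchild,
        hb.crow_indptr, hb.crow_idx, hb.cplx_bait, hb.obs, tables.mlog)
    _kernels.sweep_x(
        seeds[1], st.X_h, st.z_h,
        hb.xp_indptr, hb.xp_j, hb.xp_p, hb.ypos, hb.ytot, tables.ylog,
        tables.base_x,
        hb.xpar_indptr, hb.xpar_idx, st.X_h, tables.lxpar,
        packed.xchild_indptr, packed.xchild_idx, st.xs_flat, tables.lxchild)
    for k, (blk, zs, xs, adj, cn) in enumerate(packed.star_slices(st)):
        _kernels.sweep_pairs(
            seeds[2 + 2 * k], zs, adj, cn, xs,
            blk.ypos, blk.ytot, tables.ylog,
            blk.hobs, blk.lobs, tables.lrh, tables.lrl,
            0.0,
            blk.par_indptr, blk.par_idx, st.z_h, tables.lpar,
            np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int64),
            st.zs_flat, tables.lchild,
            blk.crow_indptr, blk.crow_idx, blk.cplx_bait, blk.obs,
            tables.mlog)
        _kernels.sweep_x(
            seeds[3 + 2 * k], xs, zs,
            blk.xp_indptr, blk.xp_j, blk.xp_p, blk.ypos, blk.ytot,
            tables.ylog, 0.0,
            blk.xpar_indptr, blk.xpar_idx, st.X_h, tables.lxpar,
            np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int64),
            st.xs_flat, tables.lxchild)


def gibbs_sweep(state: GibbsState, evidence: EvidenceSet,
                theta: ParameterVector,
                self_activation: str = "exponent") -> GibbsState:
    """Resample every latent variable once from its full conditional."""
    _check_shared(theta)
    tables = build_tables(theta, self_activation)
    _one_sweep(state.packed, state.state, tables, state.rng)
    state.z_sums += state.state.z_h
    state.sweeps += 1
    return state


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class SuffStats:
    """Monte Carlo estimates of the expected sufficient statistics.

    All quantities are means over retained sweeps; ``lit_h``/``lit_l`` hold
    ``[#z=1 pairs, #z=1 reported, #z=0 pairs, #z=0 reported]`` over the
    covered pair set of the channel, ``tz``/``tx`` the 2x2 parent-by-child
    transfer count tables and ``mpc`` the ``[hit1, miss1, hit2, miss2]``
    capture counts over all complexes.
    """

    n_sweeps: int
    zbar: np.ndarray
    xbar: np.ndarray
    ypos_tab: np.ndarray   # (2, 3): expected positive replicate counts
    ytot_tab: np.ndarray   # (2, 3): expected replicate totals
    mpc: np.ndarray        # (4,)
    lit_h: np.ndarray      # (4,)
    lit_l: np.ndarray      # (4,)
    tz: np.ndarray         # (2, 2)
    tx: np.ndarray         # (2, 2)
    self_activation: str = "exponent"


class _Accumulator:
    def __init__(self, packed: PackedProblem):
        self.packed = packed
        self.n = 0
        self.zsum = np.zeros(packed.human.n_pairs)
        self.xsum = np.zeros(packed.human.n)
        self.ypos_tab = np.zeros((2, 3))
        self.ytot_tab = np.zeros((2, 3))
        self.mpc = np.zeros(4)
        self.lit_h = np.zeros(4)
        self.lit_l = np.zeros(4)
        self.tz = np.zeros((2, 2))
        self.tx = np.zeros((2, 2))
        self._triu = {}
        for blk in [packed.human] + packed.stars:
            mask = blk.ytot > 0
            iu, ju = np.triu_indices(blk.n, 1)
            self._triu[blk.name] = (mask, iu[mask], ju[mask])

    def add(self, st: PackedState) -> None:
        packed = self.packed
        self.n += 1
        self.zsum += st.z_h
        self.xsum += st.X_h
        blocks = [(packed.human, st.z_h, st.X_h, st.adj[0], st.cn[0])]
        blocks += [(blk, zs, xs, adj, cn)
                   for blk, zs, xs, adj, cn in packed.star_slices(st)]
        for blk, z, X, adj, cn in blocks:
            mask, ii, jj = self._triu[blk.name]
            if ii.size:
                xs_arr = X[ii].astype(np.int64) + X[jj]
                idx = z[mask].astype(np.int64) * 3 + xs_arr
                self.ypos_tab += np.bincount(
                    idx, weights=blk.ypos[mask], minlength=6).reshape(2, 3)
                self.ytot_tab += np.bincount(
                    idx, weights=blk.ytot[mask], minlength=6).reshape(2, 3)
            for r in range(blk.cplx_bait.shape[0]):
                b = blk.cplx_bait[r]
                o = blk.obs[r]
                n1 = adj[b]
                n2 = (cn[b] > 0) & ~n1
                n2[b] = False
                self.mpc[0] += np.count_nonzero(n1 & o)
                self.mpc[1] += np.count_nonzero(n1 & ~o)
                self.mpc[2] += np.count_nonzero(n2 & o)
                self.mpc[3] += np.count_nonzero(n2 & ~o)
        hb = packed.human
        for arr, out in ((hb.hobs, self.lit_h), (hb.lobs, self.lit_l)):
            m = arr >= 0
            if m.any():
                zz = st.z_h[m].astype(bool)
                rep = arr[m] == 1
                out[0] += np.count_nonzero(zz)
                out[1] += np.count_nonzero(zz & rep)
                out[2] += np.count_nonzero(~zz)
                out[3] += np.count_nonzero(~zz & rep)
        if packed.link_par.size:
            zp = st.z_h[packed.link_par].astype(bool)
            zc = st.zs_flat[packed.link_child].astype(bool)
            self.tz[1, 1] += np.count_nonzero(zp & zc)
            self.tz[1, 0] += np.count_nonzero(zp & ~zc)
            self.tz[0, 1] += np.count_nonzero(~zp & zc)
            self.tz[0, 0] += np.count_nonzero(~zp & ~zc)
        if packed.xlink_par.size:
            xp = st.X_h[packed.xlink_par].astype(bool)
            xc = st.xs_flat[packed.xlink_child].astype(bool)
            self.tx[1, 1] += np.count_nonzero(xp & xc)
            self.tx[1, 0] += np.count_nonzero(xp & ~xc)
            self.tx[0, 1] += np.count_nonzero(~xp & xc)
            self.tx[0, 0] += np.count_nonzero(~xp & ~xc)

    def finalize(self, self_activation: str) -> SuffStats:
        if self.n == 0:
            raise ValueError("no retained sweeps")
        n = float(self.n)
        return SuffStats(
            n_sweeps=self.n, zbar=self.zsum / n, xbar=self.xsum / n,
            ypos_tab=self.ypos_tab / n, ytot_tab=self.ytot_tab / n,
            mpc=self.mpc / n, lit_h=self.lit_h / n, lit_l=self.lit_l / n,
            tz=self.tz / n, tx=self.tx / n,
            self_activation=self_activation)


def _run_e_step(packed: PackedProblem, st: PackedState, tables: LogTables,
                rng: np.random.Generator, n_burnin: int, n_samples: int,
                self_activation: str) -> SuffStats:
    for _ in range(n_burnin):
        _one_sweep(packed, st, tables, rng)
    acc = _Accumulator(packed)
    for _ in range(n_samples):
        _one_sweep(packed, st, tables, rng)
        acc.add(st)
    return acc.finalize(self_activation)


def e_step(evidence: EvidenceSet, theta: ParameterVector,
           n_burnin: int, n_samples: int, seed: int,
           self_activation: str = "exponent") -> SuffStats:
    """Burn in, then retain ``n_samples`` sweeps of sufficient statistics."""
    if n_burnin < 0 or n_samples <= 0:
        raise ValueError("sweep counts must be positive")
    _check_shared(theta)
    packed = build_packed(evidence)
    tables = build_tables(theta, self_activation)
    rng = np.random.default_rng(seed)
    return _run_e_step(packed, packed.new_state(), tables, rng,
                       n_burnin, n_samples, self_activation)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def _clip01(p: float, eps: float = 1e-12) -> float:
    return min(max(p, eps), 1.0 - eps)


def _q_y2h(pos_tab: np.ndarray, tot_tab: np.ndarray,
           a_i: float, a_s: float, a_u: float, self_activation: str) -> float:
    q = 0.0
    for z in (0, 1):
        for xs in (0, 1, 2):
            t = tot_tab[z, xs]
            if t == 0:
                continue
            xe = min(xs, 1) if self_activation == "indicator" else xs
            p = _clip01(1.0 - (1.0 - a_i) ** z * (1.0 - a_s) ** xe
                        * (1.0 - a_u))
            pos = pos_tab[z, xs]
            q += pos * math.log(p) + (t - pos) * math.log(1.0 - p)
    return q


def _bern_q(hit: float, miss: float, p: float) -> float:
    p = _clip01(p)
    return hit * math.log(p) + miss * math.log(1.0 - p)


def _climb(qfun, x0: List[float], step0: float = 0.1,
           step_min: float = 1e-4, eps: float = 1e-6) -> List[float]:
    """Coordinate-wise greedy ascent with step halving; accepts only
    improving moves."""
    x = list(x0)
    fx = qfun(x)
    step = step0
    while step >= step_min:
        improved = False
        for c in range(len(x)):
            for d in (step, -step):
                xn = list(x)
                xn[c] = min(max(x[c] + d, eps), 1.0 - eps)
                if xn[c] == x[c]:
                    continue
                fn = qfun(xn)
                if fn > fx:
                    x, fx = xn, fn
                    improved = True
        if not improved:
            step /= 2.0
    return x


def _ratio(hit: float, total: float, fallback: float) -> float:
    return hit / total if total > 0 else fallback


def m_step(stats: SuffStats, theta_old: ParameterVector) -> ParameterVector:
    """Maximize the Monte Carlo Q-function over theta.

    Conjugate Bernoulli components use their exact ratio maximizers;
    (alpha_I, alpha_S, alpha_U) are climbed jointly and psi1/psi2
    coordinate-wise.  Components with no supporting evidence keep their
    previous value.  The positive>negative rate ordering is enforced on the
    report and transfer rate pairs afterwards.
    """
    zb, xb = stats.zbar, stats.xbar
    if ((zb < -1e-9) | (zb > 1 + 1e-9)).any() or \
       ((xb < -1e-9) | (xb > 1 + 1e-9)).any():
        raise ValueError("pair/protein means outside [0, 1]")
    if (stats.ypos_tab > stats.ytot_tab + 1e-9).any() or \
       (stats.mpc < -1e-9).any():
        raise ValueError("sufficient statistics outside feasible range")

    new = {
        "rho": float(zb.mean()) if zb.size else theta_old.rho,
        "r": float(xb.mean()) if xb.size else theta_old.r,
        "gamma1": _ratio(stats.lit_h[1], stats.lit_h[0], theta_old.gamma1),
        "gamma0": _ratio(stats.lit_h[3], stats.lit_h[2], theta_old.gamma0),
        "beta1": _ratio(stats.lit_l[1], stats.lit_l[0], theta_old.beta1),
        "beta0": _ratio(stats.lit_l[3], stats.lit_l[2], theta_old.beta0),
        "phi1": _ratio(stats.tz[1, 1], stats.tz[1].sum(), theta_old.phi1),
        "phi0": _ratio(stats.tz[0, 1], stats.tz[0].sum(), theta_old.phi0),
        "lambda1": _ratio(stats.tx[1, 1], stats.tx[1].sum(),
                          theta_old.lambda1),
        "lambda0": _ratio(stats.tx[0, 1], stats.tx[0].sum(),
                          theta_old.lambda0),
    }
    if stats.ytot_tab.sum() > 0:
        a_i, a_s, a_u = _climb(
            lambda a: _q_y2h(stats.ypos_tab, stats.ytot_tab, a[0], a[1],
                             a[2], stats.self_activation),
            [theta_old.alpha_I, theta_old.alpha_S, theta_old.alpha_U])
        new.update(alpha_I=a_i, alpha_S=a_s, alpha_U=a_u)
    if stats.mpc[0] + stats.mpc[1] > 0:
        new["psi1"] = _climb(
            lambda p: _bern_q(stats.mpc[0], stats.mpc[1], p[0]),
            [theta_old.psi1])[0]
    if stats.mpc[2] + stats.mpc[3] > 0:
        new["psi2"] = _climb(
            lambda p: _bern_q(stats.mpc[2], stats.mpc[3], p[0]),
            [theta_old.psi2])[0]
    return replace(theta_old, **new).clipped(1e-6).with_rate_ordering()


def expected_complete_ll(stats: SuffStats, theta: ParameterVector) -> float:
    """Monte Carlo Q-function at theta (up to theta-free constants)."""
    q = 0.0
    s = float(stats.zbar.sum())
    q += _bern_q(s, stats.zbar.size - s, theta.rho)
    sx = float(stats.xbar.sum())
    q += _bern_q(sx, stats.xbar.size - sx, theta.r)
    q += _q_y2h(stats.ypos_tab, stats.ytot_tab, theta.alpha_I,
                theta.alpha_S, theta.alpha_U, stats.self_activation)
    q += _bern_q(stats.mpc[0], stats.mpc[1], theta.psi1)
    q += _bern_q(stats.mpc[2], stats.mpc[3], theta.psi2)
    for arr, pos, neg in ((stats.lit_h, theta.gamma1, theta.gamma0),
                          (stats.lit_l, theta.beta1, theta.beta0)):
        q += _bern_q(arr[1], arr[0] - arr[1], pos)
        q += _bern_q(arr[3], arr[2] - arr[3], neg)
    for tab, pos, neg in ((stats.tz, theta.phi1, theta.phi0),
                          (stats.tx, theta.lambda1, theta.lambda0)):
        q += _bern_q(tab[1, 1], tab[1, 0], pos)
        q += _bern_q(tab[0, 1], tab[0, 0], neg)
    return q


# ---------------------------------------------------------------------------
# fit and scoring
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    theta_hat: ParameterVector
    posterior: PosteriorScores
    trace: List[Dict[str, float]]
    diff_trace: List[float]
    converged: bool


def _scores_from(packed: PackedProblem, zbar: np.ndarray) -> PosteriorScores:
    prot = packed.human.proteins
    scores = {(prot[i], prot[j]): float(v)
              for i, j, v in zip(packed.iu, packed.ju, zbar)}
    return PosteriorScores(scores)


def _run_scoring(packed: PackedProblem, tables: LogTables,
                 rng: np.random.Generator, n_burnin: int,
                 n_samples: int) -> np.ndarray:
    st = packed.new_state()
    for _ in range(n_burnin):
        _one_sweep(packed, st, tables, rng)
    zsum = np.zeros(packed.human.n_pairs)
    for _ in range(n_samples):
        _one_sweep(packed, st, tables, rng)
        zsum += st.z_h
    return zsum / n_samples


def score_posteriors(evidence: EvidenceSet, theta: ParameterVector,
                     n_burnin: int = 50, n_samples: int = 500,
                     seed: int = 0,
                     self_activation: str = "exponent") -> PosteriorScores:
    """Per-pair Gibbs estimate of Pr[Z_ij=1 | all evidence] at fixed theta."""
    if n_burnin < 0 or n_samples <= 0:
        raise ValueError("sweep counts must be positive")
    _check_shared(theta)
    packed = build_packed(evidence)
    tables = build_tables(theta, self_activation)
    zbar = _run_scoring(packed, tables, np.random.default_rng(seed),
                        n_burnin, n_samples)
    return _scores_from(packed, zbar)


def fit(evidence: EvidenceSet,
        theta_init: Optional[ParameterVector] = None,
        schedule: Optional[MCEMSchedule] = None,
        tol: float = 0.01,
        max_iter: int = 50,
        seed: int = 0,
        self_activation: str = "exponent") -> FitResult:
    """Alternate Gibbs E-steps and M-steps until the parameters settle.

    ``diff`` is the maximum absolute componentwise change of theta in one
    iteration; the fit stops when ``diff < tol`` (non-convergence within
    ``max_iter`` is reported via the ``converged`` flag, not raised).  The
    chain is warm-started across iterations; the final posterior is computed
    by a fresh scoring chain at the fitted parameters.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    theta = (theta_init if theta_init is not None
             else ParameterVector()).clipped()
    _check_shared(theta)
    schedule = schedule or MCEMSchedule()
    rng = np.random.default_rng(seed)
    packed = build_packed(evidence)
    st = packed.new_state()
    trace = [theta.to_dict()]
    diffs: List[float] = []
    converged = False
    for it in range(max_iter):
        tables = build_tables(theta, self_activation)
        stats = _run_e_step(packed, st, tables, rng, schedule.burnin,
                            schedule.samples(it), self_activation)
        theta_new = m_step(stats, theta)
        d = theta_new.diff(theta)
        theta = theta_new
        trace.append(theta.to_dict())
        diffs.append(d)
        logger.info("MCEM iter %d: diff=%.5f rho=%.4g alpha_I=%.3f "
                    "psi1=%.3f gamma1=%.3f", it + 1, d, theta.rho,
                    theta.alpha_I, theta.psi1, theta.gamma1)
        if d < tol:
            converged = True
            break
    tables = build_tables(theta, self_activation)
    zbar = _run_scoring(packed, tables, rng, schedule.score_burnin,
                        schedule.score_samples)
    return FitResult(theta_hat=theta, posterior=_scores_from(packed, zbar),
                     trace=trace, diff_trace=diffs, converged=converged)


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------

def exact_posterior(evidence: EvidenceSet, theta: ParameterVector,
                    self_activation: str = "exponent",
                    transfer_parameterization: str = "constant",
                    max_vars: int = 20) -> PosteriorScores:
    """Exact pair marginals by enumerating every latent configuration.

    Intended for small test instances only; raises if the number of binary
    latent variables exceeds ``max_vars``.
    """
    from .likelihood import (complex_log_likelihood, literature_log_prob,
                             prior_log_prob, transfer_links, transfer_prob,
                             y2h_response_prob)
    uni = evidence.universe
    state = LatentState.zeros(uni, evidence.homology)
    variables: List[Tuple[str, object, Optional[str]]] = []
    pair_vars: List[Tuple[Pair, int]] = []
    for pair in sorted(state.z):
        pair_vars.append((pair, len(variables)))
        variables.append(("z", pair, None))
    for prot in sorted(state.x):
        variables.append(("x", prot, None))
    for org in sorted(state.star):
        for pair in sorted(state.star[org].z):
            variables.append(("z*", pair, org))
        for prot in sorted(state.star[org].x):
            variables.append(("x*", prot, org))
    k = len(variables)
    if k > max_vars:
        raise ValueError(f"{k} latent variables exceed the enumeration cap "
                         f"of {max_vars}")

    # flatten the evidence once; per-configuration evaluation then runs
    # over plain tuples through the reference factor functions
    from .types import canonical_pair
    theta_of = {None: theta}
    y2h_recs = []
    for row in evidence.y2h.itertuples(index=False):
        sid = str(row.source_id)
        theta_of.setdefault(sid, theta.for_source(sid))
        y2h_recs.append((uni.organism[row.a],
                         canonical_pair(row.a, row.b), row.a, row.b,
                         int(row.observed), sid))
    cpx_recs = [(uni.organism[rec.bait], rec.bait, rec.members,
                 rec.experiment_id) for rec in evidence.complexes]
    for _, _, _, eid in cpx_recs:
        theta_of.setdefault(eid, theta.for_source(eid))
    lit_recs = [(canonical_pair(row.a, row.b), row.channel,
                 int(row.observed))
                for row in evidence.literature.itertuples(index=False)]
    z_links = list(transfer_links(evidence.homology))
    x_links = [(str(row.organism), row.human, row.ortholog,
                float(row.identity))
               for row in evidence.homology.itertuples(index=False)] \
        if len(evidence.homology) else []

    def loglik() -> float:
        ll = prior_log_prob(state, theta)
        for org, pair, a, b, obs, sid in y2h_recs:
            xmap = state.x_of(org)
            p = y2h_response_prob(state.z_of(org)[pair], xmap[a], xmap[b],
                                  theta_of[sid], self_activation)
            ll += math.log(max(p if obs else 1.0 - p, 1e-300))
        for org, bait, members, eid in cpx_recs:
            ll += complex_log_likelihood(bait, members, state,
                                         theta_of[eid], org)
        for pair, channel, obs in lit_recs:
            z = state.z[pair]
            if channel == "H":
                ll += literature_log_prob(obs, z, theta.gamma1, theta.gamma0)
            else:
                ll += literature_log_prob(obs, z, theta.beta1, theta.beta0)
        for org, hpair, spair, jid in z_links:
            zs = state.star[org].z.get(spair)
            if zs is None:
                continue
            p = transfer_prob(state.z[hpair], jid, "interaction", theta,
                              transfer_parameterization)
            ll += math.log(max(p if zs else 1.0 - p, 1e-300))
        for org, human, ortholog, ident in x_links:
            xs = state.star[org].x.get(ortholog)
            if xs is None:
                continue
            p = transfer_prob(state.x[human], ident, "self_activation",
                              theta, transfer_parameterization)
            ll += math.log(max(p if xs else 1.0 - p, 1e-300))
        return ll

    lls = np.empty(2 ** k)
    prev = 0
    for cfg in range(2 ** k):
        flip = cfg ^ prev
        v = 0
        while flip:
            if flip & 1:
                kind, key, org = variables[v]
                bit = (cfg >> v) & 1
                if kind == "z":
                    state.z[key] = bit
                elif kind == "x":
                    state.x[key] = bit
                elif kind == "z*":
                    state.star[org].z[key] = bit
                else:
                    state.star[org].x[key] = bit
            flip >>= 1
            v += 1
        prev = cfg
        lls[cfg] = loglik()
    total = logsumexp(lls)
    cfgs = np.arange(2 ** k)
    scores = {}
    for pair, v in pair_vars:
        on = lls[(cfgs >> v) & 1 == 1]
        scores[pair] = float(np.exp(logsumexp(on) - total))
    return PosteriorScores(scores)
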