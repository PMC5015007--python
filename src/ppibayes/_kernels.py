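"""Numba kernels for the Gibbs sweeps.

The latent state of one organism is held as a dense pair vector ``z``
(triangular order), an adjacency matrix ``adj`` and a common-neighbour
count matrix ``cn`` (``cn[a, b]`` = number of length-2 paths a-t-b), which
together make the 1-/2-step neighbourhood classification of any (bait,
protein) entry an O(1) lookup.  Toggling one edge updates ``cn`` in O(n).

The pull-down complex factor couples a pair (i, j) only to complexes whose
bait is i, j, or a current neighbour of i or j: toggling Z_ij cannot change
the 1-/2-step neighbourhood of any more distant bait.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _fcls(cls, o, mlog):
    # cls 1: 1-step, 2: 2-step, 3: distant/unreachable
    if cls == 1:
        return mlog[0] if o else mlog[1]
    if cls == 2:
        return mlog[2] if o else mlog[3]
    return mlog[4] if o else 0.0


@njit(cache=True)
def _mpc_delta(i, j, zc, adj, cn, crow_indptr, crow_idx, cplx_bait, obs,
               mlog):
    """log f(W | Z with z_ij=1) - log f(W | Z with z_ij=0), all complexes."""
    n = adj.shape[0]
    d = 0.0
    # complexes whose bait is i or j: the partner moves between the 1-step
    # and 2-step/distant classes, and common neighbours of the partner can
    # enter or leave the 2-step class
    for side in range(2):
        a = i if side == 0 else j
        bpt = j if side == 0 else i
        for rr in range(crow_indptr[a], crow_indptr[a + 1]):
            r = crow_idx[rr]
            o = obs[r, bpt]
            c0 = 2 if cn[a, bpt] > 0 else 3
            d += _fcls(1, o, mlog) - _fcls(c0, o, mlog)
            for m in range(n):
                if m == i or m == j:
                    continue
                if adj[bpt, m] and not adj[a, m]:
                    if cn[a, m] - zc == 0:
                        o2 = obs[r, m]
                        d += _fcls(2, o2, mlog) - _fcls(3, o2, mlog)
    # complexes whose bait k is adjacent to i or j: the opposite endpoint
    # can enter or leave k's 2-step class through the path k-i-j / k-j-i
    nc = cplx_bait.shape[0]
    for r in range(nc):
        k = cplx_bait[r]
        if k == i or k == j:
            continue
        if adj[i, k] and not adj[k, j]:
            if cn[k, j] - zc == 0:
                o = obs[r, j]
                d += _fcls(2, o, mlog) - _fcls(3, o, mlog)
        if adj[j, k] and not adj[k, i]:
            if cn[k, i] - zc == 0:
                o = obs[r, i]
                d += _fcls(2, o, mlog) - _fcls(3, o, mlog)
    return d


@njit(cache=True)
def _apply_toggle(i, j, znew, adj, cn):
    n = adj.shape[0]
    delta = 1 if znew == 1 else -1
    adj[i, j] = znew == 1
    adj[j, i] = znew == 1
    for m in range(n):
        if m == i or m == j:
            continue
        if adj[j, m]:
            cn[i, m] += delta
            cn[m, i] += delta
        if adj[i, m]:
            cn[j, m] += delta
            cn[m, j] += delta


@njit(cache=True)
def sweep_pairs(seed, z, adj, cn, X,
                ypos, ytot, ylog,
                hobs, lobs, lrh, lrl,
                base_logit,
                par_indptr, par_idx, z_parent, lpar,
                child_indptr, child_idx, z_child, lchild,
                crow_indptr, crow_idx, cplx_bait, obs, mlog):
    """One systematic-scan Gibbs sweep over the pair variables of one organism.

    Each Z is resampled from its full conditional: prior (or parent-transfer
    factors for a starred organism), Y2H replicate counts, literature
    channels, transfer factors to starred children, and the local complex
    factors.
    """
    np.random.seed(seed)
    n = adj.shape[0]
    has_mpc = cplx_bait.shape[0] > 0
    p = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            lo = base_logit
            if par_indptr.shape[0] > 1:
                lo = 0.0
                for t in range(par_indptr[p], par_indptr[p + 1]):
                    lo += lpar[0] if z_parent[par_idx[t]] == 1 else lpar[1]
            tot = ytot[p]
            if tot > 0:
                xs = X[i] + X[j]
                yp = ypos[p]
                lo += yp * (ylog[1, xs, 1] - ylog[0, xs, 1]) \
                    + (tot - yp) * (ylog[1, xs, 0] - ylog[0, xs, 0])
            if hobs.shape[0] > 0:
                h = hobs[p]
                if h >= 0:
                    lo += lrh[0] if h == 1 else lrh[1]
                lv = lobs[p]
                if lv >= 0:
                    lo += lrl[0] if lv == 1 else lrl[1]
            if child_indptr.shape[0] > 1:
                for t in range(child_indptr[p], child_indptr[p + 1]):
                    lo += lchild[0] if z_child[child_idx[t]] == 1 else lchild[1]
            zc = z[p]
            if has_mpc:
                lo += _mpc_delta(i, j, zc, adj, cn, crow_indptr, crow_idx,
                                 cplx_bait, obs, mlog)
            if lo > 35.0:
                pr = 1.0
            elif lo < -35.0:
                pr = 0.0
            else:
                pr = 1.0 / (1.0 + math.exp(-lo))
            znew = 1 if np.random.random() < pr else 0
            if znew != zc:
                z[p] = znew
                _apply_toggle(i, j, znew, adj, cn)
            p += 1


@njit(cache=True)
def sweep_x(seed, X, z,
            xp_indptr, xp_j, xp_p, ypos, ytot, ylog,
            base_logit,
            xpar_indptr, xpar_idx, x_parent, lxpar,
            xchild_indptr, xchild_idx, x_child, lxchild):
    """One Gibbs sweep over the self-activation indicators of one organism."""
    np.random.seed(seed)
    n = X.shape[0]
    for i in range(n):
        lo = base_logit
        if xpar_indptr.shape[0] > 1:
            lo = 0.0
            for t in range(xpar_indptr[i], xpar_indptr[i + 1]):
                lo += lxpar[0] if x_parent[xpar_idx[t]] == 1 else lxpar[1]
        for t in range(xp_indptr[i], xp_indptr[i + 1]):
            j = xp_j[t]
            p = xp_p[t]
            zz = z[p]
            xj = X[j]
            yp = ypos[p]
            tot = ytot[p]
            lo += yp * (ylog[zz, xj + 1, 1] - ylog[zz, xj, 1]) \
                + (tot - yp) * (ylog[zz, xj + 1, 0] - ylog[zz, xj, 0])
        if xchild_indptr.shape[0] > 1:
            for t in range(xchild_indptr[i], xchild_indptr[i + 1]):
                lo += lxchild[0] if x_child[xchild_idx[t]] == 1 else lxchild[1]
        if lo > 35.0:
            pr = 1.0
        elif lo < -35.0:
            pr = 0.0
        else:
            pr = 1.0 / (1.0 + math.exp(-lo))
        X[i] = 1 if np.random.random() < pr else 0
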