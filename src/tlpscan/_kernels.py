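"""Numba-compiled dynamic-programming kernels for local profile-HMM scoring.

All scores are log2 odds (bits) against an i.i.d. background null.  The
local-alignment grammar: a path enters at any match state (uniform entry
weight 1/M), moves through match/insert/delete states under the model's
transition probabilities, and exits from any match state at no cost;
unaligned peptide flanks and insert-state residues are emitted from the
background, so their emission odds cancel to zero bits.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -1.0e300


@njit(cache=True)
def _log2addexp(a: float, b: float) -> float:
    if a < b:
        a, b = b, a
    if b <= NEG_INF / 2:
        return a
    return a + math.log2(1.0 + 2.0 ** (b - a))


@njit(cache=True)
def viterbi_kernel(llr, ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, entry):
    """Best local path score and its envelope.

    llr: (L, M) per-residue match log-odds.  Transition arrays are log2
    probabilities indexed by the 0-based source state.  Returns
    (score_bits, pep_start, pep_end, k_start, k_end) with half-open
    0-based envelopes; score is -inf for an empty model/peptide.
    """
    L, M = llr.shape
    vm_prev = np.full(M, NEG_INF)
    vi_prev = np.full(M, NEG_INF)
    vd_prev = np.full(M, NEG_INF)
    # start bookkeeping: peptide / model index where the best path entered
    sm_p = np.zeros(M, np.int64)
    sm_k = np.zeros(M, np.int64)
    si_p = np.zeros(M, np.int64)
    si_k = np.zeros(M, np.int64)
    sd_p = np.zeros(M, np.int64)
    sd_k = np.zeros(M, np.int64)
    nm_p = np.zeros(M, np.int64)
    nm_k = np.zeros(M, np.int64)
    ni_p = np.zeros(M, np.int64)
    ni_k = np.zeros(M, np.int64)
    nd_p = np.zeros(M, np.int64)
    nd_k = np.zeros(M, np.int64)

    best = NEG_INF
    best_p0 = 0
    best_p1 = 0
    best_k0 = 0
    best_k1 = 0

    vm = np.full(M, NEG_INF)
    vi = np.full(M, NEG_INF)
    vd = np.full(M, NEG_INF)

    for i in range(L):
        for k in range(M):
            # match state k emitting residue i
            s = entry
            p0 = i
            k0 = k
            if k > 0:
                c = vm_prev[k - 1] + ltMM[k - 1]
                if c > s:
                    s = c
                    p0 = sm_p[k - 1]
                    k0 = sm_k[k - 1]
                c = vi_prev[k - 1] + ltIM[k - 1]
                if c > s:
                    s = c
                    p0 = si_p[k - 1]
                    k0 = si_k[k - 1]
                c = vd_prev[k - 1] + ltDM[k - 1]
                if c > s:
                    s = c
                    p0 = sd_p[k - 1]
                    k0 = sd_k[k - 1]
            vm[k] = llr[i, k] + s
            nm_p[k] = p0
            nm_k[k] = k0
            if vm[k] > best:
                best = vm[k]
                best_p0 = p0
                best_p1 = i + 1
                best_k0 = k0
                best_k1 = k + 1
            # insert state k emitting residue i (background odds: +0 bits)
            a = vm_prev[k] + ltMI[k]
            b = vi_prev[k] + ltII[k]
            if a >= b:
                vi[k] = a
                ni_p[k] = sm_p[k]
                ni_k[k] = sm_k[k]
            else:
                vi[k] = b
                ni_p[k] = si_p[k]
                ni_k[k] = si_k[k]
        # delete states: no emission, sequential in k within the row
        nd_p[0] = 0
        nd_k[0] = 0
        vd[0] = NEG_INF
        for k in range(1, M):
            a = vm[k - 1] + ltMD[k - 1]
            b = vd[k - 1] + ltDD[k - 1]
            if a >= b:
                vd[k] = a
                nd_p[k] = nm_p[k - 1]
                nd_k[k] = nm_k[k - 1]
            else:
                vd[k] = b
                nd_p[k] = nd_p[k - 1]
                nd_k[k] = nd_k[k - 1]
        vm_prev, vm = vm, vm_prev
        vi_prev, vi = vi, vi_prev
        vd_prev, vd = vd, vd_prev
        sm_p, nm_p = nm_p, sm_p
        sm_k, nm_k = nm_k, sm_k
        si_p, ni_p = ni_p, si_p
        si_k, ni_k = ni_k, si_k
        sd_p, nd_p = nd_p, sd_p
        sd_k, nd_k = nd_k, sd_k

    return best, best_p0, best_p1, best_k0, best_k1


@njit(cache=True)
def viterbi_score_kernel(llr, ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, entry):
    """Best local path score only (no envelope bookkeeping; used for screening)."""
    L, M = llr.shape
    vm_prev = np.full(M, NEG_INF)
    vi_prev = np.full(M, NEG_INF)
    vd_prev = np.full(M, NEG_INF)
    vm = np.full(M, NEG_INF)
    vi = np.full(M, NEG_INF)
    vd = np.full(M, NEG_INF)
    best = NEG_INF
    for i in range(L):
        for k in range(M):
            s = entry
            if k > 0:
                c = vm_prev[k - 1] + ltMM[k - 1]
                if c > s:
                    s = c
                c = vi_prev[k - 1] + ltIM[k - 1]
                if c > s:
                    s = c
                c = vd_prev[k - 1] + ltDM[k - 1]
                if c > s:
                    s = c
            v = llr[i, k] + s
            vm[k] = v
            if v > best:
                best = v
            a = vm_prev[k] + ltMI[k]
            b = vi_prev[k] + ltII[k]
            vi[k] = a if a >= b else b
        vd[0] = NEG_INF
        for k in range(1, M):
            a = vm[k - 1] + ltMD[k - 1]
            b = vd[k - 1] + ltDD[k - 1]
            vd[k] = a if a >= b else b
        vm_prev, vm = vm, vm_prev
        vi_prev, vi = vi, vi_prev
        vd_prev, vd = vd, vd_prev
    return best


@njit(cache=True)
def forward_kernel(llr, ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, entry):
    """Log2 of the summed odds over all local paths (same grammar as Viterbi)."""
    L, M = llr.shape
    fm_prev = np.full(M, NEG_INF)
    fi_prev = np.full(M, NEG_INF)
    fd_prev = np.full(M, NEG_INF)
    fm = np.full(M, NEG_INF)
    fi = np.full(M, NEG_INF)
    fd = np.full(M, NEG_INF)
    total = NEG_INF
    for i in range(L):
        for k in range(M):
            s = entry
            if k > 0:
                s = _log2addexp(s, fm_prev[k - 1] + ltMM[k - 1])
                s = _log2addexp(s, fi_prev[k - 1] + ltIM[k - 1])
                s = _log2addexp(s, fd_prev[k - 1] + ltDM[k - 1])
            fm[k] = llr[i, k] + s
            # every path's final state is a unique (i, k) match: sum is exact
            total = _log2addexp(total, fm[k])
            fi[k] = _log2addexp(fm_prev[k] + ltMI[k], fi_prev[k] + ltII[k])
        fd[0] = NEG_INF
        for k in range(1, M):
            fd[k] = _log2addexp(fm[k - 1] + ltMD[k - 1], fd[k - 1] + ltDD[k - 1])
        fm_prev, fm = fm, fm_prev
        fi_prev, fi = fi, fi_prev
        fd_prev, fd = fd, fd_prev
    return total


@njit(cache=True)
def viterbi_scores_batch(llr_flat, lengths, ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, entry):
    """Viterbi scores for a batch of equal-model peptides stacked in llr_flat."""
    n = lengths.shape[0]
    out = np.empty(n)
    off = 0
    for j in range(n):
        L = lengths[j]
        out[j] = viterbi_score_kernel(
            llr_flat[off : off + L], ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, entry
        )
        off += L
    return out
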