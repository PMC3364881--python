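"""Numba dynamic-programming kernels for profile-HMM local alignment.

The model is a Plan7-lite local profile: match states M_1..M_L with
position-specific log-odds emissions, insert states emitting background
(log-odds supplied, usually 0), delete states, uniform local entry over
match states and free local exit. Scores are bits (log2 odds vs. the
background null); flanking residues outside the local alignment cancel
against the null and contribute nothing.

All kernels operate on uint8-encoded residue arrays (see alphabet.py) and
treat code 20 (X) as background (log-odds 0 is encoded directly in the
emission tables by the caller).
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def _lse2(a: float, b: float) -> float:
    """log2(2**a + 2**b), safe against the NEG sentinel."""
    if a < b:
        a, b = b, a
    if b <= NEG / 2:
        return a
    return a + math.log2(1.0 + 2.0 ** (b - a))


@njit(cache=True)
def viterbi_segments(seq, offsets, mlod, ilod,
                     tMM, tMI, tMD, tIM, tII, tDM, tDD,
                     entry, scores, starts, ends):
    """Best local-alignment bit score per stop-free segment.

    seq      : uint8 residue codes, all segments concatenated
    offsets  : int64 array, segment s spans seq[offsets[s]:offsets[s+1]]
    mlod     : (L, 22) match emission log-odds (bits)
    ilod     : (22,) insert emission log-odds (bits)
    t**      : (L,) transition log-odds; index j = transition out of
               position j (entries at j = L-1 that have no target are NEG)
    entry    : local entry bits, log2(1/L)
    scores/starts/ends : output arrays, one slot per segment; start/end are
               segment-local residue indices of the optimal alignment
    """
    L = mlod.shape[0]
    pM = np.empty(L)
    pI = np.empty(L)
    pD = np.empty(L)
    cM = np.empty(L)
    cI = np.empty(L)
    cD = np.empty(L)
    psM = np.empty(L, dtype=np.int64)
    psI = np.empty(L, dtype=np.int64)
    psD = np.empty(L, dtype=np.int64)
    csM = np.empty(L, dtype=np.int64)
    csI = np.empty(L, dtype=np.int64)
    csD = np.empty(L, dtype=np.int64)
    nseg = offsets.shape[0] - 1
    for s in range(nseg):
        a = offsets[s]
        b = offsets[s + 1]
        best = NEG
        best_start = 0
        best_end = 0
        for j in range(L):
            pM[j] = NEG
            pI[j] = NEG
            pD[j] = NEG
        for i in range(a, b):
            x = seq[i]
            for j in range(L):
                # match state j, consuming residue i
                v = entry
                st = i - a
                if j > 0:
                    w = pM[j - 1] + tMM[j - 1]
                    if w > v:
                        v = w
                        st = psM[j - 1]
                    w = pI[j - 1] + tIM[j - 1]
                    if w > v:
                        v = w
                        st = psI[j - 1]
                    w = pD[j - 1] + tDM[j - 1]
                    if w > v:
                        v = w
                        st = psD[j - 1]
                m = mlod[j, x] + v
                cM[j] = m
                csM[j] = st
                if m > best:
                    best = m
                    best_start = st
                    best_end = i - a + 1
                # insert state j (between match j and j+1)
                vi = NEG
                sti = 0
                w = pM[j] + tMI[j]
                if w > vi:
                    vi = w
                    sti = psM[j]
                w = pI[j] + tII[j]
                if w > vi:
                    vi = w
                    sti = psI[j]
                cI[j] = ilod[x] + vi
                csI[j] = sti
                # delete state j (within current row)
                vd = NEG
                std = 0
                if j > 0:
                    w = cM[j - 1] + tMD[j - 1]
                    if w > vd:
                        vd = w
                        std = csM[j - 1]
                    w = cD[j - 1] + tDD[j - 1]
                    if w > vd:
                        vd = w
                        std = csD[j - 1]
                cD[j] = vd
                csD[j] = std
            for j in range(L):
                pM[j] = cM[j]
                pI[j] = cI[j]
                pD[j] = cD[j]
                psM[j] = csM[j]
                psI[j] = csI[j]
                psD[j] = csD[j]
        scores[s] = best
        starts[s] = best_start
        ends[s] = best_end


@njit(cache=True)
def forward_segments(seq, offsets, mlod, ilod,
                     tMM, tMI, tMD, tIM, tII, tDM, tDD,
                     entry, scores):
    """Forward (log-sum over local paths) bit score per segment."""
    L = mlod.shape[0]
    pM = np.empty(L)
    pI = np.empty(L)
    pD = np.empty(L)
    cM = np.empty(L)
    cI = np.empty(L)
    cD = np.empty(L)
    nseg = offsets.shape[0] - 1
    for s in range(nseg):
        a = offsets[s]
        b = offsets[s + 1]
        total = NEG
        for j in range(L):
            pM[j] = NEG
            pI[j] = NEG
            pD[j] = NEG
        for i in range(a, b):
            x = seq[i]
            for j in range(L):
                v = entry
                if j > 0:
                    v = _lse2(v, pM[j - 1] + tMM[j - 1])
                    v = _lse2(v, pI[j - 1] + tIM[j - 1])
                    v = _lse2(v, pD[j - 1] + tDM[j - 1])
                m = mlod[j, x] + v
                cM[j] = m
                total = _lse2(total, m)
                vi = _lse2(pM[j] + tMI[j], pI[j] + tII[j])
                cI[j] = ilod[x] + vi
                if j > 0:
                    cD[j] = _lse2(cM[j - 1] + tMD[j - 1],
                                  cD[j - 1] + tDD[j - 1])
                else:
                    cD[j] = NEG
            for j in range(L):
                pM[j] = cM[j]
                pI[j] = cI[j]
                pD[j] = cD[j]
        scores[s] = total
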