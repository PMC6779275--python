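"""Numba kernels: production SSA / hybrid engines for cell ensembles.

These kernels implement exactly the reaction schedule specified by
:func:`ripoptosim.assembly.build_propensities` (the pure-Python reference
engine), using incrementally maintained group propensities so that a single
event costs O(n_origins) instead of a full channel rebuild.  A statistical
cross-check between the two engines is part of the test suite.

Layout conventions
------------------
``comp``   int64 (n_org, 11): per-origin composition
           [RIP1, RIP3, FADD, P8, FLIPL, FLIPS, DED12, DIM, HETL, HETS, TERM]
``pools``  int64 (7,): free cytosolic copies [RIP1, RIP3, FADD, P8, FL, FS, D12]
``P``      float64 parameter pack, see ``PP_*`` indices
``S``      float64 running sums of per-origin weights (exact: all weights are
           integers, so double accumulation is error-free)
``C``      int64 counters (cumulative outputs, per-window release buffers)
``y``      float64 (12,) deterministic cascade state in nM (see cascade.IDX)
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---- parameter pack indices -------------------------------------------------
(PP_SCALE, PP_KON_R1, PP_KOFF_R1, PP_KON_R3, PP_KOFF_R3, PP_KON_F, PP_KOFF_F,
 PP_KON_P8, PP_KOFF_P8, PP_KON_FL, PP_KOFF_FL, PP_KON_FS, PP_KOFF_FS,
 PP_KON_D12, PP_KOFF_D12, PP_K_CIS, PP_K_TRANS, PP_K_DIMDISS, PP_K_ACT,
 PP_K83, PP_K33, PP_K36, PP_K68, PP_K_DM, PP_KOFF_C8D, PP_KON_X, PP_KOFF_X,
 PP_KCAT_UB, PP_K_BDEG, PP_K_FRET, PP_FLIP_ACT, PP_X_RECYCLE, PP_THRESHOLD,
 PP_M_R1, PP_M_R3, PP_M_F, PP_M_P8, PP_M_FL, PP_M_FS, PP_M_D12,
 PP_K8M_DEG) = range(41)

N_PP = 41

# comp columns
(CC_R1, CC_R3, CC_F, CC_P8, CC_FL, CC_FS, CC_D12, CC_DIM, CC_HETL, CC_HETS,
 CC_TERM) = range(11)

# pool indices
PL_R1, PL_R3, PL_F, PL_P8, PL_FL, PL_FS, PL_D12 = range(7)

# sum indices
(SS_OPEN, SS_R1, SS_R3, SS_F, SS_SITES, SS_P8, SS_FL, SS_FS, SS_D12, SS_PAIR,
 SS_HPAIR_L, SS_HPAIR_S, SS_DIM, SS_HETL, SS_HETS, SS_TERMOFF, SS_TRANS) = range(17)
N_SS = 17

# counter indices
(CT_CUM_DIM, CT_CUM_DED12, CT_CUM_R1R3, CT_REL_DIM, CT_REL_MONO, CT_EVENTS,
 CT_CLAMP) = range(7)
N_CT = 7

# assembly reaction groups
(G_ELONG, G_R3B, G_FB, G_P8B, G_FLB, G_FSB, G_D12B, G_R1D, G_R3D, G_FD,
 G_P8D, G_FLD, G_FSD, G_D12D, G_UNB, G_CIS, G_HETL, G_HETS, G_DIMD, G_ACT,
 G_HLD, G_HSD, G_HLA, G_TR) = range(24)
N_G = 24

# record columns (hybrid/assembly)
REC_CUM_DIM = 0
REC_DED12 = 1
REC_R1R3 = 2
REC_MEAN_FADD = 3
REC_MAX_MASS = 4
REC_Y0 = 5            # 12 cascade states: columns 5..16
REC_RATE = 17
REC_POOL0 = 18        # 7 free pools: columns 18..24
N_REC = 25

TERM_OPEN = 0


@njit(cache=True)
def _koff_term(P, term):
    if term == 1:
        return P[PP_KOFF_P8]
    elif term == 2:
        return P[PP_KOFF_FL]
    elif term == 3:
        return P[PP_KOFF_FS]
    elif term == 4:
        return P[PP_KOFF_D12]
    return 0.0


@njit(cache=True)
def _sites_free(comp, i):
    return (comp[i, CC_F] - comp[i, CC_P8] - comp[i, CC_FL] - comp[i, CC_FS]
            - comp[i, CC_D12]
            - 2 * (comp[i, CC_DIM] + comp[i, CC_HETL] + comp[i, CC_HETS]))


@njit(cache=True)
def _init_sums(comp, P, cl_of, clS, clQ, clT, S):
    n = comp.shape[0]
    for k in range(N_SS):
        S[k] = 0.0
    clS[:] = 0.0
    clQ[:] = 0.0
    for i in range(n):
        if comp[i, CC_TERM] == TERM_OPEN:
            S[SS_OPEN] += 1.0
        else:
            S[SS_TERMOFF] += _koff_term(P, comp[i, CC_TERM])
        S[SS_R1] += comp[i, CC_R1]
        S[SS_R3] += comp[i, CC_R3]
        S[SS_F] += comp[i, CC_F]
        S[SS_SITES] += _sites_free(comp, i)
        p8 = comp[i, CC_P8]
        S[SS_P8] += p8
        S[SS_FL] += comp[i, CC_FL]
        S[SS_FS] += comp[i, CC_FS]
        S[SS_D12] += comp[i, CC_D12]
        S[SS_PAIR] += 0.5 * p8 * (p8 - 1)
        S[SS_HPAIR_L] += p8 * comp[i, CC_FL]
        S[SS_HPAIR_S] += p8 * comp[i, CC_FS]
        S[SS_DIM] += comp[i, CC_DIM]
        S[SS_HETL] += comp[i, CC_HETL]
        S[SS_HETS] += comp[i, CC_HETS]
        c = cl_of[i]
        clS[c] += p8
        clQ[c] += p8 * p8
    S[SS_TRANS] = 0.0
    for c in range(clS.shape[0]):
        clT[c] = 0.5 * (clS[c] * clS[c] - clQ[c])
        S[SS_TRANS] += clT[c]


@njit(cache=True)
def _p8_delta(i, old_p8, comp, cl_of, clS, clQ, clT, S):
    """Refresh homodimer-pair and cluster aggregates after nP8 changed on i.

    Hetero-pair sums (SS_HPAIR_*) are NOT touched here; events that change
    nP8 and nFL/nFS together adjust them explicitly from old values.
    """
    p8 = comp[i, CC_P8]
    S[SS_P8] += p8 - old_p8
    S[SS_PAIR] += 0.5 * (p8 * (p8 - 1) - old_p8 * (old_p8 - 1))
    c = cl_of[i]
    S[SS_TRANS] -= clT[c]
    clS[c] += p8 - old_p8
    clQ[c] += p8 * p8 - old_p8 * old_p8
    clT[c] = 0.5 * (clS[c] * clS[c] - clQ[c])
    S[SS_TRANS] += clT[c]


@njit(cache=True)
def _pick_col(comp, col, n, target):
    """Pick origin index weighted by an integer comp column (linear scan)."""
    acc = 0.0
    for i in range(n):
        acc += comp[i, col]
        if target < acc:
            return i
    return n - 1


@njit(cache=True)
def _assembly_rates(g, comp_n, pools, P, S, trans_on):
    """Fill the 24 assembly group propensities; returns (total, w_ded)."""
    scale = P[PP_SCALE]
    w_ded = S[SS_SITES] + S[SS_OPEN]  # DED-site binding + terminal blocking
    g[G_ELONG] = P[PP_KON_R1] * (pools[PL_R1] / scale) * S[SS_OPEN]
    g[G_R3B] = P[PP_KON_R3] * (pools[PL_R3] / scale) * S[SS_R1]
    g[G_FB] = P[PP_KON_F] * (pools[PL_F] / scale) * comp_n
    g[G_P8B] = P[PP_KON_P8] * (pools[PL_P8] / scale) * w_ded
    g[G_FLB] = P[PP_KON_FL] * (pools[PL_FL] / scale) * w_ded
    g[G_FSB] = P[PP_KON_FS] * (pools[PL_FS] / scale) * w_ded
    g[G_D12B] = P[PP_KON_D12] * (pools[PL_D12] / scale) * w_ded
    g[G_R1D] = P[PP_KOFF_R1] * (S[SS_R1] - comp_n)
    g[G_R3D] = P[PP_KOFF_R3] * S[SS_R3]
    g[G_FD] = P[PP_KOFF_F] * S[SS_SITES]
    g[G_P8D] = P[PP_KOFF_P8] * S[SS_P8]
    g[G_FLD] = P[PP_KOFF_FL] * S[SS_FL]
    g[G_FSD] = P[PP_KOFF_FS] * S[SS_FS]
    g[G_D12D] = P[PP_KOFF_D12] * S[SS_D12]
    g[G_UNB] = S[SS_TERMOFF]
    g[G_CIS] = P[PP_K_CIS] * S[SS_PAIR]
    g[G_HETL] = P[PP_K_CIS] * S[SS_HPAIR_L]
    g[G_HETS] = P[PP_K_CIS] * S[SS_HPAIR_S]
    g[G_DIMD] = P[PP_K_DIMDISS] * S[SS_DIM]
    g[G_ACT] = P[PP_K_ACT] * S[SS_DIM]
    g[G_HLD] = P[PP_K_DIMDISS] * S[SS_HETL]
    g[G_HSD] = P[PP_K_DIMDISS] * S[SS_HETS]
    g[G_HLA] = P[PP_K_ACT] * P[PP_FLIP_ACT] * S[SS_HETL]
    g[G_TR] = P[PP_K_TRANS] * S[SS_TRANS] if trans_on == 1 else 0.0
    tot = 0.0
    for k in range(N_G):
        tot += g[k]
    return tot, w_ded


@njit(cache=True)
def _apply_assembly_event(u, g, w_ded, comp, pools, P, cl_of, clS, clQ, clT,
                          cl_ptr, cl_members, S, C):
    """Dispatch and apply one assembly event; ``u`` is uniform on [0, sum g)."""
    n = comp.shape[0]
    if u < g[G_ELONG]:
        tgt = np.random.random() * S[SS_OPEN]
        acc = 0.0
        io = n - 1
        for i in range(n):
            if comp[i, CC_TERM] == TERM_OPEN:
                acc += 1.0
                if tgt < acc:
                    io = i
                    break
        pools[PL_R1] -= 1
        comp[io, CC_R1] += 1
        S[SS_R1] += 1.0
        return
    u -= g[G_ELONG]
    if u < g[G_R3B]:
        io = _pick_col(comp, CC_R1, n, np.random.random() * S[SS_R1])
        pools[PL_R3] -= 1
        comp[io, CC_R3] += 1
        S[SS_R3] += 1.0
        C[CT_CUM_R1R3] += 1
        return
    u -= g[G_R3B]
    if u < g[G_FB]:
        io = int(np.random.random() * n)
        if io >= n:
            io = n - 1
        pools[PL_F] -= 1
        comp[io, CC_F] += 1
        S[SS_F] += 1.0
        S[SS_SITES] += 1.0
        return
    u -= g[G_FB]
    # DED-species binding: to a free site, or to the filament end (blocking)
    for sp in range(4):
        gi = G_P8B + sp
        if u < g[gi]:
            tgt = np.random.random() * w_ded
            acc = 0.0
            io = n - 1
            at_end = False
            for i in range(n):
                sf = _sites_free(comp, i)
                op = 1.0 if comp[i, CC_TERM] == TERM_OPEN else 0.0
                acc += sf + op
                if tgt < acc:
                    io = i
                    at_end = tgt >= acc - op
                    break
            if sp == 0:
                pools[PL_P8] -= 1
            elif sp == 1:
                pools[PL_FL] -= 1
            elif sp == 2:
                pools[PL_FS] -= 1
            else:
                pools[PL_D12] -= 1
            if at_end:
                comp[io, CC_TERM] = sp + 1
                S[SS_OPEN] -= 1.0
                S[SS_TERMOFF] += _koff_term(P, sp + 1)
            else:
                if sp == 0:
                    old = comp[io, CC_P8]
                    comp[io, CC_P8] += 1
                    _p8_delta(io, old, comp, cl_of, clS, clQ, clT, S)
                    S[SS_HPAIR_L] += comp[io, CC_FL]
                    S[SS_HPAIR_S] += comp[io, CC_FS]
                elif sp == 1:
                    comp[io, CC_FL] += 1
                    S[SS_FL] += 1.0
                    S[SS_HPAIR_L] += comp[io, CC_P8]
                elif sp == 2:
                    comp[io, CC_FS] += 1
                    S[SS_FS] += 1.0
                    S[SS_HPAIR_S] += comp[io, CC_P8]
                else:
                    comp[io, CC_D12] += 1
                    S[SS_D12] += 1.0
                S[SS_SITES] -= 1.0
            return
        u -= g[gi]
    if u < g[G_R1D]:
        tgt = np.random.random() * (S[SS_R1] - n)
        acc = 0.0
        io = n - 1
        for i in range(n):
            acc += comp[i, CC_R1] - 1  # the seed subunit never leaves
            if tgt < acc:
                io = i
                break
        comp[io, CC_R1] -= 1
        pools[PL_R1] += 1
        S[SS_R1] -= 1.0
        return
    u -= g[G_R1D]
    if u < g[G_R3D]:
        io = _pick_col(comp, CC_R3, n, np.random.random() * S[SS_R3])
        comp[io, CC_R3] -= 1
        pools[PL_R3] += 1
        S[SS_R3] -= 1.0
        return
    u -= g[G_R3D]
    if u < g[G_FD]:
        # only FADD with an unoccupied DED site can leave
        tgt = np.random.random() * S[SS_SITES]
        acc = 0.0
        io = n - 1
        for i in range(n):
            acc += _sites_free(comp, i)
            if tgt < acc:
                io = i
                break
        comp[io, CC_F] -= 1
        pools[PL_F] += 1
        S[SS_F] -= 1.0
        S[SS_SITES] -= 1.0
        return
    u -= g[G_FD]
    if u < g[G_P8D]:
        io = _pick_col(comp, CC_P8, n, np.random.random() * S[SS_P8])
        old = comp[io, CC_P8]
        comp[io, CC_P8] -= 1
        pools[PL_P8] += 1
        _p8_delta(io, old, comp, cl_of, clS, clQ, clT, S)
        S[SS_HPAIR_L] -= comp[io, CC_FL]
        S[SS_HPAIR_S] -= comp[io, CC_FS]
        S[SS_SITES] += 1.0
        return
    u -= g[G_P8D]
    if u < g[G_FLD]:
        io = _pick_col(comp, CC_FL, n, np.random.random() * S[SS_FL])
        comp[io, CC_FL] -= 1
        pools[PL_FL] += 1
        S[SS_FL] -= 1.0
        S[SS_HPAIR_L] -= comp[io, CC_P8]
        S[SS_SITES] += 1.0
        return
    u -= g[G_FLD]
    if u < g[G_FSD]:
        io = _pick_col(comp, CC_FS, n, np.random.random() * S[SS_FS])
        comp[io, CC_FS] -= 1
        pools[PL_FS] += 1
        S[SS_FS] -= 1.0
        S[SS_HPAIR_S] -= comp[io, CC_P8]
        S[SS_SITES] += 1.0
        return
    u -= g[G_FSD]
    if u < g[G_D12D]:
        io = _pick_col(comp, CC_D12, n, np.random.random() * S[SS_D12])
        comp[io, CC_D12] -= 1
        pools[PL_D12] += 1
        S[SS_D12] -= 1.0
        S[SS_SITES] += 1.0
        return
    u -= g[G_D12D]
    if u < g[G_UNB]:
        tgt = np.random.random() * S[SS_TERMOFF]
        acc = 0.0
        io = n - 1
        for i in range(n):
            acc += _koff_term(P, comp[i, CC_TERM])
            if tgt < acc:
                io = i
                break
        code = comp[io, CC_TERM]
        if code == 1:
            pools[PL_P8] += 1
        elif code == 2:
            pools[PL_FL] += 1
        elif code == 3:
            pools[PL_FS] += 1
        elif code == 4:
            pools[PL_D12] += 1
        S[SS_TERMOFF] -= _koff_term(P, code)
        comp[io, CC_TERM] = TERM_OPEN
        S[SS_OPEN] += 1.0
        return
    u -= g[G_UNB]
    if u < g[G_CIS]:
        tgt = np.random.random() * S[SS_PAIR]
        acc = 0.0
        io = n - 1
        for i in range(n):
            p8 = comp[i, CC_P8]
            acc += 0.5 * p8 * (p8 - 1)
            if tgt < acc:
                io = i
                break
        old = comp[io, CC_P8]
        comp[io, CC_P8] -= 2
        comp[io, CC_DIM] += 1
        _p8_delta(io, old, comp, cl_of, clS, clQ, clT, S)
        S[SS_HPAIR_L] -= 2.0 * comp[io, CC_FL]
        S[SS_HPAIR_S] -= 2.0 * comp[io, CC_FS]
        S[SS_DIM] += 1.0
        return
    u -= g[G_CIS]
    if u < g[G_HETL]:
        tgt = np.random.random() * S[SS_HPAIR_L]
        acc = 0.0
        io = n - 1
        for i in range(n):
            acc += comp[i, CC_P8] * comp[i, CC_FL]
            if tgt < acc:
                io = i
                break
        old_p8 = comp[io, CC_P8]
        old_fl = comp[io, CC_FL]
        comp[io, CC_P8] -= 1
        comp[io, CC_FL] -= 1
        comp[io, CC_HETL] += 1
        _p8_delta(io, old_p8, comp, cl_of, clS, clQ, clT, S)
        S[SS_FL] -= 1.0
        S[SS_HETL] += 1.0
        S[SS_HPAIR_L] += comp[io, CC_P8] * comp[io, CC_FL] - old_p8 * old_fl
        S[SS_HPAIR_S] -= comp[io, CC_FS]
        return
    u -= g[G_HETL]
    if u < g[G_HETS]:
        tgt = np.random.random() * S[SS_HPAIR_S]
        acc = 0.0
        io = n - 1
        for i in range(n):
            acc += comp[i, CC_P8] * comp[i, CC_FS]
            if tgt < acc:
                io = i
                break
        old_p8 = comp[io, CC_P8]
        old_fs = comp[io, CC_FS]
        comp[io, CC_P8] -= 1
        comp[io, CC_FS] -= 1
        comp[io, CC_HETS] += 1
        _p8_delta(io, old_p8, comp, cl_of, clS, clQ, clT, S)
        S[SS_FS] -= 1.0
        S[SS_HETS] += 1.0
        S[SS_HPAIR_S] += comp[io, CC_P8] * comp[io, CC_FS] - old_p8 * old_fs
        S[SS_HPAIR_L] -= comp[io, CC_FL]
        return
    u -= g[G_HETS]
    if u < g[G_DIMD]:
        io = _pick_col(comp, CC_DIM, n, np.random.random() * S[SS_DIM])
        comp[io, CC_DIM] -= 1
        old = comp[io, CC_P8]
        comp[io, CC_P8] += 2
        _p8_delta(io, old, comp, cl_of, clS, clQ, clT, S)
        S[SS_HPAIR_L] += 2.0 * comp[io, CC_FL]
        S[SS_HPAIR_S] += 2.0 * comp[io, CC_FS]
        S[SS_DIM] -= 1.0
        return
    u -= g[G_DIMD]
    if u < g[G_ACT]:
        # dimer cleavage: one active Casp8 dimer + one DED1-DED2 released;
        # the two DED sites it occupied are regenerated (FADD stays bound)
        io = _pick_col(comp, CC_DIM, n, np.random.random() * S[SS_DIM])
        comp[io, CC_DIM] -= 1
        S[SS_DIM] -= 1.0
        S[SS_SITES] += 2.0
        pools[PL_D12] += 1
        C[CT_CUM_DIM] += 1
        C[CT_CUM_DED12] += 1
        C[CT_REL_DIM] += 1
        return
    u -= g[G_ACT]
    if u < g[G_HLD]:
        io = _pick_col(comp, CC_HETL, n, np.random.random() * S[SS_HETL])
        old_p8 = comp[io, CC_P8]
        old_fl = comp[io, CC_FL]
        comp[io, CC_HETL] -= 1
        comp[io, CC_P8] += 1
        comp[io, CC_FL] += 1
        _p8_delta(io, old_p8, comp, cl_of, clS, clQ, clT, S)
        S[SS_HETL] -= 1.0
        S[SS_FL] += 1.0
        S[SS_HPAIR_L] += comp[io, CC_P8] * comp[io, CC_FL] - old_p8 * old_fl
        S[SS_HPAIR_S] += comp[io, CC_FS]
        return
    u -= g[G_HLD]
    if u < g[G_HSD]:
        io = _pick_col(comp, CC_HETS, n, np.random.random() * S[SS_HETS])
        old_p8 = comp[io, CC_P8]
        old_fs = comp[io, CC_FS]
        comp[io, CC_HETS] -= 1
        comp[io, CC_P8] += 1
        comp[io, CC_FS] += 1
        _p8_delta(io, old_p8, comp, cl_of, clS, clQ, clT, S)
        S[SS_HETS] -= 1.0
        S[SS_FS] += 1.0
        S[SS_HPAIR_S] += comp[io, CC_P8] * comp[io, CC_FS] - old_p8 * old_fs
        S[SS_HPAIR_L] += comp[io, CC_FL]
        return
    u -= g[G_HSD]
    if u < g[G_HLA]:
        # catalytically active cFLIPl heterodimer (off by default): releases
        # one cleaved Casp8 monomer + DED1-DED2, cFLIPl stays platform-bound
        io = _pick_col(comp, CC_HETL, n, np.random.random() * S[SS_HETL])
        comp[io, CC_HETL] -= 1
        comp[io, CC_FL] += 1
        S[SS_HETL] -= 1.0
        S[SS_FL] += 1.0
        S[SS_HPAIR_L] += comp[io, CC_P8]
        S[SS_SITES] += 1.0
        pools[PL_D12] += 1
        C[CT_CUM_DED12] += 1
        C[CT_REL_MONO] += 1
        return
    u -= g[G_HLA]
    # trans-dimerization within one receptor cluster
    tgt = np.random.random() * S[SS_TRANS]
    acc = 0.0
    c = clS.shape[0] - 1
    for ci in range(clS.shape[0]):
        acc += clT[ci]
        if tgt < acc:
            c = ci
            break
    tgt = np.random.random() * 2.0 * clT[c]
    acc = 0.0
    io = -1
    for k in range(cl_ptr[c], cl_ptr[c + 1]):
        i = cl_members[k]
        acc += comp[i, CC_P8] * (clS[c] - comp[i, CC_P8])
        if tgt < acc:
            io = i
            break
    if io < 0:
        return
    rest = clS[c] - comp[io, CC_P8]
    tgt = np.random.random() * rest
    acc = 0.0
    jo = -1
    for k in range(cl_ptr[c], cl_ptr[c + 1]):
        j = cl_members[k]
        if j == io:
            continue
        acc += comp[j, CC_P8]
        if tgt < acc:
            jo = j
            break
    if jo < 0:
        return
    old = comp[io, CC_P8]
    comp[io, CC_P8] -= 1
    _p8_delta(io, old, comp, cl_of, clS, clQ, clT, S)
    S[SS_HPAIR_L] -= comp[io, CC_FL]
    S[SS_HPAIR_S] -= comp[io, CC_FS]
    old = comp[jo, CC_P8]
    comp[jo, CC_P8] -= 1
    _p8_delta(jo, old, comp, cl_of, clS, clQ, clT, S)
    S[SS_HPAIR_L] -= comp[jo, CC_FL]
    S[SS_HPAIR_S] -= comp[jo, CC_FS]
    # dimer hosted on io (occupies two sites there); jo's site is freed
    comp[io, CC_DIM] += 1
    S[SS_DIM] += 1.0
    return


@njit(cache=True)
def _ssa_until(t0, t_target, comp, pools, P, cl_of, clS, clQ, clT,
               cl_ptr, cl_members, trans_on, S, C, g):
    """Advance the assembly SSA to ``t_target`` with frozen cascade state."""
    n = comp.shape[0]
    t = t0
    while True:
        a0, w_ded = _assembly_rates(g, n, pools, P, S, trans_on)
        if a0 <= 0.0:
            return t_target
        dt = -np.log(np.random.random()) / a0
        if t + dt > t_target:
            return t_target  # memoryless: redraw next window
        t += dt
        C[CT_EVENTS] += 1
        u = np.random.random() * a0
        _apply_assembly_event(u, g, w_ded, comp, pools, P, cl_of, clS, clQ,
                              clT, cl_ptr, cl_members, S, C)


@njit(cache=True)
def _cascade_rhs_nb(y, P, src, dy):
    c8d = y[0]
    c8m = y[1]
    pc8 = y[2]
    pc3 = y[3]
    c3 = y[4]
    pc6 = y[5]
    c6 = y[6]
    xf = y[7]
    xc3 = y[8]
    fi = y[10]
    dim = P[PP_K_DM] * c8m * c8m
    bind = P[PP_KON_X] * xf * c3
    unbind = P[PP_KOFF_X] * xc3
    ub = P[PP_KCAT_UB] * xc3
    cleave3 = P[PP_K83] * c8d * pc3 + P[PP_K33] * c3 * pc3
    cleave6 = P[PP_K36] * c3 * pc6
    cleave8 = P[PP_K68] * c6 * pc8
    fret = P[PP_K_FRET] * c8d * fi
    dy[0] = src + 0.5 * dim - P[PP_KOFF_C8D] * c8d
    dy[1] = (cleave8 + 2.0 * P[PP_KOFF_C8D] * c8d - dim
             - P[PP_K8M_DEG] * c8m)
    dy[2] = -cleave8
    dy[3] = -cleave3
    dy[4] = cleave3 - bind + unbind - P[PP_K_BDEG] * c3
    dy[5] = -cleave6
    dy[6] = cleave6 - P[PP_K_BDEG] * c6
    dy[7] = -bind + unbind + P[PP_X_RECYCLE] * ub
    dy[8] = bind - unbind - ub
    dy[9] = ub + P[PP_K_BDEG] * c3
    dy[10] = -fret
    dy[11] = fret


@njit(cache=True)
def _rk4_advance(y, P, src, dt, h):
    k1 = np.empty(12)
    k2 = np.empty(12)
    k3 = np.empty(12)
    k4 = np.empty(12)
    yt = np.empty(12)
    t = 0.0
    while t < dt - 1e-12:
        step = min(h, dt - t)
        _cascade_rhs_nb(y, P, src, k1)
        for m in range(12):
            yt[m] = y[m] + 0.5 * step * k1[m]
        _cascade_rhs_nb(yt, P, src, k2)
        for m in range(12):
            yt[m] = y[m] + 0.5 * step * k2[m]
        _cascade_rhs_nb(yt, P, src, k3)
        for m in range(12):
            yt[m] = y[m] + step * k3[m]
        _cascade_rhs_nb(yt, P, src, k4)
        for m in range(12):
            y[m] += step / 6.0 * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
            if y[m] < 0.0:
                y[m] = 0.0
        t += step


@njit(cache=True)
def _max_mass(comp, P):
    best = 0.0
    for i in range(comp.shape[0]):
        m = (comp[i, CC_R1] * P[PP_M_R1] + comp[i, CC_R3] * P[PP_M_R3]
             + comp[i, CC_F] * P[PP_M_F]
             + (comp[i, CC_P8] + 2 * comp[i, CC_DIM] + comp[i, CC_HETL]
                + comp[i, CC_HETS]) * P[PP_M_P8]
             + (comp[i, CC_FL] + comp[i, CC_HETL]) * P[PP_M_FL]
             + (comp[i, CC_FS] + comp[i, CC_HETS]) * P[PP_M_FS]
             + comp[i, CC_D12] * P[PP_M_D12])
        term = comp[i, CC_TERM]
        if term == 1:
            m += P[PP_M_P8]
        elif term == 2:
            m += P[PP_M_FL]
        elif term == 3:
            m += P[PP_M_FS]
        elif term == 4:
            m += P[PP_M_D12]
        if m > best:
            best = m
    return best


@njit(cache=True)
def _record(rec, gi, comp, pools, y, P, C, n):
    rec[gi, REC_CUM_DIM] = C[CT_CUM_DIM]
    rec[gi, REC_DED12] = C[CT_CUM_DED12]
    rec[gi, REC_R1R3] = C[CT_CUM_R1R3]
    if n > 0:
        sfadd = 0.0
        for i in range(n):
            sfadd += comp[i, CC_F]
        rec[gi, REC_MEAN_FADD] = sfadd / n
        rec[gi, REC_MAX_MASS] = _max_mass(comp, P)
    for m in range(12):
        rec[gi, REC_Y0 + m] = y[m]
    rec[gi, REC_RATE] = P[PP_K_FRET] * y[0] * y[10]
    for m in range(7):
        rec[gi, REC_POOL0 + m] = pools[m]


@njit(cache=True)
def simulate_cell_kernel(seed, comp, pools, P, cl_of, cl_ptr, cl_members,
                         trans_on, y0, dt_sync, grid, rk_h, cascade_on, rec):
    """Hybrid (or assembly-only) simulation of one cell.

    Operator splitting with fixed step ``dt_sync``: the assembly SSA advances
    with frozen cascade state; dimers released in a window become a
    piecewise-constant source for the cascade ODEs over the same window; the
    shared free ProCasp8 pool is reconciled after each window (Casp6-cleaved
    ProCasp8 is debited from the SSA pool, clamped at zero with a counter).

    Records on the regular output grid (``rec`` has one row per grid time).
    Returns (death_time, death_idx, filled_idx, clamp_count, n_events).
    Death is the first grid crossing of the FRET cleavage-rate threshold,
    linearly interpolated between grid points; -1 if never crossed.
    """
    np.random.seed(seed)
    n_cl = cl_ptr.shape[0] - 1
    clS = np.zeros(n_cl)
    clQ = np.zeros(n_cl)
    clT = np.zeros(n_cl)
    S = np.zeros(N_SS)
    C = np.zeros(N_CT, dtype=np.int64)
    g = np.zeros(N_G)
    _init_sums(comp, P, cl_of, clS, clQ, clT, S)
    y = y0.copy()
    scale = P[PP_SCALE]
    thr = P[PP_THRESHOLD]
    n = comp.shape[0]

    n_grid = rec.shape[0]
    rec_every = max(1, int(round(grid / dt_sync)))

    gi = 0
    _record(rec, gi, comp, pools, y, P, C, n)
    prev_rate = rec[gi, REC_RATE]
    death_time = -1.0
    death_idx = -1
    pc8_debt = 0.0

    t = 0.0
    w = 0
    while gi < n_grid - 1:
        t_next = t + dt_sync
        C[CT_REL_DIM] = 0
        C[CT_REL_MONO] = 0
        if n > 0:
            _ssa_until(t, t_next, comp, pools, P, cl_of, clS, clQ, clT,
                       cl_ptr, cl_members, trans_on, S, C, g)
        if cascade_on == 1:
            src = C[CT_REL_DIM] / scale / dt_sync
            y[2] = pools[PL_P8] / scale
            pc8_before = y[2]
            _rk4_advance(y, P, src, dt_sync, rk_h)
            y[1] += C[CT_REL_MONO] / scale
            pc8_debt += (pc8_before - y[2]) * scale
            if pc8_debt >= 1.0:
                k = int(pc8_debt)
                pc8_debt -= k
                if pools[PL_P8] >= k:
                    pools[PL_P8] -= k
                else:
                    C[CT_CLAMP] += 1
                    pools[PL_P8] = 0
        t = t_next
        w += 1
        if w % rec_every == 0:
            gi += 1
            _record(rec, gi, comp, pools, y, P, C, n)
            rate = rec[gi, REC_RATE]
            if cascade_on == 1 and rate >= thr:
                if rate > prev_rate and prev_rate < thr:
                    frac = (thr - prev_rate) / (rate - prev_rate)
                else:
                    frac = 1.0
                death_time = (gi - 1) * grid + frac * grid
                death_idx = gi
                break
            prev_rate = rate
    return death_time, death_idx, gi, C[CT_CLAMP], C[CT_EVENTS]


@njit(cache=True)
def simulate_cell_full_ssa_kernel(seed, comp, pools, P, cl_of, cl_ptr,
                                  cl_members, trans_on, casc0, grid, rec):
    """Full-SSA reference: the cascade is simulated in discrete copies too.

    One exact SSA clock is shared by assembly and cascade reactions.
    ``casc0`` holds the initial cascade copy numbers [C8d, C8m, PC3, C3, PC6,
    C6, Xf, XC3, C3deg_cum, FRETi, FRETc]; free ProCasp8 lives in ``pools``.
    Observables match the hybrid kernel row-for-row.
    """
    np.random.seed(seed)
    n_cl = cl_ptr.shape[0] - 1
    clS = np.zeros(n_cl)
    clQ = np.zeros(n_cl)
    clT = np.zeros(n_cl)
    S = np.zeros(N_SS)
    C = np.zeros(N_CT, dtype=np.int64)
    g = np.zeros(N_G)
    _init_sums(comp, P, cl_of, clS, clQ, clT, S)
    n = comp.shape[0]
    scale = P[PP_SCALE]
    thr = P[PP_THRESHOLD]
    kc = 1.0 / scale

    c8d = casc0[0]
    c8m = casc0[1]
    pc3 = casc0[2]
    c3 = casc0[3]
    pc6 = casc0[4]
    c6 = casc0[5]
    xf = casc0[6]
    xc3 = casc0[7]
    c3deg = casc0[8]
    freti = casc0[9]
    fretc = casc0[10]

    n_grid = rec.shape[0]
    y = np.zeros(12)

    gi = 0
    y[0] = c8d / scale
    y[1] = c8m / scale
    y[2] = pools[PL_P8] / scale
    y[3] = pc3 / scale
    y[4] = c3 / scale
    y[5] = pc6 / scale
    y[6] = c6 / scale
    y[7] = xf / scale
    y[8] = xc3 / scale
    y[9] = c3deg / scale
    y[10] = freti / scale
    y[11] = fretc / scale
    _record(rec, gi, comp, pools, y, P, C, n)
    prev_rate = rec[gi, REC_RATE]
    death_time = -1.0
    death_idx = -1

    t = 0.0
    t_grid = grid
    while gi < n_grid - 1:
        a_asm, w_ded = _assembly_rates(g, n, pools, P, S, trans_on)

        b = np.zeros(12)
        b[0] = P[PP_KOFF_C8D] * c8d
        b[1] = P[PP_K_DM] * kc * 0.5 * c8m * (c8m - 1) if c8m > 1 else 0.0
        b[2] = P[PP_K83] * kc * c8d * pc3
        b[3] = P[PP_K33] * kc * c3 * pc3
        b[4] = P[PP_K36] * kc * c3 * pc6
        b[5] = P[PP_K68] * kc * c6 * pools[PL_P8]
        b[6] = P[PP_KON_X] * kc * xf * c3
        b[7] = P[PP_KOFF_X] * xc3
        b[8] = P[PP_KCAT_UB] * xc3
        b[9] = P[PP_K_BDEG] * c3
        b[10] = P[PP_K_BDEG] * c6
        b[11] = P[PP_K_FRET] * kc * c8d * freti
        b12 = P[PP_K8M_DEG] * c8m
        a_cas = b12
        for m in range(12):
            a_cas += b[m]

        a0 = a_asm + a_cas
        if a0 <= 0.0:
            t = t_grid
        else:
            t += -np.log(np.random.random()) / a0

        hit_death = False
        while t >= t_grid - 1e-12 and gi < n_grid - 1:
            gi += 1
            y[0] = c8d / scale
            y[1] = c8m / scale
            y[2] = pools[PL_P8] / scale
            y[3] = pc3 / scale
            y[4] = c3 / scale
            y[5] = pc6 / scale
            y[6] = c6 / scale
            y[7] = xf / scale
            y[8] = xc3 / scale
            y[9] = c3deg / scale
            y[10] = freti / scale
            y[11] = fretc / scale
            _record(rec, gi, comp, pools, y, P, C, n)
            rate = rec[gi, REC_RATE]
            if rate >= thr:
                if rate > prev_rate and prev_rate < thr:
                    frac = (thr - prev_rate) / (rate - prev_rate)
                else:
                    frac = 1.0
                death_time = (gi - 1) * grid + frac * grid
                death_idx = gi
                hit_death = True
                break
            prev_rate = rate
            t_grid += grid
        if hit_death or gi >= n_grid - 1 or a0 <= 0.0:
            if hit_death or gi >= n_grid - 1:
                break
            continue

        C[CT_EVENTS] += 1
        u = np.random.random() * a0
        if u < a_asm:
            _apply_assembly_event(u, g, w_ded, comp, pools, P, cl_of, clS,
                                  clQ, clT, cl_ptr, cl_members, S, C)
            if C[CT_REL_DIM] > 0:
                c8d += C[CT_REL_DIM]
                C[CT_REL_DIM] = 0
            if C[CT_REL_MONO] > 0:
                c8m += C[CT_REL_MONO]
                C[CT_REL_MONO] = 0
            continue
        u -= a_asm
        if u < b[0]:
            c8d -= 1
            c8m += 2
        elif u < b[0] + b[1]:
            c8m -= 2
            c8d += 1
        elif u < b[0] + b[1] + b[2]:
            pc3 -= 1
            c3 += 1
        elif u < b[0] + b[1] + b[2] + b[3]:
            pc3 -= 1
            c3 += 1
        elif u < b[0] + b[1] + b[2] + b[3] + b[4]:
            pc6 -= 1
            c6 += 1
        elif u < b[0] + b[1] + b[2] + b[3] + b[4] + b[5]:
            pools[PL_P8] -= 1
            c8m += 1
        elif u < b[0] + b[1] + b[2] + b[3] + b[4] + b[5] + b[6]:
            xf -= 1
            c3 -= 1
            xc3 += 1
        elif u < b[0] + b[1] + b[2] + b[3] + b[4] + b[5] + b[6] + b[7]:
            xc3 -= 1
            xf += 1
            c3 += 1
        elif u < b[0] + b[1] + b[2] + b[3] + b[4] + b[5] + b[6] + b[7] + b[8]:
            xc3 -= 1
            c3deg += 1
            if np.random.random() < P[PP_X_RECYCLE]:
                xf += 1
        elif u < (b[0] + b[1] + b[2] + b[3] + b[4] + b[5] + b[6] + b[7] + b[8]
                  + b[9]):
            c3 -= 1
            c3deg += 1
        elif u < (b[0] + b[1] + b[2] + b[3] + b[4] + b[5] + b[6] + b[7] + b[8]
                  + b[9] + b[10]):
            c6 -= 1
        elif u < (b[0] + b[1] + b[2] + b[3] + b[4] + b[5] + b[6] + b[7] + b[8]
                  + b[9] + b[10] + b[11]):
            freti -= 1
            fretc += 1
        else:
            c8m -= 1
    return death_time, death_idx, gi, C[CT_CLAMP], C[CT_EVENTS]
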