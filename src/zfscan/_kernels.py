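"""Numba inner loops for the two dynamic programs.

Everything here works on pre-encoded integer sequences (0..19 = amino
acids in alphabetical one-letter order, 20 = X) and log2-space parameter
arrays.  The surrounding modules own all bookkeeping; the kernels are pure
array-in / numbers-out.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = float("-inf")


@njit(cache=True)
def viterbi_local(codes, lo, ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, lentry, lexit):
    """Best local match-to-match path through a profile HMM.

    ``codes``: (L,) int64 residue codes.  ``lo``: (M, 21) match-emission
    log2-odds (column 20 = X = 0).  Transition arrays are (M,) log2
    probabilities indexed by source node (entries for transitions that
    leave the model are -inf).  Insert emissions are background-tied so
    their log-odds contribution is zero.

    Returns (score, start, end): the best path score in bits and the
    0-based inclusive residue indices it spans.  Paths enter at a match
    state (cost lentry[k]) and leave from a match state (cost lexit[k]).
    """
    L = codes.shape[0]
    M = lo.shape[0]

    prevM = np.full(M, NEG_INF)
    prevI = np.full(M, NEG_INF)
    prevD = np.full(M, NEG_INF)
    curM = np.full(M, NEG_INF)
    curI = np.full(M, NEG_INF)
    curD = np.full(M, NEG_INF)
    # start-position propagation (index of first emitted residue)
    sPM = np.zeros(M, np.int64)
    sPI = np.zeros(M, np.int64)
    sPD = np.zeros(M, np.int64)
    sCM = np.zeros(M, np.int64)
    sCI = np.zeros(M, np.int64)
    sCD = np.zeros(M, np.int64)

    best = NEG_INF
    best_start = 0
    best_end = -1

    for i in range(L):
        c = codes[i]
        for k in range(M):
            # --- match state k, emits residue i
            v = lentry[k]
            s = i
            if k > 0:
                a = prevM[k - 1] + ltMM[k - 1]
                if a > v:
                    v = a
                    s = sPM[k - 1]
                a = prevI[k - 1] + ltIM[k - 1]
                if a > v:
                    v = a
                    s = sPI[k - 1]
                a = prevD[k - 1] + ltDM[k - 1]
                if a > v:
                    v = a
                    s = sPD[k - 1]
            vm = v + lo[k, c]
            curM[k] = vm
            sCM[k] = s

            # --- insert state k, emits residue i at background odds (0)
            v = prevM[k] + ltMI[k]
            s = sPM[k]
            a = prevI[k] + ltII[k]
            if a > v:
                v = a
                s = sPI[k]
            curI[k] = v
            sCI[k] = s

            # --- delete state k, silent (same row)
            if k > 0:
                v = curM[k - 1] + ltMD[k - 1]
                s = sCM[k - 1]
                a = curD[k - 1] + ltDD[k - 1]
                if a > v:
                    v = a
                    s = sCD[k - 1]
                curD[k] = v
                sCD[k] = s
            else:
                curD[k] = NEG_INF
                sCD[k] = i

            end_score = vm + lexit[k]
            if end_score > best:
                best = end_score
                best_start = sCM[k]
                best_end = i

        prevM, curM = curM, prevM
        prevI, curI = curI, prevI
        prevD, curD = curD, prevD
        sPM, sCM = sCM, sPM
        sPI, sCI = sCI, sPI
        sPD, sCD = sCD, sPD

    return best, best_start, best_end


@njit(cache=True)
def viterbi_local_traceback(codes, lo, ltMM, ltMI, ltMD, ltIM, ltII, ltDM, ltDD, lentry, lexit):
    """Full-matrix variant storing backpointers for path recovery.

    Returns (score, end_i, end_k, bpM, bpI, bpD) where the bp arrays are
    (L, M) int8: for M cells 0=fresh entry, 1=from M, 2=from I, 3=from D;
    for I cells 0=from M, 1=from I; for D cells 0=from M, 1=from D.
    """
    L = codes.shape[0]
    M = lo.shape[0]
    VM = np.full((L, M), NEG_INF)
    VI = np.full((L, M), NEG_INF)
    VD = np.full((L, M), NEG_INF)
    bpM = np.zeros((L, M), np.int8)
    bpI = np.zeros((L, M), np.int8)
    bpD = np.zeros((L, M), np.int8)

    best = NEG_INF
    end_i = -1
    end_k = -1

    for i in range(L):
        c = codes[i]
        for k in range(M):
            v = lentry[k]
            p = 0
            if k > 0 and i > 0:
                a = VM[i - 1, k - 1] + ltMM[k - 1]
                if a > v:
                    v = a
                    p = 1
                a = VI[i - 1, k - 1] + ltIM[k - 1]
                if a > v:
                    v = a
                    p = 2
                a = VD[i - 1, k - 1] + ltDM[k - 1]
                if a > v:
                    v = a
                    p = 3
            VM[i, k] = v + lo[k, c]
            bpM[i, k] = p

            if i > 0:
                v = VM[i - 1, k] + ltMI[k]
                p = 0
                a = VI[i - 1, k] + ltII[k]
                if a > v:
                    v = a
                    p = 1
                VI[i, k] = v
                bpI[i, k] = p

            if k > 0:
                v = VM[i, k - 1] + ltMD[k - 1]
                p = 0
                a = VD[i, k - 1] + ltDD[k - 1]
                if a > v:
                    v = a
                    p = 1
                VD[i, k] = v
                bpD[i, k] = p

            e = VM[i, k] + lexit[k]
            if e > best:
                best = e
                end_i = i
                end_k = k

    return best, end_i, end_k, bpM, bpI, bpD


@njit(cache=True)
def sw_score(a, b, sub, gap_open, gap_extend):
    """Affine-gap Smith-Waterman optimum score (no traceback).

    A gap of length g costs gap_open + (g - 1) * gap_extend.
    """
    n = a.shape[0]
    m = b.shape[0]
    prevH = np.zeros(m + 1)
    prevE = np.full(m + 1, NEG_INF)
    curH = np.zeros(m + 1)
    curE = np.full(m + 1, NEG_INF)
    best = 0.0
    for i in range(1, n + 1):
        curH[0] = 0.0
        curE[0] = NEG_INF
        f = NEG_INF
        for j in range(1, m + 1):
            # E: gap in subject (consumes query residue, vertical move)
            e = prevH[j] - gap_open
            a2 = prevE[j] - gap_extend
            if a2 > e:
                e = a2
            curE[j] = e
            # F: gap in query (horizontal move)
            f2 = curH[j - 1] - gap_open
            if f - gap_extend > f2:
                f2 = f - gap_extend
            f = f2
            h = prevH[j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            curH[j] = h
            if h > best:
                best = h
        prevH, curH = curH, prevH
        prevE, curE = curE, prevE
    return best


@njit(cache=True)
def sw_full(a, b, sub, gap_open, gap_extend):
    """Affine-gap Smith-Waterman with stored matrices for traceback.

    Returns (best, end_i, end_j, H, E, F).  Ties on the optimum favour the
    earliest end cell in row-major scan order.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)
    F = np.full((n + 1, m + 1), NEG_INF)
    best = 0.0
    end_i = 0
    end_j = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i - 1, j] - gap_open
            a2 = E[i - 1, j] - gap_extend
            if a2 > e:
                e = a2
            E[i, j] = e
            f = H[i, j - 1] - gap_open
            a2 = F[i, j - 1] - gap_extend
            if a2 > f:
                f = a2
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                end_i = i
                end_j = j
    return best, end_i, end_j, H, E, F
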