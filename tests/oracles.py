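"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's kernels: the Viterbi oracle
enumerates every admissible state path by depth-first search, and the
local-alignment oracles are a plain-Python affine-gap recursion plus a
tiny exhaustive path enumerator that cross-checks it.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


def enumerate_viterbi(hmm, residues: str) -> float:
    """Max log2-odds over all single-domain paths, by explicit DFS.

    Paths enter at any match state on any residue, move through
    match/insert/delete states, and exit from a match state.  Returns
    -inf when no admissible path exists.
    """
    logs = hmm._logs()
    lo = logs["lo"]
    lentry, lexit = logs["lentry"], logs["lexit"]
    tMM, tMI, tMD = logs["ltMM"], logs["ltMI"], logs["ltMD"]
    tIM, tII = logs["ltIM"], logs["ltII"]
    tDM, tDD = logs["ltDM"], logs["ltDD"]
    from zfscan.profile_hmm import encode

    codes = encode(residues)
    L, M = len(codes), hmm.M
    best = [-math.inf]

    def dfs(state: str, k: int, i: int, acc: float) -> None:
        # i = index of last consumed residue
        if acc == -math.inf:
            return
        if state == "M":
            best[0] = max(best[0], acc + lexit[k])
            if k + 1 < M:
                if i + 1 < L:
                    dfs("M", k + 1, i + 1, acc + tMM[k] + lo[k + 1, codes[i + 1]])
                dfs("D", k + 1, i, acc + tMD[k])
            if i + 1 < L:
                dfs("I", k, i + 1, acc + tMI[k])
        elif state == "I":
            if i + 1 < L:
                dfs("I", k, i + 1, acc + tII[k])
                if k + 1 < M:
                    dfs("M", k + 1, i + 1, acc + tIM[k] + lo[k + 1, codes[i + 1]])
        else:  # D
            if k + 1 < M:
                dfs("D", k + 1, acc=acc + tDD[k], i=i)
                if i + 1 < L:
                    dfs("M", k + 1, i + 1, acc + tDM[k] + lo[k + 1, codes[i + 1]])

    for i0 in range(L):
        for k0 in range(M):
            dfs("M", k0, i0, lentry[k0] + lo[k0, codes[i0]])
    return best[0]


def gotoh_local(a: str, b: str, sub: dict, gap_open: float, gap_extend: float) -> float:
    """Plain-Python affine-gap local alignment optimum (Gotoh recursion).

    ``sub`` maps residue pairs to scores.  A gap of length g costs
    gap_open + (g-1)*gap_extend.
    """
    n, m = len(a), len(b)
    NEG = -math.inf
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + sub[(a[i - 1], b[j - 1])],
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def enumerate_local(a: str, b: str, sub: dict, gap_open: float, gap_extend: float) -> float:
    """Exhaustive enumeration of every local alignment path (tiny inputs).

    Walks all monotone move sequences (diag/up/left) from every start
    cell with affine gap accounting; used to validate :func:`gotoh_local`.
    """
    n, m = len(a), len(b)
    best = [0.0]

    def dfs(i: int, j: int, acc: float, last: str) -> None:
        best[0] = max(best[0], acc)
        if i < n and j < m:
            dfs(i + 1, j + 1, acc + sub[(a[i], b[j])], "d")
        if i < n:
            cost = gap_extend if last == "u" else gap_open
            dfs(i + 1, j, acc - cost, "u")
        if j < m:
            cost = gap_extend if last == "l" else gap_open
            dfs(i, j + 1, acc - cost, "l")

    for i in range(n):
        for j in range(m):
            dfs(i + 1, j + 1, sub[(a[i], b[j])], "d")
    return best[0]


def sub_dict(matrix: np.ndarray, alphabet: str) -> dict:
    return {
        (x, y): float(matrix[i, j])
        for i, x in enumerate(alphabet)
        for j, y in enumerate(alphabet)
    }
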