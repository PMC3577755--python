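"""Numba kernels for affine-gap global alignment (Gotoh, three matrices).

The kernel works on a precomputed column-vs-column score matrix so the same
code aligns two sequences or two profiles.  Traceback tie-break is fixed:
diagonal beats vertical beats horizontal, which makes every alignment in the
package deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def _gotoh(S, gap_open, gap_ext):  # pragma: no cover - exercised via wrapper
    n, m = S.shape
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)  # gap in the row sequence (move left)
    F = np.full((n + 1, m + 1), NEG)  # gap in the column sequence (move up)
    # pointers: for H, 0=diag 1=up(F) 2=left(E); for E/F, 0=open-from-H 1=extend
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -gap_open - (j - 1) * gap_ext
        H[0, j] = E[0, j]
        ptrH[0, j] = 2
        ptrE[0, j] = 1
    for i in range(1, n + 1):
        F[i, 0] = -gap_open - (i - 1) * gap_ext
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 1
        ptrF[i, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_ext
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 0
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 0
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            best = diag
            ptr = 0
            if F[i, j] > best:
                best = F[i, j]
                ptr = 1
            if E[i, j] > best:
                best = E[i, j]
                ptr = 2
            H[i, j] = best
            ptrH[i, j] = ptr
    # traceback: ops 0=diag 1=up 2=left, reversed order
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    state = 0  # 0=H 1=F 2=E
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif p == 1:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            k += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
        else:
            ops[k] = 2
            k += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
    return H[n, m], ops[:k][::-1].copy()


def gotoh_align(score_matrix: np.ndarray, gap_open: float, gap_extend: float):
    """Align two position sets given their pairwise score matrix.

    Returns ``(score, ops)`` where ops is an int8 array over
    {0: diagonal, 1: consume row position, 2: consume column position}.
    """
    S = np.ascontiguousarray(score_matrix, dtype=np.float64)
    if S.shape[0] == 0 or S.shape[1] == 0:
        raise ValueError("cannot align empty sequences")
    return _gotoh(S, float(gap_open), float(gap_extend))
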