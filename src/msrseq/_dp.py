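"""Numba dynamic-programming kernels for the native aligners.

All scores are integers scaled by 40 so that quality-interpolated
mismatch penalties stay exact and score ties are well-defined.

The "glocal" kernel aligns the full read (global in the read) against any
substring of the reference (local in the reference) under affine-gap
scoring with match bonus 0 — the end-to-end contract of a sensitive
short-read mapper.  The "local" kernel is a plain Smith-Waterman used
only to locate 5' extensions before mapping.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**8)

# cigar op codes (SAM convention)
OP_M = 0
OP_I = 1
OP_D = 2


@njit(cache=True)
def glocal_score(read, pen, ref, gap_open, gap_extend):
    """Best scaled score of the full read vs any reference substring.

    read, ref: uint8 code arrays (A=0 C=1 G=2 T=3 N=4).
    pen: per-read-base scaled mismatch penalty (N handled by caller).
    Gap of length L costs gap_open + L * gap_extend (scaled).
    """
    n = read.shape[0]
    m = ref.shape[0]
    first_gap = gap_open + gap_extend

    M_prev = np.empty(m + 1, dtype=np.int64)
    I_prev = np.empty(m + 1, dtype=np.int64)
    D_prev = np.empty(m + 1, dtype=np.int64)
    M_cur = np.empty(m + 1, dtype=np.int64)
    I_cur = np.empty(m + 1, dtype=np.int64)
    D_cur = np.empty(m + 1, dtype=np.int64)

    for j in range(m + 1):
        M_prev[j] = 0  # free start anywhere in the reference
        I_prev[j] = NEG
        D_prev[j] = NEG

    for i in range(1, n + 1):
        rb = read[i - 1]
        p = pen[i - 1]
        M_cur[0] = NEG
        D_cur[0] = NEG
        a = M_prev[0] - first_gap
        b = I_prev[0] - gap_extend
        I_cur[0] = a if a > b else b
        for j in range(1, m + 1):
            best_prev = M_prev[j - 1]
            if I_prev[j - 1] > best_prev:
                best_prev = I_prev[j - 1]
            if D_prev[j - 1] > best_prev:
                best_prev = D_prev[j - 1]
            if rb == ref[j - 1] and rb != 4:
                M_cur[j] = best_prev
            else:
                M_cur[j] = best_prev - p
            a = M_prev[j] - first_gap
            b = I_prev[j] - gap_extend
            I_cur[j] = a if a > b else b
            a = M_cur[j - 1] - first_gap
            b = D_cur[j - 1] - gap_extend
            D_cur[j] = a if a > b else b
        M_prev, M_cur = M_cur, M_prev
        I_prev, I_cur = I_cur, I_prev
        D_prev, D_cur = D_cur, D_prev

    best = NEG
    for j in range(m + 1):
        if M_prev[j] > best:
            best = M_prev[j]
        if I_prev[j] > best:
            best = I_prev[j]
    return best


@njit(cache=True)
def glocal_align(read, pen, ref, gap_open, gap_extend):
    """Full-matrix glocal alignment with traceback.

    Returns (score, ref_start, ref_end, ops, n_ops) where ops is an int8
    array of cigar op codes in reference order.  Ties at the final row are
    broken toward the smallest reference end; traceback prefers M over I
    over D.
    """
    n = read.shape[0]
    m = ref.shape[0]
    first_gap = gap_open + gap_extend

    M = np.empty((n + 1, m + 1), dtype=np.int64)
    I = np.empty((n + 1, m + 1), dtype=np.int64)
    D = np.empty((n + 1, m + 1), dtype=np.int64)

    for j in range(m + 1):
        M[0, j] = 0
        I[0, j] = NEG
        D[0, j] = NEG
    for i in range(1, n + 1):
        rb = read[i - 1]
        p = pen[i - 1]
        M[i, 0] = NEG
        D[i, 0] = NEG
        a = M[i - 1, 0] - first_gap
        b = I[i - 1, 0] - gap_extend
        I[i, 0] = a if a > b else b
        for j in range(1, m + 1):
            best_prev = M[i - 1, j - 1]
            if I[i - 1, j - 1] > best_prev:
                best_prev = I[i - 1, j - 1]
            if D[i - 1, j - 1] > best_prev:
                best_prev = D[i - 1, j - 1]
            if rb == ref[j - 1] and rb != 4:
                M[i, j] = best_prev
            else:
                M[i, j] = best_prev - p
            a = M[i - 1, j] - first_gap
            b = I[i - 1, j] - gap_extend
            I[i, j] = a if a > b else b
            a = M[i, j - 1] - first_gap
            b = D[i, j - 1] - gap_extend
            D[i, j] = a if a > b else b

    best = NEG
    best_j = 0
    best_state = 0  # 0=M, 1=I
    for j in range(m + 1):
        if M[n, j] > best:
            best = M[n, j]
            best_j = j
            best_state = 0
        if I[n, j] > best:
            best = I[n, j]
            best_j = j
            best_state = 1

    ops = np.empty(n + m + 1, dtype=np.int8)
    n_ops = 0
    i = n
    j = best_j
    state = best_state
    while i > 0:
        if state == 0:  # M
            if j == 0:
                break
            rb = read[i - 1]
            if rb == ref[j - 1] and rb != 4:
                sub = 0
            else:
                sub = pen[i - 1]
            target = M[i, j] + sub
            ops[n_ops] = OP_M
            n_ops += 1
            if M[i - 1, j - 1] == target:
                state = 0
            elif I[i - 1, j - 1] == target:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:  # insertion: consumes read
            ops[n_ops] = OP_I
            n_ops += 1
            if M[i - 1, j] == I[i, j] + first_gap:
                state = 0
            else:
                state = 1
            i -= 1
        else:  # deletion: consumes reference
            ops[n_ops] = OP_D
            n_ops += 1
            if M[i, j - 1] == D[i, j] + first_gap:
                state = 0
            else:
                state = 2
            j -= 1

    ref_start = j
    # reverse into alignment order
    out = np.empty(n_ops, dtype=np.int8)
    for k in range(n_ops):
        out[k] = ops[n_ops - 1 - k]
    return best, ref_start, best_j, out, n_ops


@njit(cache=True)
def local_align(read, ref, match, mismatch, gap_open, gap_extend):
    """Smith-Waterman local alignment (affine), returning the best path ends.

    Returns (score, read_start, ref_start, read_end, ref_end); ends are
    exclusive.  Used to locate the aligned core of a read so that 5'
    overhang projecting beyond reference position 0 can be trimmed.
    """
    n = read.shape[0]
    m = ref.shape[0]
    first_gap = gap_open + gap_extend

    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in ref (consumes read)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in read (consumes ref)

    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            a = H[i - 1, j] - first_gap
            b = E[i - 1, j] - gap_extend
            E[i, j] = a if a > b else b
            a = H[i, j - 1] - first_gap
            b = F[i, j - 1] - gap_extend
            F[i, j] = a if a > b else b
            s = match if read[i - 1] == ref[j - 1] and read[i - 1] != 4 else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                best_i = i
                best_j = j

    # traceback to the path start (state machine: 0=H, 1=E, 2=F)
    i = best_i
    j = best_j
    state = 0
    while True:
        if state == 0:
            if i == 0 or j == 0 or H[i, j] == 0:
                break
            s = match if read[i - 1] == ref[j - 1] and read[i - 1] != 4 else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if E[i, j] == H[i - 1, j] - first_gap:
                state = 0
            i -= 1
        else:
            if F[i, j] == H[i, j - 1] - first_gap:
                state = 0
            j -= 1
    return best, i, j, best_i, best_j
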