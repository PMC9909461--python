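"""Numba kernels for wraparound dynamic programming against a cyclic motif.

State space: D[i, j] where i = number of sequence characters consumed and
j = index of the next motif character (phase).  Transitions: diagonal
(consume one sequence char against motif[j-1]), up (insertion in the
sequence), left (deletion of a motif char, same row).  Left moves wrap
j = p-1 -> 0, so each row is relaxed in two passes; deleting a full motif
cycle is strictly negative and never optimal, hence two passes suffice.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18

# transition codes
DIAG, UP, LEFT = 0, 1, 2


def encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _relax_row(D_prev, D_row, ptr_row, seq_code, motif, match, mismatch, gap):
    p = motif.shape[0]
    # up and diagonal first
    for j in range(p):
        jm = (j - 1) % p
        best = D_prev[j] + gap
        arg = UP
        sub = match if (seq_code == motif[jm] and seq_code < 4) else mismatch
        d = D_prev[jm] + sub
        if d >= best:
            best = d
            arg = DIAG
        D_row[j] = best
        ptr_row[j] = arg
    # two passes of left (motif deletion) relaxation with wraparound
    for _ in range(2):
        for j in range(p):
            jm = (j - 1) % p
            cand = D_row[jm] + gap
            if cand > D_row[j]:
                D_row[j] = cand
                ptr_row[j] = LEFT


@njit(cache=True)
def wrap_global(codes, motif, match, mismatch, gap):
    """Global-in-sequence wraparound alignment starting at motif phase 0.

    Returns (score, end_phase, ptr) where ptr is the (L+1, p) int8 pointer
    matrix for traceback; the path may end at any phase (partial last unit).
    """
    L = codes.shape[0]
    p = motif.shape[0]
    D_prev = np.full(p, NEG)
    D_row = np.full(p, NEG)
    ptr = np.zeros((L + 1, p), dtype=np.int8)
    # row 0: start at phase 0; leading motif deletions are disallowed so the
    # first unit starts on a full-unit boundary.
    D_prev[0] = 0.0
    for i in range(1, L + 1):
        _relax_row(D_prev, D_row, ptr[i], codes[i - 1], motif, match, mismatch, gap)
        for j in range(p):
            D_prev[j] = D_row[j]
            D_row[j] = NEG
    best_j = 0
    for j in range(p):
        if D_prev[j] > D_prev[best_j]:
            best_j = j
    return D_prev[best_j], best_j, ptr


@njit(cache=True)
def traceback_global(ptr, end_phase):
    """Walk the pointer matrix back from (L, end_phase).

    Returns (steps, phases) arrays, forward order: per transition its type
    and the motif phase *consumed* (for DIAG/LEFT) or -1 (UP).
    """
    L = ptr.shape[0] - 1
    p = ptr.shape[1]
    max_steps = 2 * (L + p) + 4
    steps = np.empty(max_steps, dtype=np.int8)
    phases = np.empty(max_steps, dtype=np.int64)
    n = 0
    i, j = L, end_phase
    while i > 0 or j != 0:
        t = ptr[i, j]
        jm = (j - 1) % p
        if i == 0:
            # only LEFT moves possible in row 0; disallowed by construction
            break
        if t == DIAG:
            steps[n] = DIAG
            phases[n] = jm
            i -= 1
            j = jm
        elif t == UP:
            steps[n] = UP
            phases[n] = -1
            i -= 1
        else:
            steps[n] = LEFT
            phases[n] = jm
            j = jm
        n += 1
        if j == 0 and i == 0:
            break
    return steps[:n][::-1].copy(), phases[:n][::-1].copy()
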