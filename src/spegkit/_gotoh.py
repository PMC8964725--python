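"""Banded affine-gap (Gotoh) semi-global alignment kernel.

The read is aligned globally, the reference locally (overhanging reference
ends are free). Scoring: +match for identities, +mismatch (negative) for
substitutions, and a gap of length g costs gap_open + g * gap_extend.

The fill runs inside a diagonal band wide enough for the expected indel
sizes; a band spanning the whole reference reproduces the unbanded optimum.
Compiled with numba; the traceback returns compact op codes
(0 = diagonal, 1 = insertion into the read, 2 = deletion from the read).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 8)


@njit(cache=False)
def _fill(q: np.ndarray, r: np.ndarray, match: int, mismatch: int,
          gap_open: int, gap_ext: int, band: int):
    m, n = len(q), len(r)
    M = np.full((m + 1, n + 1), NEG, np.int32)
    X = np.full((m + 1, n + 1), NEG, np.int32)  # gap in reference (insertion)
    Y = np.full((m + 1, n + 1), NEG, np.int32)  # gap in read (deletion)
    pM = np.zeros((m + 1, n + 1), np.uint8)
    pX = np.zeros((m + 1, n + 1), np.uint8)
    pY = np.zeros((m + 1, n + 1), np.uint8)
    for j in range(n + 1):
        M[0, j] = 0  # free reference prefix
    for i in range(1, m + 1):
        X[i, 0] = -(gap_open + i * gap_ext)
        pX[i, 0] = 1 if i > 1 else 0
    diff = n - m
    lo_shift = diff if diff < 0 else 0
    hi_shift = diff if diff > 0 else 0
    for i in range(1, m + 1):
        lo = i + lo_shift - band
        if lo < 1:
            lo = 1
        hi = i + hi_shift + band
        if hi > n:
            hi = n
        for j in range(lo, hi + 1):
            s = match if q[i - 1] == r[j - 1] else mismatch
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            if best > NEG:
                M[i, j] = best + s
                pM[i, j] = ptr
            xo = M[i - 1, j] - gap_open - gap_ext
            xe = X[i - 1, j] - gap_ext
            if xe > xo:
                X[i, j] = xe
                pX[i, j] = 1
            elif xo > NEG:
                X[i, j] = xo
                pX[i, j] = 0
            yo = M[i, j - 1] - gap_open - gap_ext
            ye = Y[i, j - 1] - gap_ext
            if ye > yo:
                Y[i, j] = ye
                pY[i, j] = 1
            elif yo > NEG:
                Y[i, j] = yo
                pY[i, j] = 0
    return M, X, pM, pX, pY


@njit(cache=False)
def _traceback(q_len: int, M: np.ndarray, X: np.ndarray, pM: np.ndarray,
               pX: np.ndarray, pY: np.ndarray):
    m = q_len
    n = M.shape[1] - 1
    best = NEG
    best_j = 0
    state = 0  # 0 = M, 1 = X, 2 = Y
    for j in range(n + 1):  # smallest j wins ties -> leftmost end point
        if M[m, j] > best:
            best = M[m, j]
            best_j = j
            state = 0
        if X[m, j] > best:
            best = X[m, j]
            best_j = j
            state = 1
    ops = np.empty(m + n + 2, np.uint8)
    k = 0
    i, j = m, best_j
    while i > 0:
        if state == 0:
            ops[k] = 0
            k += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            k += 1
            state = 0 if pX[i, j] == 0 else 1
            i -= 1
        else:
            ops[k] = 2
            k += 1
            state = 0 if pY[i, j] == 0 else 2
            j -= 1
    return best, j, ops[:k][::-1].copy()


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def semiglobal_align(read: str, ref: str, match: int = 2, mismatch: int = -4,
                     gap_open: int = 6, gap_ext: int = 1,
                     band: int | None = None) -> tuple[int, int, np.ndarray]:
    """Align `read` (global) against `ref` (local ends free).

    Returns (score, ref_start, ops) where ops are 0/1/2 per aligned column.
    `band=None` uses the full dynamic-programming matrix.
    """
    q, r = encode(read), encode(ref)
    if band is None:
        band = max(len(q), len(r))
    M, X, pM, pX, pY = _fill(q, r, match, mismatch, gap_open, gap_ext, band)
    return _traceback(len(q), M, X, pM, pX, pY)
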