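"""Independent brute-force alignment oracles for the test suite.

These are full dynamic-programming alignments with explicit traceback,
written from scratch (numba-accelerated double loops) so they share no code
with the package's alignment engines.  Scoring convention matches the
package default: the first gap character costs ``gap_open`` and each further
character ``gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("oracle only handles A/C/G/T")
    return arr


@njit(cache=True)
def _sw_fill(q, t, match, mismatch, gap_open, gap_extend):
    m, n = q.size, t.size
    H = np.zeros((m + 1, n + 1), dtype=np.float32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.float32)  # gap in query
    F = np.full((m + 1, n + 1), NEG, dtype=np.float32)  # gap in target
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 stop 1 diag 2 E 3 F
    best = 0.0
    bi = bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            f = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if q[i - 1] == t[j - 1] else mismatch
            d = max(H[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1]) + s
            h = d
            p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            if h <= 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            ptr[i, j] = p
            if h > best:
                best = h
                bi, bj = i, j
    return H, E, F, ptr, best, bi, bj


@njit(cache=True)
def _sw_traceback(q, t, H, E, F, ptr, bi, bj, gap_open, gap_extend):
    """Walk back from the best cell; returns (matches, mismatches, gapcols,
    qstart, sstart).  Within gap runs the state machine re-derives whether
    the gap was opened or extended."""
    i, j = bi, bj
    matches = 0
    mismatches = 0
    gapcols = 0
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            if q[i - 1] == t[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:  # gap in query: consume target columns
            while True:
                gapcols += 1
                opened = H[i, j - 1] + gap_open >= E[i, j - 1] + gap_extend
                j -= 1
                if opened:
                    break
        else:  # gap in target: consume query rows
            while True:
                gapcols += 1
                opened = H[i - 1, j] + gap_open >= F[i - 1, j] + gap_extend
                i -= 1
                if opened:
                    break
    return matches, mismatches, gapcols, i, j


def sw_local(query: str, target: str, match: float = 1.0,
             mismatch: float = -2.0, gap_open: float = -5.0,
             gap_extend: float = -1.0) -> dict:
    """Optimal local alignment by exhaustive affine-gap DP.

    Returns score, matches, mismatches, gap columns, identity (percent,
    gap columns in the denominator) and the aligned query span.
    """
    q, t = _encode(query), _encode(target)
    H, E, F, ptr, best, bi, bj = _sw_fill(q, t, match, mismatch,
                                          gap_open, gap_extend)
    matches, mismatches, gapcols, qs, ss = _sw_traceback(
        q, t, H, E, F, ptr, bi, bj, gap_open, gap_extend)
    columns = matches + mismatches + gapcols
    return {
        "score": float(best),
        "matches": int(matches),
        "mismatches": int(mismatches),
        "gap_columns": int(gapcols),
        "columns": int(columns),
        "identity_percent": 100.0 * matches / columns if columns else 0.0,
        "q_start": int(qs), "q_end": int(bi),
        "s_start": int(ss), "s_end": int(bj),
    }


@njit(cache=True)
def _nw_fill(q, t, match, mismatch, gap_open, gap_extend):
    m, n = q.size, t.size
    H = np.full((m + 1, n + 1), NEG, dtype=np.float64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.float64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.float64)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, m + 1):
        F[i, 0] = gap_open + gap_extend * (i - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if q[i - 1] == t[j - 1] else mismatch
            prev = max(H[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1])
            H[i, j] = prev + s
    return H, E, F


@njit(cache=True)
def _nw_traceback(q, t, H, E, F, gap_open, gap_extend):
    i, j = q.size, t.size
    # state: 0=H 1=E 2=F; choose the best final state
    state = 0
    best = H[i, j]
    if E[i, j] > best:
        best = E[i, j]
        state = 1
    if F[i, j] > best:
        best = F[i, j]
        state = 2
    matches = 0
    mismatches = 0
    gapcols = 0
    while i > 0 or j > 0:
        if state == 0:
            prev = max(H[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1])
            if q[i - 1] == t[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
            if i == 0 and j == 0:
                break
            if prev == H[i, j]:
                state = 0
            elif prev == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            gapcols += 1
            opened = H[i, j - 1] + gap_open >= E[i, j - 1] + gap_extend
            j -= 1
            state = 0 if opened else 1
            if j == 0 and i > 0 and state == 0:
                state = 2
        else:
            gapcols += 1
            opened = H[i - 1, j] + gap_open >= F[i - 1, j] + gap_extend
            i -= 1
            state = 0 if opened else 2
            if i == 0 and j > 0 and state == 0:
                state = 1
    return best, matches, mismatches, gapcols


def nw_global(seq_a: str, seq_b: str, match: float = 1.0,
              mismatch: float = -2.0, gap_open: float = -5.0,
              gap_extend: float = -1.0) -> dict:
    """Optimal global alignment difference counts by exhaustive DP.

    ``n_aligned`` counts both-base columns, as in the barcode idiom.
    """
    q, t = _encode(seq_a), _encode(seq_b)
    H, E, F = _nw_fill(q, t, match, mismatch, gap_open, gap_extend)
    score, matches, mismatches, gapcols = _nw_traceback(
        q, t, H, E, F, gap_open, gap_extend)
    return {
        "score": float(score),
        "n_aligned": int(matches + mismatches),
        "n_substitutions": int(mismatches),
        "n_indel_columns": int(gapcols),
    }
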