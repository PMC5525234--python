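"""Affine-gap global alignment with position-dependent gap-open costs.

The DP core is a three-state Gotoh algorithm (match, deletion-of-reference,
insertion-in-query) with free terminal gaps on both sequences, so that query
termini longer or shorter than the reference flanks are not penalized.  Gap
opening can be made more expensive inside declared reference segments, which
is how the mapping layer keeps transmembrane helices ungapped.

Conventions (fixed so that tracebacks are deterministic):
  * state preference on ties is match > gap-in-query > gap-in-reference;
  * among equal-scoring end cells the full corner is preferred, then later
    reference positions, then later query positions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .reference_frame import STANDARD_RESIDUES

#: Alphabet used by the DP core: the 20 standard residues plus X (index 20).
ALPHABET = STANDARD_RESIDUES + "X"
X_INDEX = 20
_AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

NEG_INF = -1e30


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string as uint8 indices; ambiguity codes become X."""
    return np.array([_AA_TO_INDEX.get(ch, X_INDEX) for ch in sequence.upper()],
                    dtype=np.uint8)


def substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A 21x21 float matrix over ALPHABET.

    X scores the matrix floor against everything (a mismatch, never a match),
    regardless of what the named matrix says about ambiguity codes.
    """
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    out = np.empty((21, 21), dtype=np.float64)
    floor = float(np.min(np.asarray(mat)))
    out[:] = floor
    for i, a in enumerate(STANDARD_RESIDUES):
        for j, b in enumerate(STANDARD_RESIDUES):
            out[i, j] = mat[a, b]
    return out


@njit(cache=True)
def _gotoh_fill(a, b, sub, del_open, ins_open, gap_extend):
    """Fill the three DP matrices and their traceback pointers.

    a: encoded reference (length n); b: encoded query (length m).
    del_open[i]: cost of opening a gap that deletes reference residue i.
    ins_open[i]: cost of opening an insertion after i reference residues.
    Terminal gaps on both sequences are free.
    """
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF)
    D = np.full((n + 1, m + 1), NEG_INF)
    I = np.full((n + 1, m + 1), NEG_INF)
    # pointer codes: 0 = came from M, 1 = from D, 2 = from I
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pD = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pI = np.zeros((n + 1, m + 1), dtype=np.uint8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 0] = 0.0  # leading deletions free
        pD[i, 0] = 1
    pD[1, 0] = 0
    for j in range(1, m + 1):
        I[0, j] = 0.0  # leading insertions free
        pI[0, j] = 2
    pI[0, 1] = 0

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state
            best = M[i - 1, j - 1]
            ptr = 0
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
                ptr = 1
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + sub[a[i - 1], b[j - 1]]
            pM[i, j] = ptr

            # deletion of reference residue i (gap in query)
            od = del_open[i - 1]
            best = M[i - 1, j] - od
            ptr = 0
            if D[i - 1, j] - gap_extend > best:
                best = D[i - 1, j] - gap_extend
                ptr = 1
            if I[i - 1, j] - od > best:
                best = I[i - 1, j] - od
                ptr = 2
            D[i, j] = best
            pD[i, j] = ptr

            # insertion of query residue j (gap in reference)
            oi = ins_open[i]
            best = M[i, j - 1] - oi
            ptr = 0
            if D[i, j - 1] - oi > best:
                best = D[i, j - 1] - oi
                ptr = 1
            if I[i, j - 1] - gap_extend > best:
                best = I[i, j - 1] - gap_extend
                ptr = 2
            I[i, j] = best
            pI[i, j] = ptr
    return M, D, I, pM, pD, pI


@njit(cache=True)
def _best_state(M, D, I, i, j):
    best = M[i, j]
    state = 0
    if D[i, j] > best:
        best = D[i, j]
        state = 1
    if I[i, j] > best:
        best = I[i, j]
        state = 2
    return best, state


@njit(cache=True)
def _traceback(a_len, b_len, M, D, I, pM, pD, pI):
    """Pick the best end cell (free terminal gaps) and walk back.

    Returns (score, ref_cols, qry_cols) where the column arrays hold 0-based
    indices or -1 for a gap, in alignment order.
    """
    n, m = a_len, b_len
    # end-cell search: corner first, then last column by descending i,
    # then last row by descending j
    score, state = _best_state(M, D, I, n, m)
    ei, ej = n, m
    for i in range(n - 1, -1, -1):
        s, st = _best_state(M, D, I, i, m)
        if s > score:
            score, state, ei, ej = s, st, i, m
    for j in range(m - 1, -1, -1):
        s, st = _best_state(M, D, I, n, j)
        if s > score:
            score, state, ei, ej = s, st, n, j

    max_cols = n + m
    ref_cols = np.empty(max_cols, dtype=np.int32)
    qry_cols = np.empty(max_cols, dtype=np.int32)
    k = max_cols

    # trailing free gaps
    for i in range(n - 1, ei - 1, -1):
        k -= 1
        ref_cols[k] = i
        qry_cols[k] = -1
    for j in range(m - 1, ej - 1, -1):
        k -= 1
        ref_cols[k] = -1
        qry_cols[k] = j

    i, j = ei, ej
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 and j == 0:
                break
            prev = pM[i, j]
            k -= 1
            ref_cols[k] = i - 1
            qry_cols[k] = j - 1
            i -= 1
            j -= 1
            state = prev
        elif state == 1:
            prev = pD[i, j]
            k -= 1
            ref_cols[k] = i - 1
            qry_cols[k] = -1
            i -= 1
            state = prev
        else:
            prev = pI[i, j]
            k -= 1
            ref_cols[k] = -1
            qry_cols[k] = j - 1
            j -= 1
            state = prev
    return score, ref_cols[k:], qry_cols[k:]


def align(a: np.ndarray, b: np.ndarray, sub: np.ndarray,
          del_open: np.ndarray, ins_open: np.ndarray,
          gap_extend: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Align encoded sequences; returns (score, ref_cols, qry_cols)."""
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("cannot align an empty sequence")
    M, D, I, pM, pD, pI = _gotoh_fill(a, b, sub, del_open, ins_open,
                                      float(gap_extend))
    return _traceback(a.shape[0], b.shape[0], M, D, I, pM, pD, pI)
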