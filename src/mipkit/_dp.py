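"""Affine-gap global alignment kernel (Gotoh three-state DP).

The kernel is shared by residue-vs-residue alignment and profile-vs-profile
alignment: both reduce to a precomputed column-score matrix ``S`` plus gap
penalties.  A gap of length L costs ``gap_open + (L - 1) * gap_extend``
(the opening charge includes the first gapped position); terminal gaps are
penalized like internal ones.

Tie-breaking is deterministic: diagonal > up (gap in the second sequence) >
left (gap in the first), applied both in the state recurrences and at the
final cell, so the traceback is unique.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30  # effectively -infinity without NaN arithmetic


@njit(cache=True)
def _gotoh_fill(S, gap_open, gap_extend):
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in sequence b (move "up")
    Y = np.full((n + 1, m + 1), NEG)  # gap in sequence a (move "left")
    tbM = np.zeros((n + 1, m + 1), np.int8)
    tbX = np.zeros((n + 1, m + 1), np.int8)
    tbY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        tbX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
        tbY[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: consume one position of each; best predecessor, diag>up>left
            best = M[i - 1, j - 1]
            src = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = 2
            M[i, j] = best + S[i - 1, j - 1]
            tbM[i, j] = src
            # X: gap in b; open from M preferred on ties
            o = M[i - 1, j] - gap_open
            e = X[i - 1, j] - gap_extend
            if o >= e:
                X[i, j] = o
                tbX[i, j] = 0
            else:
                X[i, j] = e
                tbX[i, j] = 1
            # Y: gap in a; open from M preferred on ties
            o = M[i, j - 1] - gap_open
            e = Y[i, j - 1] - gap_extend
            if o >= e:
                Y[i, j] = o
                tbY[i, j] = 0
            else:
                Y[i, j] = e
                tbY[i, j] = 2
    return M, X, Y, tbM, tbX, tbY


@njit(cache=True)
def _traceback(M, X, Y, tbM, tbX, tbY):
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    state = 0
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        state = 1
    if Y[n, m] > best:
        best = Y[n, m]
        state = 2
    ops = np.empty(n + m, np.int8)  # 0 diag, 1 up, 2 left (reversed order)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = 0
            state = tbM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = tbX[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = tbY[i, j]
            j -= 1
        k += 1
    return best, ops[:k][::-1].copy()


def align_matrix(S: np.ndarray, gap_open: float, gap_extend: float):
    """Optimal global alignment over a precomputed score matrix.

    Parameters
    ----------
    S : (n, m) float array
        ``S[i, j]`` is the score for aligning position i of the first
        sequence/profile with position j of the second.
    gap_open, gap_extend : float
        Positive penalties; a length-L gap costs ``open + (L-1) * extend``.

    Returns
    -------
    score : float
    ops : int8 array
        Edit path, one entry per alignment column: 0 = match column,
        1 = gap in the second sequence, 2 = gap in the first.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    if S.shape[0] == 0 or S.shape[1] == 0:
        raise ValueError("empty sequence/profile")
    M, X, Y, tbM, tbX, tbY = _gotoh_fill(S, float(gap_open), float(gap_extend))
    return _traceback(M, X, Y, tbM, tbX, tbY)
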