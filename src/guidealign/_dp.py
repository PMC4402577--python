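"""Affine-gap dynamic-programming kernels (Gotoh three-state recursion).

The fill routines operate on a precomputed column-score matrix ``S``
where ``S[i, j]`` is the score for pairing position ``i`` of the first
input with position ``j`` of the second — residue substitution scores
for pairwise alignment, expected profile-profile scores for merges.

A gap of length ``k`` costs ``open + (k - 1) * extend``.

Tracebacks compare candidate predecessors in the exact arithmetic form
used during the fill, so float equality is reliable.  Tie-break order
is diagonal, then gap-in-second (up), then gap-in-first (left); in
local mode a fresh start is taken only when no continuation ties.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

NEG = -1.0e30

#: traceback move codes
DIAG, UP, LEFT, STOP = 0, 1, 2, 3


@njit(cache=True)
def fill_global(S: np.ndarray, go: float, ge: float):
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in second input (consume first)
    Y = np.full((n + 1, m + 1), NEG)  # gap in first input (consume second)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + (j - 1) * ge)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + S[i - 1, j - 1]

            best = M[i - 1, j] - go
            if X[i - 1, j] - ge > best:
                best = X[i - 1, j] - ge
            if Y[i - 1, j] - go > best:
                best = Y[i - 1, j] - go
            X[i, j] = best

            best = M[i, j - 1] - go
            if X[i, j - 1] - go > best:
                best = X[i, j - 1] - go
            if Y[i, j - 1] - ge > best:
                best = Y[i, j - 1] - ge
            Y[i, j] = best
    return M, X, Y


@njit(cache=True)
def fill_local(S: np.ndarray, go: float, ge: float):
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = 0.0
            if M[i - 1, j - 1] > best:
                best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + S[i - 1, j - 1]

            best = M[i - 1, j] - go
            if X[i - 1, j] - ge > best:
                best = X[i - 1, j] - ge
            if Y[i - 1, j] - go > best:
                best = Y[i - 1, j] - go
            X[i, j] = best

            best = M[i, j - 1] - go
            if X[i, j - 1] - go > best:
                best = X[i, j - 1] - go
            if Y[i, j - 1] - ge > best:
                best = Y[i, j - 1] - ge
            Y[i, j] = best
    return M, X, Y


_M_STATE, _X_STATE, _Y_STATE = 0, 1, 2


def traceback_global(S, M, X, Y, go, ge):
    """Return (score, moves) for the optimal global alignment.

    ``moves`` is a list of DIAG/UP/LEFT codes from start to end.
    """
    n, m = S.shape
    candidates = (M[n, m], X[n, m], Y[n, m])
    score = max(candidates)
    state = candidates.index(score)  # prefers M, then X, then Y
    i, j = n, m
    moves = []
    while i > 0 or j > 0:
        if state == _M_STATE:
            cur = M[i, j]
            s = S[i - 1, j - 1]
            if M[i - 1, j - 1] + s == cur:
                state = _M_STATE
            elif X[i - 1, j - 1] + s == cur:
                state = _X_STATE
            else:
                state = _Y_STATE
            moves.append(DIAG)
            i -= 1
            j -= 1
        elif state == _X_STATE:
            cur = X[i, j]
            if j == 0:
                state = _M_STATE if i == 1 else _X_STATE
            elif M[i - 1, j] - go == cur:
                state = _M_STATE
            elif X[i - 1, j] - ge == cur:
                state = _X_STATE
            else:
                state = _Y_STATE
            moves.append(UP)
            i -= 1
        else:
            cur = Y[i, j]
            if i == 0:
                state = _M_STATE if j == 1 else _Y_STATE
            elif M[i, j - 1] - go == cur:
                state = _M_STATE
            elif X[i, j - 1] - go == cur:
                state = _X_STATE
            else:
                state = _Y_STATE
            moves.append(LEFT)
            j -= 1
    moves.reverse()
    return float(score), moves


def traceback_local(S, M, X, Y, go, ge):
    """Return (score, start_i, start_j, moves) for the optimal local alignment.

    The empty alignment (score 0) is returned as ``(0.0, 0, 0, [])``.
    The end cell is the first maximum in row-major order.
    """
    n, m = S.shape
    best = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i, j] > best:
                best = M[i, j]
                bi, bj = i, j
    if best <= 0.0:
        return 0.0, 0, 0, []
    i, j = bi, bj
    state = _M_STATE
    moves = []
    while True:
        if state == _M_STATE:
            cur = M[i, j]
            s = S[i - 1, j - 1]
            moves.append(DIAG)
            i -= 1
            j -= 1
            if M[i, j] + s == cur and i > 0 and j > 0:
                state = _M_STATE
            elif X[i, j] + s == cur and i > 0:
                state = _X_STATE
            elif Y[i, j] + s == cur and j > 0:
                state = _Y_STATE
            else:
                break  # fresh start: predecessor contribution was 0
        elif state == _X_STATE:
            cur = X[i, j]
            moves.append(UP)
            if M[i - 1, j] - go == cur:
                state = _M_STATE
            elif X[i - 1, j] - ge == cur:
                state = _X_STATE
            else:
                state = _Y_STATE
            i -= 1
        else:
            cur = Y[i, j]
            moves.append(LEFT)
            if M[i, j - 1] - go == cur:
                state = _M_STATE
            elif X[i, j - 1] - go == cur:
                state = _X_STATE
            else:
                state = _Y_STATE
            j -= 1
    moves.reverse()
    return float(best), i, j, moves
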