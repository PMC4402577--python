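"""Optimal pairwise alignment (global / local, affine gaps) and percent identity.

Percent identity (PID) of two sequences is the number of identical
aligned residue pairs divided by the full length of their optimal
pairwise alignment, gap columns included.  ``X`` never counts as an
identity.  Default scoring is BLOSUM62 with gap open 10 / extend 1;
a gap of length ``k`` costs ``open + (k - 1) * extend``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from Bio.Align import substitution_matrices

from . import _dp
from .seqio import ALPHABET, GAP, Sequence

__all__ = [
    "AlignParams",
    "PairwiseAlignment",
    "global_align",
    "local_align",
    "percent_identity",
    "load_matrix",
    "default_matrix",
]

_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}


def _from_bio_array(arr) -> np.ndarray:
    out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = float(arr[a, b])
    return out


def default_matrix() -> np.ndarray:
    """BLOSUM62 restricted to the package alphabet (20 aa + X)."""
    return _from_bio_array(substitution_matrices.load("BLOSUM62"))


def load_matrix(path: Union[str, os.PathLike]) -> np.ndarray:
    """Load an NCBI-format substitution matrix file."""
    with open(path) as fh:
        arr = substitution_matrices.read(fh)
    return _from_bio_array(arr)


@dataclass
class AlignParams:
    """Scoring parameters for pairwise and profile alignment."""

    matrix: np.ndarray = field(default_factory=default_matrix)
    gap_open: float = 10.0
    gap_extend: float = 1.0
    mode: str = "global"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        k = len(ALPHABET)
        if self.matrix.shape != (k, k):
            raise ValueError(f"substitution matrix must be {k}x{k}")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def with_mode(self, mode: str) -> "AlignParams":
        return AlignParams(self.matrix, self.gap_open, self.gap_extend, mode)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows plus the identity statistics PID is built from."""

    row_a: str
    row_b: str
    n_identity: int
    l_alignment: int
    score: float
    mode: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b) or len(self.row_a) != self.l_alignment:
            raise ValueError("rows must both have length l_alignment")
        if not 0 <= self.n_identity <= self.l_alignment:
            raise ValueError("n_identity out of range")
        if self.l_alignment == 0 and self.mode == "global":
            raise ValueError("global alignment cannot be empty")
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == GAP and cb == GAP:
                raise ValueError("column with a gap in both rows")


def encode(residues: str) -> np.ndarray:
    return np.array([_INDEX[ch] for ch in residues], dtype=np.int64)


def _count_identities(row_a: str, row_b: str) -> int:
    return sum(
        1
        for ca, cb in zip(row_a, row_b)
        if ca == cb and ca != GAP and ca != "X"
    )


def _rows_from_moves(a: str, b: str, i0: int, j0: int, moves) -> tuple[str, str]:
    ra, rb = [], []
    i, j = i0, j0
    for mv in moves:
        if mv == _dp.DIAG:
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif mv == _dp.UP:
            ra.append(a[i]); rb.append(GAP); i += 1
        else:
            ra.append(GAP); rb.append(b[j]); j += 1
    return "".join(ra), "".join(rb)


def _score_matrix(a: Sequence, b: Sequence, p: AlignParams) -> np.ndarray:
    return p.matrix[np.ix_(encode(a.residues), encode(b.residues))]


def global_align(a: Sequence, b: Sequence, p: AlignParams) -> PairwiseAlignment:
    """Needleman–Wunsch with affine gaps (Gotoh), deterministic traceback."""
    if p.mode != "global":
        raise ValueError("params mode must be 'global'")
    S = _score_matrix(a, b, p)
    M, X, Y = _dp.fill_global(S, p.gap_open, p.gap_extend)
    score, moves = _dp.traceback_global(S, M, X, Y, p.gap_open, p.gap_extend)
    row_a, row_b = _rows_from_moves(a.residues, b.residues, 0, 0, moves)
    return PairwiseAlignment(
        row_a=row_a,
        row_b=row_b,
        n_identity=_count_identities(row_a, row_b),
        l_alignment=len(row_a),
        score=score,
        mode="global",
    )


def local_align(a: Sequence, b: Sequence, p: AlignParams) -> PairwiseAlignment:
    """Smith–Waterman with affine gaps; empty optimum has score 0."""
    if p.mode != "local":
        raise ValueError("params mode must be 'local'")
    S = _score_matrix(a, b, p)
    M, X, Y = _dp.fill_local(S, p.gap_open, p.gap_extend)
    score, i0, j0, moves = _dp.traceback_local(S, M, X, Y, p.gap_open, p.gap_extend)
    row_a, row_b = _rows_from_moves(a.residues, b.residues, i0, j0, moves)
    return PairwiseAlignment(
        row_a=row_a,
        row_b=row_b,
        n_identity=_count_identities(row_a, row_b),
        l_alignment=len(row_a),
        score=score,
        mode="local",
    )


def percent_identity(aln: PairwiseAlignment) -> float:
    """identities / alignment length, in [0, 1]; 0 for an empty alignment."""
    if aln.l_alignment == 0:
        return 0.0
    return aln.n_identity / aln.l_alignment
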