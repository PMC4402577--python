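"""Progressive alignment: profile-profile merges ordered by a guide tree.

A profile summarizes a partial alignment by per-column frequencies
over the 21 residue symbols plus the gap.  Two profiles are merged by
global affine-gap DP over columns, scoring each column pair by the
frequency-weighted expected substitution score (gap frequencies
contribute zero to the substitution term; new gaps pay the same affine
penalties as pairwise alignment).  With single-sequence profiles this
reduces exactly to pairwise global alignment.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import _dp
from .pairwise import AlignParams, encode
from .seqio import ALPHABET, GAP, MSA, Sequence
from .tree import GuideTree, TreeNode

__all__ = ["Profile", "profile_align", "progressive_align"]

_K = len(ALPHABET)  # residue symbols (gap tracked separately)


class Profile:
    """Member rows of a partial alignment plus per-column frequencies.

    ``freqs`` has shape ``(length, 22)``: columns 0..20 are residue
    frequencies in :data:`~guidealign.seqio.ALPHABET` order, column 21
    is the gap frequency; each row sums to 1.
    """

    def __init__(self, rows: list[tuple[str, str]]):
        if not rows:
            raise ValueError("profile needs at least one row")
        length = len(rows[0][1])
        if length < 1:
            raise ValueError("profile rows must be non-empty")
        if any(len(r) != length for _, r in rows):
            raise ValueError("profile rows must have equal length")
        self.rows: list[tuple[str, str]] = list(rows)
        self.length = length
        counts = np.zeros((length, _K + 1), dtype=np.float64)
        for _, row in rows:
            for j, ch in enumerate(row):
                if ch == GAP:
                    counts[j, _K] += 1.0
                else:
                    counts[j, ALPHABET.index(ch)] += 1.0
        self.freqs = counts / len(rows)
        #: score of the merge that produced this profile, if any
        self.merge_score: Optional[float] = None

    @classmethod
    def from_sequence(cls, seq: Sequence) -> "Profile":
        return cls([(seq.id, seq.residues)])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]


def _column_scores(p1: Profile, p2: Profile, params: AlignParams) -> np.ndarray:
    r1 = p1.freqs[:, :_K]
    r2 = p2.freqs[:, :_K]
    return (r1 @ params.matrix) @ r2.T


def profile_align(p1: Profile, p2: Profile, params: AlignParams) -> Profile:
    """Merge two profiles by global DP; all input rows are preserved.

    Stripping gaps from any row of the result recovers that row's
    original residues; the merged length is at least the longer input.
    """
    S = _column_scores(p1, p2, params)
    M, X, Y = _dp.fill_global(S, params.gap_open, params.gap_extend)
    score, moves = _dp.traceback_global(S, M, X, Y, params.gap_open, params.gap_extend)

    cols1: list[int] = []  # source column of p1 per merged column, -1 for gap
    cols2: list[int] = []
    i = j = 0
    for mv in moves:
        if mv == _dp.DIAG:
            cols1.append(i); cols2.append(j); i += 1; j += 1
        elif mv == _dp.UP:
            cols1.append(i); cols2.append(-1); i += 1
        else:
            cols1.append(-1); cols2.append(j); j += 1

    merged_rows: list[tuple[str, str]] = []
    for rid, row in p1.rows:
        merged_rows.append(
            (rid, "".join(row[c] if c >= 0 else GAP for c in cols1))
        )
    for rid, row in p2.rows:
        merged_rows.append(
            (rid, "".join(row[c] if c >= 0 else GAP for c in cols2))
        )
    out = Profile(merged_rows)
    out.merge_score = score
    return out


def progressive_align(
    seqs: list[Sequence], tree: GuideTree, params: AlignParams
) -> MSA:
    """Align ``seqs`` by post-order profile merges along ``tree``.

    The tree's leaf set must equal the sequence id set.  Output rows
    follow the input sequence order; all-gap columns are swept out.
    """
    ids = [s.id for s in seqs]
    by_id = {s.id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise ValueError("sequence ids must be unique")
    tree.validate_leaves(ids)
    if not tree.is_binary():
        from .guidetree import binarize  # deferred: avoids import cycle

        tree = binarize(tree)

    if len(seqs) == 1:
        return MSA(((seqs[0].id, seqs[0].residues),))

    def build(node: TreeNode) -> Profile:
        if node.is_leaf:
            return Profile.from_sequence(by_id[node.name])
        left = build(node.children[0])
        right = build(node.children[1])
        return profile_align(left, right, params)

    final = build(tree.root)
    order = {rid: k for k, rid in enumerate(ids)}
    rows = tuple(sorted(final.rows, key=lambda item: order[item[0]]))
    return MSA(rows).drop_all_gap_columns()
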