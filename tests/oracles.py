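"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: complete enumeration of
alignments, direct recomputation of average linkage from the original
matrix, and definition-level SP/TC counting.  None of it shares code
with the package's dynamic-programming or clustering paths.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

GAP = "-"


# ---------------------------------------------------------------------------
# Pairwise alignment by exhaustive enumeration


def score_alignment(row_a: str, row_b: str, matrix, alphabet: str,
                    gap_open: float, gap_extend: float) -> float:
    """Score a complete gapped alignment; gap run of length k costs
    open + (k-1)*extend, charged per run per row."""
    assert len(row_a) == len(row_b)
    idx = {c: i for i, c in enumerate(alphabet)}
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(row_a, row_b):
        assert not (ca == GAP and cb == GAP)
        if ca == GAP:
            score -= gap_open if not in_gap_a else gap_extend
            in_gap_a, in_gap_b = True, False
        elif cb == GAP:
            score -= gap_open if not in_gap_b else gap_extend
            in_gap_a, in_gap_b = False, True
        else:
            score += float(matrix[idx[ca], idx[cb]])
            in_gap_a = in_gap_b = False
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, GAP + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield GAP + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def count_identities(row_a: str, row_b: str) -> int:
    return sum(
        1 for ca, cb in zip(row_a, row_b)
        if ca == cb and ca != GAP and ca != "X"
    )


def oracle_global(a: str, b: str, matrix, alphabet: str,
                  gap_open: float, gap_extend: float):
    """(best score, list of optimal (row_a, row_b))."""
    best = None
    winners = []
    for ra, rb in enumerate_alignments(a, b):
        s = score_alignment(ra, rb, matrix, alphabet, gap_open, gap_extend)
        if best is None or s > best + 1e-12:
            best, winners = s, [(ra, rb)]
        elif abs(s - best) <= 1e-12:
            winners.append((ra, rb))
    return best, winners


def oracle_local(a: str, b: str, matrix, alphabet: str,
                 gap_open: float, gap_extend: float):
    """(best score, list of optimal (row_a, row_b) over substring pairs).

    A local alignment is a global alignment of one substring of each
    input; the empty alignment scores 0.
    """
    best = 0.0
    winners = [("", "")]
    for ia, ja in itertools.combinations(range(len(a) + 1), 2):
        for ib, jb in itertools.combinations(range(len(b) + 1), 2):
            s, opt = oracle_global(
                a[ia:ja], b[ib:jb], matrix, alphabet, gap_open, gap_extend
            )
            if s > best + 1e-12:
                best, winners = s, list(opt)
            elif abs(s - best) <= 1e-12 and s > 0:
                winners.extend(opt)
    return best, winners


# ---------------------------------------------------------------------------
# Faster independent oracle: enumeration over matched-column subsets.
#
# Any alignment is determined, up to gap arrangement, by the increasing
# sequence of residue-residue columns it contains.  Given that set, the
# cheapest affine arrangement of the unmatched residues between (or
# outside) consecutive matched columns is one gap run per row, costing
# open + (len-1)*extend per run.  Maximizing over all matched-column
# subsets therefore maximizes over all alignments.  Cross-validated
# against the full column-by-column enumeration above at small sizes.


def _run_cost(length: int, gap_open: float, gap_extend: float) -> float:
    return 0.0 if length <= 0 else gap_open + (length - 1) * gap_extend


def _match_subsets(la: int, lb: int):
    """Yield all pairs of equal-length increasing index tuples."""
    for k in range(1, min(la, lb) + 1):
        for ia in itertools.combinations(range(la), k):
            for ib in itertools.combinations(range(lb), k):
                yield ia, ib


def matchset_global(a: str, b: str, matrix, alphabet: str,
                    gap_open: float, gap_extend: float):
    """(best score, set of identity counts among optimal alignments)."""
    idx = {c: i for i, c in enumerate(alphabet)}
    la, lb = len(a), len(b)
    # the matchless alignment: both sequences fully gapped against each other
    best = _run_cost(la, gap_open, gap_extend) * -1 - _run_cost(
        lb, gap_open, gap_extend
    )
    ids = {0}
    for ia, ib in _match_subsets(la, lb):
        s = 0.0
        nid = 0
        for x, y in zip(ia, ib):
            s += float(matrix[idx[a[x]], idx[b[y]]])
            if a[x] == b[y] and a[x] != "X":
                nid += 1
        s -= _run_cost(ia[0], gap_open, gap_extend)
        s -= _run_cost(ib[0], gap_open, gap_extend)
        s -= _run_cost(la - 1 - ia[-1], gap_open, gap_extend)
        s -= _run_cost(lb - 1 - ib[-1], gap_open, gap_extend)
        for t in range(len(ia) - 1):
            s -= _run_cost(ia[t + 1] - ia[t] - 1, gap_open, gap_extend)
            s -= _run_cost(ib[t + 1] - ib[t] - 1, gap_open, gap_extend)
        if s > best + 1e-12:
            best, ids = s, {nid}
        elif abs(s - best) <= 1e-12:
            ids.add(nid)
    return best, ids


def matchset_local(a: str, b: str, matrix, alphabet: str,
                   gap_open: float, gap_extend: float):
    """(best local score, set of (identities, alignment length) among optima).

    Matched-column subsets with internal gap costs only; the empty
    alignment contributes score 0 with stats (0, 0).
    """
    idx = {c: i for i, c in enumerate(alphabet)}
    best = 0.0
    stats = {(0, 0)}
    for ia, ib in _match_subsets(len(a), len(b)):
        s = 0.0
        nid = 0
        length = len(ia)
        for x, y in zip(ia, ib):
            s += float(matrix[idx[a[x]], idx[b[y]]])
            if a[x] == b[y] and a[x] != "X":
                nid += 1
        for t in range(len(ia) - 1):
            ga = ia[t + 1] - ia[t] - 1
            gb = ib[t + 1] - ib[t] - 1
            s -= _run_cost(ga, gap_open, gap_extend)
            s -= _run_cost(gb, gap_open, gap_extend)
            length += ga + gb
        if s > best + 1e-12:
            best, stats = s, {(nid, length)}
        elif abs(s - best) <= 1e-12 and s > 0:
            stats.add((nid, length))
    return best, stats


# ---------------------------------------------------------------------------
# Brute-force average-linkage clustering


def brute_upgma(d, ids):
    """Nested-tuple UPGMA recomputing linkage from the original matrix.

    Returns (topology, heights) where topology is a nested frozenset
    structure over leaf names and heights maps each cluster's member
    frozenset to its merge height.
    """
    n = len(ids)
    index = {ids[i]: i for i in range(n)}
    clusters = [(frozenset([ids[i]]), ids[i]) for i in range(n)]  # (members, repr)
    heights = {}

    def linkage(mem_a, mem_b):
        vals = [
            d[index[i]][index[j]] for i in sorted(mem_a) for j in sorted(mem_b)
        ]
        return sum(vals) / len(vals)

    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(range(len(clusters)), 2):
            dist = linkage(clusters[x][0], clusters[y][0])
            key = (dist, x, y)
            if best is None or key < best:
                best = key
        dist, x, y = best
        mem = clusters[x][0] | clusters[y][0]
        rep = frozenset([clusters[x][1], clusters[y][1]])
        heights[mem] = dist / 2.0
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (x, y)]
            + [(mem, rep)]
        )
    return clusters[0][1], heights


def tree_topology(tree):
    """Canonical unordered nested-frozenset topology of a GuideTree."""

    def rec(node):
        if node.is_leaf:
            return node.name
        return frozenset(rec(c) for c in node.children)

    return rec(tree.root)


def tree_heights(tree):
    """Map each internal node's leaf-name frozenset to its height."""
    out = {}

    def rec(node):
        if node.is_leaf:
            return frozenset([node.name])
        members = frozenset().union(*(rec(c) for c in node.children))
        out[frozenset(members)] = node.height
        return members

    rec(tree.root)
    return out


# ---------------------------------------------------------------------------
# Definition-level SP / TC


def _position_columns(rows):
    """Per row id, the test/ref column index of each residue ordinal."""
    out = {}
    for rid, row in rows:
        cols = [j for j, ch in enumerate(row) if ch != GAP]
        out[rid] = cols
    return out


def brute_sp(test_rows, ref_rows) -> Fraction:
    """Fraction of ref residue pairs also aligned in test (exact rational)."""
    tpos = _position_columns(test_rows)
    rpos = _position_columns(ref_rows)
    ids = sorted(rpos)
    hit = total = 0
    for ia, ib in itertools.combinations(range(len(ids)), 2):
        a, b = ids[ia], ids[ib]
        for ka, ca in enumerate(rpos[a]):
            for kb, cb in enumerate(rpos[b]):
                if ca == cb:
                    total += 1
                    if tpos[a][ka] == tpos[b][kb]:
                        hit += 1
    if total == 0:
        raise ValueError("reference has no aligned residue pairs")
    return Fraction(hit, total)


def brute_tc(test_rows, ref_rows) -> Fraction:
    """Fraction of >=2-residue ref columns reproduced in one test column."""
    tpos = _position_columns(test_rows)
    rpos = _position_columns(ref_rows)
    ref_len = len(ref_rows[0][1])
    hit = total = 0
    for col in range(ref_len):
        entries = []
        for rid, _ in ref_rows:
            if col in rpos[rid]:
                entries.append((rid, rpos[rid].index(col)))
        if len(entries) < 2:
            continue
        total += 1
        test_cols = {tpos[rid][k] for rid, k in entries}
        if len(test_cols) == 1:
            hit += 1
    if total == 0:
        raise ValueError("reference has no columns with >= 2 residues")
    return Fraction(hit, total)
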