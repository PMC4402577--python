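"""Guide-tree construction: adaptive, random, and reference strategies.

The adaptive strategy is the pipeline

    PID matrix -> similarity class -> class-specific distance matrix -> UPGMA

where the distance estimate follows the family's similarity regime:
HIGH families use global-alignment PID, MODERATE families local PID,
and LOW families the consensus (average) of the two estimates.

Random guide trees are uniform over labeled rooted binary topologies,
realized by repeatedly joining a uniformly chosen pair of lineages.
Reference trees are consumed as Newick (midpoint-rooted if unrooted,
multifurcations binarized by left-nesting); a neighbor-joining
fallback builds a tree from a trusted reference alignment.

Distance matrices are plain numpy arrays validated by
:func:`validate_distance_matrix`.  All tie-breaks pick the lowest
``(i, j)`` index pair, making every construction deterministic.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .pairwise import AlignParams
from .seqio import GAP, MSA, Sequence, read_newick
from .similarity import (
    SimilarityClass,
    average_pid,
    classify,
    pid_matrix,
)
from .tree import GuideTree, TreeNode, format_newick, parse_newick, to_dendropy

__all__ = [
    "AdaptiveTreeResult",
    "validate_distance_matrix",
    "distances_for_class",
    "upgma",
    "adaptive_guide_tree",
    "random_tree",
    "load_reference_tree",
    "nj_reference_tree",
    "robinson_foulds",
    "binarize",
    "midpoint_root",
]


def validate_distance_matrix(d: np.ndarray, n: Optional[int] = None) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if n is not None and d.shape[0] != n:
        raise ValueError(f"distance matrix must be {n}x{n}")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if (d < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    return d


def distances_for_class(
    seqs: list[Sequence],
    klass: SimilarityClass,
    p: AlignParams,
    pid_global: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Class-appropriate dissimilarity matrix ``1 - PID``.

    HIGH uses global PID, MODERATE local PID, LOW the average of the
    global and local estimates.  ``pid_global`` lets callers reuse an
    already-computed global PID matrix.
    """
    klass = SimilarityClass(klass)
    if klass is SimilarityClass.HIGH:
        pid = pid_global if pid_global is not None else pid_matrix(
            seqs, p.with_mode("global")
        )
    elif klass is SimilarityClass.MODERATE:
        pid = pid_matrix(seqs, p.with_mode("local"))
    else:
        pg = pid_global if pid_global is not None else pid_matrix(
            seqs, p.with_mode("global")
        )
        pl = pid_matrix(seqs, p.with_mode("local"))
        pid = (pg + pl) / 2.0
    d = 1.0 - pid
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# UPGMA


def upgma(d: np.ndarray, ids: list[str]) -> GuideTree:
    """Average-linkage clustering into a rooted ultrametric binary tree.

    Node height is half the average-linkage merge distance; a child's
    branch length is the height difference to its parent.  Among
    equally close pairs the lowest ``(i, j)`` index pair merges first
    (cluster indices are assigned in creation order).
    """
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(ids)) != n:
        raise ValueError("taxon ids must be unique")
    d = validate_distance_matrix(d, n)

    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=ids[i], height=0.0) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        bi, bj = min(
            ((i, j) for i, j in itertools.combinations(active, 2)),
            key=lambda ij: (dist[ij], ij),
        )
        h = dist[(bi, bj)] / 2.0
        left, right = nodes[bi], nodes[bj]
        left.length = h - left.height
        right.length = h - right.height
        parent = TreeNode(children=[left, right], height=h)
        si, sj = sizes[bi], sizes[bj]
        for k in active:
            if k in (bi, bj):
                continue
            dik = dist[(min(bi, k), max(bi, k))]
            djk = dist[(min(bj, k), max(bj, k))]
            dist[(k, nxt)] = (si * dik + sj * djk) / (si + sj)
        nodes[nxt] = parent
        sizes[nxt] = si + sj
        active = [k for k in active if k not in (bi, bj)] + [nxt]
        nxt += 1
    return GuideTree(nodes[active[0]])


@dataclass(frozen=True)
class AdaptiveTreeResult:
    """Adaptive guide tree plus the similarity evidence behind it."""

    tree: GuideTree
    klass: SimilarityClass
    avg_pid: float
    distances: np.ndarray


def adaptive_guide_tree(seqs: list[Sequence], p: AlignParams) -> AdaptiveTreeResult:
    """Build the adaptive guide tree for a family of sequences."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    pid_g = pid_matrix(seqs, p.with_mode("global"))
    avg = average_pid(pid_g)
    klass = classify(avg)
    d = distances_for_class(seqs, klass, p, pid_global=pid_g)
    tree = upgma(d, ids)
    return AdaptiveTreeResult(tree=tree, klass=klass, avg_pid=avg, distances=d)


# ---------------------------------------------------------------------------
# Random guide trees


def random_tree(ids: list[str], seed: int) -> GuideTree:
    """Uniform random labeled rooted binary topology (no branch lengths).

    Realized by sequential coalescence: repeatedly join a uniformly
    chosen pair of the current lineages.  Reproducible from ``seed``.
    """
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(ids)) != len(ids):
        raise ValueError("taxon ids must be unique")
    rng = np.random.default_rng(seed)
    lineages: list[TreeNode] = [TreeNode(name=i) for i in ids]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False).tolist())
        parent = TreeNode(children=[lineages[i], lineages[j]])
        lineages[i] = parent
        del lineages[j]
    return GuideTree(lineages[0])


# ---------------------------------------------------------------------------
# Reference guide trees


def binarize(tree: GuideTree) -> GuideTree:
    """Resolve multifurcations by deterministic left-nesting.

    ``(a,b,c,d)`` becomes ``(((a,b),c),d)``; introduced nodes carry
    zero-length branches so path lengths are preserved.
    """

    def resolve(node: TreeNode) -> TreeNode:
        children = [resolve(c) for c in node.children]
        if len(children) <= 2:
            node.children = children
            return node
        acc = children[0]
        for child in children[1:-1]:
            acc = TreeNode(children=[acc, child], length=0.0)
        node.children = [acc, children[-1]]
        return node

    out = tree.copy()
    out.root = resolve(out.root)
    out.root.length = None
    return out


def midpoint_root(tree: GuideTree) -> GuideTree:
    """Re-root at the midpoint of the longest leaf-to-leaf path.

    Missing branch lengths are treated as 1.  Delegates to dendropy's
    midpoint rooting; a tree whose branches are all zero-length has no
    midpoint and is returned unchanged.
    """
    dtree = to_dendropy(tree)
    total = 0.0
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is not dtree.seed_node and edge.length is None:
            edge.length = 1.0
        total += edge.length or 0.0
    if total <= 0.0:
        return tree.copy()
    dtree.reroot_at_midpoint(update_bipartitions=False)
    rerooted = parse_newick(
        dtree.as_string(schema="newick", suppress_rooting=True)
    )
    return rerooted


def load_reference_tree(
    source: Union[str, os.PathLike, GuideTree], ids: list[str]
) -> GuideTree:
    """Load a reference tree and normalize it into a rooted binary guide tree.

    The Newick leaf set must equal ``ids`` (mismatches are reported by
    name).  A multifurcating root is taken to mean the tree is unrooted
    and is resolved by midpoint rooting; remaining multifurcations are
    binarized by left-nesting.
    """
    tree = source if isinstance(source, GuideTree) else read_newick(source)
    tree.validate_leaves(ids)
    if len(tree.root.children) > 2:
        tree = midpoint_root(tree)
    return binarize(tree)


def _p_distance(row_a: str, row_b: str) -> float:
    shared = mism = 0
    for ca, cb in zip(row_a, row_b):
        if ca == GAP or cb == GAP:
            continue
        shared += 1
        if ca != cb or ca == "X":
            mism += 1
    if shared == 0:
        raise ValueError("undefined p-distance: rows share no ungapped columns")
    return mism / shared


def _neighbor_joining(d: np.ndarray, ids: list[str]) -> GuideTree:
    """Plain NJ; returns a tree with a trifurcating root for n >= 3."""
    n = len(ids)
    nodes: dict[int, TreeNode] = {i: TreeNode(name=ids[i]) for i in range(n)}
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    nxt = n

    def D(i: int, j: int) -> float:
        return dist[(min(i, j), max(i, j))]

    while len(active) > 3:
        N = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        bi, bj = min(
            ((i, j) for i, j in itertools.combinations(active, 2)),
            key=lambda ij: ((N - 2) * D(*ij) - r[ij[0]] - r[ij[1]], ij),
        )
        dij = D(bi, bj)
        li = dij / 2.0 + (r[bi] - r[bj]) / (2.0 * (N - 2))
        li = min(max(li, 0.0), dij)
        lj = dij - li
        nodes[bi].length = li
        nodes[bj].length = lj
        parent = TreeNode(children=[nodes[bi], nodes[bj]])
        for k in active:
            if k in (bi, bj):
                continue
            dist[(k, nxt)] = max((D(bi, k) + D(bj, k) - dij) / 2.0, 0.0)
        nodes[nxt] = parent
        active = [k for k in active if k not in (bi, bj)] + [nxt]
        nxt += 1

    if len(active) == 3:
        a, b, c = active
        la = (D(a, b) + D(a, c) - D(b, c)) / 2.0
        lb = (D(a, b) + D(b, c) - D(a, c)) / 2.0
        lc = (D(a, c) + D(b, c) - D(a, b)) / 2.0
        for k, lk in ((a, la), (b, lb), (c, lc)):
            nodes[k].length = max(lk, 0.0)
        root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    else:
        a, b = active
        half = D(a, b) / 2.0
        nodes[a].length = half
        nodes[b].length = half
        root = TreeNode(children=[nodes[a], nodes[b]])
    return GuideTree(root)


def nj_reference_tree(ref_msa: MSA) -> GuideTree:
    """Neighbor joining on p-distances from a trusted reference alignment.

    Columns gapped in either row are ignored per pair.  The unrooted NJ
    tree is midpoint-rooted and binarized.  With two rows the result is
    the unique cherry.
    """
    ids = ref_msa.ids()
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 rows")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _p_distance(ref_msa.rows[i][1], ref_msa.rows[j][1])
    if n == 2:
        return upgma(d, ids)
    tree = _neighbor_joining(d, ids)
    return binarize(midpoint_root(tree))


# ---------------------------------------------------------------------------
# Tree comparison


def robinson_foulds(t1: GuideTree, t2: GuideTree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-first={sorted(l1 - l2)} "
            f"only-second={sorted(l2 - l1)}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())
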