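"""Synthetic protein families with a known true tree and true alignment.

Evolution is deliberately simple and fully transparent: a uniform
random root sequence evolves down a Yule tree; along a branch of
length ``L`` each site is replaced with probability ``subst_rate * L``
(draw uniform over the 20 amino acids), and indel events arrive as a
Poisson count with geometric lengths.  Every insertion creates fresh
columns in a global column registry, so the true alignment is exact by
construction and always satisfies the scoring module's gap-strip
precondition.

All randomness flows from one seed through named per-stage generators
(tree, root, branch events), so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .pairwise import AlignParams
from .seqio import AMINO_ACIDS, GAP, MSA, Sequence
from .similarity import average_pid, pid_matrix
from .tree import GuideTree, TreeNode

__all__ = [
    "EvolutionParams",
    "SyntheticFamily",
    "sample_tree",
    "evolve",
    "scale_tree",
    "calibrate_divergence",
    "synthesize_family",
]


@dataclass(frozen=True)
class EvolutionParams:
    """Knobs of the family simulator."""

    n_taxa: int = 8
    root_length: int = 100
    branch_mean: float = 0.2
    subst_rate: float = 1.0
    indel_rate: float = 0.02
    indel_len_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if self.branch_mean <= 0:
            raise ValueError("branch_mean must be positive")
        if self.subst_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 < self.indel_len_p <= 1.0:
            raise ValueError("indel_len_p must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticFamily:
    """A simulated family: truth plus the observable leaf sequences."""

    true_tree: GuideTree
    sequences: tuple[Sequence, ...]
    true_msa: MSA
    realized_avg_pid: float


def sample_tree(n: int, seed: int, branch_mean: float = 0.2) -> GuideTree:
    """Yule-process topology with iid exponential branch lengths."""
    if n < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    tips = [root]
    while len(tips) < n:
        k = int(rng.integers(len(tips)))
        tip = tips.pop(k)
        tip.children = [TreeNode(), TreeNode()]
        tips.extend(tip.children)
    tree = GuideTree(root)
    for node in tree.postorder():
        if node is not root:
            node.length = float(rng.exponential(branch_mean))
    for idx, leaf in enumerate(root.leaves(), start=1):
        leaf.name = f"t{idx}"
    return tree


def scale_tree(tree: GuideTree, factor: float) -> GuideTree:
    """Copy of ``tree`` with every branch length multiplied by ``factor``."""
    out = tree.copy()
    for node in out.postorder():
        if node.length is not None:
            node.length = node.length * factor
    return out


def _evolve_branch(
    parent_seq: list[tuple[int, str]],
    length: float,
    params: EvolutionParams,
    master: list[int],
    counter: list[int],
    rng: np.random.Generator,
) -> list[tuple[int, str]]:
    seq = list(parent_seq)

    p_sub = min(1.0, params.subst_rate * length)
    if p_sub > 0 and seq:
        hits = rng.random(len(seq)) < p_sub
        draws = rng.integers(0, len(AMINO_ACIDS), size=len(seq))
        for i in range(len(seq)):
            if hits[i]:
                seq[i] = (seq[i][0], AMINO_ACIDS[draws[i]])

    n_events = int(rng.poisson(params.indel_rate * length * len(seq)))
    for _ in range(n_events):
        is_insertion = rng.random() < 0.5
        k = int(rng.geometric(params.indel_len_p))
        if is_insertion:
            pos = int(rng.integers(0, len(seq) + 1))
            fresh = []
            for _ in range(k):
                cid = counter[0]
                counter[0] += 1
                fresh.append((cid, AMINO_ACIDS[int(rng.integers(0, 20))]))
            # register new columns in the master ordering
            if pos == 0:
                anchor = master.index(seq[0][0]) if seq else len(master)
            else:
                anchor = master.index(seq[pos - 1][0]) + 1
            master[anchor:anchor] = [cid for cid, _ in fresh]
            seq[pos:pos] = fresh
        else:
            if len(seq) <= 1:
                continue  # never delete the whole sequence
            k = min(k, len(seq) - 1)
            pos = int(rng.integers(0, len(seq) - k + 1))
            del seq[pos : pos + k]
    return seq


def evolve(
    tree: GuideTree,
    params: EvolutionParams,
    align_params: Optional[AlignParams] = None,
) -> SyntheticFamily:
    """Simulate sequences down ``tree`` and return family plus exact truth."""
    leaves = list(tree.root.leaves())
    if any(leaf.name is None for leaf in leaves):
        raise ValueError("tree leaves must be labeled")

    ss = np.random.SeedSequence(params.seed)
    root_ss, branch_ss = ss.spawn(2)
    rng_root = np.random.default_rng(root_ss)
    rng_branch = np.random.default_rng(branch_ss)

    master = list(range(params.root_length))
    counter = [params.root_length]
    root_draw = rng_root.integers(0, 20, size=params.root_length)
    root_seq = [(i, AMINO_ACIDS[root_draw[i]]) for i in range(params.root_length)]

    leaf_seqs: dict[str, list[tuple[int, str]]] = {}

    def walk(node: TreeNode, seq: list[tuple[int, str]]) -> None:
        for child in node.children:
            branch_len = child.length if child.length is not None else 0.0
            child_seq = _evolve_branch(
                seq, branch_len, params, master, counter, rng_branch
            )
            if child.is_leaf:
                leaf_seqs[child.name] = child_seq
            else:
                walk(child, child_seq)

    if tree.root.is_leaf:
        raise ValueError("tree must have at least 2 leaves")
    walk(tree.root, root_seq)

    order = {cid: k for k, cid in enumerate(master)}
    rows = []
    sequences = []
    for leaf in leaves:
        by_col = dict(leaf_seqs[leaf.name])
        row = "".join(by_col.get(cid, GAP) for cid in master)
        rows.append((leaf.name, row))
        sequences.append(Sequence(leaf.name, row.replace(GAP, "")))
    true_msa = MSA(tuple(rows)).drop_all_gap_columns()

    ap = align_params if align_params is not None else AlignParams()
    pid = pid_matrix(list(sequences), ap.with_mode("global"))
    return SyntheticFamily(
        true_tree=tree,
        sequences=tuple(sequences),
        true_msa=true_msa,
        realized_avg_pid=average_pid(pid),
    )


def synthesize_family(
    params: EvolutionParams, scale: float = 1.0
) -> SyntheticFamily:
    """Sample a tree and evolve a family in one call (both from ``params.seed``)."""
    tree = sample_tree(params.n_taxa, seed=params.seed, branch_mean=params.branch_mean)
    if scale != 1.0:
        tree = scale_tree(tree, scale)
    return evolve(tree, params)


def calibrate_divergence(
    target_avg_pid: float,
    params: EvolutionParams,
    k: int = 3,
    tol: float = 0.03,
    scale_bounds: tuple[float, float] = (1e-3, 50.0),
    max_iter: int = 40,
) -> float:
    """Bisect a global branch-length scale to hit a target average PID.

    Returns the scale at which the mean realized average PID over ``k``
    seeded replicates is within ``tol`` of ``target_avg_pid``.  Raises
    if the target lies outside what the scale bounds can reach.
    """
    if not 0.0 < target_avg_pid < 1.0:
        raise ValueError("target_avg_pid must be in (0, 1)")

    def realized(scale: float) -> float:
        vals = []
        for rep in range(k):
            rep_params = replace(params, seed=params.seed + 7919 * (rep + 1))
            vals.append(synthesize_family(rep_params, scale=scale).realized_avg_pid)
        return float(np.mean(vals))

    lo, hi = scale_bounds
    pid_lo, pid_hi = realized(lo), realized(hi)
    if pid_lo < target_avg_pid - tol:
        raise ValueError(
            f"target {target_avg_pid} unreachable: PID at minimum scale is {pid_lo:.3f}"
        )
    if pid_hi > target_avg_pid + tol:
        raise ValueError(
            f"target {target_avg_pid} unreachable: PID at maximum scale is {pid_hi:.3f}"
        )
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        pid_mid = realized(mid)
        if abs(pid_mid - target_avg_pid) <= tol:
            return mid
        if pid_mid > target_avg_pid:
            lo = mid
        else:
            hi = mid
    raise ValueError(
        f"calibration did not converge to {target_avg_pid} within {max_iter} bisections"
    )
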