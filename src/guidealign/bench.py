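"""Desk-scale experiment harness: tree strategies compared on families.

For each family and each requested guide-tree strategy the harness
builds the tree, runs the progressive aligner, and scores the result
against the family's reference (true) alignment, yielding paired
records suitable for a scatter / diagonal summary.  When the true tree
is known the Robinson-Foulds distance of the guide tree to it is also
recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence as TypingSequence

import pandas as pd

from .guidetree import (
    adaptive_guide_tree,
    load_reference_tree,
    nj_reference_tree,
    random_tree,
    robinson_foulds,
)
from .pairwise import AlignParams
from .progressive import progressive_align
from .scoring import ScorePair, score_pair
from .seqio import MSA, Sequence
from .tree import GuideTree

__all__ = ["Family", "ExperimentResult", "run_comparison", "diagonal_summary",
           "STRATEGIES"]

STRATEGIES = ("adaptive", "random", "reference", "nj-reference")


@dataclass(frozen=True)
class Family:
    """One benchmark family: inputs plus its trusted reference alignment."""

    family_id: str
    sequences: tuple[Sequence, ...]
    reference_msa: MSA
    true_tree: Optional[GuideTree] = None


@dataclass
class ExperimentResult:
    """Per-family, per-strategy records of one comparison run."""

    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def summary(self) -> pd.DataFrame:
        df = self.to_frame()
        return (
            df.groupby("strategy")[["sp", "tc"]]
            .mean()
            .round(3)
            .reset_index()
        )


def _build_tree(
    family: Family,
    strategy: str,
    params: AlignParams,
    seed: Optional[int],
):
    ids = [s.id for s in family.sequences]
    if strategy == "adaptive":
        res = adaptive_guide_tree(list(family.sequences), params)
        return res.tree, res.avg_pid
    if strategy == "random":
        if seed is None:
            raise ValueError("random strategy needs a seed")
        return random_tree(ids, seed), None
    if strategy == "reference":
        if family.true_tree is None:
            raise ValueError(
                f"family {family.family_id!r} has no reference tree"
            )
        return load_reference_tree(family.true_tree.copy(), ids), None
    if strategy == "nj-reference":
        return nj_reference_tree(family.reference_msa), None
    raise ValueError(f"unknown strategy {strategy!r}")


def run_comparison(
    families: TypingSequence[Family],
    strategies: TypingSequence[str],
    seeds: TypingSequence[int],
    params: Optional[AlignParams] = None,
) -> ExperimentResult:
    """Run every strategy on every family and score against the reference.

    ``seeds`` supplies one seed per family; only the random strategy
    consumes it.  The run is deterministic given (families, seeds).
    """
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")
    if len(seeds) < len(families):
        raise ValueError("need one seed per family")
    params = params if params is not None else AlignParams()

    result = ExperimentResult()
    for family, seed in zip(families, seeds):
        if family.reference_msa is None:
            raise ValueError(f"family {family.family_id!r} has no reference MSA")
        seqs = list(family.sequences)
        adaptive_avg_pid = None
        for strategy in strategies:
            tree, avg_pid = _build_tree(family, strategy, params, seed)
            if avg_pid is not None:
                adaptive_avg_pid = avg_pid
            msa = progressive_align(seqs, tree, params)
            scores = score_pair(msa, family.reference_msa)
            rf = (
                robinson_foulds(tree, family.true_tree)
                if family.true_tree is not None
                else None
            )
            result.records.append(
                {
                    "family_id": family.family_id,
                    "strategy": strategy,
                    "avg_pid": avg_pid,
                    "sp": scores.sp,
                    "tc": scores.tc,
                    "rf_to_true": rf,
                    "seed": seed if strategy == "random" else None,
                }
            )
        # backfill the family-level avg_pid onto every record of this family
        if adaptive_avg_pid is not None:
            for rec in result.records:
                if rec["family_id"] == family.family_id and rec["avg_pid"] is None:
                    rec["avg_pid"] = adaptive_avg_pid
    return result


def diagonal_summary(
    result: ExperimentResult, strategy_x: str, strategy_y: str
) -> dict[str, dict[str, int]]:
    """Count families with y-score below / on / above the x-score diagonal."""
    df = result.to_frame()
    out: dict[str, dict[str, int]] = {}
    xs = df[df.strategy == strategy_x].set_index("family_id")
    ys = df[df.strategy == strategy_y].set_index("family_id")
    if set(xs.index) != set(ys.index):
        raise ValueError("strategies were not run on the same families")
    for metric in ("sp", "tc"):
        below = on = above = 0
        for fam in xs.index:
            x, y = xs.loc[fam, metric], ys.loc[fam, metric]
            if y < x:
                below += 1
            elif y > x:
                above += 1
            else:
                on += 1
        out[metric] = {"below": below, "on": on, "above": above}
    return out
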