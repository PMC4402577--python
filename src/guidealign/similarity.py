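"""All-pairs percent-identity matrix, average PID and similarity regimes.

Families are classified by average PID over all unordered pairs:
HIGH above 40%, MODERATE between 25% and 40% (both ends inclusive,
since HIGH requires *strictly* greater than 40%), LOW below 25%.
Classification uses global-mode PID; the class then selects the mode
used for the tree-building distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .pairwise import AlignParams, global_align, local_align, percent_identity
from .seqio import Sequence

__all__ = [
    "SimilarityClass",
    "SimilarityProfile",
    "pid_matrix",
    "average_pid",
    "classify",
    "similarity_profile",
    "HIGH_THRESHOLD",
    "LOW_THRESHOLD",
]

HIGH_THRESHOLD = 0.40
LOW_THRESHOLD = 0.25


class SimilarityClass(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"


@dataclass(frozen=True)
class SimilarityProfile:
    """Pairwise PID matrix with its family-level summary."""

    n: int
    pid: np.ndarray
    avg_pid: float
    klass: SimilarityClass
    mode_used: str


def pid_matrix(seqs: list[Sequence], p: AlignParams) -> np.ndarray:
    """Symmetric matrix of pairwise PIDs under ``p`` (diagonal 1)."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    align = global_align if p.mode == "global" else local_align
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = percent_identity(align(seqs[i], seqs[j], p))
    return out


def average_pid(pid: np.ndarray) -> float:
    """Unweighted mean over the strictly-upper-triangle entries."""
    pid = np.asarray(pid)
    n = pid.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.mean(pid[iu]))


def classify(avg_pid: float) -> SimilarityClass:
    """Map average PID (a fraction) to its similarity regime."""
    if not 0.0 <= avg_pid <= 1.0:
        raise ValueError(f"average PID must be in [0, 1], got {avg_pid}")
    if avg_pid > HIGH_THRESHOLD:
        return SimilarityClass.HIGH
    if avg_pid >= LOW_THRESHOLD:
        return SimilarityClass.MODERATE
    return SimilarityClass.LOW


def similarity_profile(seqs: list[Sequence], p: AlignParams) -> SimilarityProfile:
    """Compute the PID matrix, its mean and the similarity class in one pass.

    The classification matrix is always computed in global mode,
    regardless of ``p.mode``.
    """
    pid = pid_matrix(seqs, p.with_mode("global"))
    avg = average_pid(pid)
    return SimilarityProfile(
        n=len(seqs),
        pid=pid,
        avg_pid=avg,
        klass=classify(avg),
        mode_used="global",
    )
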