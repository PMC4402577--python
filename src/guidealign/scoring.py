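"""SP / TC accuracy of a test alignment against a reference.

SP is the percentage of reference-aligned residue pairs that the test
alignment reproduces; TC is the percentage of reference columns whose
complete residue correspondence lands in a single test column.  Every
fully-recovered column contributes all of its residue pairs, so
``tc <= sp`` always holds.  Reference columns with fewer than two
residues are excluded from the TC denominator; SP counts
residue-residue pairs only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import GAP, MSA

__all__ = ["ScorePair", "BinnedReport", "sp_score", "tc_score", "bin_report",
           "OXBENCH_EDGES", "BALIBASE_EDGES"]

#: similarity-bin presets (percent)
OXBENCH_EDGES = (0.0, 20.0, 40.0, 70.0, 100.0)
BALIBASE_EDGES = (0.0, 30.0, 60.0)


@dataclass(frozen=True)
class ScorePair:
    """SP and TC percentages for one test/reference comparison.

    ``tc <= sp`` whenever every reference column holds the same number
    of residues (e.g. gap-free references); with heterogeneous column
    occupancy the normalizations differ and TC can exceed SP, so the
    constructor only range-checks.
    """

    sp: float
    tc: float

    def __post_init__(self) -> None:
        for name, v in (("sp", self.sp), ("tc", self.tc)):
            if not 0.0 <= v <= 100.0 + 1e-9:
                raise ValueError(f"{name} must be a percentage, got {v}")


def _check_comparable(test: MSA, ref: MSA) -> None:
    if set(test.ids()) != set(ref.ids()):
        raise ValueError(
            f"row id sets differ: test={sorted(test.ids())} ref={sorted(ref.ids())}"
        )
    for rid in ref.ids():
        if test.row(rid).replace(GAP, "") != ref.row(rid).replace(GAP, ""):
            raise ValueError(
                f"row {rid!r} differs between test and reference after gap removal"
            )


def _residue_columns(msa: MSA) -> list[dict[str, int]]:
    """Per column, map row id -> residue ordinal (occurrence index)."""
    counters = {rid: 0 for rid in msa.ids()}
    out: list[dict[str, int]] = []
    for j in range(msa.length):
        col: dict[str, int] = {}
        for rid, row in msa.rows:
            if row[j] != GAP:
                col[rid] = counters[rid]
                counters[rid] += 1
        out.append(col)
    return out


def _pair_set(columns: list[dict[str, int]]) -> set[tuple]:
    pairs: set[tuple] = set()
    for col in columns:
        items = sorted(col.items())
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                pairs.add((items[a], items[b]))
    return pairs


def sp_score(test: MSA, ref: MSA) -> float:
    """Percentage of reference residue pairs reproduced by the test MSA."""
    _check_comparable(test, ref)
    ref_pairs = _pair_set(_residue_columns(ref))
    if not ref_pairs:
        raise ValueError("reference alignment has no aligned residue pairs")
    test_pairs = _pair_set(_residue_columns(test))
    return 100.0 * len(ref_pairs & test_pairs) / len(ref_pairs)


def tc_score(test: MSA, ref: MSA) -> float:
    """Percentage of reference columns reproduced intact in one test column.

    A reference column counts if every (row, residue) entry it contains
    appears together in a single test column.
    """
    _check_comparable(test, ref)
    ref_cols = [c for c in _residue_columns(ref) if len(c) >= 2]
    if not ref_cols:
        raise ValueError("reference alignment has no columns with >= 2 residues")
    test_cols = [set(c.items()) for c in _residue_columns(test)]
    hit = 0
    for col in ref_cols:
        want = set(col.items())
        if any(want <= tcol for tcol in test_cols):
            hit += 1
    return 100.0 * hit / len(ref_cols)


def score_pair(test: MSA, ref: MSA) -> ScorePair:
    return ScorePair(sp=sp_score(test, ref), tc=tc_score(test, ref))


@dataclass(frozen=True)
class BinnedReport:
    """Per-similarity-bin mean SP/TC and family counts."""

    edges: tuple[float, ...]
    labels: tuple[str, ...]
    mean_sp: tuple[float, ...]
    mean_tc: tuple[float, ...]
    counts: tuple[int, ...]

    def to_rows(self) -> list[dict]:
        return [
            {
                "bin": lab,
                "n_families": n,
                "mean_sp": sp,
                "mean_tc": tc,
            }
            for lab, n, sp, tc in zip(
                self.labels, self.counts, self.mean_sp, self.mean_tc
            )
        ]


def bin_report(
    records: list[tuple[float, ScorePair]],
    edges: tuple[float, ...] = OXBENCH_EDGES,
) -> BinnedReport:
    """Bin families by average PID (percent) and average their scores.

    Bins are left-closed / right-open; the last bin is closed on the
    right, so a family at exactly an interior edge falls in the upper
    bin and 100% falls in the last bin.
    """
    edges = tuple(float(e) for e in edges)
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    labels = tuple(
        f"{a:g}%-{b:g}%" for a, b in zip(edges, edges[1:])
    )
    nbins = len(labels)
    sums_sp = [0.0] * nbins
    sums_tc = [0.0] * nbins
    counts = [0] * nbins
    for avg_pid, scores in records:
        if not 0.0 <= avg_pid <= 100.0:
            raise ValueError(f"family avg_pid {avg_pid} outside [0, 100]")
        if avg_pid < edges[0] or avg_pid > edges[-1]:
            raise ValueError(f"family avg_pid {avg_pid} outside bin range")
        k = nbins - 1
        for b in range(nbins):
            if avg_pid < edges[b + 1]:
                k = b
                break
        sums_sp[k] += scores.sp
        sums_tc[k] += scores.tc
        counts[k] += 1
    mean_sp = tuple(
        round(sums_sp[k] / counts[k], 3) if counts[k] else float("nan")
        for k in range(nbins)
    )
    mean_tc = tuple(
        round(sums_tc[k] / counts[k], 3) if counts[k] else float("nan")
        for k in range(nbins)
    )
    return BinnedReport(
        edges=edges,
        labels=labels,
        mean_sp=mean_sp,
        mean_tc=mean_tc,
        counts=tuple(counts),
    )
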