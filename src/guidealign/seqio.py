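"""FASTA / aligned-FASTA / Newick input and output.

Sequences are protein-only: the 20 standard amino acids plus ``X`` for
an unknown residue.  ``X`` never counts as an identity match downstream.
On input ``.`` is accepted as a gap and normalized to ``-``; ``*`` and
whitespace are stripped; case is normalized to upper.  Parsers reject
malformed records rather than repairing them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TypingSequence, Union

from Bio import SeqIO

from .tree import GuideTree, format_newick, parse_newick

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "GAP",
    "Sequence",
    "MSA",
    "read_fasta",
    "read_msa",
    "write_fasta",
    "read_newick",
    "write_newick",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residue alphabet: 20 amino acids plus X (unknown).
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

_RESIDUE_SET = frozenset(ALPHABET)
_GAPPED_SET = _RESIDUE_SET | {GAP}


@dataclass(frozen=True)
class Sequence:
    """A named, ungapped protein sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        for pos, ch in enumerate(self.residues):
            if ch not in _RESIDUE_SET:
                raise ValueError(
                    f"sequence {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MSA:
    """A multiple alignment: ordered rows of equal-length gapped strings."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        object.__setattr__(self, "rows", tuple((i, r) for i, r in self.rows))
        length = len(self.rows[0][1])
        if length < 1:
            raise ValueError("alignment rows must be non-empty")
        seen = set()
        for rid, row in self.rows:
            if rid in seen:
                raise ValueError(f"duplicate row id {rid!r} in alignment")
            seen.add(rid)
            if len(row) != length:
                raise ValueError(
                    f"row {rid!r} has length {len(row)}, expected {length}"
                )
            for pos, ch in enumerate(row):
                if ch not in _GAPPED_SET:
                    raise ValueError(
                        f"row {rid!r}: illegal character {ch!r} at column {pos}"
                    )

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for i, r in self.rows:
            if i == rid:
                return r
        raise KeyError(rid)

    def ungapped(self) -> list[Sequence]:
        """Strip gaps from every row, recovering the input sequences."""
        return [Sequence(rid, row.replace(GAP, "")) for rid, row in self.rows]

    def drop_all_gap_columns(self) -> "MSA":
        keep = [
            j
            for j in range(self.length)
            if any(row[j] != GAP for _, row in self.rows)
        ]
        if len(keep) == self.length:
            return self
        return MSA(
            tuple((rid, "".join(row[j] for j in keep)) for rid, row in self.rows)
        )


def _clean(raw: str, *, allow_gaps: bool, rid: str) -> str:
    out = []
    for ch in raw:
        if ch.isspace() or ch == "*":
            continue
        ch = ch.upper()
        if ch == ".":
            ch = GAP
        out.append(ch)
    cleaned = "".join(out)
    if not cleaned:
        raise ValueError(f"record {rid!r} is empty")
    allowed = _GAPPED_SET if allow_gaps else _RESIDUE_SET
    for pos, ch in enumerate(cleaned):
        if ch not in allowed:
            raise ValueError(
                f"record {rid!r}: illegal character {ch!r} at position {pos}"
            )
    return cleaned


def _parse_records(path: Union[str, os.PathLike], *, allow_gaps: bool):
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        cleaned = _clean(str(rec.seq), allow_gaps=allow_gaps, rid=rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append((rec.id, cleaned, desc))
    return out


def read_fasta(path: Union[str, os.PathLike]) -> list[Sequence]:
    """Read unaligned sequences from a FASTA file, preserving record order."""
    return [
        Sequence(rid, res, desc)
        for rid, res, desc in _parse_records(path, allow_gaps=False)
    ]


def read_msa(path: Union[str, os.PathLike]) -> MSA:
    """Read an aligned FASTA file into an :class:`MSA`."""
    rows = tuple((rid, res) for rid, res, _ in _parse_records(path, allow_gaps=True))
    return MSA(rows)


def _wrap(s: str, width: int = 60) -> Iterable[str]:
    for i in range(0, len(s), width):
        yield s[i : i + width]


def write_fasta(
    data: Union[TypingSequence[Sequence], MSA], path: Union[str, os.PathLike]
) -> None:
    """Write sequences or an alignment as (aligned) FASTA, wrapped at 60."""
    if isinstance(data, MSA):
        items = [(rid, row, "") for rid, row in data.rows]
    else:
        items = [(s.id, s.residues, s.description) for s in data]
        if not items:
            raise ValueError("refusing to write an empty sequence set")
    with open(path, "w") as fh:
        for rid, res, desc in items:
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for line in _wrap(res):
                fh.write(line + "\n")


def read_newick(path: Union[str, os.PathLike]) -> GuideTree:
    """Read a Newick tree file (multifurcations accepted, binarize later)."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(
    tree: GuideTree, path: Union[str, os.PathLike], lengths: bool = True
) -> None:
    with open(path, "w") as fh:
        fh.write(format_newick(tree, lengths=lengths) + "\n")
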