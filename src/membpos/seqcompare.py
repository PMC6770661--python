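"""Pairwise isoform sequence comparison.

Percent identity and residue-difference reports for closely related
cytochrome P450 isoforms.  Equal-length pairs (e.g. the 490-residue
CYP 2C9 / CYP 2C19 pair) are compared positionally, gap-free, by default;
unequal-length pairs fall back to a BLOSUM62 global alignment with affine
gap penalties.  The identity denominator is the full alignment length
including gapped columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "percent_identity",
    "difference_report",
    "format_substitutions",
]

_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence (1-letter codes, standard alphabet plus X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[SequenceRecord]:
    """Read all records of a FASTA file."""
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(Path(path)), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def _global_alignment(a: str, b: str, gap_open: float, gap_extend: float):
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _aligned_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    mode: str,
    gap_open: float,
    gap_extend: float,
) -> tuple[str, str]:
    if mode == "positional":
        if len(a) != len(b):
            raise ValueError(
                "positional comparison requires equal lengths "
                f"({len(a)} vs {len(b)}); use mode='global'"
            )
        return a.residues.upper(), b.residues.upper()
    if mode == "global":
        return _global_alignment(a.residues.upper(), b.residues.upper(),
                                 gap_open, gap_extend)
    raise ValueError(f"unknown comparison mode {mode!r}")


def percent_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    mode: str = "positional",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Percent sequence identity, reported to one decimal.

    ``100 * identical aligned positions / aligned length``, with gapped
    columns counted in the length for global mode.
    """
    sa, sb = _aligned_pair(a, b, mode, gap_open, gap_extend)
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return round(100.0 * matches / len(sa), 1)


@dataclass
class DifferenceReport:
    """Aligned positions (1-based) at which two sequences differ."""

    differences: list  # of (position, res_a, res_b)
    mode: str
    restricted_to: dict | None = None

    def substitutions(self) -> list[str]:
        return [f"{ra}{pos}{rb}" for pos, ra, rb in self.differences]


def difference_report(
    a: SequenceRecord,
    b: SequenceRecord,
    positions=None,
    ranges=None,
    mode: str = "positional",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> DifferenceReport:
    """List every aligned position where the two sequences differ.

    ``positions`` restricts the report to a set of 1-based alignment
    positions, ``ranges`` to inclusive (lo, hi) ranges; either may be None.
    Substitution strings use the ``X<pos>Y`` convention (residue of ``a``,
    position, residue of ``b``), e.g. ``K72E``.
    """
    sa, sb = _aligned_pair(a, b, mode, gap_open, gap_extend)
    wanted = None
    if positions is not None:
        wanted = set(int(p) for p in positions)
    diffs = []
    for i, (x, y) in enumerate(zip(sa, sb), start=1):
        if x == y:
            continue
        if wanted is not None and i not in wanted:
            continue
        if ranges is not None and not any(lo <= i <= hi for lo, hi in ranges):
            continue
        diffs.append((i, x, y))
    restricted = None
    if positions is not None or ranges is not None:
        restricted = {"positions": sorted(wanted) if wanted else None,
                      "ranges": list(ranges) if ranges else None}
    return DifferenceReport(differences=diffs, mode=mode, restricted_to=restricted)


def format_substitutions(report: DifferenceReport) -> str:
    return ", ".join(report.substitutions())
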