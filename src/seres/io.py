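"""Sequence and alignment containers, FASTA I/O, and homology extraction.

The two central objects are :class:`Sequence` (an unaligned, gap-free
biomolecular sequence) and :class:`MultipleAlignment` (a rectangular matrix
of residues and ``-`` gap characters whose columns assert homology).  A
*nucleotide-nucleotide homology* is a pair of residues from two different
sequences placed in the same alignment column; homologies are represented as
canonical :class:`ResiduePair` objects in terms of 0-based *unaligned*
residue indices, so that homology sets from different alignments of the same
sequences are directly comparable.

Conventions used throughout the package:

* coordinates are 0-based and intervals are half-open;
* the gap symbol is ``-``; ``.`` (used by some rRNA alignment dialects) is
  normalized to ``-`` on read;
* residues are stored uppercase and compared case-insensitively.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence as TypingSequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: IUPAC nucleotide codes, including ambiguity codes.
NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")


class AlignmentShapeError(ValueError):
    """Raised when aligned input rows are not all the same length."""


class FastaFormatError(ValueError):
    """Raised for empty or malformed FASTA input."""


@dataclass(frozen=True)
class Sequence:
    """An unaligned sequence: a label and a gap-free residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        if GAP in self.residues or "." in self.residues:
            raise ValueError(f"sequence {self.id!r} contains gap characters")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse(self) -> "Sequence":
        return Sequence(self.id, self.residues[::-1])


@dataclass(frozen=True, order=True)
class ResiduePair:
    """A canonical residue pair: two residues identified by sequence label
    and 0-based unaligned index, with ``seq_i < seq_j`` lexicographically."""

    seq_i: str
    pos_i: int
    seq_j: str
    pos_j: int

    @staticmethod
    def make(seq_a: str, pos_a: int, seq_b: str, pos_b: int) -> "ResiduePair":
        if seq_a == seq_b:
            raise ValueError("a residue pair needs two distinct sequences")
        if seq_a < seq_b:
            return ResiduePair(seq_a, pos_a, seq_b, pos_b)
        return ResiduePair(seq_b, pos_b, seq_a, pos_a)


class MultipleAlignment:
    """A rectangular residue/gap matrix with per-cell provenance.

    ``provenance[i][j]`` is the 0-based index, in row *i*'s own degapped
    sequence, of the residue in cell ``(i, j)``, or ``-1`` for a gap cell.
    Degapping row *i* therefore reproduces the *i*-th unaligned sequence
    exactly, and provenance indices increase left to right over non-gap
    cells of a row.
    """

    def __init__(self, ids: TypingSequence[str], rows: TypingSequence[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if len(rows) == 0:
            raise FastaFormatError("alignment has no rows")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        rows = [r.upper().replace(".", GAP) for r in rows]
        k = len(rows[0])
        for label, row in zip(ids, rows):
            if len(row) != k:
                raise AlignmentShapeError(
                    f"row {label!r} has length {len(row)}, expected {k}"
                )
        self.ids: list[str] = list(ids)
        self.rows: list[str] = rows
        self._provenance: list[list[int]] | None = None

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def k(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    @property
    def provenance(self) -> list[list[int]]:
        if self._provenance is None:
            prov = []
            for row in self.rows:
                seen = 0
                entries = []
                for ch in row:
                    if ch == GAP:
                        entries.append(-1)
                    else:
                        entries.append(seen)
                        seen += 1
                prov.append(entries)
            self._provenance = prov
        return self._provenance

    def degap(self) -> list[Sequence]:
        """The unaligned sequences, in row order."""
        return [
            Sequence(label, row.replace(GAP, ""))
            for label, row in zip(self.ids, self.rows)
        ]

    def take_columns(self, cols: Iterable[int]) -> "MultipleAlignment":
        """A new alignment whose j-th column is this alignment's cols[j]."""
        cols = list(cols)
        rows = ["".join(row[c] for c in cols) for row in self.rows]
        return MultipleAlignment(self.ids, rows)

    def reverse_columns(self) -> "MultipleAlignment":
        return MultipleAlignment(self.ids, [row[::-1] for row in self.rows])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MultipleAlignment)
            and self.ids == other.ids
            and self.rows == other.rows
        )

    def __repr__(self) -> str:
        return f"<MultipleAlignment n={self.n} k={self.k}>"


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _check_alphabet(label: str, residues: str, on_invalid: str) -> str:
    bad = set(residues) - NUCLEOTIDE_ALPHABET - {GAP}
    if not bad:
        return residues
    if on_invalid == "mask":
        table = {ord(c): "N" for c in bad}
        return residues.translate(table)
    raise FastaFormatError(
        f"record {label!r} contains non-alphabet characters: {sorted(bad)!r}"
    )


def read_fasta(
    path: Union[str, Path],
    aligned: bool = False,
    on_invalid: str = "reject",
) -> Union[list[Sequence], MultipleAlignment]:
    """Read a FASTA file as unaligned sequences or as an alignment.

    Parameters
    ----------
    path:
        Plain or gzip-compressed FASTA file.
    aligned:
        If true, all records must have equal length and the result is a
        :class:`MultipleAlignment` (``.`` normalized to ``-``); otherwise
        the result is a list of gap-free :class:`Sequence` objects.
    on_invalid:
        ``"reject"`` raises on characters outside the IUPAC nucleotide
        alphabet; ``"mask"`` replaces them with ``N``.
    """
    with _open_text(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [
        _check_alphabet(r.id, str(r.seq).upper().replace(".", GAP), on_invalid)
        for r in records
    ]
    if aligned:
        return MultipleAlignment(ids, seqs)
    return [Sequence(label, s) for label, s in zip(ids, seqs)]


def write_fasta(
    path: Union[str, Path],
    data: Union[MultipleAlignment, Iterable[Sequence]],
    width: int = 70,
) -> None:
    """Write sequences or an alignment as FASTA (gzip if path ends in .gz)."""
    if isinstance(data, MultipleAlignment):
        records = [
            SeqRecord(Seq(row), id=label, description="")
            for label, row in zip(data.ids, data.rows)
        ]
    else:
        records = [
            SeqRecord(Seq(s.residues), id=s.id, description="") for s in data
        ]
    with _open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def iter_column_pairs(msa: MultipleAlignment, j: int) -> Iterator[ResiduePair]:
    """Canonical residue pairs asserted by column *j* of the alignment."""
    prov = msa.provenance
    present = [
        (msa.ids[i], prov[i][j])
        for i in range(msa.n)
        if msa.rows[i][j] != GAP
    ]
    for a in range(len(present)):
        for b in range(a + 1, len(present)):
            yield ResiduePair.make(*present[a], *present[b])


def extract_homologies(msa: MultipleAlignment) -> set[ResiduePair]:
    """All residue-pair homologies asserted by an alignment.

    One pair per unordered sequence pair per column in which both cells are
    non-gap; the total count is sum over columns of C(non-gap count, 2).
    """
    pairs: set[ResiduePair] = set()
    for j in range(msa.k):
        pairs.update(iter_column_pairs(msa, j))
    return pairs
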