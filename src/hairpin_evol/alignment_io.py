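"""Sequence and structure I/O, the alignment data model, and coordinate utilities.

Conventions used throughout the package:

* Coordinates on the public surface are 1-based and inclusive, matching the
  field's habit of writing "positions 1 to 73".
* Sequences are normalised to an internal DNA alphabet (``U`` -> ``T``); the
  input alphabet is remembered per record and restored on output, since
  genomic clones are conventionally written as DNA and mature miRNAs as RNA.
* The only gap character is ``-``.  ``N`` is accepted and treated as missing
  data by every statistic; other IUPAC ambiguity codes are rejected outright
  so that dialect differences never pass silently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class AlignmentError(ValueError):
    """Base class for data-model violations."""


class FormatError(AlignmentError):
    """Malformed input file."""


class CoordinateError(AlignmentError):
    """Region or position outside the alignment bounds."""


class Role(str, enum.Enum):
    INGROUP = "ingroup"
    OUTGROUP = "outgroup"
    REFERENCE_LOCUS = "reference_locus"


#: characters permitted after normalisation
VALID_CHARS = frozenset("ACGTN-")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def normalize_seq(raw: str, record_id: str = "?") -> tuple[str, bool]:
    """Uppercase *raw*, map U->T, validate the alphabet.

    Returns ``(normalised, was_rna)``.  Rejects ``.`` gaps and IUPAC
    ambiguity codes other than N with a :class:`FormatError`.
    """
    up = raw.upper()
    was_rna = "U" in up
    norm = up.replace("U", "T")
    bad = set(norm) - VALID_CHARS
    if bad:
        raise FormatError(
            f"record {record_id!r}: unsupported characters {sorted(bad)} "
            "(alphabet is A/C/G/T/U/N and gap '-')"
        )
    if not norm:
        raise FormatError(f"record {record_id!r}: empty sequence")
    return norm, was_rna


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned (or unaligned) nucleotide sequence.

    ``seq`` is stored in the normalised DNA alphabet; ``rna`` records
    whether the source used U so writers can restore it.
    """

    id: str
    seq: str
    role: Role = Role.INGROUP
    rna: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("record id must be non-empty")
        bad = set(self.seq) - VALID_CHARS
        if bad or not self.seq:
            raise AlignmentError(
                f"record {self.id!r}: invalid normalised sequence ({sorted(bad)})"
            )

    @classmethod
    def from_raw(cls, id: str, raw_seq: str, role: Role = Role.INGROUP) -> "SequenceRecord":
        norm, was_rna = normalize_seq(raw_seq, id)
        return cls(id=id, seq=norm, role=role, rna=was_rna)

    @property
    def output_seq(self) -> str:
        """Sequence in the record's original alphabet (U restored for RNA)."""
        return self.seq.replace("T", "U") if self.rna else self.seq

    def ungapped(self) -> str:
        return self.seq.replace("-", "")

    def with_role(self, role: Role) -> "SequenceRecord":
        return replace(self, role=role)


@dataclass(frozen=True)
class RegionSpec:
    """A named, 1-based inclusive column interval."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"region {self.name!r}: require 1 <= start <= end, got "
                f"[{self.start}, {self.end}]"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, column: int) -> bool:
        return self.start <= column <= self.end


@dataclass(frozen=True)
class MultipleAlignment:
    """An ordered set of equal-length gapped rows with unique ids."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        object.__setattr__(self, "records", tuple(self.records))
        width = len(self.records[0].seq)
        for rec in self.records:
            if len(rec.seq) != width:
                raise AlignmentError(
                    f"ragged alignment: record {rec.id!r} has width "
                    f"{len(rec.seq)}, expected {width}"
                )
        ids = [rec.id for rec in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    @property
    def length(self) -> int:
        """Number of columns."""
        return len(self.records[0].seq)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise AlignmentError(f"no record with id {record_id!r}")

    def subset(self, roles: Iterable[Role]) -> "MultipleAlignment":
        wanted = set(roles)
        kept = tuple(r for r in self.records if r.role in wanted)
        if not kept:
            raise AlignmentError(f"no records with role in {sorted(x.value for x in wanted)}")
        return MultipleAlignment(kept)

    def ingroup(self) -> "MultipleAlignment":
        return self.subset([Role.INGROUP])

    def column(self, col: int) -> str:
        """1-based column as a string, one character per row."""
        if not (1 <= col <= self.length):
            raise CoordinateError(f"column {col} outside 1..{self.length}")
        i = col - 1
        return "".join(rec.seq[i] for rec in self.records)

    def with_roles(self, role_of: dict[str, Role]) -> "MultipleAlignment":
        """Return a copy with roles reassigned for the listed ids."""
        unknown = set(role_of) - set(self.ids)
        if unknown:
            raise AlignmentError(f"unknown ids in role map: {sorted(unknown)}")
        return MultipleAlignment(
            tuple(
                rec.with_role(role_of[rec.id]) if rec.id in role_of else rec
                for rec in self.records
            )
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, role: Role = Role.INGROUP) -> MultipleAlignment:
    """Read a multi-record FASTA alignment (wrapped or unwrapped).

    Records keep file order.  Widths are validated; a ragged file raises an
    :class:`AlignmentError` naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    bio_records = list(SeqIO.parse(str(path), "fasta"))
    if not bio_records:
        raise FormatError(f"{path}: no FASTA records found")
    records = [SequenceRecord.from_raw(r.id, str(r.seq), role) for r in bio_records]
    return MultipleAlignment(tuple(records))


def write_fasta(aln: MultipleAlignment, path: str | Path, width: int = 70) -> None:
    """Write the alignment, restoring each record's original alphabet."""
    bio = [
        _BioSeqRecord(Seq(rec.output_seq), id=rec.id, description="")
        for rec in aln.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Region and comparison utilities


def slice_region(aln: MultipleAlignment, region: RegionSpec) -> MultipleAlignment:
    """Columns ``region.start..region.end`` (1-based inclusive), rows in order."""
    if region.end > aln.length:
        raise CoordinateError(
            f"region {region.name!r} [{region.start}, {region.end}] exceeds "
            f"alignment length {aln.length}"
        )
    a, b = region.start - 1, region.end
    return MultipleAlignment(
        tuple(replace(rec, seq=rec.seq[a:b]) for rec in aln.records)
    )


def mismatch_positions(a: str, b: str) -> list[int]:
    """Sorted 1-based positions where two ungapped sequences differ.

    Alphabet differences (U vs T, case) are ignored; gaps are rejected
    because positional comparison is undefined across indels.
    """
    na, _ = normalize_seq(a, "a")
    nb, _ = normalize_seq(b, "b")
    if len(na) != len(nb):
        raise AlignmentError(
            f"sequence lengths differ ({len(na)} vs {len(nb)})"
        )
    if "-" in na or "-" in nb:
        raise AlignmentError("mismatch_positions requires ungapped sequences")
    return [i + 1 for i, (x, y) in enumerate(zip(na, nb)) if x != y]


def consensus_base(aln: MultipleAlignment, col: int, tie_break_id: str | None = None) -> str | None:
    """Majority base (A/C/G/T) of a column, gaps and N excluded.

    Ties go to the base carried by ``tie_break_id`` when given and countable,
    else to the alphabetically first of the tied bases.  Returns ``None``
    when no row contributes a countable base.
    """
    column = aln.column(col)
    counts = {b: column.count(b) for b in "ACGT"}
    top = max(counts.values())
    if top == 0:
        return None
    tied = sorted(b for b, c in counts.items() if c == top)
    if len(tied) > 1 and tie_break_id is not None:
        ref_base = aln.get(tie_break_id).seq[col - 1]
        if ref_base in tied:
            return ref_base
    return tied[0]


def complement(base: str) -> str:
    """Watson-Crick complement in the internal DNA alphabet."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise AlignmentError(f"cannot complement {base!r}")


# ---------------------------------------------------------------------------
# Vienna dot-bracket and Newick parsing (consumed by hairpin_fold / rate_test)


def read_vienna(path: str | Path) -> tuple[str | None, str, str]:
    """Parse a Vienna file: optional ``>name`` line, sequence line, structure line.

    Returns ``(name, sequence, dot_bracket)``; the structure string is
    validated only for alphabet here (balance is checked by the parser in
    :mod:`hairpin_evol.hairpin_fold`).
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty Vienna file")
    name = None
    if lines[0].startswith(">"):
        name = lines[0][1:].strip()
        lines = lines[1:]
    if len(lines) < 2:
        raise FormatError(f"{path}: expected a sequence line and a structure line")
    seq, struct = lines[0], lines[1].split()[0]
    if set(struct) - set("().)"):
        raise FormatError(f"{path}: structure line contains non-dot-bracket characters")
    if len(seq) != len(struct):
        raise FormatError(
            f"{path}: sequence ({len(seq)}) and structure ({len(struct)}) lengths differ"
        )
    return name, seq, struct


def write_vienna(path: str | Path, seq: str, dot_bracket: str, name: str | None = None) -> None:
    if len(seq) != len(dot_bracket):
        raise AlignmentError("sequence and structure lengths differ")
    with open(path, "w") as fh:
        if name:
            fh.write(f">{name}\n")
        fh.write(seq + "\n" + dot_bracket + "\n")


def parse_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree from a string or a file path."""
    looks_like_data = isinstance(source, str) and ("(" in source or ";" in source)
    try:
        if not looks_like_data and Path(source).exists():
            return dendropy.Tree.get(path=str(source), schema="newick")
        return dendropy.Tree.get(data=str(source), schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"invalid Newick input: {exc}") from exc
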