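"""Hairpin secondary structure: prediction, parsing, partitioning, context.

The folder is a Nussinov-style base-pair-maximisation dynamic programme
admitting Watson-Crick pairs plus the G-U wobble, with a minimum hairpin
loop of ``min_loop`` unpaired bases.  It deliberately does not minimise
free energy: every downstream statistic also accepts an externally supplied
dot-bracket string, so a thermodynamic structure (ViennaRNA, mfold) can be
injected wherever higher fidelity is wanted.

A hairpin alignment is partitioned into three regions — the 5' fold-back
arm, the terminal loop region, and the 3' fold-back arm — either at fixed
coordinates (the usual mode for a curated study alignment) or from the
innermost stem pair of a predicted structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .alignment_io import (
    AlignmentError,
    CoordinateError,
    FormatError,
    MultipleAlignment,
    RegionSpec,
    consensus_base,
    normalize_seq,
    read_vienna,
    write_vienna,
)


class StructureError(AlignmentError):
    """Invalid secondary structure or pairing query."""


#: allowed pairs in the internal DNA alphabet (T plays the role of U)
WATSON_CRICK_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "T"), ("T", "G")})


def can_pair(x: str, y: str, wobble: bool = True) -> bool:
    p = (x, y)
    return p in WATSON_CRICK_PAIRS or (wobble and p in WOBBLE_PAIRS)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free pairing of positions 1..length.

    ``pair_of[i-1]`` is the 1-based partner of position ``i`` or ``None``.
    """

    pair_of: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        n = len(self.pair_of)
        for i, j in enumerate(self.pair_of, start=1):
            if j is None:
                continue
            if not (1 <= j <= n) or j == i:
                raise StructureError(f"position {i}: invalid partner {j}")
            if self.pair_of[j - 1] != i:
                raise StructureError(f"pairing is not an involution at {i}<->{j}")

    @property
    def length(self) -> int:
        return len(self.pair_of)

    @property
    def n_pairs(self) -> int:
        return sum(1 for j in self.pair_of if j is not None) // 2

    def pairs(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, sorted by i."""
        return [
            (i, j)
            for i, j in enumerate(self.pair_of, start=1)
            if j is not None and i < j
        ]

    def partner(self, position: int) -> Optional[int]:
        if not (1 <= position <= self.length):
            raise StructureError(f"position {position} outside 1..{self.length}")
        return self.pair_of[position - 1]

    @property
    def dot_bracket(self) -> str:
        chars = []
        for i, j in enumerate(self.pair_of, start=1):
            if j is None:
                chars.append(".")
            else:
                chars.append("(" if i < j else ")")
        return "".join(chars)

    @classmethod
    def from_pairs(cls, length: int, pairs: list[tuple[int, int]]) -> "SecondaryStructure":
        table: list[Optional[int]] = [None] * length
        for i, j in pairs:
            if table[i - 1] is not None or table[j - 1] is not None:
                raise StructureError(f"position paired twice in ({i}, {j})")
            table[i - 1] = j
            table[j - 1] = i
        return cls(tuple(table))


@dataclass(frozen=True)
class FoldResult:
    structure: SecondaryStructure

    @property
    def n_pairs(self) -> int:
        return self.structure.n_pairs

    @property
    def paired_fraction(self) -> float:
        return 2 * self.n_pairs / self.structure.length

    @property
    def dot_bracket(self) -> str:
        return self.structure.dot_bracket


@dataclass(frozen=True)
class HairpinPartition:
    """Contiguous 5'-arm / terminal-loop / 3'-arm cover of 1..length."""

    arm5: RegionSpec
    loop: RegionSpec
    arm3: RegionSpec

    def __post_init__(self) -> None:
        ok = (
            self.arm5.start == 1
            and self.loop.start == self.arm5.end + 1
            and self.arm3.start == self.loop.end + 1
        )
        if not ok:
            raise CoordinateError(
                "partition regions must be contiguous and ordered arm5/loop/arm3"
            )

    @property
    def length(self) -> int:
        return self.arm3.end

    def regions(self) -> list[RegionSpec]:
        return [self.arm5, self.loop, self.arm3]

    def region_of(self, column: int) -> RegionSpec:
        for region in self.regions():
            if region.contains(column):
                return region
        raise CoordinateError(f"column {column} outside partition 1..{self.length}")

    @classmethod
    def fixed(cls, length: int, arm5_end: int, loop_end: int) -> "HairpinPartition":
        """Partition from declared coordinates (e.g. the 73/66/75 split of a
        214-column hairpin alignment)."""
        if not (1 <= arm5_end < loop_end < length):
            raise CoordinateError(
                f"require 1 <= arm5_end < loop_end < length, got "
                f"{arm5_end}/{loop_end}/{length}"
            )
        return cls(
            arm5=RegionSpec("5' fold-back arm", 1, arm5_end),
            loop=RegionSpec("terminal loop region", arm5_end + 1, loop_end),
            arm3=RegionSpec("3' fold-back arm", loop_end + 1, length),
        )


# ---------------------------------------------------------------------------
# Base-pair maximisation folding


def fold_maxpair(seq: str, min_loop: int = 3, wobble: bool = True) -> FoldResult:
    """Maximise the number of nested pairs on an ungapped sequence.

    Pairs must be separated by at least ``min_loop`` unpaired positions
    (``j - i - 1 >= min_loop``).  The traceback is deterministic: at any
    interval the 5'-most base is paired whenever pairing it is optimal,
    with the 3'-most partner among optimal choices.
    """
    norm, _ = normalize_seq(seq, "fold input")
    if "-" in norm:
        raise AlignmentError("fold_maxpair requires an ungapped sequence")
    n = len(norm)
    if n < min_loop + 2:
        # too short for any pair: the open chain is the (trivial) optimum
        return FoldResult(SecondaryStructure.from_pairs(n, []))

    # M[i][j] = max pairs on norm[i..j], 0-based inclusive; i > j -> 0
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(norm[i], norm[k], wobble):
                    inner = M[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    right = M[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            M[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = M[i][j]
        chosen = None
        for k in range(j, i + min_loop, -1):  # largest partner first
            if can_pair(norm[i], norm[k], wobble):
                inner = M[i + 1][k - 1] if k - 1 >= i + 1 else 0
                right = M[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + right == target:
                    chosen = k
                    break
        if chosen is not None:
            pairs.append((i + 1, chosen + 1))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))

    return FoldResult(SecondaryStructure.from_pairs(n, pairs))


# ---------------------------------------------------------------------------
# Dot-bracket parsing


def parse_dot_bracket(s: str) -> SecondaryStructure:
    """Pair table of a balanced, pseudoknot-free dot-bracket string."""
    bad = set(s) - set("().")
    if bad:
        raise FormatError(f"dot-bracket string contains {sorted(bad)}")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(s, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at column {pos}")
            pairs.append((stack.pop(), pos))
    if stack:
        raise FormatError(f"unbalanced '(' at column {stack[0]}")
    return SecondaryStructure.from_pairs(len(s), pairs)


def read_structure(path: str | Path) -> tuple[str | None, str, SecondaryStructure]:
    """Read a Vienna file and parse its structure line."""
    name, seq, db = read_vienna(path)
    return name, seq, parse_dot_bracket(db)


def write_structure(
    path: str | Path, seq: str, structure: SecondaryStructure, name: str | None = None
) -> None:
    write_vienna(path, seq, structure.dot_bracket, name)


# ---------------------------------------------------------------------------
# Partitioning


def partition_hairpin(structure: SecondaryStructure) -> HairpinPartition:
    """Partition at the innermost pair of the hairpin's longest nested stem.

    With (i, j) the pair maximising i (the stem pair closest to the loop),
    the 5' arm is 1..i, the terminal loop i+1..j-1, the 3' arm j..length.
    """
    pairs = structure.pairs()
    if not pairs:
        raise StructureError("cannot partition a structure with no pairs")
    i, j = max(pairs, key=lambda p: p[0])
    if j - i < 2:
        raise StructureError("innermost pair leaves no loop positions")
    return HairpinPartition(
        arm5=RegionSpec("5' fold-back arm", 1, i),
        loop=RegionSpec("terminal loop region", i + 1, j - 1),
        arm3=RegionSpec("3' fold-back arm", j, structure.length),
    )


# ---------------------------------------------------------------------------
# Alignment-column <-> structure-position mapping and pairing context


@dataclass(frozen=True)
class ColumnMap:
    """Map between alignment columns and ungapped reference positions.

    The structure is computed on one designated reference sequence; its
    gapped row in the alignment defines which columns carry a structural
    position at all.  Columns that are gaps in the reference have no
    defined structural context.
    """

    col_to_pos: tuple[Optional[int], ...]  # alignment column -> structure position
    pos_to_col: tuple[int, ...]  # structure position -> alignment column

    @classmethod
    def from_reference(cls, gapped_seq: str) -> "ColumnMap":
        col_to_pos: list[Optional[int]] = []
        pos_to_col: list[int] = []
        pos = 0
        for col, ch in enumerate(gapped_seq, start=1):
            if ch == "-":
                col_to_pos.append(None)
            else:
                pos += 1
                col_to_pos.append(pos)
                pos_to_col.append(col)
        return cls(tuple(col_to_pos), tuple(pos_to_col))

    @classmethod
    def identity(cls, length: int) -> "ColumnMap":
        rng = tuple(range(1, length + 1))
        return cls(rng, rng)

    @property
    def n_columns(self) -> int:
        return len(self.col_to_pos)

    def position_of(self, column: int) -> Optional[int]:
        if not (1 <= column <= self.n_columns):
            raise CoordinateError(f"column {column} outside 1..{self.n_columns}")
        return self.col_to_pos[column - 1]

    def column_of(self, position: int) -> int:
        if not (1 <= position <= len(self.pos_to_col)):
            raise CoordinateError(
                f"structure position {position} outside 1..{len(self.pos_to_col)}"
            )
        return self.pos_to_col[position - 1]


@dataclass(frozen=True)
class PairingContext:
    """Structural context of an alignment column: a partner, or loop/unpaired."""

    paired: bool
    partner_position: Optional[int] = None  # structure coordinate
    partner_column: Optional[int] = None  # alignment coordinate
    partner_base: Optional[str] = None  # consensus base at the partner column

    @property
    def label(self) -> str:
        if not self.paired:
            return "internal_loop/unpaired"
        return f"pairs {self.partner_position} ({self.partner_base or '?'})"


def pairing_context(
    structure: SecondaryStructure,
    aln_column: int,
    column_map: ColumnMap,
    aln: MultipleAlignment | None = None,
) -> PairingContext:
    """Partner position/base for an alignment column, or the unpaired marker.

    The partner base is the majority consensus of the partner's alignment
    column when an alignment is supplied (reported in the RNA alphabet).
    """
    pos = column_map.position_of(aln_column)
    if pos is None:
        raise StructureError(
            f"column {aln_column} is a gap in the structure reference; context undefined"
        )
    partner = structure.partner(pos)
    if partner is None:
        return PairingContext(paired=False)
    partner_col = column_map.column_of(partner)
    base = None
    if aln is not None:
        dna = consensus_base(aln, partner_col)
        base = dna.replace("T", "U") if dna else None
    return PairingContext(
        paired=True,
        partner_position=partner,
        partner_column=partner_col,
        partner_base=base,
    )
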