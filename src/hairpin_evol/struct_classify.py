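"""Structure-aware classification of stem substitutions (co-evolution evidence).

Each polymorphic substitution inside the fold-back arms is placed in its
structural context (the base at the partnered stem position, or an
internal-loop marker) and classified by its effect on pairing:

``new_pairing``
    A mismatch becomes a Watson-Crick or wobble pair — the change creates
    pairing and increases hairpin stability.
``synonymous_pair``
    Pairing is preserved: Watson-Crick <-> wobble interchanges such as
    A-U -> G-U or G-U -> G-C, and Watson-Crick -> Watson-Crick (the true
    compensatory double substitution, annotated as such).
``no_change``
    Substitutions at unpaired/internal-loop positions, or mismatch ->
    mismatch at a nominally paired position.
``destabilizing``
    A Watson-Crick or wobble pair becomes a mismatch.

A hairpin under selection for its stem should accumulate only the first
three classes; co-evolution of the two arms shows up as ``new_pairing``
and ``synonymous_pair`` events whose partner strand tracks the change.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .alignment_io import (
    AlignmentError,
    MultipleAlignment,
    RegionSpec,
    Role,
)
from .diversity_stats import site_table
from .hairpin_fold import (
    ColumnMap,
    HairpinPartition,
    SecondaryStructure,
    StructureError,
    pairing_context,
)


class PairClass(enum.Enum):
    WATSON_CRICK = "watson_crick"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"


class SubstitutionClass(enum.Enum):
    NEW_PAIRING = "new_pairing"
    SYNONYMOUS_PAIR = "synonymous_pair"
    NO_CHANGE = "no_change"
    DESTABILIZING = "destabilizing"


#: sentinel context for unpaired / internal-loop positions
LOOP = "internal_loop"

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _to_rna(base: str) -> str:
    b = base.upper().replace("T", "U")
    if b not in "ACGU":
        raise AlignmentError(f"not a nucleotide: {base!r}")
    return b


def pair_class(x: str, y: str) -> PairClass:
    """Pair taxonomy of two bases: Watson-Crick, wobble, or mismatch."""
    p = (_to_rna(x), _to_rna(y))
    if p in _WC:
        return PairClass.WATSON_CRICK
    if p in _WOBBLE:
        return PairClass.WOBBLE
    return PairClass.MISMATCH


@dataclass(frozen=True)
class PairContext:
    """Partner state of a paired stem position.

    ``partner_base`` is the ancestral (consensus) partner state.
    ``derived_partner_base`` is the partner state carried by the taxa
    bearing the derived allele, when it differs — the signature of a
    compensatory double substitution.  The derived pair is evaluated
    against it, so A-U -> G-C classifies as pairing-preserving rather
    than as a break against the stale consensus partner.
    """

    partner_base: str  # RNA alphabet
    partner_position: Optional[int] = None  # alignment column, when known
    derived_partner_base: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "partner_base", _to_rna(self.partner_base))
        if self.derived_partner_base is not None:
            object.__setattr__(
                self, "derived_partner_base", _to_rna(self.derived_partner_base)
            )


Context = Union[PairContext, str, None]  # PairContext | LOOP | unannotated


@dataclass(frozen=True)
class SubstitutionRecord:
    """One derived allele at one polymorphic alignment column.

    ``ancestral`` is the majority (consensus) state; multi-allelic sites
    yield one record per derived allele.  ``context`` is ``None`` until
    annotated from a structure or an explicit context table.
    """

    position: int  # 1-based alignment column
    ancestral: str
    derived: str
    carrier_taxa: tuple[str, ...] = ()
    context: Context = None
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ancestral", _to_rna(self.ancestral))
        object.__setattr__(self, "derived", _to_rna(self.derived))
        if self.ancestral == self.derived:
            raise AlignmentError(
                f"column {self.position}: ancestral and derived states are equal"
            )

    @property
    def is_annotated(self) -> bool:
        return self.context is not None

    @property
    def is_paired(self) -> bool:
        return isinstance(self.context, PairContext)


@dataclass(frozen=True)
class CoevolutionSummary:
    counts: dict[SubstitutionClass, int]
    counts_arm5: dict[SubstitutionClass, int]
    counts_arm3: dict[SubstitutionClass, int]
    records: tuple[SubstitutionRecord, ...]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def structure_preserved_fraction(self) -> float:
        """Fraction of arm substitutions that leave pairing intact or improved."""
        if self.total == 0:
            return 1.0
        kept = (
            self.counts[SubstitutionClass.NEW_PAIRING]
            + self.counts[SubstitutionClass.SYNONYMOUS_PAIR]
            + self.counts[SubstitutionClass.NO_CHANGE]
        )
        return kept / self.total


# ---------------------------------------------------------------------------
# Extraction


def extract_substitutions(
    aln: MultipleAlignment,
    regions: Iterable[RegionSpec],
    reference_id: Optional[str] = None,
    ingroup_only: bool = True,
) -> list[SubstitutionRecord]:
    """All (variable site x derived allele) records within the regions.

    The ancestral state is the majority base, ties broken by the state of
    the designated reference record (default: the first ingroup row).
    Records come back unannotated; attach contexts with
    :func:`annotate_contexts` or :func:`apply_context_table`.
    """
    regions = list(regions)
    for region in regions:
        if region.end > aln.length:
            raise AlignmentError(
                f"region {region.name!r} exceeds alignment length {aln.length}"
            )
    sub = aln.ingroup() if ingroup_only and any(
        r.role != Role.INGROUP for r in aln.records
    ) else aln
    if reference_id is None:
        reference_id = sub.records[0].id
    table = site_table(sub, ingroup_only=False)
    records: list[SubstitutionRecord] = []
    for region in regions:
        for site in table[region.start - 1 : region.end]:
            if not site.is_variable:
                continue
            counts = site.allele_counts
            top = max(counts.values())
            tied = sorted(b for b, c in counts.items() if c == top)
            ancestral = tied[0]
            if len(tied) > 1:
                ref_base = sub.get(reference_id).seq[site.column - 1]
                if ref_base in tied:
                    ancestral = ref_base
            for derived in sorted(b for b, c in counts.items() if c > 0 and b != ancestral):
                carriers = tuple(
                    rec.id
                    for rec in sub.records
                    if rec.seq[site.column - 1] == derived
                )
                records.append(
                    SubstitutionRecord(
                        position=site.column,
                        ancestral=ancestral,
                        derived=derived,
                        carrier_taxa=carriers,
                    )
                )
    return records


def annotate_contexts(
    records: Sequence[SubstitutionRecord],
    structure: SecondaryStructure,
    column_map: ColumnMap,
    aln: Optional[MultipleAlignment] = None,
) -> list[SubstitutionRecord]:
    """Attach pairing contexts projected from the reference structure.

    A record whose column is a gap in the structure reference keeps
    ``context=None`` (classify it from an explicit context table instead).
    When the alignment is given and the partner column is itself
    polymorphic among the record's carriers, a compensatory note listing
    the partner-state change is attached.
    """
    out = []
    for rec in records:
        try:
            ctx = pairing_context(structure, rec.position, column_map, aln)
        except StructureError:
            out.append(rec)
            continue
        if not ctx.paired:
            out.append(replace(rec, context=LOOP))
            continue
        note = rec.note
        derived_partner = None
        if aln is not None and ctx.partner_column is not None:
            partner_states = {
                aln.get(t).seq[ctx.partner_column - 1].replace("T", "U")
                for t in rec.carrier_taxa
                if t in aln.ids
            } - {"-", "N"}
            consensus = ctx.partner_base
            changed = sorted(partner_states - ({consensus} if consensus else set()))
            if len(partner_states) == 1:
                derived_partner = next(iter(partner_states))
            if changed:
                note = (note + "; " if note else "") + (
                    f"compensatory: partner column {ctx.partner_column} "
                    f"{consensus}->{','.join(changed)} in carriers"
                )
        out.append(
            replace(
                rec,
                context=PairContext(
                    partner_base=ctx.partner_base or "N",
                    partner_position=ctx.partner_column,
                    derived_partner_base=derived_partner,
                ),
                note=note,
            )
        )
    return out


def read_context_table(path: str | Path) -> dict[int, Context]:
    """TSV of (position, partner or 'loop'[, partner_position]).

    The partner field is a base (the paired nucleotide) or the literal
    ``loop`` / ``internal_loop`` marker.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in frame.columns]
    frame.columns = cols
    if "position" not in cols or "partner" not in cols:
        raise AlignmentError("context table needs 'position' and 'partner' columns")
    table: dict[int, Context] = {}
    for _, row in frame.iterrows():
        pos = int(row["position"])
        partner = str(row["partner"]).strip()
        if partner.lower() in ("loop", "internal_loop", "unpaired"):
            table[pos] = LOOP
        else:
            ppos = None
            if "partner_position" in cols and not pd.isna(row.get("partner_position")):
                ppos = int(row["partner_position"])
            table[pos] = PairContext(partner_base=partner, partner_position=ppos)
    return table


def apply_context_table(
    records: Sequence[SubstitutionRecord], table: dict[int, Context]
) -> list[SubstitutionRecord]:
    """Attach explicitly supplied contexts (overrides any prior annotation)."""
    out = []
    for rec in records:
        if rec.position in table:
            out.append(replace(rec, context=table[rec.position]))
        else:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Classification


def classify_substitution(rec: SubstitutionRecord) -> SubstitutionClass:
    """Pure classification of one record from (ancestral, derived, context)."""
    if rec.context is None:
        raise AlignmentError(
            f"column {rec.position}: no structural context; annotate before classifying"
        )
    if rec.context == LOOP:
        return SubstitutionClass.NO_CHANGE
    assert isinstance(rec.context, PairContext)
    z = rec.context.partner_base
    z_after = rec.context.derived_partner_base or z
    before = pair_class(rec.ancestral, z)
    after = pair_class(rec.derived, z_after)
    paired = (PairClass.WATSON_CRICK, PairClass.WOBBLE)
    if before == PairClass.MISMATCH and after in paired:
        return SubstitutionClass.NEW_PAIRING
    if before in paired and after in paired:
        return SubstitutionClass.SYNONYMOUS_PAIR
    if before == PairClass.MISMATCH and after == PairClass.MISMATCH:
        return SubstitutionClass.NO_CHANGE
    return SubstitutionClass.DESTABILIZING


def summarize_coevolution(
    records: Sequence[SubstitutionRecord],
    partition: Optional[HairpinPartition] = None,
) -> CoevolutionSummary:
    """Class counts per arm and overall, plus the structure-preserved fraction."""

    def zero() -> dict[SubstitutionClass, int]:
        return {c: 0 for c in SubstitutionClass}

    counts, arm5, arm3 = zero(), zero(), zero()
    annotated = []
    for rec in records:
        cls = classify_substitution(rec)
        counts[cls] += 1
        if partition is not None:
            if partition.arm5.contains(rec.position):
                arm5[cls] += 1
            elif partition.arm3.contains(rec.position):
                arm3[cls] += 1
        note = rec.note
        annotated.append(replace(rec, note=note))
    return CoevolutionSummary(
        counts=counts, counts_arm5=arm5, counts_arm3=arm3, records=tuple(annotated)
    )


def classification_frame(records: Sequence[SubstitutionRecord]) -> pd.DataFrame:
    """Report table mirroring the usual presentation: taxa, position,
    substitution, partner or loop marker, class."""
    rows = []
    for rec in records:
        cls = classify_substitution(rec)
        if isinstance(rec.context, PairContext):
            partner = rec.context.partner_base
            ppos = rec.context.partner_position
        else:
            partner, ppos = "internal loop", None
        rows.append(
            {
                "taxa": ", ".join(rec.carrier_taxa),
                "position": rec.position,
                "substitution": f"{rec.ancestral}->{rec.derived}",
                "partner": partner,
                "partner_position": ppos,
                "class": cls.value,
                "note": rec.note,
            }
        )
    frame = pd.DataFrame(rows)
    if "partner_position" in frame.columns:
        frame["partner_position"] = frame["partner_position"].astype("Int64")
    return frame
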