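"""Per-site variability, region diversity (Watterson theta), entropy profile.

Counting rules
--------------
* Only A/C/G/T residues are counted; gaps and N are missing data, never a
  fifth allele.  A column whose countable residues are all identical is
  monomorphic even if some rows are gapped.
* A segregating (variable) site has >= 2 distinct countable bases; a
  singleton is a biallelic site whose minor base occurs in exactly one row.
* Region site counts keep the full region width (gapped columns included),
  so theta is per alignment column, the convention of the standard
  population-genetics reports this module mirrors.
* Diversity is computed over ingroup rows by default; outgroups do not
  enter polymorphism statistics.

Indel polymorphism is reported separately (:func:`indel_runs`), since the
statistics above are substitution-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .alignment_io import (
    AlignmentError,
    MultipleAlignment,
    RegionSpec,
    Role,
    slice_region,
)

BASES = "ACGT"


@dataclass(frozen=True)
class SiteVariability:
    column: int  # 1-based
    allele_counts: dict[str, int]  # A/C/G/T among countable residues
    n_effective: int

    @property
    def n_alleles(self) -> int:
        return sum(1 for c in self.allele_counts.values() if c > 0)

    @property
    def is_variable(self) -> bool:
        return self.n_alleles >= 2

    @property
    def is_singleton(self) -> bool:
        if self.n_alleles != 2:
            return False
        present = sorted(c for c in self.allele_counts.values() if c > 0)
        return present[0] == 1


@dataclass(frozen=True)
class DiversitySummary:
    region: RegionSpec
    n_seq: int
    n_sites: int
    S: int
    n_singletons: int

    @property
    def harmonic_sum(self) -> float:
        """a_{n-1} = sum_{i=1}^{n-1} 1/i."""
        return harmonic_number(self.n_seq - 1)

    @property
    def theta_w(self) -> float:
        return watterson_theta(self.S, self.n_sites, self.n_seq)


@dataclass(frozen=True)
class EntropyProfile:
    values: tuple[float, ...]  # per-column H_i; nan where no residue countable
    log_base: Literal["e", "2"]

    def __len__(self) -> int:
        return len(self.values)

    @property
    def missing_columns(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, v in enumerate(self.values) if math.isnan(v))

    def region_mean(self, region: RegionSpec) -> float:
        vals = [
            v
            for v in self.values[region.start - 1 : region.end]
            if not math.isnan(v)
        ]
        if not vals:
            raise AlignmentError(f"region {region.name!r}: no countable columns")
        return float(np.mean(vals))


def _countable(aln: MultipleAlignment, ingroup_only: bool) -> MultipleAlignment:
    if ingroup_only and any(r.role != Role.INGROUP for r in aln.records):
        return aln.ingroup()
    return aln


def site_table(aln: MultipleAlignment, ingroup_only: bool = True) -> list[SiteVariability]:
    """One :class:`SiteVariability` per column."""
    sub = _countable(aln, ingroup_only)
    if len(sub) < 2:
        raise AlignmentError("site statistics need at least 2 sequences")
    rows = np.array([list(rec.seq) for rec in sub.records])
    out = []
    for col in range(aln.length):
        column = rows[:, col]
        counts = {b: int(np.sum(column == b)) for b in BASES}
        out.append(
            SiteVariability(
                column=col + 1,
                allele_counts=counts,
                n_effective=sum(counts.values()),
            )
        )
    return out


def harmonic_number(m: int) -> float:
    return float(sum(1.0 / i for i in range(1, m + 1)))


def watterson_theta(S: int, n_sites: int, n_seq: int) -> float:
    """Watterson's per-site estimate of the scaled mutation rate.

    theta_W = S / (a_{n-1} * L) with a_m the m-th harmonic number,
    S the segregating-site count and L the number of sites.
    """
    if n_seq < 2:
        raise AlignmentError("Watterson's estimator is undefined for n_seq < 2")
    if n_sites < 1:
        raise AlignmentError("n_sites must be >= 1")
    if not (0 <= S <= n_sites):
        raise AlignmentError(f"require 0 <= S <= n_sites, got S={S}, n_sites={n_sites}")
    return S / (harmonic_number(n_seq - 1) * n_sites)


def entropy_profile(
    aln: MultipleAlignment,
    log_base: Literal["e", "2"] = "e",
    ingroup_only: bool = True,
) -> EntropyProfile:
    """Shannon entropy of the base proportions at every column.

    H_i = -sum_j P_ij log(P_ij) over j in {A, C, G, T}, with proportions
    among countable residues and 0*log(0) = 0.  Columns with no countable
    residue are reported as NaN and listed by ``missing_columns``.
    """
    if log_base not in ("e", "2"):
        raise AlignmentError(f"log_base must be 'e' or '2', got {log_base!r}")
    log = math.log if log_base == "e" else math.log2
    values = []
    for site in site_table(aln, ingroup_only=ingroup_only):
        n = site.n_effective
        if n == 0:
            values.append(float("nan"))
            continue
        h = -sum(
            (c / n) * log(c / n) for c in site.allele_counts.values() if c > 0
        )
        values.append(max(h, 0.0))  # guard the -0.0 of monomorphic columns
    return EntropyProfile(values=tuple(values), log_base=log_base)


def region_diversity(
    aln: MultipleAlignment,
    regions: Iterable[RegionSpec],
    include_whole: bool = True,
    ingroup_only: bool = True,
) -> list[DiversitySummary]:
    """Segregating sites, singletons and theta_W per region.

    A whole-alignment summary is appended when ``include_whole`` is set.
    ``n_sites`` is the full region width; rows are the ingroup by default.
    """
    regions = list(regions)
    for region in regions:
        if region.end > aln.length:
            raise AlignmentError(
                f"region {region.name!r} exceeds alignment length {aln.length}"
            )
    table = site_table(aln, ingroup_only=ingroup_only)
    n_seq = len(_countable(aln, ingroup_only))

    def summarise(region: RegionSpec) -> DiversitySummary:
        sites = table[region.start - 1 : region.end]
        return DiversitySummary(
            region=region,
            n_seq=n_seq,
            n_sites=len(region),
            S=sum(1 for s in sites if s.is_variable),
            n_singletons=sum(1 for s in sites if s.is_singleton),
        )

    out = [summarise(r) for r in regions]
    if include_whole:
        out.append(summarise(RegionSpec("whole alignment", 1, aln.length)))
    return out


@dataclass(frozen=True)
class IndelRun:
    """A maximal gap run in one row (deletion polymorphism annotation)."""

    record_id: str
    start: int  # 1-based first gapped column
    length: int


def indel_runs(aln: MultipleAlignment, ingroup_only: bool = True) -> list[IndelRun]:
    """Maximal '-' runs per row, the package's indel-polymorphism report."""
    sub = _countable(aln, ingroup_only)
    runs = []
    for rec in sub.records:
        start = None
        for i, ch in enumerate(rec.seq + "X", start=1):  # sentinel flushes final run
            if ch == "-" and start is None:
                start = i
            elif ch != "-" and start is not None:
                runs.append(IndelRun(rec.id, start, i - start))
                start = None
    return runs


# ---------------------------------------------------------------------------
# Tabular reports


def diversity_frame(summaries: Iterable[DiversitySummary]) -> pd.DataFrame:
    """TSV-ready table: one row per region, theta rounded to 3 decimals."""
    rows = [
        {
            "region": s.region.name,
            "start": s.region.start,
            "end": s.region.end,
            "n_seq": s.n_seq,
            "n_sites": s.n_sites,
            "S": s.S,
            "singletons": s.n_singletons,
            "theta_w": round(s.theta_w, 3),
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def entropy_frame(profile: EntropyProfile, table: Optional[list[SiteVariability]] = None) -> pd.DataFrame:
    rows = []
    for i, h in enumerate(profile.values, start=1):
        row: dict = {"column": i, "entropy": h, "log_base": profile.log_base}
        if table is not None:
            row.update({b: table[i - 1].allele_counts[b] for b in BASES})
        rows.append(row)
    return pd.DataFrame(rows)
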