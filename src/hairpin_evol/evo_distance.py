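"""Pairwise substitutions per site (D_XY) and the neutral-locus contrast.

Three distance models are provided:

``p``
    Raw proportion of mismatching sites.
``jc69``
    Jukes-Cantor one-parameter correction, d = -(3/4) ln(1 - 4p/3).
``six_parameter``
    A six-parameter correction separating the two transition classes
    (A<->G and C<->T) from transversions, with unequal base frequencies
    estimated from each sequence pair.  The closed form used is the
    Tamura-Nei composite:

        d = -k1 ln(w1) - k2 ln(w2) - k3 ln(w3)

        k1 = 2 pA pG / pR            w1 = 1 - P1/k1 - Q/(2 pR)
        k2 = 2 pT pC / pY            w2 = 1 - P2/k2 - Q/(2 pY)
        k3 = 2 (pR pY - pA pG pY/pR - pT pC pR/pY)
                                     w3 = 1 - Q/(2 pR pY)

    with P1/P2 the observed purine/pyrimidine transition proportions, Q
    the transversion proportion, and pR = pA + pG, pY = pC + pT.  The
    model has six free parameters (three frequency parameters, two
    transition rates, one transversion rate) and collapses to JC69 when
    composition is uniform and transitions are unbiased.

Sites where either sequence carries a gap or N are deleted pairwise, so
regional distances remain defined on indel-bearing loops.  A pair whose
correction is undefined (logarithm of a non-positive number) is flagged
saturated rather than raising; saturated entries are excluded from
summaries, with the exclusion count reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .alignment_io import (
    AlignmentError,
    MultipleAlignment,
    RegionSpec,
    Role,
    slice_region,
)

DistanceModel = Literal["p", "jc69", "six_parameter"]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class DistanceError(AlignmentError):
    """Distance computation impossible (e.g. zero comparable sites)."""


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # square, symmetric; NaN marks saturated entries
    model: DistanceModel
    region: Optional[RegionSpec] = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DistanceError("matrix shape does not match id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def pair_values(self) -> dict[tuple[str, str], float]:
        """Strict-upper-triangle entries keyed by sorted id pair."""
        out = {}
        for i, j in itertools.combinations(range(self.n), 2):
            key = tuple(sorted((self.ids[i], self.ids[j])))
            out[key] = float(self.values[i, j])
        return out

    @property
    def n_saturated(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class PairedLocusComparison:
    """Matched-pairs t-test of a test locus against a reference locus.

    Negative ``mean_difference`` means the test locus is less divergent
    than the reference.  Each species pair is treated as an independent
    observation; with n taxa the C(n, 2) pairs share taxa, so the test is
    anti-conservative (pseudo-replication) — reports carry this caveat.
    """

    pair_ids: tuple[tuple[str, str], ...]
    d_test: tuple[float, ...]
    d_reference: tuple[float, ...]
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float  # two-sided
    p_value_lower: float  # one-sided, H1: test locus less divergent
    degenerate_variance: bool = False

    caveat: str = (
        "species pairs are treated as independent observations; shared taxa "
        "make this test anti-conservative"
    )


# ---------------------------------------------------------------------------
# Per-pair estimators


def _pair_site_counts(a: str, b: str) -> tuple[int, int, int, int, dict[str, float]]:
    """Pairwise-deletion counts: (n, purine transitions, pyrimidine
    transitions, transversions, average base frequencies)."""
    n = p1 = p2 = q = 0
    freq = {x: 0.0 for x in "ACGT"}
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        freq[x] += 0.5
        freq[y] += 0.5
        if x == y:
            continue
        if {x, y} <= PURINES:
            p1 += 1
        elif {x, y} <= PYRIMIDINES:
            p2 += 1
        else:
            q += 1
    if n:
        freq = {k: v / n for k, v in freq.items()}
    return n, p1, p2, q, freq


def p_distance(a: str, b: str) -> float:
    n, p1, p2, q, _ = _pair_site_counts(a, b)
    if n == 0:
        raise DistanceError("zero comparable sites between sequences")
    return (p1 + p2 + q) / n


def jc69_distance(a: str, b: str) -> float:
    """JC69 correction; NaN (saturation) when p >= 3/4."""
    p = p_distance(a, b)
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return float("nan")
    return -0.75 * math.log(arg)


def six_parameter_distance(a: str, b: str) -> float:
    """Six-parameter transition/transversion distance (formula above).

    Terms whose coefficient vanishes (a base class absent from the pair)
    contribute nothing; an undefined logarithm yields NaN (saturated).
    """
    n, np1, np2, nq, f = _pair_site_counts(a, b)
    if n == 0:
        raise DistanceError("zero comparable sites between sequences")
    P1, P2, Q = np1 / n, np2 / n, nq / n
    pA, pC, pG, pT = f["A"], f["C"], f["G"], f["T"]
    pR, pY = pA + pG, pC + pT

    d = 0.0
    # purine-transition term
    if pA * pG > 0:
        k1 = 2.0 * pA * pG / pR
        w1 = 1.0 - P1 / k1 - Q / (2.0 * pR)
        if w1 <= 0.0:
            return float("nan")
        d += -k1 * math.log(w1)
    elif P1 > 0:
        return float("nan")
    # pyrimidine-transition term
    if pT * pC > 0:
        k2 = 2.0 * pT * pC / pY
        w2 = 1.0 - P2 / k2 - Q / (2.0 * pY)
        if w2 <= 0.0:
            return float("nan")
        d += -k2 * math.log(w2)
    elif P2 > 0:
        return float("nan")
    # transversion term
    if pR * pY > 0:
        k3 = 2.0 * (pR * pY - (pA * pG * pY / pR if pR else 0.0) - (pT * pC * pR / pY if pY else 0.0))
        w3 = 1.0 - Q / (2.0 * pR * pY)
        if w3 <= 0.0:
            return float("nan")
        d += -k3 * math.log(w3)
    elif Q > 0:
        return float("nan")
    return max(d, 0.0)


_ESTIMATORS = {
    "p": p_distance,
    "jc69": jc69_distance,
    "six_parameter": six_parameter_distance,
}


# ---------------------------------------------------------------------------
# Matrix-level operations


def pairwise_distances(
    aln: MultipleAlignment,
    region: Optional[RegionSpec] = None,
    model: DistanceModel = "six_parameter",
    include_roles: tuple[Role, ...] = (Role.INGROUP,),
) -> DistanceMatrix:
    """Symmetric D_XY matrix over the selected rows and region."""
    if model not in _ESTIMATORS:
        raise DistanceError(f"unknown model {model!r}")
    sub = aln.subset(include_roles) if include_roles else aln
    if region is not None:
        sub = slice_region(sub, region)
    if len(sub) < 2:
        raise DistanceError("need at least 2 sequences for a distance matrix")
    est = _ESTIMATORS[model]
    n = len(sub)
    values = np.zeros((n, n))
    seqs = [rec.seq for rec in sub.records]
    for i, j in itertools.combinations(range(n), 2):
        d = est(seqs[i], seqs[j])
        values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=sub.ids, values=values, model=model, region=region)


def summarize_pairwise(dm: DistanceMatrix) -> dict[str, float]:
    """min/max/mean over the strict upper triangle, saturated entries excluded."""
    if dm.n < 2:
        raise DistanceError("summary needs at least one off-diagonal entry")
    iu = np.triu_indices(dm.n, k=1)
    vals = dm.values[iu]
    finite = vals[~np.isnan(vals)]
    if finite.size == 0:
        raise DistanceError("all pairwise entries are saturated")
    return {
        "min": float(finite.min()),
        "max": float(finite.max()),
        "mean": float(finite.mean()),
        "n_pairs": int(finite.size),
        "n_saturated": int(vals.size - finite.size),
    }


def matched_pairs_test(
    test: DistanceMatrix, reference: DistanceMatrix
) -> PairedLocusComparison:
    """Paired t-test of per-pair distances, test locus minus reference.

    Pairs are matched by sorted id pair across the two matrices; pairs
    with a saturated (NaN) entry on either locus are dropped.
    """
    tv = test.pair_values()
    rv = reference.pair_values()
    common = sorted(
        k
        for k in set(tv) & set(rv)
        if not (math.isnan(tv[k]) or math.isnan(rv[k]))
    )
    if len(common) < 2:
        raise DistanceError("need at least 2 shared, unsaturated sequence pairs")
    d_test = np.array([tv[k] for k in common])
    d_ref = np.array([rv[k] for k in common])
    diff = d_test - d_ref
    n = len(diff)
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    degenerate = False
    if sd == 0.0:
        if mean == 0.0:
            t = 0.0
            p_two = 1.0
        else:
            # all differences equal and nonzero: p is the zero-variance limit
            t = math.copysign(math.inf, mean)
            p_two = 0.0
            degenerate = True
    else:
        t = mean / (sd / math.sqrt(n))
        p_two = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    if math.isinf(t):
        p_lower = 0.0 if t < 0 else 1.0
    elif sd == 0.0:
        p_lower = 0.5
    else:
        p_lower = float(stats.t.cdf(t, df=n - 1))
    return PairedLocusComparison(
        pair_ids=tuple(common),
        d_test=tuple(float(x) for x in d_test),
        d_reference=tuple(float(x) for x in d_ref),
        mean_difference=mean,
        t_statistic=float(t),
        df=n - 1,
        p_value=p_two,
        p_value_lower=p_lower,
        degenerate_variance=degenerate,
    )


# ---------------------------------------------------------------------------
# Output helpers


def write_matrix_tsv(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def write_matrix_phylip(dm: DistanceMatrix, path) -> None:
    """PHYLIP square format (saturated entries written as -1)."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, name in enumerate(dm.ids):
            row = " ".join(
                f"{(-1.0 if math.isnan(v) else v):.6f}" for v in dm.values[i]
            )
            fh.write(f"{name[:10]:<10} {row}\n")
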