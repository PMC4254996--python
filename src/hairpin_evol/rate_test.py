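"""Maximum-likelihood relative-rate tests under JC69.

For two ingroup sequences *a*, *b* and an outgroup *o*, the unrooted
three-taxon tree has one internal node and branch lengths (a, b, o) in
substitutions per site.  Under JC69 the likelihood depends on the data
only through five distinguishable site-pattern classes:

    xxx   all three bases equal
    xxy   a == b != o
    xyx   a == o != b
    yxx   b == o != a
    xyz   all three distinct

Rate constancy is tested by comparing the free fit against the constrained
fit with a = b; twice the log-likelihood difference is referred to the
chi-square distribution with one degree of freedom.

Columns with a gap or N in any of the three sequences are deleted for that
triplet.  Optimisation is bounded ([0, 10] substitutions/site) and
deterministically initialised from pairwise JC69 distances, so results are
reproducible without stochastic restarts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .alignment_io import AlignmentError, MultipleAlignment, RegionSpec, Role, slice_region
from .evo_distance import jc69_distance

BRANCH_BOUNDS = (0.0, 10.0)
LNL_TOL = 1e-8
MIN_SITES = 10


class RateTestError(AlignmentError):
    pass


@dataclass(frozen=True)
class TripletTestResult:
    ingroup_a: str
    ingroup_b: str
    outgroup: str
    lnl_free: float
    lnl_equal: float
    a_hat: float
    b_hat: float
    o_hat: float
    n_sites: int
    converged: bool = True

    @property
    def lrt(self) -> float:
        return max(0.0, 2.0 * (self.lnl_free - self.lnl_equal))

    @property
    def p_value(self) -> float:
        return float(stats.chi2.sf(self.lrt, df=1))


@dataclass(frozen=True)
class RateTestSummary:
    region: Optional[RegionSpec]
    outgroup: str
    n_tests: int
    n_rejected: int
    alpha: float

    def __post_init__(self) -> None:
        if self.n_rejected > self.n_tests:
            raise RateTestError("rejections exceed test count")


# ---------------------------------------------------------------------------
# JC69 pattern likelihood


def _jc69_probs(d: float) -> tuple[float, float]:
    """(P(same base), P(one specific different base)) after distance d."""
    e = math.exp(-4.0 * d / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def pattern_counts(a: str, b: str, o: str) -> tuple[int, int, int, int, int]:
    """Counts of (xxx, xxy, xyx, yxx, xyz) after triplet gap deletion."""
    n_same = n_ab = n_ao = n_bo = n_diff = 0
    for x, y, z in zip(a, b, o):
        if x not in "ACGT" or y not in "ACGT" or z not in "ACGT":
            continue
        if x == y == z:
            n_same += 1
        elif x == y:
            n_ab += 1
        elif x == z:
            n_ao += 1
        elif y == z:
            n_bo += 1
        else:
            n_diff += 1
    return n_same, n_ab, n_ao, n_bo, n_diff


def pattern_log_probs(da: float, db: float, do: float) -> np.ndarray:
    """Log probability of one *specific* site pattern from each class.

    Obtained by summing the uniform-rooted JC69 transition probabilities
    over the internal-node state; by model symmetry every specific pattern
    within a class has the same probability.
    """
    sa, ma = _jc69_probs(da)
    sb, mb = _jc69_probs(db)
    so, mo = _jc69_probs(do)
    p_same = 0.25 * (sa * sb * so + 3.0 * ma * mb * mo)
    p_ab = 0.25 * (sa * sb * mo + ma * mb * so + 2.0 * ma * mb * mo)
    p_ao = 0.25 * (sa * mb * so + ma * sb * mo + 2.0 * ma * mb * mo)
    p_bo = 0.25 * (ma * sb * so + sa * mb * mo + 2.0 * ma * mb * mo)
    p_diff = 0.25 * (sa * mb * mo + ma * sb * mo + ma * mb * so + ma * mb * mo)
    # a zero-length branch zeroes some pattern classes; floor keeps the
    # log finite (classes with zero observed count contribute nothing)
    probs = np.array([p_same, p_ab, p_ao, p_bo, p_diff])
    return np.log(np.maximum(probs, 1e-300))


def _lnl(counts: np.ndarray, da: float, db: float, do: float) -> float:
    return float(counts @ pattern_log_probs(da, db, do))


def per_site_log_likelihood(a: str, b: str, o: str, da: float, db: float, do: float) -> float:
    """Likelihood from the raw site product (oracle route for tests)."""
    counts = np.array(pattern_counts(a, b, o), dtype=float)
    return _lnl(counts, da, db, do)


# ---------------------------------------------------------------------------
# The test


def triplet_test(a_seq: str, b_seq: str, o_seq: str,
                 ids: tuple[str, str, str] = ("a", "b", "o")) -> TripletTestResult:
    """LRT of equal root-to-ingroup rates on one (a, b, outgroup) triplet."""
    if not (len(a_seq) == len(b_seq) == len(o_seq)):
        raise RateTestError("triplet sequences must have equal aligned length")
    counts = np.array(pattern_counts(a_seq, b_seq, o_seq), dtype=float)
    n_sites = int(counts.sum())
    if n_sites < MIN_SITES:
        raise RateTestError(
            f"only {n_sites} comparable sites in triplet (minimum {MIN_SITES})"
        )

    def fin(d: float) -> float:
        return min(max(d, 1e-6), BRANCH_BOUNDS[1] - 1e-6) if not math.isnan(d) else 0.05

    d_ab = jc69_distance(a_seq, b_seq)
    d_ao = jc69_distance(a_seq, o_seq)
    d_bo = jc69_distance(b_seq, o_seq)
    # deterministic initialisation from the three-point (midpoint) formulas
    a0 = fin(0.5 * (d_ab + d_ao - d_bo))
    b0 = fin(0.5 * (d_ab + d_bo - d_ao))
    o0 = fin(0.5 * (d_ao + d_bo - d_ab))

    def neg_free(x: np.ndarray) -> float:
        return -_lnl(counts, x[0], x[1], x[2])

    def neg_equal(x: np.ndarray) -> float:
        return -_lnl(counts, x[0], x[0], x[1])

    converged = True
    res_eq = optimize.minimize(
        neg_equal,
        x0=np.array([fin(0.5 * (a0 + b0)), o0]),
        method="L-BFGS-B",
        bounds=[BRANCH_BOUNDS, BRANCH_BOUNDS],
        options={"ftol": LNL_TOL, "gtol": 1e-10},
    )
    converged &= bool(res_eq.success)
    res_free = optimize.minimize(
        neg_free,
        x0=np.array([a0, b0, o0]),
        method="L-BFGS-B",
        bounds=[BRANCH_BOUNDS] * 3,
        options={"ftol": LNL_TOL, "gtol": 1e-10},
    )
    converged &= bool(res_free.success)

    lnl_equal = -float(res_eq.fun)
    a_hat, b_hat, o_hat = (float(v) for v in res_free.x)
    lnl_free = -float(res_free.fun)
    # nested models: the free fit can never be worse than the constrained one
    if lnl_free < lnl_equal:
        lnl_free = lnl_equal
        a_hat = b_hat = float(res_eq.x[0])
        o_hat = float(res_eq.x[1])

    return TripletTestResult(
        ingroup_a=ids[0],
        ingroup_b=ids[1],
        outgroup=ids[2],
        lnl_free=lnl_free,
        lnl_equal=lnl_equal,
        a_hat=a_hat,
        b_hat=b_hat,
        o_hat=o_hat,
        n_sites=n_sites,
        converged=converged,
    )


def n_ingroup_pairs(n_ingroup: int) -> int:
    return math.comb(n_ingroup, 2)


def batch_rate_tests(
    aln: MultipleAlignment,
    outgroup_id: str,
    region: Optional[RegionSpec] = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> tuple[RateTestSummary, pd.DataFrame]:
    """One triplet test per unordered ingroup pair against one outgroup.

    Raw p-values are retained; rejection counts use ``alpha`` directly
    unless Benjamini-Hochberg correction is requested.
    """
    if outgroup_id not in aln.ids:
        raise RateTestError(f"outgroup id {outgroup_id!r} not in alignment")
    sub = slice_region(aln, region) if region is not None else aln
    out_seq = sub.get(outgroup_id).seq
    ingroup_ids = [
        rec.id for rec in sub.records if rec.id != outgroup_id and rec.role == Role.INGROUP
    ]
    if len(ingroup_ids) < 2:
        raise RateTestError("need at least 2 ingroup records")

    rows = []
    for id_a, id_b in itertools.combinations(ingroup_ids, 2):
        res = triplet_test(
            sub.get(id_a).seq, sub.get(id_b).seq, out_seq, ids=(id_a, id_b, outgroup_id)
        )
        rows.append(
            {
                "a": id_a,
                "b": id_b,
                "outgroup": outgroup_id,
                "lnl_free": res.lnl_free,
                "lnl_equal": res.lnl_equal,
                "lrt": res.lrt,
                "p": res.p_value,
                "a_hat": res.a_hat,
                "b_hat": res.b_hat,
                "o_hat": res.o_hat,
                "n_sites": res.n_sites,
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows)
    if bh_correct:
        table["p_adjusted"] = _benjamini_hochberg(table["p"].to_numpy())
        rejected = int((table["p_adjusted"] <= alpha).sum())
    else:
        rejected = int((table["p"] <= alpha).sum())
    summary = RateTestSummary(
        region=region,
        outgroup=outgroup_id,
        n_tests=len(table),
        n_rejected=rejected,
        alpha=alpha,
    )
    return summary, table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
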