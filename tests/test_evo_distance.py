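import math

import numpy as np
import pytest
from scipy import stats

from hairpin_evol.alignment_io import MultipleAlignment, RegionSpec
from hairpin_evol.evo_distance import (
    DistanceError,
    DistanceMatrix,
    jc69_distance,
    matched_pairs_test,
    p_distance,
    pairwise_distances,
    six_parameter_distance,
    summarize_pairwise,
)
from hairpin_evol.synthetic_data import evolve_jc69, random_sequence

from .conftest import make_alignment


class TestPairEstimators:
    def test_identical_sequences_zero_under_every_model(self):
        s = "ACGTACGTAC"
        assert p_distance(s, s) == 0.0
        assert jc69_distance(s, s) == 0.0
        assert six_parameter_distance(s, s) == 0.0

    def test_one_mismatch_closed_forms(self):
        a, b = "ACGTACGT", "ACGTACGA"
        assert p_distance(a, b) == pytest.approx(0.125)
        assert jc69_distance(a, b) == pytest.approx(-0.75 * math.log(1 - 1 / 6))
        assert jc69_distance(a, b) == pytest.approx(0.1367, abs=2e-4)

    def test_jc69_saturation_flagged_not_raised(self):
        a = "AAAA" * 5
        b = "CCCC" * 5  # p = 1 >= 3/4
        assert math.isnan(jc69_distance(a, b))

    def test_pairwise_deletion_of_gap_and_n_columns(self):
        a = "AC-TNCGT"
        b = "ACGTAC-T"
        # comparable columns: 1,2,4,6,8 -> no mismatches
        assert p_distance(a, b) == 0.0

    def test_zero_comparable_sites_is_an_error(self):
        with pytest.raises(DistanceError):
            p_distance("----", "AAAA")

    def test_jc69_exceeds_p_distance_for_intermediate_divergence(self):
        rng = np.random.default_rng(5)
        anc = random_sequence(rng, 2000)
        der = evolve_jc69(rng, anc, 0.3)
        p = p_distance(anc, der)
        assert 0 < p < 0.75
        assert jc69_distance(anc, der) > p

    def test_six_parameter_matches_jc69_under_symmetric_evolution(self):
        # equal base frequencies, no transition bias: the six-parameter
        # correction must converge on the one-parameter one
        rng = np.random.default_rng(17)
        for _ in range(5):
            anc = random_sequence(rng, 10_000)
            der = evolve_jc69(rng, anc, 0.1)
            six = six_parameter_distance(anc, der)
            jc = jc69_distance(anc, der)
            assert six == pytest.approx(jc, rel=0.02, abs=0.002)


class TestDistanceMatrix:
    def test_matrix_properties(self, simulated_default):
        aln = simulated_default.alignment
        dm = pairwise_distances(aln, model="jc69")
        assert np.allclose(np.diag(dm.values), 0.0)
        assert np.allclose(dm.values, dm.values.T, equal_nan=True)
        finite = dm.values[~np.isnan(dm.values)]
        assert (finite >= 0).all()

    def test_row_order_invariance(self, simulated_default):
        aln = simulated_default.alignment
        rev = MultipleAlignment(tuple(reversed(aln.records)))
        d1 = pairwise_distances(aln, model="p").pair_values()
        d2 = pairwise_distances(rev, model="p").pair_values()
        assert d1 == d2

    def test_region_restriction(self, simulated_default, study_partition):
        aln = simulated_default.alignment
        arm = pairwise_distances(aln, region=study_partition.arm5, model="p")
        loop = pairwise_distances(aln, region=study_partition.loop, model="p")
        assert summarize_pairwise(arm)["mean"] < summarize_pairwise(loop)["mean"]

    def test_summary_of_constant_matrix(self):
        dm = DistanceMatrix(
            ids=("a", "b"), values=np.array([[0.0, 0.1], [0.1, 0.0]]), model="p"
        )
        s = summarize_pairwise(dm)
        assert s["min"] == s["max"] == s["mean"] == pytest.approx(0.1)

    def test_summary_of_zero_matrix(self):
        dm = DistanceMatrix(ids=("a", "b", "c"), values=np.zeros((3, 3)), model="p")
        s = summarize_pairwise(dm)
        assert s["min"] == s["max"] == s["mean"] == 0.0

    def test_single_sequence_summary_rejected(self):
        dm = DistanceMatrix(ids=("a",), values=np.zeros((1, 1)), model="p")
        with pytest.raises(DistanceError):
            summarize_pairwise(dm)


def _dm(ids, tri):
    n = len(ids)
    values = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tri[k]
            k += 1
    return DistanceMatrix(ids=tuple(ids), values=values, model="p")


class TestMatchedPairsTest:
    def test_identical_matrices_accept_equality(self):
        dm = _dm("abcd", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        cmp = matched_pairs_test(dm, dm)
        assert cmp.t_statistic == 0.0 and cmp.p_value == 1.0

    def test_hand_computed_five_pair_example(self):
        # differences -1, -2, 0, -1, -1: mean -1, sd sqrt(0.5),
        # t = -1 / (sqrt(0.5)/sqrt(5)) = -3.1623 on 4 df
        ref = _dm("abcd", [0.0] * 6)
        test = _dm("abcd", [-1.0, -2.0, 0.0, -1.0, -1.0, float("nan")])
        cmp = matched_pairs_test(test, ref)  # NaN pair is dropped
        assert cmp.df == 4
        assert cmp.t_statistic == pytest.approx(-3.1623, abs=1e-4)
        diffs = np.array([-1.0, -2.0, 0.0, -1.0, -1.0])
        assert cmp.t_statistic == pytest.approx(
            stats.ttest_rel(diffs, np.zeros(5)).statistic
        )

    def test_consistent_negative_differences_give_tiny_one_sided_p(self):
        rng = np.random.default_rng(3)
        base = [0.5] * 6
        ref = _dm("abcd", base)
        test = _dm("abcd", [0.4 + rng.normal(0, 1e-4) for _ in base])
        cmp = matched_pairs_test(test, ref)
        assert cmp.mean_difference < 0
        assert cmp.p_value_lower < 0.001

    def test_degenerate_variance_flagged(self):
        ref = _dm("abcd", [0.5] * 6)
        test = _dm("abcd", [0.4] * 6)
        cmp = matched_pairs_test(test, ref)
        assert cmp.degenerate_variance
        assert cmp.p_value == 0.0 and cmp.p_value_lower == 0.0

    def test_pairs_matched_by_id_not_order(self):
        a = _dm("abc", [0.1, 0.2, 0.3])
        b = _dm("cba", [0.3, 0.2, 0.1])  # same values under id matching
        cmp = matched_pairs_test(a, b)
        assert cmp.t_statistic == 0.0 and cmp.p_value == 1.0

    def test_sign_convention(self, simulated_default, study_partition):
        """The constrained hairpin arms are less divergent than the loop."""
        aln = simulated_default.alignment
        arm = pairwise_distances(aln, region=study_partition.arm5, model="jc69")
        loop = pairwise_distances(aln, region=study_partition.loop, model="jc69")
        cmp = matched_pairs_test(arm, loop)
        assert cmp.mean_difference < 0
        assert cmp.p_value_lower < 0.001
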