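import itertools

import pytest

from hairpin_evol.alignment_io import AlignmentError, RegionSpec
from hairpin_evol.hairpin_fold import ColumnMap, HairpinPartition, parse_dot_bracket
from hairpin_evol.struct_classify import (
    LOOP,
    PairClass,
    PairContext,
    SubstitutionClass,
    SubstitutionRecord,
    annotate_contexts,
    apply_context_table,
    classification_frame,
    classify_substitution,
    extract_substitutions,
    pair_class,
    read_context_table,
    summarize_coevolution,
)
from hairpin_evol.synthetic_data import SimulationConfig, default_partition, simulate

from .conftest import make_alignment


class TestPairClass:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ("G", "C", PairClass.WATSON_CRICK),
            ("A", "U", PairClass.WATSON_CRICK),
            ("U", "A", PairClass.WATSON_CRICK),
            ("G", "U", PairClass.WOBBLE),
            ("U", "G", PairClass.WOBBLE),
            ("C", "A", PairClass.MISMATCH),
            ("A", "A", PairClass.MISMATCH),
        ],
    )
    def test_pair_taxonomy(self, x, y, expected):
        assert pair_class(x, y) == expected

    def test_dna_alphabet_accepted(self):
        assert pair_class("A", "T") == PairClass.WATSON_CRICK

    def test_non_nucleotide_rejected(self):
        with pytest.raises(AlignmentError):
            pair_class("A", "-")

    def test_symmetric_in_arguments(self):
        for x, y in itertools.product("ACGU", repeat=2):
            assert pair_class(x, y) == pair_class(y, x)


def _rec(anc, der, context, position=1):
    return SubstitutionRecord(
        position=position, ancestral=anc, derived=der, context=context
    )


class TestClassifySubstitution:
    def test_wc_to_wobble_is_pairing_preserving(self):
        # A-U -> G-U, the canonical synonymous base-pair substitution
        rec = _rec("A", "G", PairContext("U"))
        assert classify_substitution(rec) == SubstitutionClass.SYNONYMOUS_PAIR

    def test_mismatch_to_wc_is_new_pairing(self):
        # C.A -> U-A gains a pair and stabilises the stem
        rec = _rec("C", "U", PairContext("A"))
        assert classify_substitution(rec) == SubstitutionClass.NEW_PAIRING

    def test_internal_loop_substitution_changes_nothing(self):
        rec = _rec("A", "G", LOOP)
        assert classify_substitution(rec) == SubstitutionClass.NO_CHANGE

    def test_mismatch_to_mismatch_changes_nothing(self):
        rec = _rec("C", "A", PairContext("C"))
        assert classify_substitution(rec) == SubstitutionClass.NO_CHANGE

    def test_wc_to_mismatch_destabilises(self):
        rec = _rec("G", "A", PairContext("C"))
        assert classify_substitution(rec) == SubstitutionClass.DESTABILIZING

    def test_compensatory_double_substitution_is_synonymous(self):
        # A-U -> G-C: partner tracked the change, pairing preserved
        rec = _rec("A", "G", PairContext("U", derived_partner_base="C"))
        assert classify_substitution(rec) == SubstitutionClass.SYNONYMOUS_PAIR

    def test_unannotated_record_rejected(self):
        with pytest.raises(AlignmentError):
            classify_substitution(_rec("A", "G", None))

    def test_strand_orientation_symmetry(self):
        # classifying the substitution from either side of the pair gives
        # the same class, because the pair taxonomy is symmetric
        for anc, der, z in itertools.product("ACGU", repeat=3):
            if anc == der:
                continue
            fwd = classify_substitution(_rec(anc, der, PairContext(z)))
            # seen from the partner strand, the pair before is (z, anc) and
            # after is (z, der): same pair classes, same category
            before = pair_class(z, anc)
            after = pair_class(z, der)
            paired = (PairClass.WATSON_CRICK, PairClass.WOBBLE)
            if before == PairClass.MISMATCH and after in paired:
                expected = SubstitutionClass.NEW_PAIRING
            elif before in paired and after in paired:
                expected = SubstitutionClass.SYNONYMOUS_PAIR
            elif before == after == PairClass.MISMATCH:
                expected = SubstitutionClass.NO_CHANGE
            else:
                expected = SubstitutionClass.DESTABILIZING
            assert fwd == expected


class TestExtractSubstitutions:
    def test_single_derived_allele_with_one_carrier(self):
        aln = make_alignment(
            {"t1": "ACGT", "t2": "ACGT", "t3": "ACGT", "t4": "AGGT"}
        )
        records = extract_substitutions(aln, [RegionSpec("all", 1, 4)])
        assert len(records) == 1
        rec = records[0]
        assert (rec.position, rec.ancestral, rec.derived) == (2, "C", "G")
        assert rec.carrier_taxa == ("t4",)

    def test_monomorphic_alignment_yields_nothing(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        assert extract_substitutions(aln, [RegionSpec("all", 1, 4)]) == []

    def test_multiallelic_site_one_record_per_derived_allele(self):
        aln = make_alignment(
            {"t1": "A", "t2": "A", "t3": "C", "t4": "G"}
        )
        records = extract_substitutions(aln, [RegionSpec("all", 1, 1)])
        assert [(r.ancestral, r.derived) for r in records] == [("A", "C"), ("A", "G")]

    def test_majority_tie_broken_by_reference_record(self):
        aln = make_alignment({"t1": "G", "t2": "G", "t3": "A", "t4": "A"})
        recs = extract_substitutions(aln, [RegionSpec("all", 1, 1)], reference_id="t3")
        assert recs[0].ancestral == "A"
        recs = extract_substitutions(aln, [RegionSpec("all", 1, 1)], reference_id="t1")
        assert recs[0].ancestral == "G"

    def test_region_out_of_bounds(self, toy_alignment):
        with pytest.raises(AlignmentError):
            extract_substitutions(toy_alignment, [RegionSpec("bad", 1, 99)])


class TestAnnotateAndSummarize:
    def test_annotation_from_structure_and_context_table(self, tmp_path):
        #       123456789
        # str:  (((...)))
        aln = make_alignment(
            {
                "t1": "GGGAAACCC",
                "t2": "GGGAAACCC",
                "t3": "GGUAAACCC",  # position 3 G->U vs partner C at 7
                "t4": "GGGATACCC",  # loop substitution at 5
            }
        )
        structure = parse_dot_bracket("(((...)))")
        cmap = ColumnMap.from_reference(aln.records[0].seq)
        records = extract_substitutions(aln, [RegionSpec("all", 1, 9)])
        annotated = annotate_contexts(records, structure, cmap, aln)
        by_pos = {r.position: r for r in annotated}
        assert isinstance(by_pos[3].context, PairContext)
        assert by_pos[3].context.partner_base == "C"
        assert by_pos[5].context == LOOP
        # the same classification via an explicit context table
        table_path = tmp_path / "ctx.tsv"
        table_path.write_text("position\tpartner\n3\tC\n5\tloop\n")
        table = read_context_table(table_path)
        from_table = apply_context_table(records, table)
        assert [classify_substitution(r) for r in from_table] == [
            classify_substitution(r) for r in annotated
        ]

    def test_counts_conserved_and_fraction(self):
        records = [
            _rec("A", "G", PairContext("U"), position=1),  # synonymous
            _rec("C", "U", PairContext("A"), position=2),  # new pairing
            _rec("A", "G", LOOP, position=80),  # no change
            _rec("G", "A", PairContext("C"), position=3),  # destabilizing
        ]
        summary = summarize_coevolution(records)
        assert summary.total == len(records)
        assert sum(summary.counts.values()) == summary.total
        assert summary.structure_preserved_fraction == pytest.approx(0.75)

    def test_empty_summary_is_all_zeros(self):
        summary = summarize_coevolution([])
        assert summary.total == 0
        assert all(v == 0 for v in summary.counts.values())
        assert summary.structure_preserved_fraction == 1.0

    def test_arm_split_uses_partition(self, study_partition):
        records = [
            _rec("A", "G", PairContext("U"), position=10),  # 5' arm
            _rec("U", "C", PairContext("G"), position=150),  # 3' arm
        ]
        summary = summarize_coevolution(records, study_partition)
        assert summary.counts_arm5[SubstitutionClass.SYNONYMOUS_PAIR] == 1
        assert summary.counts_arm3[SubstitutionClass.SYNONYMOUS_PAIR] == 1

    def test_classification_frame_columns(self):
        frame = classification_frame([_rec("A", "G", PairContext("U", 140))])
        assert list(frame["class"]) == ["synonymous_pair"]
        assert list(frame["partner"]) == ["U"]


class TestOnSimulatedData:
    def test_no_destabilizing_when_mismatches_are_lethal(self):
        ds = simulate(SimulationConfig(seed=5, w_mismatch=0.0))
        accepted_mismatches = [
            e
            for e in ds.event_log
            if e["accepted"] and e["pair_class"] == "mismatch"
        ]
        assert accepted_mismatches == []
        partition = default_partition()
        records = extract_substitutions(
            ds.alignment, [partition.arm5, partition.arm3]
        )
        cmap = ColumnMap.identity(ds.alignment.length)
        annotated = annotate_contexts(
            records, ds.true_structure, cmap, ds.alignment
        )
        summary = summarize_coevolution(annotated, partition)
        assert summary.counts[SubstitutionClass.DESTABILIZING] == 0

    def test_preserved_fraction_non_increasing_in_mismatch_tolerance(self):
        """More tolerance for mismatches -> structure preserved less often."""
        fractions = []
        for w in (0.0, 0.3, 1.0):
            vals = []
            for rep in range(8):
                ds = simulate(
                    SimulationConfig(seed=100 + rep, w_mismatch=w, w_wobble=0.5,
                                     compensatory_rate=0.0)
                )
                partition = default_partition()
                records = extract_substitutions(
                    ds.alignment, [partition.arm5, partition.arm3]
                )
                cmap = ColumnMap.identity(ds.alignment.length)
                annotated = annotate_contexts(
                    records, ds.true_structure, cmap, ds.alignment
                )
                vals.append(
                    summarize_coevolution(annotated, partition).structure_preserved_fraction
                )
            fractions.append(sum(vals) / len(vals))
        assert fractions[0] >= fractions[1] >= fractions[2]
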