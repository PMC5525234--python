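import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fntkit import _align
from fntkit.mapping import (AlignParams, AlignmentError, align_to_reference,
                            cluster_redundancy, extract_region, qc_filter,
                            refine_maps)
from fntkit.reference_frame import STANDARD_RESIDUES

from .oracle import oracle_score


def _frame_index(frame, position):
    return position - frame.offset


class TestAlignToReference:
    def test_self_alignment_identity(self, frame, mapped_ref):
        for pos in frame.positions:
            assert mapped_ref.map[pos] == _frame_index(frame, pos)
        assert set(mapped_ref.coverage.values()) == {1.0}

    def test_loop_insertion_leaves_segments_untouched(self, frame):
        # 5 extra residues in the loop between TM5b (…224) and TM6 (247…)
        ref = frame.reference_sequence
        cut = _frame_index(frame, 235)
        query = ref[:cut] + "GSGSG" + ref[cut:]
        mapped = align_to_reference(("ins", query), frame)
        for pos in frame.segments.all_positions():
            expected = _frame_index(frame, pos)
            if pos >= 247:
                expected += 5
            assert mapped.map[pos] == expected

    def test_deleted_segment_has_zero_coverage(self, frame):
        ref = frame.reference_sequence
        start, end = _frame_index(frame, 107), _frame_index(frame, 134)
        query = ref[:start] + ref[end + 1:]
        mapped = align_to_reference(("del", query), frame)
        assert mapped.coverage["TM3"] == 0.0
        for name in mapped.coverage:
            if name != "TM3":
                assert mapped.coverage[name] == 1.0

    def test_empty_sequence_rejected(self, frame):
        with pytest.raises(AlignmentError):
            align_to_reference(("empty", ""), frame)

    def test_monotone_map(self, frame, small_cohort_mapped):
        mapped, _, _ = small_cohort_mapped
        for m in mapped:
            images = [m.map[p] for p in sorted(m.map) if m.map[p] is not None]
            assert all(a < b for a, b in zip(images, images[1:]))

    def test_map_covers_every_frame_position_once(self, frame,
                                                  small_cohort_mapped):
        mapped, _, _ = small_cohort_mapped
        for m in mapped[:10]:
            assert set(m.map) == set(frame.positions)

    def test_idempotent_remapping(self, frame, small_cohort_mapped):
        """Extracting the mapped core and re-aligning reproduces residues."""
        mapped, _, _ = small_cohort_mapped
        for m in mapped[:5]:
            core = extract_region(m, list(frame.positions)).replace("-", "")
            again = align_to_reference(("again", core), frame)
            for pos in frame.segments.all_positions():
                assert again.residue_at(pos) == m.residue_at(pos)


class TestExtractRegion:
    def test_reference_site_strings(self, mapped_ref):
        assert extract_region(mapped_ref, [75, 202, 209, 212]) == "FFHA"
        assert extract_region(mapped_ref, [79, 89, 91, 175]) == "LLTV"
        assert extract_region(mapped_ref, [79, 89, 90, 172, 175]) == "LLFNV"

    def test_gapped_positions_yield_gap_symbols(self, frame):
        ref = frame.reference_sequence
        start, end = _frame_index(frame, 161), _frame_index(frame, 184)
        query = ref[:start] + ref[end + 1:]  # TM4 deleted
        mapped = align_to_reference(("del4", query), frame)
        assert extract_region(mapped, [172, 175]) == "--"

    def test_out_of_frame_position_rejected(self, mapped_ref):
        with pytest.raises(IndexError):
            extract_region(mapped_ref, [500])


class TestQcFilter:
    def test_short_sequence_discarded(self, frame):
        short = ("short", "A" * 149)
        report, _ = qc_filter([short, ("ref", frame.reference_sequence)],
                              frame)
        assert ("short", "too_short") in report.discarded
        assert report.kept == ["ref"]

    def test_missing_segment_discarded(self, frame):
        ref = frame.reference_sequence
        start, end = _frame_index(frame, 107), _frame_index(frame, 134)
        no_tm3 = ("no_tm3", ref[:start] + ref[end + 1:])
        report, _ = qc_filter([no_tm3], frame)
        assert report.discarded == [("no_tm3", "missing_segment")]

    def test_kept_and_discarded_partition_inputs(self, frame, small_cohort):
        _, records, _ = small_cohort
        subset = records[:20] + [("tiny", "MKV")]
        report, _ = qc_filter(subset, frame)
        all_ids = {i for i, _ in subset}
        assert set(report.kept) | {i for i, _ in report.discarded} == all_ids
        assert not set(report.kept) & {i for i, _ in report.discarded}

    def test_order_invariance(self, frame, small_cohort):
        _, records, _ = small_cohort
        subset = records[:12]
        r1, _ = qc_filter(subset, frame)
        r2, _ = qc_filter(subset[::-1], frame)
        assert set(r1.kept) == set(r2.kept)
        assert set(r1.discarded) == set(r2.discarded)


class TestClusterRedundancy:
    def test_identical_same_species_collapsed(self, frame):
        seq = frame.reference_sequence
        report = cluster_redundancy([("a", seq), ("b", seq)],
                                    {"a": "E. coli", "b": "E. coli"})
        assert report.kept == ["a"]
        assert report.discarded == [("b", "redundant")]

    def test_identical_different_species_retained(self, frame):
        seq = frame.reference_sequence
        report = cluster_redundancy([("a", seq), ("b", seq)],
                                    {"a": "E. coli", "b": "S. typhimurium"})
        assert sorted(report.kept) == ["a", "b"]
        assert report.discarded == []

    def test_dissimilar_sequences_both_kept(self, frame, small_cohort):
        _, records, truth = small_cohort
        focA = truth[truth.subfamily == "FocA"].id.iloc[0]
        yfdc = truth[truth.subfamily == "YfdC-β"].id.iloc[0]
        pool = {i: s for i, s in records}
        report = cluster_redundancy([(focA, pool[focA]), (yfdc, pool[yfdc])])
        assert sorted(report.kept) == sorted([focA, yfdc])

    def test_order_invariance(self, frame):
        seq = frame.reference_sequence
        records = [("b", seq), ("a", seq), ("c", seq[:-30])]
        species = {"a": "sp1", "b": "sp1", "c": "sp1"}
        r1 = cluster_redundancy(records, species)
        r2 = cluster_redundancy(records[::-1], species)
        assert set(r1.kept) == set(r2.kept)
        assert set(r1.discarded) == set(r2.discarded)


class TestOracleEquivalence:
    def test_production_score_matches_bruteforce(self):
        """Production DP equals an independent affine-gap oracle on random
        pairs (uniform gap costs, free terminal gaps)."""
        sub = _align.substitution_matrix("BLOSUM62")
        enc = {aa: k for k, aa in enumerate(STANDARD_RESIDUES)}
        gap_open, gap_extend = 11.0, 1.0
        rng = np.random.default_rng(20260923)
        for trial in range(50):
            n = int(rng.integers(10, 81))
            m = int(rng.integers(10, 81))
            a = "".join(rng.choice(list(STANDARD_RESIDUES), n))
            b = "".join(rng.choice(list(STANDARD_RESIDUES), m))
            del_open = np.full(n, gap_open)
            ins_open = np.full(n + 1, gap_open)
            score, _, _ = _align.align(_align.encode(a), _align.encode(b),
                                       sub, del_open, ins_open, gap_extend)
            expected = oracle_score(a, b,
                                    lambda x, y: sub[enc[x], enc[y]],
                                    gap_open, gap_extend)
            assert score == pytest.approx(expected), f"trial {trial}: {a} {b}"


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_map_monotone_for_random_mutants(seed):
    """Maps stay monotone for arbitrary mutated/indel variants."""
    from fntkit.reference_frame import load_reference

    frame = load_reference()
    rng = np.random.default_rng(seed)
    seq = list(frame.reference_sequence)
    for _ in range(int(rng.integers(0, 40))):
        i = int(rng.integers(len(seq)))
        seq[i] = STANDARD_RESIDUES[rng.integers(20)]
    # a random loop indel
    cut = int(rng.integers(len(seq)))
    if rng.random() < 0.5:
        seq = seq[:cut] + list("GSN") + seq[cut:]
    else:
        seq = seq[:cut] + seq[cut + 3:]
    mapped = align_to_reference(("mut", "".join(seq)), frame)
    images = [mapped.map[p] for p in sorted(mapped.map)
              if mapped.map[p] is not None]
    assert all(a < b for a, b in zip(images, images[1:]))


class TestRefinement:
    def test_refinement_preserves_monotone_full_maps(self, frame,
                                                     small_cohort_mapped):
        mapped, labels, _ = small_cohort_mapped
        refined = refine_maps(mapped, labels, frame)
        assert len(refined) == len(mapped)
        for m in refined[:10]:
            assert set(m.map) == set(frame.positions)
            images = [m.map[p] for p in sorted(m.map) if m.map[p] is not None]
            assert all(a < b for a, b in zip(images, images[1:]))

    def test_small_groups_keep_original_maps(self, frame,
                                             small_cohort_mapped):
        mapped, labels, _ = small_cohort_mapped
        refined = refine_maps(mapped, labels, frame, min_group_size=50)
        for before, after in zip(mapped, refined):
            assert before is after
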