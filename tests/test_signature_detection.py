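import pytest

from karyosig.genome_model import (
    GeneAnnotation,
    GenomeBuild,
    Segment,
    SegmentedProfile,
    ValidationError,
)
from karyosig.signature_detection import (
    LOH_CHROMOTHRIPSIS,
    LOH_COPY_NEUTRAL,
    LOH_DELETION,
    annotate_amplified_genes,
    call_arm_events,
    classify_loh_mechanism,
    cooccurrence_summary,
    count_altered_bp,
    detect_bfb,
    detect_chromothripsis,
)

from conftest import make_segments


def mirror(seg: SegmentedProfile, build: GenomeBuild) -> SegmentedProfile:
    """Flip every chromosome's coordinates end-for-end."""
    out = []
    for chrom in seg.chromosomes:
        length = build.lengths[chrom]
        for s in reversed(seg.chromosome(chrom)):
            out.append(Segment(chrom, length - s.end, length - s.start,
                               s.mean_log2, s.n_probes, s.state, s.level))
    return SegmentedProfile(seg.sample_id, tuple(out), seg.thresholds)


class TestArmEvents:
    def test_full_chromosome_loss(self, build5, thresholds):
        seg = make_segments({"chr1": [-1]}, thresholds, seg_bp=50_000_000)
        calls = call_arm_events(seg, build5)
        assert len(calls) == 1
        assert (calls[0].chrom, calls[0].state, calls[0].fraction) == \
            ("chr1", "LOSS", 1.0)

    @pytest.mark.parametrize("covered_mb,expect_call", [(37, False), (38, True)])
    def test_threshold_is_strict_at_75_percent(self, build5, thresholds,
                                               covered_mb, expect_call):
        # 50 Mb chromosome: 37 Mb = 74%, 38 Mb = 76%
        segs = (Segment("chr1", 0, covered_mb * 10**6, 0.58, 100, "GAIN", 1),
                Segment("chr1", covered_mb * 10**6, 50_000_000, 0.0, 100,
                        "NEUTRAL", 0))
        seg = SegmentedProfile("t", segs, thresholds)
        calls = call_arm_events(seg, build5)
        assert bool(calls) is expect_call

    def test_mixed_states_do_not_aggregate(self, build5, thresholds):
        # 40% LOSS + 40% GAIN: neither class passes 75% alone
        segs = (Segment("chr1", 0, 20_000_000, -1.0, 100, "LOSS", -1),
                Segment("chr1", 20_000_000, 40_000_000, 0.58, 100, "GAIN", 1),
                Segment("chr1", 40_000_000, 50_000_000, 0.0, 100,
                        "NEUTRAL", 0))
        assert call_arm_events(SegmentedProfile("t", segs, thresholds),
                               build5) == []

    def test_amp_counts_toward_gain_class(self, build5, thresholds):
        segs = (Segment("chr1", 0, 30_000_000, 0.58, 100, "GAIN", 1),
                Segment("chr1", 30_000_000, 50_000_000, 2.0, 100, "AMP", 3))
        calls = call_arm_events(SegmentedProfile("t", segs, thresholds),
                                build5)
        assert [c.state for c in calls] == ["GAIN"]
        assert calls[0].fraction == 1.0

    def test_two_armed_chromosome_called_per_arm(self, thresholds):
        b = GenomeBuild(("chr1",), {"chr1": 100}, {"chr1": 40})
        segs = (Segment("chr1", 0, 40, -1.0, 10, "LOSS", -1),
                Segment("chr1", 40, 100, 0.0, 10, "NEUTRAL", 0))
        calls = call_arm_events(SegmentedProfile("t", segs, thresholds), b)
        assert [(c.arm, c.state) for c in calls] == [("p", "LOSS")]


class TestAlteredBp:
    def test_all_neutral_counts_zero(self, build5, thresholds):
        seg = make_segments({"chr1": [0]}, thresholds, seg_bp=50_000_000)
        assert count_altered_bp(seg, []) == 0

    def test_focal_losses_sum(self, build5, thresholds):
        segs = (Segment("chr1", 0, 1_000_000, -1.0, 10, "LOSS", -1),
                Segment("chr1", 1_000_000, 48_000_000, 0.0, 10, "NEUTRAL", 0),
                Segment("chr1", 48_000_000, 50_000_000, -1.0, 10, "LOSS", -1))
        seg = SegmentedProfile("t", segs, thresholds)
        assert count_altered_bp(seg, []) == 3_000_000

    def test_called_aneuploidy_excluded(self, build5, thresholds):
        seg = make_segments({"chr1": [1]}, thresholds, seg_bp=50_000_000)
        calls = call_arm_events(seg, build5)
        assert count_altered_bp(seg, calls, build5) == 0

    def test_conservation_of_non_neutral_bp(self, build5, thresholds):
        # whole-chr gain on chr1 + 2 Mb focal loss on chr2
        segs = (Segment("chr1", 0, 50_000_000, 0.58, 100, "GAIN", 1),
                Segment("chr2", 0, 2_000_000, -1.0, 10, "LOSS", -1),
                Segment("chr2", 2_000_000, 50_000_000, 0.0, 100,
                        "NEUTRAL", 0))
        seg = SegmentedProfile("t", segs, thresholds)
        calls = call_arm_events(seg, build5)
        focal = count_altered_bp(seg, calls, build5)
        total_non_neutral = sum(s.end - s.start for s in segs if s.level != 0)
        excluded = total_non_neutral - focal
        assert focal == 2_000_000
        assert excluded == 50_000_000


class TestChromothripsis:
    def test_alternating_two_state_chromosome_called(self, thresholds):
        levels = [0, -1] * 6  # 12 segments, 11 switches, 2 states
        seg = make_segments({"chr1": levels}, thresholds)
        calls = detect_chromothripsis(seg)
        assert len(calls) == 1
        assert calls[0].n_switches == 11
        assert calls[0].distinct_states == 2

    def test_flat_chromosome_not_called(self, thresholds):
        seg = make_segments({"chr1": [0]}, thresholds)
        assert detect_chromothripsis(seg) == []

    def test_four_distinct_states_rejected(self, thresholds):
        # 13 segments cycling through 4 states -> 12 switches but 4 states
        levels = [0, -1, 1, 2] * 3 + [0]
        seg = make_segments({"chr1": levels}, thresholds)
        assert detect_chromothripsis(seg) == []

    def test_switch_count_equals_merged_segments_minus_one(self, thresholds):
        for n_seg in (11, 12, 20):
            levels = [(0, -1)[i % 2] for i in range(n_seg)]
            seg = make_segments({"chr1": levels}, thresholds)
            calls = detect_chromothripsis(seg, min_switches=1)
            assert calls[0].n_switches == n_seg - 1

    def test_nine_switches_below_cutoff(self, thresholds):
        levels = [(0, -1)[i % 2] for i in range(10)]  # 9 switches
        seg = make_segments({"chr1": levels}, thresholds)
        assert detect_chromothripsis(seg) == []


class TestBFB:
    def test_terminal_stair_with_drop_called(self, thresholds):
        # inward from chr end: AMP2, AMP1, GAIN, then NEUTRAL
        seg = make_segments({"chr1": [0, 1, 2, 3]}, thresholds)
        calls = detect_bfb(seg)
        assert len(calls) == 1
        assert (calls[0].anchor, calls[0].n_stairs) == ("end", 3)
        assert calls[0].peak_level == 3

    def test_two_level_rise_not_called(self, thresholds):
        seg = make_segments({"chr1": [0, 1, 2]}, thresholds)
        assert detect_bfb(seg) == []

    def test_interior_stair_not_called(self, thresholds):
        # stair not anchored at a terminus
        seg = make_segments({"chr1": [0, 1, 2, 3, 0]}, thresholds)
        assert detect_bfb(seg) == []

    def test_whole_chromosome_monotone_not_called(self, thresholds):
        # no interior drop segment exists
        seg = make_segments({"chr1": [1, 2, 3]}, thresholds)
        assert detect_bfb(seg) == []

    def test_mirror_symmetry_flips_anchor(self, build5, thresholds):
        seg = make_segments({"chr1": [0, 1, 2, 3]}, thresholds,
                            seg_bp=12_500_000)
        fwd = detect_bfb(seg)
        rev = detect_bfb(mirror(seg, build5))
        assert [c.anchor for c in fwd] == ["end"]
        assert [c.anchor for c in rev] == ["start"]
        assert [c.n_stairs for c in fwd] == [c.n_stairs for c in rev]

    def test_five_stairs_counted(self, thresholds):
        seg = make_segments({"chr1": [0, 1, 2, 3, 4, 5]}, thresholds)
        calls = detect_bfb(seg)
        assert calls[0].n_stairs == 5
        assert calls[0].peak_level == 5


class TestGeneAnnotation:
    def _bfb_call(self, thresholds):
        seg = make_segments({"chr1": [0, 1, 2, 3]}, thresholds)
        (call,) = detect_bfb(seg)
        return call

    def test_gene_inside_peak_segment(self, thresholds):
        call = self._bfb_call(thresholds)  # AMP segments at 2-4 Mb
        genes = GeneAnnotation((("Myc", "chr1", 3_100_000, 3_200_000),))
        assert annotate_amplified_genes([call], genes) == [["Myc"]]

    def test_gene_on_other_chromosome_ignored(self, thresholds):
        call = self._bfb_call(thresholds)
        genes = GeneAnnotation((("Myc", "chr2", 3_100_000, 3_200_000),))
        assert annotate_amplified_genes([call], genes) == [[]]

    def test_one_bp_overlap_counts(self, thresholds):
        call = self._bfb_call(thresholds)
        # AMP tier-2 segment spans [2 Mb, 3 Mb); gene ends 1 bp into it
        genes = GeneAnnotation((("Alk", "chr1", 1_500_000, 2_000_001),))
        assert annotate_amplified_genes([call], genes) == [["Alk"]]

    def test_gain_only_stair_segment_not_amplified(self, thresholds):
        call = self._bfb_call(thresholds)
        # GAIN (level 1) stair segment spans [1 Mb, 2 Mb): below AMP
        genes = GeneAnnotation((("Vegfa", "chr1", 1_200_000, 1_300_000),))
        assert annotate_amplified_genes([call], genes) == [[]]


class TestLohMechanism:
    LOCUS = ("chr1", 10_000_000, 10_100_000)

    def test_loss_segment_means_deletion(self, thresholds):
        seg = make_segments({"chr1": [0, -1, 0]}, thresholds,
                            seg_bp=7_000_000)
        # locus at 10 Mb falls in the LOSS segment [7, 14) Mb
        assert classify_loh_mechanism(seg, [], self.LOCUS) == LOH_DELETION

    def test_chromothripsis_takes_precedence(self, thresholds):
        levels = [0, -1] * 6
        seg = make_segments({"chr1": levels}, thresholds, seg_bp=4_000_000)
        ct = detect_chromothripsis(seg)
        assert ct
        assert classify_loh_mechanism(seg, ct, self.LOCUS) == \
            LOH_CHROMOTHRIPSIS

    def test_neutral_chromosome_is_copy_neutral(self, thresholds):
        seg = make_segments({"chr1": [0]}, thresholds, seg_bp=50_000_000)
        assert classify_loh_mechanism(seg, [], self.LOCUS) == LOH_COPY_NEUTRAL

    def test_absent_chromosome_is_an_error(self, thresholds):
        seg = make_segments({"chr2": [0]}, thresholds, seg_bp=50_000_000)
        with pytest.raises(ValidationError):
            classify_loh_mechanism(seg, [], self.LOCUS)


class _Rec:
    def __init__(self, ct, bfb):
        self.ct_chroms = tuple(ct)
        self.bfb_chroms = tuple(bfb)
        self.chromothripsis = bool(ct)
        self.bfb = bool(bfb)


class TestCooccurrence:
    def test_empty_cohort(self):
        assert cooccurrence_summary([]) == (0, 0, 0)

    def test_single_record_set_logic(self):
        assert cooccurrence_summary([_Rec(["1", "2"], ["2"])]) == (1, 1, 1)

    def test_disjoint_chromosomes_not_shared(self):
        recs = [_Rec(["1"], ["7"]), _Rec([], ["9"]), _Rec(["3"], [])]
        assert cooccurrence_summary(recs) == (2, 1, 0)
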