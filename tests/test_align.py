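"""The fitting aligner, the overlap scorer, breakpoint arithmetic and the
gap-removal adjustment."""

import random

import pytest

from conftest import oracle_fit_score
from svfocal import simulate
from svfocal.align import (
    adjust_breakpoints,
    global_align_score,
    implied_deletion,
    overlap_align_frac,
    place_clipped_segment,
    semi_global_align,
)
from svfocal.model import (
    AnchoredSplitRead,
    DeletionCall,
    GenomicInterval,
    Parameters,
    Pattern,
    SplitAlignment,
)
from svfocal.reference import RefGenome

# A frozen instance whose optimal fitting alignment has 27 matched columns,
# one mismatch and a single-base internal gap with both flanks unaligned,
# i.e. score 27 - 1 - 3 = 23 under the default scoring.
FIG_SEGMENT = "GCTAATGACAATTAATAACATACACGTC"
FIG_REGION = "GTTCTAAGCCGCTAAAGACAATTACATAACATACACGTCGAATCACTTGGA"

_RC = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(_RC)[::-1]


class TestSemiGlobalAlign:
    def test_27_matches_1_mismatch_1_gap_scores_23(self):
        aln = semi_global_align(FIG_SEGMENT, FIG_REGION)
        assert aln.score == 23
        assert (aln.n_match, aln.n_mismatch, aln.gap_cols) == (27, 1, 1)
        assert aln.check_decomposition()

    def test_perfect_substring(self):
        region = "TTGGACCA" + "ACGTACGTCC" + "GGATT"
        aln = semi_global_align("ACGTACGTCC", region)
        assert aln.score == 10
        assert aln.gap_cols == 0
        assert (aln.placed_interval.start, aln.placed_interval.end) == (8, 18)

    def test_leftmost_tie_break(self):
        # the segment occurs twice; the earlier placement must win
        region = "AAATTTCGCGTTTAAACGCGAA"
        aln = semi_global_align("CGCG", region)
        assert aln.placed_interval.start == 6

    def test_n_scores_as_mismatch(self):
        assert semi_global_align("NNNN", "NNNN").score == -4
        assert semi_global_align("ACGT", "ANGT").score == 2

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            semi_global_align("", "ACGT")

    def test_matches_exhaustive_oracle(self):
        rng = random.Random(202)
        for _ in range(150):
            m = rng.randint(1, 8)
            n = rng.randint(1, 24)
            seg = "".join(rng.choice("ACGT") for _ in range(m))
            reg = "".join(rng.choice("ACGT") for _ in range(n))
            aln = semi_global_align(seg, reg)
            assert aln.score == oracle_fit_score(seg, reg), (seg, reg)
            assert aln.check_decomposition()

    def test_reverse_complement_symmetry(self):
        rng = random.Random(7)
        for _ in range(50):
            seg = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 12)))
            reg = "".join(rng.choice("ACGT") for _ in range(rng.randint(12, 40)))
            assert (semi_global_align(seg, reg).score
                    == semi_global_align(rc(seg), rc(reg)).score)


class TestOverlapFrac:
    def test_identical_heads(self):
        assert overlap_align_frac("ACGTACGTACGTACGTACGTACGTACGTAC",
                                  "ACGTACGTACGTACGTACGTACGTACGTAC") == 1.0

    def test_random_heads_fall_below_threshold(self):
        rng = random.Random(99)
        fracs = []
        for _ in range(2000):
            h1 = "".join(rng.choice("ACGT") for _ in range(30))
            h2 = "".join(rng.choice("ACGT") for _ in range(30))
            fracs.append(overlap_align_frac(h1, h2))
        mean = sum(fracs) / len(fracs)
        assert -0.6 < mean < -0.35  # expectation ~ 0.25 - 0.75 = -0.5
        assert sum(f < 0.1 for f in fracs) / len(fracs) >= 0.99

    def test_17_of_30_matches(self):
        h1 = "A" * 30
        h2 = "A" * 17 + "C" * 13
        assert overlap_align_frac(h1, h2) == pytest.approx((17 - 13) / 30)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            overlap_align_frac("", "ACGT")

    def test_global_alignment_consumes_everything(self):
        # one unavoidable end gap: 3 matches minus one gap column
        assert global_align_score("ACG", "ACGT") == 3 - 3


def _type1_split(chrom, mapped_start, clip_seq, anchor_start):
    return AnchoredSplitRead(
        "r1", Pattern.TYPE_I,
        GenomicInterval(chrom, mapped_start, mapped_start + 60),
        clip_seq, GenomicInterval(chrom, anchor_start, anchor_start + 100),
        "+", "-", len(clip_seq) + 60, 100, "left",
        anchor_is_downstream=True)


class TestPlacement:
    def _setup(self):
        rng = random.Random(31)
        ref = "".join(rng.choice("ACGT") for _ in range(4000))
        reference = RefGenome({"c": ref})
        return ref, reference

    def test_error_free_clip_placed_at_true_position(self, params):
        ref, reference = self._setup()
        # deletion [1000, 1500): a split read mapped at 1500 carries a clip
        # that truly belongs at [960, 1000)
        clip = ref[960:1000]
        split = _type1_split("c", 1500, clip, 1800)
        focal = GenomicInterval("c", 900, 1010)  # admissible starts
        aln = place_clipped_segment(split, focal, reference, params)
        assert aln is not None
        assert (aln.placed_interval.start, aln.placed_interval.end) == (960, 1000)
        single = implied_deletion(split, aln, params)
        assert single.deleted_interval == GenomicInterval("c", 1000, 1500)

    def test_low_identity_rejected(self, params):
        ref, reference = self._setup()
        rng = random.Random(5)
        junk = "".join(rng.choice("ACGT") for _ in range(50))
        split = _type1_split("c", 1500, junk, 1800)
        assert place_clipped_segment(
            split, GenomicInterval("c", 900, 1010), reference, params) is None

    def test_sub_minimum_deletion_rejected(self, params):
        ref, reference = self._setup()
        clip = ref[1440:1480]  # placement would imply a 20-bp deletion
        split = _type1_split("c", 1500, clip, 1800)
        assert place_clipped_segment(
            split, GenomicInterval("c", 1400, 1490), reference, params) is None


class TestImpliedDeletion:
    def test_anchor_distal_clip_arithmetic(self, params):
        # mapped segment starts at a=4100 (1-based), clip placed ending d=3999
        split = _type1_split("c", 4099, "A" * 40, 4800)
        placement = SplitAlignment(GenomicInterval("c", 3959, 3999), 40, 40, 0, 0)
        single = implied_deletion(split, placement, params)
        assert single.length == 100
        assert single.total_weight == params.weight_type1

    def test_anchor_proximal_clip_arithmetic(self, params):
        # type II: mapped ends at b=1000 (1-based), clip placed from c=1101
        split = AnchoredSplitRead(
            "r2", Pattern.TYPE_II, GenomicInterval("c", 940, 1000), "A" * 40,
            GenomicInterval("c", 1600, 1700), "+", "-", 100, 100, "right",
            anchor_is_downstream=True)
        placement = SplitAlignment(GenomicInterval("c", 1100, 1140), 40, 40, 0, 0)
        single = implied_deletion(split, placement, params)
        assert single.length == 100
        assert single.total_weight == params.weight_type2

    def test_non_positive_length_rejected(self, params):
        split = _type1_split("c", 4099, "A" * 40, 4800)
        placement = SplitAlignment(GenomicInterval("c", 4090, 4130), 40, 40, 0, 0)
        assert implied_deletion(split, placement, params) is None


class TestAdjustment:
    def test_spurious_gap_repaired_to_true_length(self, params):
        reference, split, placement, truth = simulate.make_gap_adjustment_case(1)
        single = implied_deletion(split, placement, params)
        assert single.length == 101  # the mapper artifact
        adjusted, consensus = adjust_breakpoints([single], reference, params)
        assert consensus.length == 100
        assert consensus.deleted_interval == truth
        assert consensus.adjusted

    def test_adjustment_is_idempotent_and_never_lowers_scores(self, params):
        reference, split, placement, truth = simulate.make_gap_adjustment_case(3)
        single = implied_deletion(split, placement, params)
        adjusted, consensus = adjust_breakpoints([single], reference, params)
        again, consensus2 = adjust_breakpoints(adjusted, reference, params)
        assert consensus2.deleted_interval == consensus.deleted_interval
        # the adopted placement is gap-free and at least as good as before
        new_split, new_placement, _ = consensus.support[0]
        assert new_placement.gap_cols == 0
        assert all(op == "M" for op, _ in new_split.mapped_cigar)

    def test_gap_free_group_is_fixed_point(self, params):
        ref = "A" * 100 + "C" * 100
        reference = RefGenome({"c": ref})
        split = _type1_split("c", 150, "A" * 40, 190)
        placement = SplitAlignment(GenomicInterval("c", 20, 60), 40, 40, 0, 0)
        single = implied_deletion(split, placement, params)
        adjusted, consensus = adjust_breakpoints([single], reference, params)
        assert consensus.deleted_interval == single.deleted_interval
        assert not consensus.adjusted

    def test_voting_prefers_higher_total_score(self, params):
        reference = RefGenome({"c": "A" * 2000})
        def make(read_id, placed_start, score):
            split = _type1_split("c", 1500, "A" * 40, 1800)
            split.read_id = read_id
            split.mapped_cigar = ()
            placement = SplitAlignment(
                GenomicInterval("c", placed_start, placed_start + 40),
                score, score, 0, 0)
            return implied_deletion(split, placement, params)
        # two reads imply a 100-bp deletion (scores 24+24); one implies 101
        a1 = make("a1", 1360, 24)
        a2 = make("a2", 1360, 24)
        b1 = make("b1", 1359, 40)
        assert a1.length == 100 and b1.length == 101
        _, consensus = adjust_breakpoints([a1, a2, b1], reference, params)
        assert consensus.length == 100
        assert consensus.total_weight == 2 * params.weight_type1
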