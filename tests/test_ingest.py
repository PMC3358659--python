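"""Library-stats estimation and evidence extraction from alignment records."""

import random

import numpy as np
import pytest

from conftest import make_pair, make_record, store_of
from svfocal.ingest import (
    ReadStore,
    estimate_library_stats,
    extract_insertion_candidates,
    extract_split_candidates,
    find_spanning_pairs,
)
from svfocal.model import InputError, LibraryStats, Parameters, Pattern

SEQ = "ACGT" * 25  # 100 bp placeholder sequence


def _plain_pairs(n, outer, chrom="c", start0=1000, spacing=700):
    pairs = []
    for i in range(n):
        s = start0 + i * spacing
        pairs.append(make_pair(f"q{i}", chrom, s, [("M", 100)], SEQ,
                               s + outer - 100, [("M", 100)], SEQ))
    return pairs


class TestLibraryStats:
    def test_constant_outer_distance(self):
        store = store_of(*_plain_pairs(1000, 500))
        st = estimate_library_stats(store)
        assert st.insert_mean == pytest.approx(500)
        assert st.insert_sd == pytest.approx(0)
        assert st.read_length == 100

    def test_recovers_normal_insert_model(self):
        rng = np.random.default_rng(42)
        outers = np.rint(rng.normal(230, 30, size=10_000)).astype(int)
        pairs = []
        for i, o in enumerate(outers):
            o = max(int(o), 110)
            s = 1000 + (i % 500) * 400
            pairs.append(make_pair(f"q{i}", "c", s, [("M", 100)], SEQ,
                                   s + o - 100, [("M", 100)], SEQ))
        st = estimate_library_stats(store_of(*pairs))
        assert abs(st.insert_mean - float(outers.mean())) < 1.5
        assert abs(st.insert_sd - float(outers.std(ddof=1))) < 1.5

    def test_too_few_pairs_is_an_error(self):
        with pytest.raises(InputError, match="insert_mean"):
            estimate_library_stats(store_of(*_plain_pairs(50, 500)))

    def test_invariant_to_record_order(self):
        pairs = _plain_pairs(300, 480)
        flat = [r for p in pairs for r in p]
        st1 = estimate_library_stats(ReadStore(flat))
        rng = random.Random(3)
        rng.shuffle(flat)
        st2 = estimate_library_stats(ReadStore(flat))
        assert (st1.insert_mean, st1.insert_sd) == (st2.insert_mean, st2.insert_sd)

    def test_clipped_pairs_are_excluded(self):
        good = _plain_pairs(200, 500)
        clipped = [make_pair(f"c{i}", "c", 500_000 + i * 700,
                             [("S", 30), ("M", 70)], SEQ,
                             500_000 + i * 700 + 900, [("M", 100)], SEQ)
                   for i in range(50)]
        st = estimate_library_stats(store_of(*good, *clipped))
        assert st.insert_mean == pytest.approx(500)


class TestSplitCandidates:
    def test_forward_clip_left_is_type1(self, params, stats):
        pair = make_pair("s", "c", 5000, [("S", 50), ("M", 50)], SEQ,
                         5400, [("M", 100)], SEQ)
        out = extract_split_candidates(store_of(pair), params, stats)
        assert len(out) == 1
        cand = out[0]
        assert cand.pattern is Pattern.TYPE_I
        assert cand.clip_length == 50
        assert cand.mapped_interval.width() == 50
        assert cand.clipped_seq == SEQ[:50]
        assert cand.anchor_is_downstream

    def test_forward_clip_right_is_type2(self, params, stats):
        pair = make_pair("s", "c", 5000, [("M", 50), ("S", 50)], SEQ,
                         5400, [("M", 100)], SEQ)
        out = extract_split_candidates(store_of(pair), params, stats)
        assert [c.pattern for c in out] == [Pattern.TYPE_II]
        assert out[0].clipped_seq == SEQ[-50:]

    def test_reverse_geometry_swaps_the_rule(self, params, stats):
        # clipped read on the reverse strand with its anchor upstream
        fwd, rev = make_pair("s", "c", 5000, [("M", 100)], SEQ,
                             5400, [("S", 40), ("M", 60)], SEQ)
        out = extract_split_candidates(store_of((fwd, rev)), params, stats)
        assert [c.pattern for c in out] == [Pattern.TYPE_II]
        fwd, rev = make_pair("s", "c", 5000, [("M", 100)], SEQ,
                             5400, [("M", 60), ("S", 40)], SEQ)
        out = extract_split_candidates(store_of((fwd, rev)), params, stats)
        assert [c.pattern for c in out] == [Pattern.TYPE_I]
        assert not out[0].anchor_is_downstream

    def test_short_clip_and_double_clip_excluded(self, params, stats):
        short = make_pair("a", "c", 5000, [("S", 10), ("M", 90)], SEQ,
                          5400, [("M", 100)], SEQ)
        double = make_pair("b", "c", 7000, [("S", 30), ("M", 40), ("S", 30)], SEQ,
                           7400, [("M", 100)], SEQ)
        assert extract_split_candidates(store_of(short, double), params, stats) == []

    def test_low_quality_or_unmapped_anchor_excluded(self, params, stats):
        lowq = make_pair("a", "c", 5000, [("S", 50), ("M", 50)], SEQ,
                         5400, [("M", 100)], SEQ, mapq=5)
        lone = make_record("b", "c", 6000, [("S", 50), ("M", 50)], SEQ)
        assert extract_split_candidates(store_of(lowq, lone), params, stats) == []

    def test_candidates_map_back_to_unique_records(self, params, stats):
        pairs = [make_pair(f"s{i}", "c", 5000 + 300 * i,
                           [("S", 50), ("M", 50)], SEQ,
                           5400 + 300 * i, [("M", 100)], SEQ)
                 for i in range(10)]
        out = extract_split_candidates(store_of(*pairs), params, stats)
        assert len({c.read_id for c in out}) == len(out) == 10


class TestSpanningPairs:
    def _split(self, params, stats, a0=9999):
        # type-I split read mapped at 1-based a = a0+1 with downstream anchor
        pair = make_pair("split", "c", a0, [("S", 50), ("M", 50)], SEQ,
                         a0 + 400, [("M", 100)], SEQ)
        store = store_of(pair)
        cands = extract_split_candidates(store, params, stats)
        return cands[0], store

    def test_window_boundaries(self, params):
        stats = LibraryStats(200, 50, 100)
        split, base = self._split(params, stats)
        a0 = split.mapped_interval.start  # 1-based a = a0 + 1 = 10,000
        inside = make_pair("in", "c", a0 - 300, [("M", 100)], SEQ,
                           a0 + 100, [("M", 100)], SEQ)
        at_edge = make_pair("edge", "c", a0 - 300, [("M", 100)], SEQ,
                            a0 + 150, [("M", 100)], SEQ)
        before = make_pair("before", "c", a0 - 400, [("M", 100)], SEQ,
                           a0 - 1, [("M", 100)], SEQ)
        beyond = make_pair("beyond", "c", a0 - 300, [("M", 100)], SEQ,
                           a0 + 151, [("M", 100)], SEQ)
        store = store_of(*base.records, inside, at_edge, before, beyond)
        found = find_spanning_pairs(split, store, stats, params)
        starts = sorted(p.right_interval.start for p in found)
        assert starts == [a0 + 100, a0 + 150]

    def test_forward_end_must_be_upstream_of_mapped_segment(self, params):
        stats = LibraryStats(200, 50, 100)
        split, base = self._split(params, stats)
        a0 = split.mapped_interval.start
        overlapping = make_pair("ov", "c", a0 - 50, [("M", 100)], SEQ,
                                a0 + 100, [("M", 100)], SEQ)
        store = store_of(*base.records, overlapping)
        assert find_spanning_pairs(split, store, stats, params) == []


class TestInsertionCandidates:
    def test_head_clip_retained_tail_kept(self, params):
        # reverse read: head is the high-coordinate end
        fwd, rev = make_pair("a", "c", 5000, [("M", 100)], SEQ,
                             5400, [("M", 60), ("S", 40)], SEQ)
        out = extract_insertion_candidates(store_of((fwd, rev)), params)
        assert [r.strand for r in out] == ["-"]
        assert out[0].alignment_interval.width() == 60

    def test_fully_aligned_excluded(self, params):
        pair = make_pair("a", "c", 5000, [("M", 100)], SEQ,
                         5400, [("M", 100)], SEQ)
        assert extract_insertion_candidates(store_of(pair), params) == []

    def test_gappy_head_retained(self, params):
        cigar = [("M", 10), ("I", 2), ("M", 10), ("D", 3), ("M", 78)]
        fwd, rev = make_pair("a", "c", 5000, cigar, SEQ,
                             5400, [("M", 100)], SEQ)
        out = extract_insertion_candidates(store_of((fwd, rev)), params)
        assert [r.read_id for r in out] == ["a"]
        one_gap = [("M", 10), ("I", 2), ("M", 88)]
        fwd, rev = make_pair("b", "c", 5000, one_gap, SEQ,
                             5400, [("M", 100)], SEQ)
        assert extract_insertion_candidates(store_of((fwd, rev)), params) == []

    def test_improper_pairs_excluded(self, params):
        fwd, rev = make_pair("a", "c", 5000, [("M", 100)], SEQ,
                             5400, [("M", 60), ("S", 40)], SEQ, proper=False)
        assert extract_insertion_candidates(store_of((fwd, rev)), params) == []
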