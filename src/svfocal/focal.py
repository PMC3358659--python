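"""Focal-region geometry for split-read realignment.

Given the insert-size model of the library, a soft-clipped split read and
(for a type-I pattern) a spanning pair, these functions bound where the
clipped segment can start on the reference.  The bounds are derived from the
outer-distance model: writing l_i for the expected outer distance, sigma for
its standard deviation, l_1/l_2 for the pair's read lengths, l_s for the
clip length, m_d for the minimum deletion size and k for the sd multiplier
(default 3), in 1-based closed coordinates:

* spanning-pair window (type I, mapped segment starts at a):
      a <= s2 <= a - l1 - l2 + l_i + k*sigma
* type-I focal region for the clip start c, given a pair ending at e1:
      e1 - l_s <= c <= min(e1 + l_i - l_s - l1 - l2 + k*sigma, a - m_d - l_s)
* type-II focal region (mapped segment ends at b, anchor starts at s):
      max(b + m_d, s - l_i - l_s + l1 + l2 - k*sigma) <= c <= s

The mirrored geometry (split read on the reverse strand, anchor upstream)
uses the reflection of each formula; the mirrored bounds below are obtained
by substituting x -> R - x + 1 and are covered by a reflection-equivalence
property test.

All public functions evaluate the bounds in 1-based closed coordinates and
convert the result to the package's 0-based half-open convention.
"""

from __future__ import annotations

import math

from .model import (
    AnchoredSplitRead,
    GenomicInterval,
    LibraryStats,
    Parameters,
    Pattern,
    SpanningPair,
    from_closed_coords,
)


def _hi(x: float) -> int:
    return math.floor(x)


def _lo(x: float) -> int:
    return math.ceil(x)


def spanning_search_window(a: int, l1: int, l2: int, stats: LibraryStats,
                           params: Parameters):
    """Admissible start s2 (1-based closed) of a spanning pair's reverse read.

    ``a`` is the 1-based start of the split read's mapped segment (the
    right-breakpoint candidate).  Returns ``(lo, hi)`` or ``None`` if empty.
    """
    lo = a
    hi = _hi(a - l1 - l2 + stats.insert_mean
             + params.sd_multiplier * stats.insert_sd)
    if hi < lo:
        return None
    return lo, hi


def spanning_search_window_mirror(b_end: int, l1: int, l2: int,
                                  stats: LibraryStats, params: Parameters):
    """Mirror of :func:`spanning_search_window`: admissible *end* e1 of the
    forward read of a spanning pair, for a reverse-strand split read whose
    mapped segment ends at ``b_end`` (1-based)."""
    hi = b_end
    lo = _lo(b_end + l1 + l2 - stats.insert_mean
             - params.sd_multiplier * stats.insert_sd)
    if hi < lo:
        return None
    return lo, hi


def type1_focal_region(pair: SpanningPair, a: int, l_s: int,
                       stats: LibraryStats, params: Parameters) -> GenomicInterval:
    """Admissible clip-start positions c for a forward type-I split read.

    ``a`` is the 1-based start of the split read's mapped segment; the clip
    is placed upstream of it.  Returns an interval of admissible c values in
    the internal 0-based half-open convention (possibly empty).
    """
    _, e1 = pair.left_interval.start + 1, pair.left_interval.end
    l1, l2 = pair.left_length, pair.right_length
    lo = e1 - l_s
    hi = min(
        _hi(e1 + stats.insert_mean - l_s - l1 - l2
            + params.sd_multiplier * stats.insert_sd),
        a - params.min_deletion_size - l_s,
    )
    lo = max(lo, 1)
    return from_closed_coords(pair.left_interval.chrom, lo, hi)


def type1_focal_region_mirror(pair: SpanningPair, b_end: int, l_s: int,
                              stats: LibraryStats, params: Parameters) -> GenomicInterval:
    """Mirror of :func:`type1_focal_region` for a reverse-strand split read.

    The mapped segment ends at ``b_end`` (1-based) and the clip is placed
    downstream; the spanning pair's reverse read starts at s2.  Admissible c:
        max(b_end + m_d + 1, s2 + 1 + l1 + l2 - l_i - k*sigma) <= c <= s2 + 1
    """
    s2 = pair.right_interval.start + 1
    l1, l2 = pair.left_length, pair.right_length
    lo = max(
        b_end + params.min_deletion_size + 1,
        _lo(s2 + 1 + l1 + l2 - stats.insert_mean
            - params.sd_multiplier * stats.insert_sd),
    )
    hi = s2 + 1
    lo = max(lo, 1)
    return from_closed_coords(pair.right_interval.chrom, lo, hi)


def type2_focal_region(split: AnchoredSplitRead, stats: LibraryStats,
                       params: Parameters) -> GenomicInterval:
    """Admissible clip-start positions c for a type-II split read.

    The read pair is its own spanning pair, so the anchor position bounds the
    focal region directly.  Handles both orientations: anchor downstream
    (forward geometry) and anchor upstream (mirrored geometry).
    """
    if split.pattern is not Pattern.TYPE_II:
        raise ValueError("type2_focal_region requires a TYPE_II split read")
    l_s = split.clip_length
    l1 = split.read_length
    l2 = split.mate_length
    chrom = split.mapped_interval.chrom
    slack = stats.insert_mean + l_s - l1 - l2 + params.sd_multiplier * stats.insert_sd
    if split.anchor_is_downstream:
        b = split.mapped_interval.end  # 1-based end of the mapped segment
        s = split.anchor_interval.start + 1
        lo = max(b + params.min_deletion_size, _lo(s - slack))
        hi = s
    else:
        # mirrored: mapped [A, B] lies right of the deletion, anchor [.., E]
        # upstream; the clip is placed at [c, d] with d < A.  Bounds on d:
        #   E <= d <= min(A - m_d, E + l_i + l_s - l1 - l2 + k*sigma)
        # converted to c = d - l_s + 1.
        A = split.mapped_interval.start + 1
        E = split.anchor_interval.end
        lo = E - l_s + 1
        hi = min(A - params.min_deletion_size, _hi(E + slack)) - l_s + 1
    lo = max(lo, 1)
    return from_closed_coords(chrom, lo, hi)


def union_focal_regions(regions: list[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal set of disjoint intervals covering the union, sorted by start."""
    live = [r for r in regions if not r.is_empty()]
    if not live:
        return []
    chroms = {r.chrom for r in live}
    if len(chroms) > 1:
        raise ValueError(f"regions span multiple chromosomes: {sorted(chroms)}")
    live.sort(key=lambda r: (r.start, r.end))
    merged: list[GenomicInterval] = [live[0]]
    for r in live[1:]:
        last = merged[-1]
        if r.start <= last.end:
            if r.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, r.end)
        else:
            merged.append(r)
    return merged
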