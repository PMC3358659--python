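"""Orchestration of split-read evidence into deletion and insertion calls."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import align, focal, ingest
from .model import (
    AnchoredSplitRead,
    DeletionCall,
    GenomicInterval,
    InputError,
    InsertionCall,
    LibraryStats,
    Parameters,
    Pattern,
)

log = logging.getLogger(__name__)


def call_deletions(store: ingest.ReadStore, reference, params: Parameters,
                   stats: LibraryStats | None = None) -> list[DeletionCall]:
    """Full deletion pipeline.

    Split candidates are extracted; type-I candidates require at least one
    spanning pair whose focal regions (unioned over all pairs) localize the
    clipped segment, type-II candidates use their own anchor.  Accepted
    placements become single-read calls, which are clustered, gap-adjusted,
    voted to a consensus breakpoint, and emitted when the summed pattern
    weight reaches the cutoff.
    """
    if stats is None:
        stats = ingest.estimate_library_stats(store)
    splits = ingest.extract_split_candidates(store, params, stats)
    singles: list[DeletionCall] = []
    for split in splits:
        chrom = split.mapped_interval.chrom
        if chrom not in reference:
            raise InputError(f"chromosome {chrom!r} present in alignments but "
                             "absent from the reference FASTA")
        regions = _focal_regions_for(split, store, stats, params)
        if not regions:
            continue
        placement = None
        for region in regions:
            aln = align.place_clipped_segment(split, region, reference, params)
            if aln is None:
                continue
            if placement is None or (aln.score, -aln.placed_interval.start) > (
                    placement.score, -placement.placed_interval.start):
                placement = aln
        if placement is None:
            continue
        single = align.implied_deletion(split, placement, params)
        if single is not None and single.length >= params.min_deletion_size:
            singles.append(single)
    calls: list[DeletionCall] = []
    for cluster in cluster_evidence(singles, params):
        _, consensus = align.adjust_breakpoints(cluster, reference, params)
        if consensus is None:
            continue
        if (consensus.total_weight >= params.deletion_weight_cutoff
                and consensus.length >= params.min_deletion_size):
            calls.append(consensus)
    calls.sort(key=lambda c: (c.chrom, c.deleted_interval.start,
                              c.deleted_interval.end))
    return calls


def _focal_regions_for(split: AnchoredSplitRead, store, stats, params):
    if split.pattern is Pattern.TYPE_I:
        pairs = ingest.find_spanning_pairs(split, store, stats, params)
        if not pairs:
            return []
        if split.anchor_is_downstream:
            a = split.mapped_interval.start + 1
            regions = [focal.type1_focal_region(p, a, split.clip_length,
                                                stats, params) for p in pairs]
        else:
            b_end = split.mapped_interval.end
            regions = [focal.type1_focal_region_mirror(p, b_end, split.clip_length,
                                                       stats, params) for p in pairs]
        merged = focal.union_focal_regions(regions)
        return _cap_focal_width(merged, split, params)
    region = focal.type2_focal_region(split, stats, params)
    return [] if region.is_empty() else [region]


def _cap_focal_width(regions: list[GenomicInterval], split: AnchoredSplitRead,
                     params: Parameters) -> list[GenomicInterval]:
    """Guard against pathological anchor scatter: keep at most
    ``max_focal_width`` of unioned admissible positions, preferring the
    regions closest to the split read's mapped segment."""
    total = sum(r.width() for r in regions)
    if total <= params.max_focal_width:
        return regions
    anchor_pos = split.mapped_interval.start
    ordered = sorted(regions, key=lambda r: min(abs(r.start - anchor_pos),
                                                abs(r.end - anchor_pos)))
    kept, budget = [], params.max_focal_width
    for r in ordered:
        if r.width() <= budget:
            kept.append(r)
            budget -= r.width()
        elif budget > 0:
            if r.start < anchor_pos:
                kept.append(GenomicInterval(r.chrom, r.end - budget, r.end))
            else:
                kept.append(GenomicInterval(r.chrom, r.start, r.start + budget))
            budget = 0
    log.warning("focal union for read %s truncated from %d to %d bp",
                split.read_id, total, params.max_focal_width)
    kept.sort(key=lambda r: r.start)
    return kept


def cluster_evidence(singles: list[DeletionCall],
                     params: Parameters) -> list[list[DeletionCall]]:
    """Single-linkage grouping of single-read calls.

    Two calls are linked when both breakpoints agree within
    ``adjacency_tolerance``; clusters are the transitive closure.
    """
    if not singles:
        return []
    order = sorted(range(len(singles)),
                   key=lambda i: (singles[i].chrom,
                                  singles[i].deleted_interval.start,
                                  singles[i].deleted_interval.end))
    parent = list(range(len(singles)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tol = params.adjacency_tolerance
    for oi, i in enumerate(order):
        a = singles[i].deleted_interval
        for j in order[oi + 1:]:
            b = singles[j].deleted_interval
            if b.start - a.start > tol:
                break
            if a.chrom == b.chrom and abs(a.end - b.end) <= tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[DeletionCall]] = {}
    for i in order:
        groups.setdefault(find(i), []).append(singles[i])
    out = list(groups.values())
    out.sort(key=lambda g: (g[0].chrom, g[0].deleted_interval.start))
    return out


# --- insertions --------------------------------------------------------------

@dataclass
class _InsEvidence:
    rev: ingest.ReadRecord
    fwd: ingest.ReadRecord
    breakpoint: int
    frac: float


def call_insertions(store: ingest.ReadStore, reference,
                    params: Parameters) -> list[InsertionCall]:
    """Insertion calling from pairs of head-clipped reads (type-III pattern).

    A reverse-strand read whose 5' head is clipped marks a candidate
    breakpoint at the end of its tail mapping; forward-strand head-clipped
    reads whose tail starts within ``adjacency_tolerance`` are examined as
    partners.  When the overlapped head portions of such an
    opposite-strand pair align with score/overlap below
    ``insertion_overlap_frac``, the pair is evidence; a breakpoint with at
    least ``insertion_support_cutoff`` supporting reads from both strands is
    emitted.
    """
    cands = ingest.extract_insertion_candidates(store, params)
    rev_cands, fwd_cands = [], []
    for rec in cands:
        left, right = rec.clip_lengths()
        if rec.strand == "-" and right >= params.min_clip_length:
            rev_cands.append(rec)
        elif rec.strand == "+" and left >= params.min_clip_length:
            fwd_cands.append(rec)
    fwd_by_start = sorted(fwd_cands, key=lambda r: r.alignment_interval.start)
    evidences: list[_InsEvidence] = []
    tol = params.adjacency_tolerance
    for rev in rev_cands:
        bp = rev.alignment_interval.end
        for fwd in fwd_by_start:
            delta = fwd.alignment_interval.start - bp
            if delta < -tol:
                continue
            if delta > tol:
                break
            if fwd.chrom != rev.chrom:
                continue
            frac = _pair_overlap_frac(rev, fwd, params)
            if frac is not None and frac < params.insertion_overlap_frac:
                evidences.append(_InsEvidence(
                    rev, fwd, (bp + fwd.alignment_interval.start) // 2, frac))
    return _emit_insertions(evidences, params)


def _pair_overlap_frac(rev: ingest.ReadRecord, fwd: ingest.ReadRecord,
                       params: Parameters) -> float | None:
    """Score/overlap of the head portions of a candidate type-III pair.

    Each read's clipped head is compared against the other read's bases over
    the reference positions the two reads would share if the clips actually
    continued along the reference.  Without an insertion the heads match the
    partner read (the fraction is near +1); heads drawn from inserted
    sequence are unrelated to the partner and score far below the threshold.
    """
    _, h_r = rev.clip_lengths()
    h_f, _ = fwd.clip_lengths()
    bp_r = rev.alignment_interval.end
    start_f = fwd.alignment_interval.start
    m_r = rev.alignment_interval.width()
    m_f = fwd.alignment_interval.width()
    score = 0
    total = 0
    # reverse head [bp_r, bp_r+h_r) vs forward mapped span [start_f, start_f+m_f)
    lo = max(bp_r, start_f)
    hi = min(bp_r + h_r, start_f + m_f)
    if hi > lo:
        s1 = rev.sequence[m_r + (lo - bp_r): m_r + (hi - bp_r)]
        s2 = fwd.sequence[h_f + (lo - start_f): h_f + (hi - start_f)]
        score += align.global_align_score(s1, s2, params)
        total += hi - lo
    # forward head [start_f-h_f, start_f) vs reverse mapped span
    lo = max(start_f - h_f, rev.alignment_interval.start)
    hi = min(start_f, bp_r)
    if hi > lo:
        off = lo - (start_f - h_f)
        s1 = fwd.sequence[off: off + (hi - lo)]
        rev_start = rev.alignment_interval.start
        s2 = rev.sequence[lo - rev_start: hi - rev_start]
        score += align.global_align_score(s1, s2, params)
        total += hi - lo
    if total < 10:
        return None  # too little overlap to judge
    return score / total


def _emit_insertions(evidences: list[_InsEvidence],
                     params: Parameters) -> list[InsertionCall]:
    if not evidences:
        return []
    evidences.sort(key=lambda e: e.breakpoint)
    tol = params.adjacency_tolerance
    clusters: list[list[_InsEvidence]] = [[evidences[0]]]
    for ev in evidences[1:]:
        if ev.breakpoint - clusters[-1][-1].breakpoint <= tol:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    calls = []
    for group in clusters:
        rev_reads = {e.rev.read_id: e.rev for e in group}
        fwd_reads = {e.fwd.read_id: e.fwd for e in group}
        support = set(rev_reads) | set(fwd_reads)
        if len(support) < params.insertion_support_cutoff:
            continue
        if not rev_reads or not fwd_reads:
            continue
        bp_rev = _mode(e.rev.alignment_interval.end for e in group)
        bp_fwd = _mode(e.fwd.alignment_interval.start for e in group)
        prefix = max((r.sequence[-r.clip_lengths()[1]:] for r in rev_reads.values()),
                     key=len)
        suffix = max((r.sequence[:r.clip_lengths()[0]] for r in fwd_reads.values()),
                     key=len)
        chrom = group[0].rev.chrom
        calls.append(InsertionCall(
            chrom=chrom,
            breakpoint=(bp_rev + bp_fwd) // 2,
            n_support=len(support),
            inserted_prefix=prefix,
            inserted_suffix=suffix,
            support_ids=tuple(sorted(support)),
        ))
    calls.sort(key=lambda c: (c.chrom, c.breakpoint))
    return calls


def _mode(values) -> int:
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
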