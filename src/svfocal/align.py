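"""Semi-global placement of clipped segments, breakpoint arithmetic and the
gap-removal adjustment step.

The aligner is the "fitting" flavour of pairwise alignment: the clipped
segment is consumed in full while region bases before the first and after
the last aligned column are free.  Inside the aligned core a match scores
+1, a mismatch -1 and every gap column -3 (all three configurable).  Focal
regions are a few hundred bases, so a plain quadratic DP is fast enough.
"""

from __future__ import annotations

from dataclasses import replace

from .model import (
    AlnOp,
    AnchoredSplitRead,
    DeletionCall,
    GenomicInterval,
    Parameters,
    Pattern,
    SplitAlignment,
)

_BASES = "ACGT"


def _sub_score(a: str, b: str, params: Parameters) -> int:
    # N counts as a mismatch: masked sequence must not inflate placements
    if a == b and a in _BASES:
        return params.match_score
    return params.mismatch_score


def semi_global_align(segment: str, region: str,
                      params: Parameters | None = None) -> SplitAlignment:
    """Best placement of ``segment`` inside ``region``.

    Every segment base is consumed; region flanks outside the aligned core
    are free.  Ties are broken deterministically: smallest start of the
    aligned core first, then fewest gap columns.  The returned
    ``placed_interval`` uses region-local coordinates on chromosome ``""``.
    """
    if params is None:
        params = Parameters()
    segment = segment.upper()
    region = region.upper()
    m, n = len(segment), len(region)
    if m == 0:
        raise ValueError("empty clipped segment")
    g = params.gap_penalty

    # Per-cell state: score H (max), start column S (min), gap columns G (min),
    # compared lexicographically as (H, -S, -G).
    H = [[0] * (n + 1) for _ in range(m + 1)]
    S = [[0] * (n + 1) for _ in range(m + 1)]
    G = [[0] * (n + 1) for _ in range(m + 1)]
    H[0] = [0] * (n + 1)
    S[0] = list(range(n + 1))
    for i in range(1, m + 1):
        H[i][0] = -g * i
        S[i][0] = 0
        G[i][0] = i

    for i in range(1, m + 1):
        base = segment[i - 1]
        Hp, Sp, Gp = H[i - 1], S[i - 1], G[i - 1]
        Hc, Sc, Gc = H[i], S[i], G[i]
        for j in range(1, n + 1):
            # diagonal: segment base vs region base
            bh = Hp[j - 1] + _sub_score(base, region[j - 1], params)
            bs = Sp[j - 1]
            bg = Gp[j - 1]
            # vertical: segment base vs gap (gap in region)
            vh = Hp[j] - g
            if vh > bh or (vh == bh and (Sp[j] < bs or (Sp[j] == bs and Gp[j] + 1 < bg))):
                bh, bs, bg = vh, Sp[j], Gp[j] + 1
            # horizontal: region base vs gap inside the core (gap in segment)
            hh = Hc[j - 1] - g
            if hh > bh or (hh == bh and (Sc[j - 1] < bs or (Sc[j - 1] == bs and Gc[j - 1] + 1 < bg))):
                bh, bs, bg = hh, Sc[j - 1], Gc[j - 1] + 1
            Hc[j], Sc[j], Gc[j] = bh, bs, bg

    # best end column: maximize (H, -S, -G), then earliest j
    j_end, best = 0, (H[m][0], -S[m][0], -G[m][0])
    for j in range(1, n + 1):
        key = (H[m][j], -S[m][j], -G[m][j])
        if key > best:
            best, j_end = key, j

    ops = _traceback(segment, region, params, H, S, G, j_end)
    n_match = sum(l for op, l in ops if op is AlnOp.MATCH)
    n_mismatch = sum(l for op, l in ops if op is AlnOp.MISMATCH)
    gap_cols = sum(l for op, l in ops
                   if op in (AlnOp.GAP_IN_SEGMENT, AlnOp.GAP_IN_REGION))
    return SplitAlignment(
        placed_interval=GenomicInterval("", S[m][j_end], j_end),
        score=H[m][j_end],
        n_match=n_match,
        n_mismatch=n_mismatch,
        gap_cols=gap_cols,
        cigar_like=tuple(ops),
    )


def _traceback(segment, region, params, H, S, G, j_end):
    g = params.gap_penalty
    i, j = len(segment), j_end
    rev = []
    while i > 0:
        h, s, gc = H[i][j], S[i][j], G[i][j]
        if j > 0:
            sub = _sub_score(segment[i - 1], region[j - 1], params)
            if H[i - 1][j - 1] + sub == h and S[i - 1][j - 1] == s and G[i - 1][j - 1] == gc:
                rev.append(AlnOp.MATCH if sub == params.match_score else AlnOp.MISMATCH)
                i, j = i - 1, j - 1
                continue
        if H[i - 1][j] - g == h and S[i - 1][j] == s and G[i - 1][j] + 1 == gc:
            rev.append(AlnOp.GAP_IN_REGION)
            i -= 1
            continue
        if j > 0 and H[i][j - 1] - g == h and S[i][j - 1] == s and G[i][j - 1] + 1 == gc:
            rev.append(AlnOp.GAP_IN_SEGMENT)
            j -= 1
            continue
        raise AssertionError("traceback lost its path")  # pragma: no cover
    rev.reverse()
    # merge runs
    ops: list[tuple[AlnOp, int]] = []
    for op in rev:
        if ops and ops[-1][0] is op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return ops


def global_align_score(seq1: str, seq2: str, params: Parameters | None = None) -> int:
    """Needleman-Wunsch score with the placement scoring (both ends fixed)."""
    if params is None:
        params = Parameters()
    seq1, seq2 = seq1.upper(), seq2.upper()
    g = params.gap_penalty
    m, n = len(seq1), len(seq2)
    prev = [-g * j for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [-g * i] + [0] * n
        base = seq1[i - 1]
        for j in range(1, n + 1):
            cur[j] = max(
                prev[j - 1] + _sub_score(base, seq2[j - 1], params),
                prev[j] - g,
                cur[j - 1] - g,
            )
        prev = cur
    return prev[n]


def overlap_align_frac(head1: str, head2: str,
                       params: Parameters | None = None) -> float:
    """Alignment score of two overlapped head segments divided by the
    overlap length.

    Used by the insertion test: heads drawn from inserted sequence are
    unrelated and score far below the evidence threshold, heads drawn from
    the reference agree and score near +1 per base.
    """
    if len(head1) == 0 or len(head2) == 0:
        raise ValueError("zero-length overlap")
    overlap = max(len(head1), len(head2))
    return global_align_score(head1, head2, params) / overlap


# --- placement inside a focal region ---------------------------------------

#: extra region bases beyond the last admissible start, so that placements
#: using a few gap columns remain reachable
_GAP_PAD = 5


def place_clipped_segment(split: AnchoredSplitRead, focal: GenomicInterval,
                          reference, params: Parameters) -> SplitAlignment | None:
    """Place ``split``'s clipped segment inside ``focal`` (admissible start
    positions, 0-based half-open) and accept or reject the placement.

    Returns the placement in genome coordinates, or ``None`` when the best
    placement scores below the identity threshold or implies a deletion
    shorter than the minimum size.
    """
    if focal.is_empty():
        return None
    l_s = split.clip_length
    chrom = focal.chrom
    chrom_len = reference.length(chrom)
    region_start = max(0, focal.start)
    region_end = min(chrom_len, focal.end - 1 + l_s + _GAP_PAD)
    if region_end <= region_start:
        return None
    region = reference.fetch(chrom, region_start, region_end)
    aln = semi_global_align(split.clipped_seq, region, params)
    if aln.score < params.placement_min_score(l_s):
        return None
    placed = GenomicInterval(
        chrom,
        region_start + aln.placed_interval.start,
        region_start + aln.placed_interval.end,
    )
    aln = replace(aln, placed_interval=placed)
    width = _implied_width(split, aln)
    if width is None or width < params.min_deletion_size:
        return None
    return aln


def _implied_width(split: AnchoredSplitRead, placement: SplitAlignment) -> int | None:
    if split.clip_side == "left":
        width = split.mapped_interval.start - placement.placed_interval.end
    else:
        width = placement.placed_interval.start - split.mapped_interval.end
    return width if width > 0 else None


def implied_deletion(split: AnchoredSplitRead, placement: SplitAlignment,
                     params: Parameters | None = None) -> DeletionCall | None:
    """Single-read deletion implied by a clipped-segment placement.

    The deleted bases are those strictly between the placed segment and the
    mapped segment.  Returns ``None`` for a non-positive implied length
    (an inconsistent placement).
    """
    if params is None:
        params = Parameters()
    width = _implied_width(split, placement)
    if width is None:
        return None
    if split.clip_side == "left":
        deleted = GenomicInterval(split.mapped_interval.chrom,
                                  placement.placed_interval.end,
                                  split.mapped_interval.start)
    else:
        deleted = GenomicInterval(split.mapped_interval.chrom,
                                  split.mapped_interval.end,
                                  placement.placed_interval.start)
    weight = (params.weight_type1 if split.pattern is Pattern.TYPE_I
              else params.weight_type2)
    return DeletionCall(
        chrom=deleted.chrom,
        deleted_interval=deleted,
        total_weight=weight,
        support=[(split, placement, split.pattern)],
    )


# --- breakpoint adjustment ---------------------------------------------------

#: adjustment search limits: bases relocated across the junction
_MAX_SHIFT = 5


def mapped_alignment_score(split: AnchoredSplitRead, reference,
                           params: Parameters) -> int:
    """Score of the mapped-side alignment under the placement scoring."""
    if not split.mapped_cigar or not split.read_seq:
        return 0
    chrom = split.mapped_interval.chrom
    ref = reference.fetch(chrom, split.mapped_interval.start,
                          split.mapped_interval.end)
    read_off = split.clip_length if split.clip_side == "left" else 0
    ref_off = 0
    score = 0
    for op, length in split.mapped_cigar:
        if op == "M":
            for k in range(length):
                score += _sub_score(split.read_seq[read_off + k],
                                    ref[ref_off + k], params)
            read_off += length
            ref_off += length
        elif op == "I":
            score -= params.gap_penalty * length
            read_off += length
        elif op == "D":
            score -= params.gap_penalty * length
            ref_off += length
        else:  # pragma: no cover - soft clips are stripped upstream
            raise ValueError(f"unexpected op {op!r} in mapped cigar")
    return score


def _ungapped_score(read: str, ref: str, params: Parameters) -> tuple[int, int, int]:
    match = mismatch = 0
    for a, b in zip(read, ref):
        if a == b and a in _BASES:
            match += 1
        else:
            mismatch += 1
    return (match * params.match_score + mismatch * params.mismatch_score,
            match, mismatch)


def adjust_breakpoints(cluster: list[DeletionCall], reference,
                       params: Parameters) -> tuple[list[DeletionCall], DeletionCall | None]:
    """Gap-removal rearrangement plus score-weighted voting over a cluster.

    Each member whose split alignment (either side) contains an internal gap
    is re-split gap-free with the two outer alignment ends fixed; the
    rearrangement is adopted when its score is at least the original total
    (clip placement plus mapped-side alignment).  Members are then grouped
    by implied deletion and the group with the highest summed alignment
    score wins the vote; the consensus call keeps only agreeing members.
    """
    adjusted_singles: list[DeletionCall] = []
    votes: dict[GenomicInterval, list] = {}
    for single in cluster:
        split, placement, pattern = single.support[0]
        new_single, total_score = _adjust_member(single, reference, params)
        adjusted_singles.append(new_single)
        iv = new_single.deleted_interval
        bucket = votes.setdefault(iv, [0, []])
        bucket[0] += total_score
        bucket[1].append(new_single)
    if not votes:
        return adjusted_singles, None
    winner = max(votes.items(),
                 key=lambda kv: (kv[1][0], len(kv[1][1]), -kv[0].start))
    interval, (_, members) = winner
    support = [m.support[0] for m in members]
    call = DeletionCall(
        chrom=interval.chrom,
        deleted_interval=interval,
        total_weight=sum(m.total_weight for m in members),
        support=support,
        adjusted=any(m.adjusted for m in members),
    )
    return adjusted_singles, call


def _adjust_member(single: DeletionCall, reference,
                   params: Parameters) -> tuple[DeletionCall, int]:
    """Attempt the gap-free rearrangement on one supporting read.

    Returns the (possibly rewritten) single-read call and the member's total
    alignment score used for voting.
    """
    split, placement, pattern = single.support[0]
    mapped_score = mapped_alignment_score(split, reference, params)
    total = placement.score + mapped_score
    has_gap = placement.gap_cols > 0 or any(
        op in ("I", "D") for op, _ in split.mapped_cigar
    )
    if not has_gap or not split.read_seq or len(split.read_seq) != split.read_length:
        return single, total

    L = split.read_length
    read = split.read_seq
    chrom = split.mapped_interval.chrom
    if split.clip_side == "left":
        outer_left = placement.placed_interval.start      # fixed clip start c
        outer_right = split.mapped_interval.end           # fixed mapped end b
        t0 = split.clip_length
    else:
        outer_left = split.mapped_interval.start          # fixed mapped start a
        outer_right = placement.placed_interval.end       # fixed placed end d
        t0 = L - split.clip_length
    adj_len = (outer_right - outer_left) - L
    if adj_len < 1:
        return single, total

    best = None  # (score, t, match/mismatch of both parts)
    for t in range(max(1, t0 - _MAX_SHIFT), min(L - 1, t0 + _MAX_SHIFT) + 1):
        left_ref = reference.fetch(chrom, outer_left, outer_left + t)
        right_ref = reference.fetch(chrom, outer_right - (L - t), outer_right)
        if len(left_ref) < t or len(right_ref) < L - t:
            continue
        s_l, m_l, x_l = _ungapped_score(read[:t], left_ref, params)
        s_r, m_r, x_r = _ungapped_score(read[t:], right_ref, params)
        cand = (s_l + s_r, -t, (m_l, x_l, s_l, m_r, x_r, s_r))
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None or best[0] < total:
        return single, total

    score, neg_t, (m_l, x_l, s_l, m_r, x_r, s_r) = best
    t = -neg_t
    if split.clip_side == "left":
        new_split = replace(
            split,
            clipped_seq=read[:t],
            mapped_interval=GenomicInterval(chrom, outer_right - (L - t), outer_right),
            mapped_cigar=(("M", L - t),),
        )
        new_placement = SplitAlignment(
            placed_interval=GenomicInterval(chrom, outer_left, outer_left + t),
            score=s_l, n_match=m_l, n_mismatch=x_l, gap_cols=0,
            cigar_like=((AlnOp.MATCH, t),) if x_l == 0 else (),
        )
    else:
        new_split = replace(
            split,
            clipped_seq=read[t:],
            mapped_interval=GenomicInterval(chrom, outer_left, outer_left + t),
            mapped_cigar=(("M", t),),
        )
        new_placement = SplitAlignment(
            placed_interval=GenomicInterval(chrom, outer_right - (L - t), outer_right),
            score=s_r, n_match=m_r, n_mismatch=x_r, gap_cols=0,
            cigar_like=((AlnOp.MATCH, L - t),) if x_r == 0 else (),
        )
    new_single = implied_deletion(new_split, new_placement, params)
    if new_single is None:
        return single, total
    new_single.adjusted = True
    return new_single, score
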