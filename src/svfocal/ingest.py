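"""Reading mapped paired-end data and extracting split-read evidence.

Three kinds of evidence drive the caller: soft-clipped split-read
candidates, spanning pairs with a stretched apparent insert, and
head-clipped reads used by the insertion test.  Secondary, supplementary
and duplicate-flagged alignments are ignored throughout.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pysam

from .model import (
    AnchoredSplitRead,
    GenomicInterval,
    InputError,
    LibraryStats,
    Parameters,
    Pattern,
    SpanningPair,
)

log = logging.getLogger(__name__)

#: minimum mapping quality for anchors and spanning-pair reads
ANCHOR_MIN_MAPQ = 20


@dataclass
class ReadRecord:
    """One primary alignment record (a thin, pysam-independent carrier)."""

    read_id: str
    chrom: Optional[str]
    alignment_interval: Optional[GenomicInterval]
    strand: str  # '+', '-'; meaningless if unmapped
    cigar: tuple  # ((op, length), ...) with op in {M, I, D, S}
    sequence: str
    is_first_in_pair: bool
    mate_chrom: Optional[str]
    mate_position: Optional[int]
    mapq: int
    is_proper_pair: bool
    mate_is_reverse: bool = False

    @property
    def is_mapped(self) -> bool:
        return self.alignment_interval is not None

    @property
    def read_length(self) -> int:
        return len(self.sequence)

    def clip_lengths(self) -> tuple[int, int]:
        """(leading, trailing) soft-clip lengths."""
        left = self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0
        right = self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0
        return left, right


_OP_NAMES = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}


def record_from_pysam(aln: pysam.AlignedSegment) -> ReadRecord:
    cigar = []
    for op, length in aln.cigartuples or ():
        name = _OP_NAMES.get(op)
        if name is None:
            continue  # hard clips / padding / splices carry no evidence here
        if cigar and cigar[-1][0] == name:
            cigar[-1] = (name, cigar[-1][1] + length)
        else:
            cigar.append((name, length))
    interval = None
    if not aln.is_unmapped:
        interval = GenomicInterval(aln.reference_name, aln.reference_start,
                                   aln.reference_end)
    return ReadRecord(
        read_id=aln.query_name,
        chrom=aln.reference_name if not aln.is_unmapped else None,
        alignment_interval=interval,
        strand="-" if aln.is_reverse else "+",
        cigar=tuple(cigar),
        sequence=(aln.query_sequence or "").upper(),
        is_first_in_pair=aln.is_read1,
        mate_chrom=aln.next_reference_name if not aln.mate_is_unmapped else None,
        mate_position=aln.next_reference_start if not aln.mate_is_unmapped else None,
        mapq=aln.mapping_quality,
        is_proper_pair=aln.is_proper_pair,
        mate_is_reverse=aln.mate_is_reverse,
    )


class ReadStore:
    """In-memory collection of primary records with mate resolution and
    positional queries (sufficient for the focal-region scale this caller
    works at; whole-genome runs would stream per chromosome)."""

    def __init__(self, records: Iterable[ReadRecord]):
        self.records: list[ReadRecord] = list(records)
        self._by_qname: dict[str, dict[bool, ReadRecord]] = {}
        for rec in self.records:
            self._by_qname.setdefault(rec.read_id, {})[rec.is_first_in_pair] = rec
        self._fwd: dict[str, tuple[list[int], list[ReadRecord]]] = {}
        self._rev: dict[str, tuple[list[int], list[ReadRecord]]] = {}
        fwd: dict[str, list[ReadRecord]] = {}
        rev: dict[str, list[ReadRecord]] = {}
        for rec in self.records:
            if not rec.is_mapped:
                continue
            (rev if rec.strand == "-" else fwd).setdefault(rec.chrom, []).append(rec)
        for chrom, rs in fwd.items():
            rs.sort(key=lambda r: r.alignment_interval.end)
            self._fwd[chrom] = ([r.alignment_interval.end for r in rs], rs)
        for chrom, rs in rev.items():
            rs.sort(key=lambda r: r.alignment_interval.start)
            self._rev[chrom] = ([r.alignment_interval.start for r in rs], rs)

    def __len__(self) -> int:
        return len(self.records)

    def mate(self, rec: ReadRecord) -> Optional[ReadRecord]:
        return self._by_qname.get(rec.read_id, {}).get(not rec.is_first_in_pair)

    def reverse_starts_in(self, chrom: str, lo: int, hi: int) -> list[ReadRecord]:
        """Reverse-strand records whose 0-based start lies in [lo, hi]."""
        keys, rs = self._rev.get(chrom, ([], []))
        i = bisect.bisect_left(keys, lo)
        j = bisect.bisect_right(keys, hi)
        return rs[i:j]

    def forward_ends_in(self, chrom: str, lo: int, hi: int) -> list[ReadRecord]:
        """Forward-strand records whose 0-based exclusive end lies in [lo, hi]."""
        keys, rs = self._fwd.get(chrom, ([], []))
        i = bisect.bisect_left(keys, lo)
        j = bisect.bisect_right(keys, hi)
        return rs[i:j]


def load_alignments(path: str) -> ReadStore:
    """Load primary, non-duplicate records from a SAM/BAM file."""
    mode = "r" if str(path).endswith(".sam") else "rb"
    try:
        af = pysam.AlignmentFile(path, mode, require_index=False)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot open alignments {path}: {exc}") from exc
    records = []
    skipped = 0
    with af:
        for aln in af.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                skipped += 1
                continue
            records.append(record_from_pysam(aln))
    if skipped:
        log.info("ignored %d secondary/supplementary/duplicate records", skipped)
    return ReadStore(records)


# --- library statistics ------------------------------------------------------

def estimate_library_stats(store: ReadStore, max_sample: int = 100_000) -> LibraryStats:
    """Sample mean/sd of outer distances over proper, fully-mapped FR pairs.

    Outer distances above the 99.5th percentile are discarded before the
    moments are taken, so stray discordant pairs do not inflate the model.
    """
    outers = []
    read_lengths: dict[int, int] = {}
    for qname, ends in store._by_qname.items():
        if len(outers) >= max_sample:
            break
        if len(ends) != 2:
            continue
        r1, r2 = ends.values()
        if not (r1.is_mapped and r2.is_mapped and r1.chrom == r2.chrom):
            continue
        if r1.strand == r2.strand:
            continue
        if any(op == "S" for rec in (r1, r2) for op, _ in rec.cigar):
            continue
        fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
        if fwd.alignment_interval.start > rev.alignment_interval.start:
            continue  # not FR
        outer = rev.alignment_interval.end - fwd.alignment_interval.start
        if outer <= 0:
            continue
        outers.append(outer)
        for rec in (r1, r2):
            read_lengths[rec.read_length] = read_lengths.get(rec.read_length, 0) + 1
    if len(outers) < 100:
        raise InputError(
            f"only {len(outers)} usable pairs for insert-size estimation "
            "(need >= 100); supply insert_mean and insert_sd explicitly"
        )
    arr = np.asarray(outers, dtype=float)
    cutoff = np.percentile(arr, 99.5)
    arr = arr[arr <= cutoff]
    modal_len = max(read_lengths.items(), key=lambda kv: (kv[1], kv[0]))[0]
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return LibraryStats(insert_mean=float(arr.mean()), insert_sd=sd,
                        read_length=modal_len)


# --- split-read candidates ---------------------------------------------------

def extract_split_candidates(store: ReadStore, params: Parameters,
                             stats: LibraryStats | None = None) -> list[AnchoredSplitRead]:
    """Reads with exactly one terminal soft clip, classified as type I/II.

    The strand-resolved rule: with the anchor downstream (forward split
    read), a clip at the low-coordinate end is anchor-distal and gives a
    type-I candidate, a clip at the high-coordinate end gives type II; the
    mirrored geometry (reverse split read, anchor upstream) swaps the rule.
    """
    out = []
    skipped_unmapped_mate = 0
    for rec in store.records:
        if not rec.is_mapped:
            continue
        left, right = rec.clip_lengths()
        if left > 0 and right > 0:
            continue
        clip_len = left or right
        if clip_len < params.min_clip_length:
            continue
        mate = store.mate(rec)
        if mate is None or not mate.is_mapped:
            skipped_unmapped_mate += 1
            continue
        if mate.chrom != rec.chrom or mate.strand == rec.strand:
            continue
        if mate.mapq < ANCHOR_MIN_MAPQ:
            continue
        # proper FR orientation: the forward read is the upstream one
        if rec.strand == "+":
            if mate.strand != "-" or mate.alignment_interval.start < rec.alignment_interval.start:
                continue
            anchor_downstream = True
        else:
            if mate.strand != "+" or mate.alignment_interval.start > rec.alignment_interval.start:
                continue
            anchor_downstream = False
        clip_side = "left" if left else "right"
        if anchor_downstream:
            pattern = Pattern.TYPE_I if clip_side == "left" else Pattern.TYPE_II
        else:
            pattern = Pattern.TYPE_I if clip_side == "right" else Pattern.TYPE_II
        clipped_seq = rec.sequence[:left] if left else rec.sequence[-right:]
        mapped_cigar = tuple((op, n) for op, n in rec.cigar if op != "S")
        out.append(AnchoredSplitRead(
            read_id=rec.read_id,
            pattern=pattern,
            mapped_interval=rec.alignment_interval,
            clipped_seq=clipped_seq,
            anchor_interval=mate.alignment_interval,
            strand=rec.strand,
            mate_strand=mate.strand,
            read_length=rec.read_length,
            mate_length=mate.read_length,
            clip_side=clip_side,
            read_seq=rec.sequence,
            mapped_cigar=mapped_cigar,
            anchor_is_downstream=anchor_downstream,
        ))
    if skipped_unmapped_mate:
        log.info("skipped %d clipped reads with unmapped mates", skipped_unmapped_mate)
    return out


# --- spanning pairs ----------------------------------------------------------

def find_spanning_pairs(split: AnchoredSplitRead, store: ReadStore,
                        stats: LibraryStats, params: Parameters) -> list[SpanningPair]:
    """All FR pairs that could span the deletion supported by ``split``.

    For the forward geometry the reverse-strand end must start inside the
    spanning-pair search window downstream of the split read's mapped start,
    with the forward end mapped upstream of the mapped segment; the mirrored
    geometry reflects both conditions.
    """
    if split.pattern is not Pattern.TYPE_I:
        raise ValueError("spanning pairs are searched for TYPE_I split reads")
    chrom = split.mapped_interval.chrom
    k = params.sd_multiplier
    reach = int(math.floor(stats.insert_mean + k * stats.insert_sd))
    pairs = []
    if split.anchor_is_downstream:
        a = split.mapped_interval.start + 1  # 1-based mapped start
        for rev in store.reverse_starts_in(chrom, a - 1, a - 1 + reach):
            if rev.mapq < ANCHOR_MIN_MAPQ:
                continue
            fwd = store.mate(rev)
            if (fwd is None or not fwd.is_mapped or fwd.chrom != chrom
                    or fwd.strand != "+" or fwd.mapq < ANCHOR_MIN_MAPQ):
                continue
            if fwd.alignment_interval.end > split.mapped_interval.start:
                continue  # forward end must lie upstream of the mapped segment
            if fwd.alignment_interval.end > rev.alignment_interval.start:
                continue
            # mapped spans, not read lengths: a soft-clipped pair end only
            # contributes its aligned footprint to the window geometry
            l1 = fwd.alignment_interval.width()
            l2 = rev.alignment_interval.width()
            s2 = rev.alignment_interval.start + 1
            hi = math.floor(a - l1 - l2 + stats.insert_mean + k * stats.insert_sd)
            if not a <= s2 <= hi:
                continue
            pairs.append(SpanningPair(fwd.alignment_interval, rev.alignment_interval,
                                      l1, l2, pair_id=rev.read_id))
    else:
        b_end = split.mapped_interval.end  # == 1-based mapped end
        for fwd in store.forward_ends_in(chrom, b_end - reach, b_end):
            if fwd.mapq < ANCHOR_MIN_MAPQ:
                continue
            rev = store.mate(fwd)
            if (rev is None or not rev.is_mapped or rev.chrom != chrom
                    or rev.strand != "-" or rev.mapq < ANCHOR_MIN_MAPQ):
                continue
            if rev.alignment_interval.start < split.mapped_interval.end:
                continue  # reverse end must lie downstream of the mapped segment
            if fwd.alignment_interval.end > rev.alignment_interval.start:
                continue
            l1 = fwd.alignment_interval.width()
            l2 = rev.alignment_interval.width()
            e1 = fwd.alignment_interval.end  # == 1-based last aligned base
            lo = math.ceil(b_end + l1 + l2 - stats.insert_mean - k * stats.insert_sd)
            if not lo <= e1 <= b_end:
                continue
            pairs.append(SpanningPair(fwd.alignment_interval, rev.alignment_interval,
                                      l1, l2, pair_id=fwd.read_id))
    return pairs


# --- insertion candidates ----------------------------------------------------

#: gap-open events in the head half that count as a low-quality head mapping
HEAD_GAP_EVENTS = 2


def extract_insertion_candidates(store: ReadStore,
                                 params: Parameters) -> list[ReadRecord]:
    """Reads from proper pairs whose 5' head portion is mapped with low
    quality: soft-clipped at the head end, or carrying several gap events in
    the head half of the read.

    The head of a forward read is its low-coordinate end; for a reverse read
    it is the high-coordinate end.
    """
    out = []
    for rec in store.records:
        if not rec.is_mapped or not rec.is_proper_pair:
            continue
        mate = store.mate(rec)
        if mate is None or not mate.is_mapped:
            continue
        left, right = rec.clip_lengths()
        if left > 0 and right > 0:
            continue
        head_clip = left if rec.strand == "+" else right
        if head_clip >= params.min_clip_length:
            out.append(rec)
            continue
        if _head_gap_events(rec) >= HEAD_GAP_EVENTS:
            out.append(rec)
    return out


def _head_gap_events(rec: ReadRecord) -> int:
    half = rec.read_length / 2.0
    events = 0
    read_off = 0
    for op, length in rec.cigar:
        if op in ("I", "D"):
            mid = read_off + (length / 2.0 if op == "I" else 0.0)
            in_head = mid < half if rec.strand == "+" else mid >= half
            if in_head:
                events += 1
        if op in ("M", "I", "S"):
            read_off += length
    return events
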