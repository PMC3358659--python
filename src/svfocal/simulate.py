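"""Synthetic diploid datasets with implanted deletions and insertions.

The generator emulates a low-coverage paired-end study: a pseudo-random
reference, two haplotypes carrying heterozygous variants, FR read pairs with
normally distributed outer distance (default 500 +/- 50, read length 100)
and uniform substitution errors (default rate 2%).  Instead of invoking an
external mapper, each read's known donor coordinates are projected onto the
reference, producing soft-clipped SAM records with the exact geometry a
soft-clip-aware mapper would report for breakpoint-spanning reads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pysam

from .model import GenomicInterval, InputError

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class TruthVariant:
    """A ground-truth variant placed on one haplotype (heterozygous)."""

    kind: str  # "deletion" or "insertion"
    chrom: str
    haplotype: int
    interval: Optional[GenomicInterval] = None  # deletions: deleted ref bases
    breakpoint: Optional[int] = None  # insertions: 0-based ref position
    inserted_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "deletion":
            if self.interval is None or self.interval.width() < 1:
                raise ValueError("deletion needs a non-empty interval")
        elif self.kind == "insertion":
            if self.breakpoint is None or not self.inserted_seq:
                raise ValueError("insertion needs breakpoint and sequence")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")


def make_reference(length: int, gc: float = 0.41, seed: int = 0) -> str:
    """Pseudo-random reference sequence with the requested GC fraction."""
    if length < 10_000:
        raise ValueError("reference shorter than 10 kb is below the scale "
                         "the simulation is meant to emulate")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(["A", "C", "G", "T"])[
        rng.choice(4, size=length, p=probs)])


#: default deletion-length mixture: (weight, min_len, max_len); the three
#: strata cover short (<1 kb), mid-range (1-7 kb) and large (>7 kb) events
DEFAULT_DELETION_MIXTURE = ((0.70, 60, 1000), (0.25, 1000, 7000), (0.05, 7000, 12000))


def implant_variants(ref: str, n_deletions: int = 0, n_insertions: int = 0, *,
                     deletion_mixture=DEFAULT_DELETION_MIXTURE,
                     insertion_length_range: tuple[int, int] = (150, 500),
                     seed: int = 0, min_gap: int = 2000, margin: int = 1500,
                     chrom: str = "chr1") -> tuple[str, str, list[TruthVariant]]:
    """Place non-overlapping heterozygous variants and build both haplotypes.

    Variant reference footprints are kept ``min_gap`` apart and ``margin``
    away from the chromosome ends so each event can be flanked by full
    fragments.  Each variant goes to one haplotype chosen at random.
    """
    rng = np.random.default_rng(seed)
    footprints: list[tuple[int, int]] = []
    variants: list[TruthVariant] = []
    weights = np.array([w for w, _, _ in deletion_mixture], dtype=float)
    weights /= weights.sum()

    def _place(length: int, kind: str) -> int:
        for _ in range(20_000):
            pos = int(rng.integers(margin, len(ref) - margin - length))
            if not any(pos - min_gap < fe and fs < pos + length + min_gap
                       for fs, fe in footprints):
                footprints.append((pos, pos + length))
                return pos
        raise InputError("cannot place variants without overlap; request "
                         "fewer or smaller variants")

    for _ in range(n_deletions):
        stratum = deletion_mixture[int(rng.choice(len(deletion_mixture), p=weights))]
        length = int(rng.integers(stratum[1], stratum[2] + 1))
        pos = _place(length, "deletion")
        variants.append(TruthVariant(
            kind="deletion", chrom=chrom, haplotype=int(rng.integers(0, 2)),
            interval=GenomicInterval(chrom, pos, pos + length)))
    lo_ins, hi_ins = insertion_length_range
    for _ in range(n_insertions):
        length = int(rng.integers(lo_ins, hi_ins + 1))
        pos = _place(1, "insertion")
        seq = "".join(np.array(["A", "C", "G", "T"])[rng.integers(0, 4, size=length)])
        variants.append(TruthVariant(
            kind="insertion", chrom=chrom, haplotype=int(rng.integers(0, 2)),
            breakpoint=pos, inserted_seq=seq))

    variants.sort(key=lambda v: v.interval.start if v.kind == "deletion"
                  else v.breakpoint)
    haps = []
    for h in (0, 1):
        parts = []
        cur = 0
        for v in variants:
            if v.haplotype != h:
                continue
            if v.kind == "deletion":
                parts.append(ref[cur:v.interval.start])
                cur = v.interval.end
            else:
                parts.append(ref[cur:v.breakpoint])
                parts.append(v.inserted_seq)
                cur = v.breakpoint
        parts.append(ref[cur:])
        haps.append("".join(parts))
    return haps[0], haps[1], variants


def donor_map(ref_len: int, variants: list[TruthVariant],
              haplotype: int) -> list[tuple]:
    """Piecewise donor->reference map for one haplotype.

    Segments are ``("ref", donor_start, donor_end, ref_start)`` or
    ``("ins", donor_start, donor_end, ref_breakpoint)``, sorted by donor
    coordinate.
    """
    segs = []
    cur_ref = 0
    cur_don = 0
    for v in sorted(variants, key=lambda v: v.interval.start
                    if v.kind == "deletion" else v.breakpoint):
        if v.haplotype != haplotype:
            continue
        if v.kind == "deletion":
            n = v.interval.start - cur_ref
            if n:
                segs.append(("ref", cur_don, cur_don + n, cur_ref))
            cur_don += n
            cur_ref = v.interval.end
        else:
            n = v.breakpoint - cur_ref
            if n:
                segs.append(("ref", cur_don, cur_don + n, cur_ref))
            cur_don += n
            cur_ref = v.breakpoint
            k = len(v.inserted_seq)
            segs.append(("ins", cur_don, cur_don + k, v.breakpoint))
            cur_don += k
    if ref_len > cur_ref:
        segs.append(("ref", cur_don, cur_don + ref_len - cur_ref, cur_ref))
    return segs


@dataclass
class SimPair:
    """One simulated fragment with provenance (donor coordinates kept)."""

    pair_id: str
    haplotype: int
    frag_start: int  # donor coordinate of the leftmost fragment base
    frag_len: int
    read_len: int
    seq_fwd: str  # forward read, reference orientation
    seq_rev: str  # reverse read, reference orientation

    @property
    def fwd_donor_interval(self) -> tuple[int, int]:
        return self.frag_start, self.frag_start + self.read_len

    @property
    def rev_donor_interval(self) -> tuple[int, int]:
        end = self.frag_start + self.frag_len
        return end - self.read_len, end


def simulate_reads(hap0: str, hap1: str, coverage: float, read_len: int = 100,
                   insert_mean: float = 500.0, insert_sd: float = 50.0,
                   error_rate: float = 0.02, seed: int = 0) -> list[SimPair]:
    """FR read pairs with normal outer distances and substitution errors.

    Coverage is measured against the mean haplotype length, i.e. it is the
    total depth of the diploid sample (each haplotype receives about half).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    haps = (hap0, hap1)
    genome = (len(hap0) + len(hap1)) / 2.0
    n_pairs = int(round(coverage * genome / (2 * read_len)))
    bases = np.array(["A", "C", "G", "T"])
    pairs = []
    frag_lens = np.maximum(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int),
        2 * read_len)
    hap_idx = rng.integers(0, 2, size=n_pairs)
    for i in range(n_pairs):
        h = int(hap_idx[i])
        donor = haps[h]
        frag = min(int(frag_lens[i]), len(donor))
        start = int(rng.integers(0, len(donor) - frag + 1))
        fwd = donor[start:start + read_len]
        rev = donor[start + frag - read_len:start + frag]
        if error_rate > 0:
            fwd = _mutate(fwd, error_rate, rng, bases)
            rev = _mutate(rev, error_rate, rng, bases)
        pairs.append(SimPair(
            pair_id=f"p{i}:h{h}:f{frag}",
            haplotype=h, frag_start=start, frag_len=frag, read_len=read_len,
            seq_fwd=fwd, seq_rev=rev))
    return pairs


def _mutate(seq: str, rate: float, rng, bases) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        cur = out[i]
        choices = [b for b in "ACGT" if b != cur]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


# --- projection to SAM -------------------------------------------------------

def _project_read(segs: list[tuple], x: int, length: int):
    """Project donor interval [x, x+length) onto the reference.

    Returns ``(pos, cigar, mapped)`` where ``cigar`` is ((op, len), ...) with
    soft clips for the portions that do not belong to the mapped block.  The
    largest reference-mapped piece becomes the aligned block; everything
    else is soft-clipped, which is the geometry a soft-clip mapper reports
    for breakpoint-spanning reads.  Reads lying entirely inside inserted
    sequence are unmapped.
    """
    end = x + length
    pieces = []  # (kind, take, refpos)
    for kind, ds, de, refpos in segs:
        if de <= x or ds >= end:
            continue
        lo, hi = max(ds, x), min(de, end)
        if kind == "ref":
            pieces.append(("ref", hi - lo, refpos + (lo - ds)))
        else:
            pieces.append(("ins", hi - lo, None))
    if not pieces:
        return None, (), False
    ref_pieces = [(i, p) for i, p in enumerate(pieces) if p[0] == "ref"]
    if not ref_pieces:
        return None, (), False
    # major reference piece wins; ties go left
    major_i = max(ref_pieces, key=lambda ip: (ip[1][1], -ip[0]))[0]
    before = sum(p[1] for p in pieces[:major_i])
    major = pieces[major_i]
    after = length - before - major[1]
    cigar = []
    if before:
        cigar.append(("S", before))
    cigar.append(("M", major[1]))
    if after:
        cigar.append(("S", after))
    return major[2], tuple(cigar), True


def write_truth_alignments(pairs: list[SimPair], ref: str,
                           variants: list[TruthVariant], out_path: str,
                           chrom: str = "chr1",
                           comments: list[str] | None = None) -> None:
    """Write coordinate-sorted SAM with ground-truth soft-clip projections."""
    maps = {h: donor_map(len(ref), variants, h) for h in (0, 1)}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": len(ref)}],
        "CO": comments or [],
    }
    rows = []
    for pair in pairs:
        segs = maps[pair.haplotype]
        fx, _ = pair.fwd_donor_interval
        rx, _ = pair.rev_donor_interval
        fpos, fcig, fmap = _project_read(segs, fx, pair.read_len)
        rpos, rcig, rmap = _project_read(segs, rx, pair.read_len)
        rows.extend(_pair_rows(pair, fpos, fcig, fmap, rpos, rcig, rmap))
    rows.sort(key=lambda r: (r["pos"] if r["pos"] is not None else 1 << 40))
    with pysam.AlignmentFile(out_path, "wh", header=header) as sam:
        hdr = sam.header
        for row in rows:
            a = pysam.AlignedSegment(hdr)
            a.query_name = row["qname"]
            a.query_sequence = row["seq"]
            a.flag = row["flag"]
            a.reference_id = 0 if row["pos"] is not None else -1
            a.reference_start = row["pos"] if row["pos"] is not None else -1
            a.mapping_quality = row["mapq"]
            if row["cigar"]:
                a.cigarstring = "".join(f"{n}{op}" for op, n in row["cigar"])
            a.next_reference_id = 0 if row["pnext"] is not None else -1
            a.next_reference_start = row["pnext"] if row["pnext"] is not None else -1
            a.template_length = row["tlen"]
            sam.write(a)


def _pair_rows(pair: SimPair, fpos, fcig, fmap, rpos, rcig, rmap):
    both = fmap and rmap
    proper = both
    tlen = 0
    if both:
        f_end = fpos + sum(n for op, n in fcig if op in ("M", "D"))
        r_end = rpos + sum(n for op, n in rcig if op in ("M", "D"))
        left = min(fpos, rpos)
        right = max(f_end, r_end)
        tlen = right - left
    f_flag = 1 | 64 | (2 if proper else 0)
    r_flag = 1 | 128 | (2 if proper else 0) | 16
    f_flag |= 32  # mate (reverse read) on reverse strand
    if not fmap:
        f_flag |= 4
        f_flag &= ~2
    if not rmap:
        r_flag |= 4
        r_flag &= ~16
        f_flag |= 8
        f_flag &= ~32
        f_flag &= ~2
    if not fmap:
        r_flag |= 8
        r_flag &= ~2
    f_row = {
        "qname": pair.pair_id, "seq": pair.seq_fwd,
        "flag": f_flag, "pos": fpos if fmap else (rpos if rmap else None),
        "mapq": 60 if fmap else 0, "cigar": fcig if fmap else (),
        "pnext": rpos if rmap else (fpos if fmap else None),
        "tlen": tlen if both and fpos <= rpos else (-tlen if both else 0),
    }
    r_row = {
        "qname": pair.pair_id, "seq": pair.seq_rev,
        "flag": r_flag, "pos": rpos if rmap else (fpos if fmap else None),
        "mapq": 60 if rmap else 0, "cigar": rcig if rmap else (),
        "pnext": fpos if fmap else (rpos if rmap else None),
        "tlen": -tlen if both and fpos <= rpos else (tlen if both else 0),
    }
    return [f_row, r_row]


def write_reference_fasta(ref: str, path: str, chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(ref), 60):
            fh.write(ref[i:i + 60] + "\n")


def make_gap_adjustment_case(seed: int = 0, chrom: str = "chr1"):
    """Synthetic evidence for the gap-removal adjustment.

    Builds a reference carrying a 100-bp deletion and a breakpoint-spanning
    read engineered so that a greedy local alignment of the mapped portion
    extends one base past the true junction by opening a single-base gap,
    which makes the initially implied deletion length 101; the gap-free
    re-split restores 100.  Returns ``(reference, split, placement,
    true_interval)``.
    """
    from .model import AnchoredSplitRead, Pattern, SplitAlignment
    from .reference import RefGenome

    rng = np.random.default_rng(seed)
    bases = np.array(["A", "C", "G", "T"])
    ref = list("".join(bases[rng.integers(0, 4, 600)]))
    # true deletion removes ref[250:350).  The greedy mapped-side alignment
    # 50M 1I 4M exists when the four bases after the junction re-occur right
    # after the deletion start, and is not replaceable by a gap-free
    # extension when the inserted read base differs from the next ref base.
    ref[250:254] = ref[351:355]
    if ref[350] == ref[254]:
        ref[350] = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref[254]]
    ref = "".join(ref)
    read = ref[200:250] + ref[350:400]
    reference = RefGenome({chrom: ref})
    split = AnchoredSplitRead(
        read_id="engineered-gap", pattern=Pattern.TYPE_II,
        mapped_interval=GenomicInterval(chrom, 200, 254),
        clipped_seq=read[55:],
        anchor_interval=GenomicInterval(chrom, 500, 600),
        strand="+", mate_strand="-", read_length=100, mate_length=100,
        clip_side="right", read_seq=read,
        mapped_cigar=(("M", 50), ("I", 1), ("M", 4)),
        anchor_is_downstream=True)
    placement = SplitAlignment(
        placed_interval=GenomicInterval(chrom, 355, 400),
        score=45, n_match=45, n_mismatch=0, gap_cols=0)
    return reference, split, placement, GenomicInterval(chrom, 250, 350)


@dataclass
class SimulatedDataset:
    reference_fasta: str
    alignments_sam: str
    truth_deletions_vcf: str
    truth_insertions_vcf: str
    reference: str
    variants: list[TruthVariant]
    pairs: list[SimPair] = field(repr=False, default_factory=list)


def simulate_dataset(outdir: str, *, length: int = 1_000_000,
                     coverage: float = 6.0, n_deletions: int = 40,
                     n_insertions: int = 0, gc: float = 0.41,
                     read_len: int = 100, insert_mean: float = 500.0,
                     insert_sd: float = 50.0, error_rate: float = 0.02,
                     seed: int = 0, chrom: str = "chr1") -> SimulatedDataset:
    """Generate reference FASTA, truth VCFs and ground-truth SAM in one call."""
    from . import writers

    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_ref, s_var, s_reads = (int(c.generate_state(1)[0] % (2 ** 31))
                             for c in ss.spawn(3))
    ref = make_reference(length, gc=gc, seed=s_ref)
    hap0, hap1, variants = implant_variants(
        ref, n_deletions=n_deletions, n_insertions=n_insertions,
        seed=s_var, chrom=chrom)
    pairs = simulate_reads(hap0, hap1, coverage, read_len=read_len,
                           insert_mean=insert_mean, insert_sd=insert_sd,
                           error_rate=error_rate, seed=s_reads)
    fa = os.path.join(outdir, "reference.fa")
    sam = os.path.join(outdir, "alignments.sam")
    del_vcf = os.path.join(outdir, "truth_deletions.vcf")
    ins_vcf = os.path.join(outdir, "truth_insertions.vcf")
    comments = [f"svfocal simulate seed={seed} length={length} "
                f"coverage={coverage} n_deletions={n_deletions} "
                f"n_insertions={n_insertions} read_len={read_len} "
                f"insert_mean={insert_mean} insert_sd={insert_sd} "
                f"error_rate={error_rate}"]
    write_reference_fasta(ref, fa, chrom)
    write_truth_alignments(pairs, ref, variants, sam, chrom, comments)
    writers.write_truth_deletions_vcf(
        [v for v in variants if v.kind == "deletion"], ref, del_vcf, chrom)
    writers.write_truth_insertions_vcf(
        [v for v in variants if v.kind == "insertion"], ref, ins_vcf, chrom)
    return SimulatedDataset(fa, sam, del_vcf, ins_vcf, ref, variants, pairs)
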