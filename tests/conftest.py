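"""Shared fixtures: crafted read records, small simulated datasets, and the
exhaustive alignment oracle used to cross-check the DP."""

from __future__ import annotations

import sys
from functools import lru_cache

import pytest

from svfocal.ingest import ReadRecord, ReadStore
from svfocal.model import GenomicInterval, LibraryStats, Parameters


@pytest.fixture
def params() -> Parameters:
    return Parameters()


@pytest.fixture
def stats() -> LibraryStats:
    return LibraryStats(insert_mean=500.0, insert_sd=50.0, read_length=100)


def make_record(read_id, chrom, start, cigar, seq, strand="+", *,
                first=True, mate_chrom=None, mate_position=None, mapq=60,
                proper=True, mate_is_reverse=False):
    """Craft a mapped ReadRecord; reference span derives from the CIGAR."""
    ref_span = sum(n for op, n in cigar if op in ("M", "D"))
    return ReadRecord(
        read_id=read_id,
        chrom=chrom,
        alignment_interval=GenomicInterval(chrom, start, start + ref_span),
        strand=strand,
        cigar=tuple(cigar),
        sequence=seq,
        is_first_in_pair=first,
        mate_chrom=mate_chrom if mate_chrom is not None else chrom,
        mate_position=mate_position,
        mapq=mapq,
        is_proper_pair=proper,
        mate_is_reverse=mate_is_reverse,
    )


def make_pair(read_id, chrom, fwd_start, fwd_cigar, fwd_seq,
              rev_start, rev_cigar, rev_seq, mapq=60, proper=True):
    """A mapped FR pair as two ReadRecords (forward first-in-pair)."""
    fwd = make_record(read_id, chrom, fwd_start, fwd_cigar, fwd_seq, "+",
                      first=True, mate_position=rev_start, mapq=mapq,
                      proper=proper, mate_is_reverse=True)
    rev = make_record(read_id, chrom, rev_start, rev_cigar, rev_seq, "-",
                      first=False, mate_position=fwd_start, mapq=mapq,
                      proper=proper, mate_is_reverse=False)
    return fwd, rev


def store_of(*records) -> ReadStore:
    flat = []
    for r in records:
        flat.extend(r if isinstance(r, (tuple, list)) else [r])
    return ReadStore(flat)


def oracle_fit_score(seg: str, reg: str, match=1, mismatch=-1, gap=3) -> int:
    """Exhaustive-recursion score for the fitting alignment: every segment
    base consumed, region flanks free, internal gap columns penalized."""
    sys.setrecursionlimit(10_000)
    n = len(reg)

    def sub(a, b):
        return match if (a == b and a in "ACGT") else mismatch

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(seg):
            return 0
        opts = [-gap + rec(i + 1, j)]  # segment base vs gap
        if j < n:
            opts.append(sub(seg[i], reg[j]) + rec(i + 1, j + 1))
            opts.append(-gap + rec(i, j + 1))  # region base vs gap (internal)
        return max(opts)

    try:
        return max(rec(0, s) for s in range(n + 1))
    finally:
        rec.cache_clear()


@pytest.fixture(scope="session")
def small_deletion_dataset(tmp_path_factory):
    """200 kb, 8 heterozygous deletions, 6x, 1% error (session-cached)."""
    from svfocal import simulate

    outdir = tmp_path_factory.mktemp("sim_del")
    return simulate.simulate_dataset(
        str(outdir), length=200_000, coverage=6.0, n_deletions=8,
        n_insertions=0, error_rate=0.01, seed=5)


@pytest.fixture(scope="session")
def small_insertion_dataset(tmp_path_factory):
    """150 kb, 5 heterozygous insertions, 20x, 2% error (session-cached)."""
    from svfocal import simulate

    outdir = tmp_path_factory.mktemp("sim_ins")
    return simulate.simulate_dataset(
        str(outdir), length=150_000, coverage=20.0, n_deletions=0,
        n_insertions=5, error_rate=0.02, seed=11)
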