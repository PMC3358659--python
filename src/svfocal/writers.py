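"""VCF/BED output and input for deletion and insertion call sets.

Deletions use the symbolic-allele convention: POS is the base before the
deleted run (so a deleted 0-based half-open interval [s, e) is written with
POS = s, END = e) and SVLEN is negative.  Insertions report the breakpoint
position with the partial inserted sequence recovered from the two strands.
"""

from __future__ import annotations

import hashlib

import pysam

from .model import DeletionCall, GenomicInterval, InputError, InsertionCall

_DEL_HEADER = """\
##fileformat=VCFv4.2
##source=svfocal
##ALT=<ID=DEL,Description="Deletion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based, last deleted base)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the variant">
##INFO=<ID=WEIGHT,Number=1,Type=Integer,Description="Total supporting pattern weight">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of supporting split reads">
##INFO=<ID=ADJUSTED,Number=0,Type=Flag,Description="Breakpoints refined by the gap-removal adjustment">
"""

_INS_HEADER = """\
##fileformat=VCFv4.2
##source=svfocal
##ALT=<ID=INS,Description="Insertion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the variant (if known)">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of supporting reads">
##INFO=<ID=PREFIX,Number=1,Type=String,Description="Recovered head of the inserted sequence">
##INFO=<ID=SUFFIX,Number=1,Type=String,Description="Recovered tail of the inserted sequence">
"""


def _contig_lines(reference) -> str:
    return "".join(f"##contig=<ID={c},length={reference.length(c)}>\n"
                   for c in reference.chroms)


_COLS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def write_deletions_vcf(calls: list[DeletionCall], reference, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_DEL_HEADER)
        fh.write(_contig_lines(reference))
        fh.write(_COLS)
        for call in calls:
            iv = call.deleted_interval
            pos = max(iv.start, 1)  # 1-based base before the deleted run
            ref_base = reference.fetch(iv.chrom, pos - 1, pos) or "N"
            info = (f"SVTYPE=DEL;END={iv.end};SVLEN={-iv.width()};"
                    f"WEIGHT={call.total_weight};SUPPORT={len(call.support)}")
            if call.adjusted:
                info += ";ADJUSTED"
            fh.write(f"{iv.chrom}\t{pos}\t.\t{ref_base}\t<DEL>\t.\tPASS\t{info}\n")


def write_insertions_vcf(calls: list[InsertionCall], reference, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_INS_HEADER)
        fh.write(_contig_lines(reference))
        fh.write(_COLS)
        for call in calls:
            pos = max(call.breakpoint, 1)
            ref_base = reference.fetch(call.chrom, pos - 1, pos) or "N"
            info = f"SVTYPE=INS;SUPPORT={call.n_support}"
            if call.inserted_prefix:
                info += f";PREFIX={call.inserted_prefix}"
            if call.inserted_suffix:
                info += f";SUFFIX={call.inserted_suffix}"
            fh.write(f"{call.chrom}\t{pos}\t.\t{ref_base}\t<INS>\t.\tPASS\t{info}\n")


def write_truth_deletions_vcf(variants, ref: str, path: str, chrom: str) -> None:
    from .reference import RefGenome

    reference = RefGenome({chrom: ref})
    calls = [DeletionCall(chrom=chrom, deleted_interval=v.interval,
                          total_weight=0) for v in variants]
    write_deletions_vcf(calls, reference, path)


def write_truth_insertions_vcf(variants, ref: str, path: str, chrom: str) -> None:
    from .reference import RefGenome

    reference = RefGenome({chrom: ref})
    calls = [InsertionCall(chrom=chrom, breakpoint=v.breakpoint,
                           n_support=0, inserted_prefix=v.inserted_seq or "")
             for v in variants]
    write_insertions_vcf(calls, reference, path)


def write_deletions_bed(calls: list[DeletionCall], path: str) -> None:
    with open(path, "w") as fh:
        for call in calls:
            iv = call.deleted_interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"DEL_{iv.width()}\t{call.total_weight}\n")


def write_focal_bed(regions: list[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def load_deletions_vcf(path: str) -> list[GenomicInterval]:
    """Deleted intervals (0-based half-open) from a VCF with SVTYPE=DEL."""
    out = []
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {path}: {exc}") from exc
    with vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype not in (None, "DEL"):
                continue
            end = rec.info.get("END", rec.stop)
            out.append(GenomicInterval(rec.chrom, rec.pos, int(end)))
    return out


def load_insertions_vcf(path: str) -> list[tuple[str, int]]:
    """(chrom, 0-based breakpoint) pairs from a VCF with SVTYPE=INS."""
    out = []
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {path}: {exc}") from exc
    with vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype not in (None, "INS"):
                continue
            out.append((rec.chrom, rec.pos))
    return out


def file_md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
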