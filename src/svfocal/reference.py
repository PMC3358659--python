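"""Uniform access to reference sequence from FASTA or in-memory strings."""

from __future__ import annotations

import os

import pysam

from .model import InputError


class RefGenome:
    """Reference genome backed by an indexed FASTA file or a dict of strings.

    ``fetch`` uses 0-based half-open coordinates and returns upper-case
    sequence, clamped to the chromosome.
    """

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in seqs.items()}
        self._fasta = None

    @classmethod
    def from_fasta(cls, path: str) -> "RefGenome":
        if not os.path.exists(path):
            raise InputError(f"reference FASTA not found: {path}")
        obj = cls.__new__(cls)
        obj._seqs = None
        try:
            obj._fasta = pysam.FastaFile(path)  # builds .fai if absent
        except OSError as exc:
            raise InputError(f"cannot open/index FASTA {path}: {exc}") from exc
        return obj

    @property
    def chroms(self) -> list[str]:
        if self._fasta is not None:
            return list(self._fasta.references)
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def length(self, chrom: str) -> int:
        if self._fasta is not None:
            if chrom not in self._fasta.references:
                raise InputError(f"chromosome {chrom!r} absent from FASTA")
            return self._fasta.get_reference_length(chrom)
        try:
            return len(self._seqs[chrom])
        except KeyError:
            raise InputError(f"chromosome {chrom!r} absent from reference") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = self.length(chrom)
        start = max(0, start)
        end = min(n, end)
        if end <= start:
            return ""
        if self._fasta is not None:
            return self._fasta.fetch(chrom, start, end).upper()
        return self._seqs[chrom][start:end]
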