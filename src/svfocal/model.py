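"""Domain types, coordinate conventions and the default-parameter registry.

All internal arithmetic uses 0-based half-open intervals (the BED
convention).  The deletion/insertion geometry in the literature is commonly
written in 1-based closed coordinates; :func:`to_closed_coords` and
:func:`from_closed_coords` convert at the formula boundary, and nowhere else.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class SVFocalError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(SVFocalError):
    """A parameter value violates its documented range."""


class InputError(SVFocalError):
    """Problem with user-supplied input files or values."""


class Pattern(str, Enum):
    """Split-read configuration relative to the anchor.

    TYPE_I: the clipped segment lies on the anchor-distal side of the mapped
    segment (the mapped segment faces the anchor).  TYPE_II: the clip is
    anchor-proximal; the read pair itself spans the deletion.
    """

    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"


class AlnOp(str, Enum):
    MATCH = "MATCH"
    MISMATCH = "MISMATCH"
    GAP_IN_SEGMENT = "GAP_IN_SEGMENT"  # region base aligned to a gap
    GAP_IN_REGION = "GAP_IN_REGION"    # segment base aligned to a gap


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end < self.start:
            raise ValueError(f"end < start: [{self.start}, {self.end})")

    def width(self) -> int:
        return self.end - self.start

    def is_empty(self) -> bool:
        return self.end == self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_width(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def to_closed_coords(iv: GenomicInterval) -> tuple[int, int]:
    """Convert to 1-based closed (first, last); errors on empty intervals."""
    if iv.is_empty():
        raise ValueError("empty interval has no closed-coordinate form")
    return iv.start + 1, iv.end


def from_closed_coords(chrom: str, first: int, last: int) -> GenomicInterval:
    """Inverse of :func:`to_closed_coords`.

    ``last < first`` denotes an empty range and yields an empty interval
    anchored at ``first - 1`` (clamped to zero).
    """
    if last < first:
        anchor = max(first - 1, 0)
        return GenomicInterval(chrom, anchor, anchor)
    if first < 1:
        raise ValueError(f"1-based coordinate must be >= 1, got {first}")
    return GenomicInterval(chrom, first - 1, last)


@dataclass(frozen=True)
class LibraryStats:
    """Insert-size model of the sequencing library.

    ``insert_mean`` is the expected *outer* distance of a pair (leftmost base
    of one read to rightmost base of its mate) and ``insert_sd`` its standard
    deviation; together with ``sd_multiplier`` they bound every search window
    used during calling.
    """

    insert_mean: float
    insert_sd: float
    read_length: int

    def __post_init__(self) -> None:
        if self.insert_mean <= 0:
            raise ValueError("insert_mean must be positive")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be non-negative")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must cover at least one read")


@dataclass
class AnchoredSplitRead:
    """A soft-clipped read plus its mapped mate (the anchor)."""

    read_id: str
    pattern: Pattern
    mapped_interval: GenomicInterval
    clipped_seq: str
    anchor_interval: GenomicInterval
    strand: str
    mate_strand: str
    read_length: int
    mate_length: int
    clip_side: str  # "left" or "right": end of the alignment carrying the clip
    read_seq: str = ""
    mapped_cigar: tuple = ()  # (op, length) with ops M/I/D, soft clips removed
    anchor_is_downstream: bool = True

    def __post_init__(self) -> None:
        if len(self.clipped_seq) < 1:
            raise ValueError("clipped segment must be non-empty")
        if self.clip_side not in ("left", "right"):
            raise ValueError(f"bad clip_side {self.clip_side!r}")
        if self.strand == self.mate_strand:
            raise ValueError("split read and anchor must be on opposite strands")
        read_consumed = self.clip_length + sum(
            n for op, n in self.mapped_cigar if op in ("M", "I")
        )
        if self.mapped_cigar and read_consumed > self.read_length:
            raise ValueError("clip + matched bases exceed read length")

    @property
    def clip_length(self) -> int:
        return len(self.clipped_seq)


@dataclass(frozen=True)
class SpanningPair:
    """A read pair whose ends flank a deletion: [s1,e1] forward, [s2,e2] reverse.

    ``left_length``/``right_length`` are the mapped spans of the two ends
    (equal to the read lengths for fully aligned reads; shorter when an end
    is soft-clipped, which keeps the window geometry conservative).
    """

    left_interval: GenomicInterval
    right_interval: GenomicInterval
    left_length: int
    right_length: int
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.left_interval.chrom != self.right_interval.chrom:
            raise ValueError("spanning pair must lie on one chromosome")
        li, ri = self.left_interval, self.right_interval
        if not (li.start < li.end <= ri.start < ri.end):
            raise ValueError(
                f"pair intervals out of order: {li.start},{li.end},{ri.start},{ri.end}"
            )


@dataclass
class SplitAlignment:
    """Placement of a clipped segment at [c, d] inside a region (Fig-3 scoring)."""

    placed_interval: GenomicInterval
    score: int
    n_match: int
    n_mismatch: int
    gap_cols: int
    cigar_like: tuple = ()

    def check_decomposition(self, match_score: int = 1, mismatch_score: int = -1,
                            gap_penalty: int = 3) -> bool:
        return self.score == (
            self.n_match * match_score
            + self.n_mismatch * mismatch_score
            - self.gap_cols * gap_penalty
        )


@dataclass
class DeletionCall:
    chrom: str
    deleted_interval: GenomicInterval
    total_weight: int
    support: list = field(default_factory=list)  # (AnchoredSplitRead, SplitAlignment, Pattern)
    adjusted: bool = False

    @property
    def length(self) -> int:
        return self.deleted_interval.width()


@dataclass
class InsertionCall:
    chrom: str
    breakpoint: int  # 0-based position between reference bases bp-1 and bp
    n_support: int
    inserted_prefix: str = ""
    inserted_suffix: str = ""
    support_ids: tuple = ()


# --- parameters -------------------------------------------------------------

_POSITIVE = {"min_deletion_size", "weight_type1", "weight_type2",
             "deletion_weight_cutoff", "insertion_support_cutoff",
             "match_score", "min_clip_length", "max_focal_width"}
_NON_NEGATIVE = {"gap_penalty", "sd_multiplier", "adjacency_tolerance"}


@dataclass
class Parameters:
    """Tunable constants of the caller.

    Defaults are the published operating point of the method: minimum
    deletion size 50 bp, pattern weights 3 (type I) and 1 (type II) with a
    call cutoff of 3, three supporting reads for an insertion, match +1 /
    mismatch -1 / linear gap 3 alignment scoring, 3-sigma insert windows and
    the 0.1 overlap-fraction threshold of the insertion test.
    """

    min_deletion_size: int = 50
    weight_type1: int = 3
    weight_type2: int = 1
    deletion_weight_cutoff: int = 3
    insertion_support_cutoff: int = 3
    match_score: int = 1
    mismatch_score: int = -1
    gap_penalty: int = 3
    sd_multiplier: float = 3.0
    insertion_overlap_frac: float = 0.1
    min_clip_length: int = 20
    min_segment_identity: float = 0.8
    adjacency_tolerance: int = 5
    max_focal_width: int = 5000

    def validate(self) -> "Parameters":
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ConfigError(f"parameter {name} must be positive, got "
                                  f"{getattr(self, name)}")
        for name in _NON_NEGATIVE:
            if getattr(self, name) < 0:
                raise ConfigError(f"parameter {name} must be non-negative, got "
                                  f"{getattr(self, name)}")
        if self.mismatch_score > 0:
            raise ConfigError("parameter mismatch_score must be <= 0, got "
                              f"{self.mismatch_score}")
        if not 0.5 <= self.min_segment_identity <= 1.0:
            raise ConfigError("parameter min_segment_identity must lie in "
                              f"[0.5, 1], got {self.min_segment_identity}")
        if not 0.0 < self.insertion_overlap_frac <= 1.0:
            raise ConfigError("parameter insertion_overlap_frac must lie in "
                              f"(0, 1], got {self.insertion_overlap_frac}")
        return self

    def placement_min_score(self, clip_length: int) -> int:
        """Acceptance threshold on a clipped-segment placement.

        Equivalent to requiring ``min_segment_identity`` matches in an
        ungapped placement: score >= ceil((2*identity - 1) * l_s).
        """
        import math
        raw = (2.0 * self.min_segment_identity - 1.0) * clip_length
        return math.ceil(round(raw, 9))

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_parameters(config_source=None, **overrides) -> Parameters:
    """Build a validated :class:`Parameters` from defaults plus overrides.

    ``config_source`` may be ``None``, a mapping, or a path to a ``key=value``
    file ('#' starts a comment).  Keyword overrides are applied last.
    """
    values: dict = {}
    if config_source is not None:
        if hasattr(config_source, "items"):
            values.update(config_source)
        else:
            with open(config_source) as fh:
                for lineno, raw in enumerate(fh, 1):
                    line = raw.split("#", 1)[0].strip()
                    if not line:
                        continue
                    if "=" not in line:
                        raise ConfigError(
                            f"{config_source}:{lineno}: expected key=value, got {raw!r}"
                        )
                    key, val = (part.strip() for part in line.split("=", 1))
                    values[key] = val
    values.update(overrides)

    valid = {f.name: f.type for f in dataclasses.fields(Parameters)}
    coerced = {}
    for key, val in values.items():
        if key not in valid:
            raise ConfigError(f"unknown parameter {key!r}")
        want = type(getattr(Parameters(), key))
        try:
            coerced[key] = want(val)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"parameter {key}: cannot parse {val!r}") from exc
    return Parameters(**coerced).validate()
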