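"""Scoring call sets against a truth set.

Two deletion criteria are supported: *strict* (a call is correct when an
overlapping truth deletion has exactly the same length) and *overlap50*
(at least half of the called bases are supported by truth deletions, with
support accumulating over multiple truth records).  Insertions are matched
by breakpoint distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import GenomicInterval, InputError

CRITERIA = ("strict", "overlap50")


def _interval_of(call) -> GenomicInterval:
    return call.deleted_interval if hasattr(call, "deleted_interval") else call


def strict_match(call, truth: Sequence) -> Optional[GenomicInterval]:
    """The truth deletion validating ``call`` under the strict criterion.

    A match requires an overlapping truth record of identical length; among
    several, the one with the largest overlap (then leftmost) is returned.
    """
    civ = _interval_of(call)
    best = None
    for t in truth:
        tiv = _interval_of(t)
        if tiv.width() == civ.width() and civ.overlaps(tiv):
            key = (civ.overlap_width(tiv), -tiv.start)
            if best is None or key > best[0]:
                best = (key, tiv)
    return best[1] if best else None


def overlap_match(call, truth: Sequence) -> Optional[GenomicInterval]:
    """The truth deletion validating ``call`` when >= 50% of the called bases
    are covered by truth deletions (support accumulates across records)."""
    civ = _interval_of(call)
    overlapping = sorted(
        (o for t in truth if (o := _interval_of(t)).overlaps(civ)),
        key=lambda iv: (iv.start, iv.end))
    if not overlapping:
        return None
    covered = 0
    cursor = civ.start
    best = None
    for iv in overlapping:
        lo = max(iv.start, cursor, civ.start)
        hi = min(iv.end, civ.end)
        if hi > lo:
            covered += hi - lo
            cursor = max(cursor, hi)
        w = civ.overlap_width(iv)
        if best is None or (w, -iv.start) > best[0]:
            best = ((w, -iv.start), iv)
    if 2 * covered >= civ.width():
        return best[1]
    return None


def summarize(calls: Sequence, truth: Sequence, criterion: str = "strict") -> dict:
    """Findings / true positives / accuracy / sensitivity for one call set.

    Accuracy is TP over findings (``None`` for an empty call set);
    sensitivity counts each truth record at most once, as the fraction of
    truth records validating at least one call.  Both are percentages.
    """
    if criterion not in CRITERIA:
        raise InputError(f"unknown criterion {criterion!r}; pick from {CRITERIA}")
    matcher = strict_match if criterion == "strict" else overlap_match
    truth_ivs = [_interval_of(t) for t in truth]
    tp = 0
    matched_truth: set[GenomicInterval] = set()
    for call in calls:
        hit = matcher(call, truth_ivs)
        if hit is not None:
            tp += 1
            matched_truth.add(hit)
            if criterion == "overlap50":
                civ = _interval_of(call)
                matched_truth.update(t for t in truth_ivs if t.overlaps(civ))
    findings = len(calls)
    return {
        "findings": findings,
        "true_positives": tp,
        "accuracy": (100.0 * tp / findings) if findings else None,
        "sensitivity": (100.0 * len(matched_truth) / len(truth_ivs))
        if truth_ivs else None,
    }


def match_insertions(call_breakpoints: Sequence[int],
                     truth_breakpoints: Sequence[int],
                     tolerance: int = 10) -> dict:
    """Breakpoint-tolerance matching for insertion calls.

    Each truth breakpoint validates at most one call and vice versa
    (greedy nearest-first assignment).
    """
    pairs = sorted(
        (abs(c - t), ci, ti)
        for ci, c in enumerate(call_breakpoints)
        for ti, t in enumerate(truth_breakpoints)
        if abs(c - t) <= tolerance)
    used_c: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        tp += 1
    findings = len(call_breakpoints)
    n_truth = len(truth_breakpoints)
    return {
        "findings": findings,
        "true_positives": tp,
        "accuracy": (100.0 * tp / findings) if findings else None,
        "sensitivity": (100.0 * tp / n_truth) if n_truth else None,
    }


def format_summary(rows: list[tuple[str, dict]]) -> str:
    """Tab-separated summary table (label, findings, TP, accuracy, sensitivity)."""
    lines = ["Label\tFindings\tTrue Positive\tAccuracy (%)\tSensitivity (%)"]
    for label, s in rows:
        acc = "NA" if s["accuracy"] is None else f"{s['accuracy']:.0f}"
        sen = "NA" if s["sensitivity"] is None else f"{s['sensitivity']:.0f}"
        lines.append(f"{label}\t{s['findings']}\t{s['true_positives']}\t{acc}\t{sen}")
    return "\n".join(lines) + "\n"
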