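"""Assembly evaluation: sensitivity, false-positive ratio, oracle set.

A reference transcript counts as recovered when some reconstructed
transcript covers more than a threshold fraction (default 90%) of its
exonic bases by co-linear coordinate overlap.  A reconstructed transcript
is a false positive when it is below-threshold against every reference —
unless it is contained within a reference, in which case it is a plausible
partial product and exempted.  The oracle set restricts real-data
evaluation to references fully covered by reads (up to an end tolerance),
i.e. the transcripts an assembler can fairly be expected to recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import ReadAlignment
from .transcript_io import TranscriptRecord

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.9
DEFAULT_CONTAINMENT = 0.95
DEFAULT_END_TOL = 25


@dataclass
class MatchResult:
    ref_id: str
    best_rec_id: str | None
    match_fraction: float
    contained: bool  # best rec lies (almost) entirely within the ref


@dataclass
class EvalReport:
    sensitivity: float
    false_positive_ratio: float
    per_ref: list[MatchResult]
    threshold: float = DEFAULT_THRESHOLD

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ref_id": [m.ref_id for m in self.per_ref],
                "best_rec_id": [m.best_rec_id for m in self.per_ref],
                "match_fraction": [m.match_fraction for m in self.per_ref],
                "contained": [m.contained for m in self.per_ref],
            }
        )


def _intersection_length(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total, i, j = 0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _pair_fractions(
    t: TranscriptRecord, r: TranscriptRecord
) -> tuple[float, float]:
    """(fraction of t covered by r, fraction of r inside t)."""
    if t.chrom != r.chrom or not t.exons or not r.exons:
        return 0.0, 0.0
    inter = _intersection_length(t.exons, r.exons)
    return inter / t.length, inter / r.length


def match_transcripts(
    rec_set: list[TranscriptRecord],
    ref_set: list[TranscriptRecord],
    cont_threshold: float = DEFAULT_CONTAINMENT,
) -> list[MatchResult]:
    """Associate each reference with its best-matching reconstruction."""
    if not ref_set:
        raise ValueError("empty reference set")
    results: list[MatchResult] = []
    for t in ref_set:
        best_id, best_frac, best_cont = None, 0.0, False
        for r in rec_set:
            frac, rin = _pair_fractions(t, r)
            if frac > best_frac or best_id is None:
                best_id, best_frac, best_cont = r.transcript_id, frac, rin >= cont_threshold
        results.append(MatchResult(t.transcript_id, best_id, best_frac, best_cont))
    return results


def sensitivity(matches: list[MatchResult], threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fraction of references matched above the threshold."""
    if not matches:
        return 0.0
    return sum(1 for m in matches if m.match_fraction > threshold) / len(matches)


def false_positive_ratio(
    rec_set: list[TranscriptRecord],
    ref_set: list[TranscriptRecord],
    threshold: float = DEFAULT_THRESHOLD,
    cont_threshold: float = DEFAULT_CONTAINMENT,
) -> float:
    """Fraction of reconstructions below threshold against every reference
    and not contained in any reference."""
    if not rec_set:
        logger.warning("empty reconstructed set; false-positive ratio 0 by convention")
        return 0.0
    fp = 0
    for r in rec_set:
        best_frac, contained = 0.0, False
        for t in ref_set:
            frac, rin = _pair_fractions(t, r)
            best_frac = max(best_frac, frac)
            contained = contained or rin >= cont_threshold
        if best_frac <= threshold and not contained:
            fp += 1
    return fp / len(rec_set)


def evaluate(
    rec_set: list[TranscriptRecord],
    ref_set: list[TranscriptRecord],
    threshold: float = DEFAULT_THRESHOLD,
    cont_threshold: float = DEFAULT_CONTAINMENT,
) -> EvalReport:
    matches = match_transcripts(rec_set, ref_set, cont_threshold)
    return EvalReport(
        sensitivity=sensitivity(matches, threshold),
        false_positive_ratio=false_positive_ratio(
            rec_set, ref_set, threshold, cont_threshold
        ),
        per_ref=matches,
        threshold=threshold,
    )


def oracle_set(
    ref_set: list[TranscriptRecord],
    alignments: list[ReadAlignment],
    end_tol: int = DEFAULT_END_TOL,
) -> list[TranscriptRecord]:
    """References fully covered by reads, tolerating ``end_tol`` bases at
    each end of the transcript."""
    blocks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for aln in alignments:
        for b in aln.blocks:
            blocks_by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    for chrom in blocks_by_chrom:
        blocks_by_chrom[chrom].sort()
    kept: list[TranscriptRecord] = []
    for t in ref_set:
        depth = np.zeros(t.length, dtype=np.int32)
        offset = 0
        for s, e in t.exons:
            for bs, be in blocks_by_chrom.get(t.chrom, ()):
                if be <= s:
                    continue
                if bs >= e:
                    break
                lo, hi = max(bs, s), min(be, e)
                depth[offset + lo - s: offset + hi - s] += 1
            offset += e - s
        inner = depth[end_tol: max(end_tol, t.length - end_tol)]
        if inner.size == 0 or (inner > 0).all():
            kept.append(t)
    return kept
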