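"""Ingest spliced read alignments from SAM/BAM.

Alignments are decomposed into genomic blocks (one block per contiguous
reference stretch; an ``N`` gap in the CIGAR opens a new block and marks a
candidate intron) and mate pairs are linked into fragments.  All internal
coordinates are 0-based half-open; SAM's 1-based coordinates are converted
at this boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric encoding)
_CONSUME_REF_MATCH = {0, 7, 8}  # M, =, X
_OP_INS, _OP_DEL, _OP_SKIP, _OP_SOFT, _OP_HARD, _OP_PAD = 1, 2, 3, 4, 5, 6


@dataclass(frozen=True)
class AlignedBlock:
    """A contiguous aligned stretch on the reference (0-based half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty block [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReadAlignment:
    """One (possibly split) primary alignment of a read."""

    read_id: str
    chrom: str
    blocks: tuple[AlignedBlock, ...]
    is_paired: bool = False
    is_first_in_pair: bool = True
    mate_of: str | None = None

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    @property
    def aligned_length(self) -> int:
        return sum(len(b) for b in self.blocks)


@dataclass
class Fragment:
    """A sequenced fragment: one alignment, or two mated alignments."""

    first: ReadAlignment
    second: ReadAlignment | None = None

    @property
    def start(self) -> int:
        s = self.first.start
        return min(s, self.second.start) if self.second else s

    def alignments(self) -> list[ReadAlignment]:
        return [self.first] if self.second is None else [self.first, self.second]


def blocks_from_cigar(
    chrom: str, pos: int, cigartuples: Iterable[tuple[int, int]], min_intron: int = 20
) -> list[AlignedBlock]:
    """Convert a CIGAR at 0-based reference position ``pos`` into blocks.

    ``N`` gaps always split blocks; ``D`` gaps shorter than ``min_intron``
    are absorbed into the flanking block (small deletions are not splice
    events), longer ones split like introns.
    """
    blocks: list[AlignedBlock] = []
    cur_start, cur_len = pos, 0

    def close(gap: int) -> None:
        nonlocal cur_start, cur_len
        if cur_len > 0:
            blocks.append(AlignedBlock(chrom, cur_start, cur_start + cur_len))
        cur_start = cur_start + cur_len + gap
        cur_len = 0

    for op, length in cigartuples:
        if op in _CONSUME_REF_MATCH:
            cur_len += length
        elif op == _OP_DEL:
            if length < min_intron:
                cur_len += length
            else:
                close(length)
        elif op == _OP_SKIP:
            close(length)
        elif op in (_OP_INS, _OP_SOFT, _OP_HARD, _OP_PAD):
            continue
        else:
            raise ValueError(f"unsupported CIGAR op code {op}")
    close(0)
    return blocks


def parse_alignments(
    path: str,
    region: str | None = None,
    min_intron: int = 20,
) -> Iterator[ReadAlignment]:
    """Stream primary, mapped alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped (multi-mapped
    reads therefore contribute exactly once, keeping edge weights integer
    read counts).  Records with malformed CIGARs are skipped with a warning.
    """
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        skipped = 0
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if region is not None and rec.reference_name != region:
                continue
            if rec.cigartuples is None:
                skipped += 1
                continue
            try:
                blocks = blocks_from_cigar(
                    rec.reference_name, rec.reference_start, rec.cigartuples, min_intron
                )
            except ValueError:
                skipped += 1
                continue
            if not blocks:
                skipped += 1
                continue
            yield ReadAlignment(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                blocks=tuple(blocks),
                is_paired=rec.is_paired,
                is_first_in_pair=(not rec.is_paired) or rec.is_read1,
            )
        if skipped:
            logger.warning("skipped %d records with missing/malformed CIGAR", skipped)


def pair_fragments(alignments: Iterable[ReadAlignment]) -> list[Fragment]:
    """Link mated alignments into fragments, sorted by leftmost coordinate.

    Alignments whose mate is not found (or maps to a different chromosome)
    become single-alignment fragments.  Pairing is per chromosome, so
    cross-chromosome pairs are split with a warning.
    """
    pending: dict[tuple[str, str], ReadAlignment] = {}
    fragments: list[Fragment] = []
    dropped_cross = 0
    for aln in alignments:
        if not aln.is_paired:
            fragments.append(Fragment(aln))
            continue
        key = (aln.chrom, aln.read_id)
        mate = pending.get(key)
        if mate is None:
            pending[key] = aln
            continue
        if mate.is_first_in_pair == aln.is_first_in_pair:
            logger.warning("read %s: both mates flagged %s-in-pair; treated as unpaired",
                           aln.read_id, "first" if aln.is_first_in_pair else "second")
            fragments.append(Fragment(mate))
            fragments.append(Fragment(aln))
            del pending[key]
            continue
        first, second = (mate, aln) if mate.start <= aln.start else (aln, mate)
        first.mate_of = second.read_id
        second.mate_of = first.read_id
        fragments.append(Fragment(first, second))
        del pending[key]
    # leftover mates whose partner never appeared (or was on another chromosome)
    leftovers = list(pending.values())
    seen_ids = {a.read_id for a in leftovers}
    if len(seen_ids) < len(leftovers):
        dropped_cross = len(leftovers) - len(seen_ids)
        logger.warning("%d cross-chromosome pairs treated as single-end", dropped_cross)
    fragments.extend(Fragment(a) for a in leftovers)
    fragments.sort(key=lambda f: (f.first.chrom, f.start, f.first.read_id))
    return fragments
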