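"""Synthetic loci, reads and exact spliced alignments.

Every stage of the assembler is testable without an external aligner: a
:class:`GeneModel` describes a multi-exon locus with several isoforms at
distinct abundances; :func:`simulate_reads` samples fixed-length reads
uniformly along each transcript (isoform chosen proportionally to
abundance x length) and writes their *exact* spliced alignments as a sorted
SAM with split CIGARs across junctions, plus the ground-truth GTF.  Toy
splice graphs with hand-set edge weights are provided for exercising the
flow decomposition in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .splice_graph import GraphEdge, GraphNode, SpliceGraph
from .transcript_io import TranscriptRecord, write_gtf

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """A gene locus: disjoint sorted exons and isoforms over them."""

    chrom: str
    exons: list[tuple[int, int]]
    isoforms: list[tuple[tuple[int, ...], float]]  # (exon indices, abundance)
    chrom_length: int = 100_000

    def isoform_exons(self, k: int) -> list[tuple[int, int]]:
        return [self.exons[i] for i in self.isoforms[k][0]]

    def isoform_length(self, k: int) -> int:
        return sum(e - s for s, e in self.isoform_exons(k))

    def to_records(self, gene_id: str = "gene1") -> list[TranscriptRecord]:
        return [
            TranscriptRecord(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.iso{k + 1}",
                chrom=self.chrom,
                exons=self.isoform_exons(k),
                score=ab,
            )
            for k, (_, ab) in enumerate(self.isoforms)
        ]


def three_isoform_gene() -> GeneModel:
    """Default test locus: 5 exons, 3 isoforms at abundances 1:2:4.

    The middle exons are mutually exclusive, so the three isoforms share
    their first and last exon, carry pairwise distinct junctions, and have
    identical length.  Equal lengths matter: a path's flow estimates the
    number of reads crossing its junctions, which for unequal transcript
    lengths would be length-biased; here the recovered flow ratios estimate
    the abundance ratios directly.
    """
    return GeneModel(
        chrom="chrS",
        exons=[(100, 180), (260, 340), (420, 500), (580, 660), (740, 820)],
        isoforms=[
            ((0, 1, 4), 1.0),
            ((0, 2, 4), 2.0),
            ((0, 3, 4), 4.0),
        ],
    )


def skipped_exon_gene() -> GeneModel:
    """Nested exon-skipping locus (full form / one skip / two skips).

    Unlike :func:`three_isoform_gene` the transcripts differ in length, so
    recovered flows are junction read counts, not abundance estimates.
    """
    return GeneModel(
        chrom="chrS",
        exons=[(100, 400), (500, 700), (800, 1100), (1200, 1400), (1500, 1900)],
        isoforms=[
            ((0, 1, 2, 3, 4), 1.0),
            ((0, 1, 3, 4), 2.0),
            ((0, 3, 4), 4.0),
        ],
    )


def two_isoform_gene(ratio: float = 4.0) -> GeneModel:
    """Minimal skipped-exon locus: inclusion at 1, skipping at ``ratio``."""
    return GeneModel(
        chrom="chrS",
        exons=[(100, 400), (500, 700), (800, 1200)],
        isoforms=[((0, 1, 2), 1.0), ((0, 2), ratio)],
    )


@dataclass
class SimulatedRead:
    """Ground truth for one simulated read (first mate if paired)."""

    read_id: str
    isoform: int
    blocks: list[tuple[int, int]]
    mate_blocks: list[tuple[int, int]] | None = None


def _tx_to_genome(
    exons: list[tuple[int, int]], tx_start: int, length: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval onto genomic blocks."""
    blocks: list[tuple[int, int]] = []
    offset = 0
    remaining = length
    for s, e in exons:
        exon_len = e - s
        if tx_start >= offset + exon_len:
            offset += exon_len
            continue
        local = max(tx_start - offset, 0)
        take = min(exon_len - local, remaining)
        blocks.append((s + local, s + local + take))
        remaining -= take
        offset += exon_len
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends past transcript end")
    return blocks


def _cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def simulate_reads(
    model: GeneModel,
    read_len: int = 50,
    n_reads: int = 6000,
    paired: bool = False,
    frag_len: int = 200,
    seed: int = 0,
    out_sam: str | Path = "reads.sam",
    out_gtf: str | Path = "truth.gtf",
    gene_id: str = "gene1",
) -> list[SimulatedRead]:
    """Sample error-free reads and write their exact alignments.

    Isoforms are drawn with probability proportional to abundance x length;
    start positions are uniform along the transcript (fragments, in paired
    mode, with a fixed fragment length).  The SAM is coordinate-sorted and
    fully deterministic given ``seed``; the truth GTF carries the model's
    isoforms with abundances as scores.  Isoforms shorter than the read
    (or fragment) are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    span = frag_len if paired else read_len
    usable = [k for k in range(len(model.isoforms)) if model.isoform_length(k) >= span]
    if len(usable) < len(model.isoforms):
        logger.warning(
            "%d isoforms shorter than %d bp skipped",
            len(model.isoforms) - len(usable), span,
        )
    truth = model.to_records(gene_id)
    write_gtf(truth, out_gtf)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": model.chrom, "LN": model.chrom_length}],
        }
    )
    reads: list[SimulatedRead] = []
    if usable and n_reads > 0:
        weights = np.array(
            [model.isoforms[k][1] * model.isoform_length(k) for k in usable]
        )
        probs = weights / weights.sum()
        choices = rng.choice(len(usable), size=n_reads, p=probs)
        for i, c in enumerate(choices):
            k = usable[c]
            exons = model.isoform_exons(k)
            tx_len = model.isoform_length(k)
            start = int(rng.integers(0, tx_len - span + 1))
            blocks = _tx_to_genome(exons, start, read_len)
            mate = None
            if paired:
                mate = _tx_to_genome(exons, start + frag_len - read_len, read_len)
            reads.append(SimulatedRead(f"read{i}", k, blocks, mate))

    segments: list[pysam.AlignedSegment] = []
    for r in reads:
        first = pysam.AlignedSegment(header)
        first.query_name = r.read_id
        first.reference_id = 0
        first.reference_start = r.blocks[0][0]
        first.cigarstring = _cigar(r.blocks)
        first.mapping_quality = 60
        if r.mate_blocks is None:
            first.flag = 0
            segments.append(first)
        else:
            second = pysam.AlignedSegment(header)
            second.query_name = r.read_id
            second.reference_id = 0
            second.reference_start = r.mate_blocks[0][0]
            second.cigarstring = _cigar(r.mate_blocks)
            second.mapping_quality = 60
            first.flag = 0x1 | 0x2 | 0x20 | 0x40
            second.flag = 0x1 | 0x2 | 0x10 | 0x80
            first.next_reference_id = 0
            first.next_reference_start = second.reference_start
            second.next_reference_id = 0
            second.next_reference_start = first.reference_start
            tlen = r.mate_blocks[-1][1] - r.blocks[0][0]
            first.template_length = tlen
            second.template_length = -tlen
            segments.extend([first, second])
    segments.sort(key=lambda s: (s.reference_start, s.query_name, s.flag))
    with pysam.AlignmentFile(str(out_sam), "wh", header=header) as fh:
        for seg in segments:
            fh.write(seg)
    return reads


def write_random_genome(
    path: str | Path, chrom_lengths: dict[str, int], seed: int = 0
) -> None:
    """Random uniform-base FASTA (wrapped at 60 columns) for sequence tests."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            seq = "".join(rng.choice(bases, size=length))
            fh.write(f">{chrom}\n")
            for i in range(0, length, 60):
                fh.write(seq[i:i + 60] + "\n")


def graph_from_paths(
    paths: list[tuple[tuple[int, ...], float]], n_nodes: int | None = None
) -> SpliceGraph:
    """Build a splice graph whose edge weights are a known path superposition.

    Nodes are laid out left to right with intronic gaps (node ``i`` spans
    ``[300*i, 300*i + 200)``); each path is a strictly increasing node
    sequence carrying a flow weight, and edge weights are the sums of the
    flows traversing them.  Used to test that sparse decomposition recovers
    a ground-truth path set exactly.
    """
    if n_nodes is None:
        n_nodes = 1 + max(max(p) for p, _ in paths)
    used = sorted({i for p, _ in paths for i in p})
    nodes = [GraphNode(i, "toy", 300 * i, 300 * i + 200, 10.0) for i in used]
    weights: dict[tuple[int, int], float] = {}
    for p, w in paths:
        if list(p) != sorted(set(p)):
            raise ValueError("paths must be strictly increasing node sequences")
        for u, v in zip(p, p[1:]):
            weights[(u, v)] = weights.get((u, v), 0.0) + w
    edges = [GraphEdge(u, v, w) for (u, v), w in sorted(weights.items())]
    return SpliceGraph("toy", nodes, edges)


def _toy(nodes_spec, edges_spec, known=()):
    letters = [l for l, _, _ in nodes_spec]
    ids = {l: i for i, l in enumerate(letters)}
    nodes = [
        GraphNode(ids[l], "toy", s, e, coverage=10.0) for l, s, e in nodes_spec
    ]
    edges = [GraphEdge(ids[u], ids[v], float(w)) for u, v, w in edges_spec]
    paths = {tuple(ids[l] for l in t) for t in known}
    return SpliceGraph("toy", nodes, edges, paths), ids


def toy_splice_graph(name: str) -> tuple[SpliceGraph, dict[str, int]]:
    """Hand-built demonstration graphs for the flow decomposition.

    ``two_path``
        Two isoforms at abundance 1 and 4 sharing the middle node; the
        weights alone pin down the correct two-path decomposition
        (A->C->E = 1, B->C->D = 4).
    ``greedy_trap``
        Three paths (A->C->E = 15, B->C->D = 10, F->C->D = 8) whose summed
        edge weights lure a heaviest-path-first strategy into extracting
        the non-existent A->C->D; sparse decomposition recovers all three.
    ``tied_ambiguity``
        Node C admits two equally sparse 3-flow decompositions; the known
        path (A, C, D) selects the one containing the A->D pairing.

    Returns the graph plus a letter -> node-id map.
    """
    if name == "two_path":
        return _toy(
            [("A", 0, 100), ("B", 150, 250), ("C", 300, 400),
             ("D", 450, 550), ("E", 600, 700)],
            [("A", "C", 1), ("B", "C", 4), ("C", "E", 1), ("C", "D", 4)],
        )
    if name == "greedy_trap":
        return _toy(
            [("A", 0, 100), ("B", 150, 250), ("F", 260, 360), ("C", 400, 500),
             ("E", 550, 650), ("D", 700, 800)],
            [("A", "C", 15), ("B", "C", 10), ("F", "C", 8),
             ("C", "E", 15), ("C", "D", 18)],
        )
    if name == "tied_ambiguity":
        return _toy(
            [("A", 0, 100), ("B", 150, 250), ("C", 300, 400),
             ("E", 450, 550), ("D", 600, 700)],
            [("A", "C", 5), ("B", "C", 4), ("C", "E", 6), ("C", "D", 3)],
            known=[("A", "C", "D")],
        )
    raise ValueError(f"unknown toy graph: {name}")
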