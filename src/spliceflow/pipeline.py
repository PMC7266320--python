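"""End-to-end assembly: alignments in, transcript records out."""

from __future__ import annotations

import logging
from pathlib import Path

from joblib import Parallel, delayed

from .alignment_io import Fragment, ReadAlignment, pair_fragments, parse_alignments
from .config import RunConfig
from .sparse_flow import decompose_graph
from .splice_graph import build_splice_graph
from .transcript_io import TranscriptRecord, records_from_transcripts

logger = logging.getLogger(__name__)


def assemble_alignments(
    alignments: list[ReadAlignment],
    fragments: list[Fragment] | None = None,
    config: RunConfig | None = None,
) -> list[TranscriptRecord]:
    """Build per-locus splice graphs and decompose each into transcripts.

    Loci are independent; with ``config.processes > 1`` they are decomposed
    in parallel and merged back in deterministic chromosome/coordinate
    order.
    """
    config = config or RunConfig()
    graphs = build_splice_graph(alignments, fragments, config.graph)
    logger.info("built %d locus graphs (%d nodes, %d edges)",
                len(graphs), sum(len(g.nodes) for g in graphs),
                sum(len(g.edges) for g in graphs))
    if config.processes > 1 and len(graphs) > 1:
        per_graph = Parallel(n_jobs=config.processes)(
            delayed(decompose_graph)(g, config.flow) for g in graphs
        )
    else:
        per_graph = [decompose_graph(g, config.flow) for g in graphs]
    records: list[TranscriptRecord] = []
    gene_counter: dict[str, int] = {}
    for graph, txs in zip(graphs, per_graph):
        gene_counter[graph.chrom] = gene_counter.get(graph.chrom, 0) + 1
        gene_id = f"{graph.chrom}.g{gene_counter[graph.chrom]}"
        records.extend(records_from_transcripts(txs, gene_id))
    logger.info("assembled %d transcripts", len(records))
    return records


def assemble(
    alignment_path: str | Path,
    config: RunConfig | None = None,
) -> list[TranscriptRecord]:
    """Assemble transcripts from a SAM/BAM file."""
    config = config or RunConfig()
    alignments = list(
        parse_alignments(
            str(alignment_path),
            region=config.chromosome,
            min_intron=config.graph.min_intron,
        )
    )
    logger.info("parsed %d alignments", len(alignments))
    fragments = pair_fragments(alignments)
    return assemble_alignments(alignments, fragments, config)
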