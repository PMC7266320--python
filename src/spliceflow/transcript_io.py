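"""Serialize assembled transcripts to GTF and FASTA."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from pyfaidx import Fasta

from .sparse_flow import Transcript

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class TranscriptRecord:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str = "."
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    score: float = 0.0

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def records_from_transcripts(
    transcripts: list[Transcript], gene_id: str, prefix: str = "tx"
) -> list[TranscriptRecord]:
    return [
        TranscriptRecord(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.{prefix}{i + 1}",
            chrom=t.chrom,
            exons=list(t.exons),
            score=t.weight,
        )
        for i, t in enumerate(transcripts)
    ]


def write_gtf(records: list[TranscriptRecord], path: str | Path) -> None:
    """Write GTF 2.2 (transcript + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for rec in records:
            attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}";'
            score = f"{rec.score:.6g}"
            fh.write(
                f"{rec.chrom}\tspliceflow\ttranscript\t{rec.start + 1}\t{rec.end}\t"
                f"{score}\t{rec.strand}\t.\t{attrs}\n"
            )
            for s, e in rec.exons:
                fh.write(
                    f"{rec.chrom}\tspliceflow\texon\t{s + 1}\t{e}\t{score}\t"
                    f"{rec.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Read transcript models (exon features grouped by transcript_id)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, TranscriptRecord] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes.get("gene_id", [tx_id])[0]
        rec = by_tx.setdefault(
            tx_id,
            TranscriptRecord(
                gene_id=gene_id,
                transcript_id=tx_id,
                chrom=feat.seqid,
                strand=feat.strand or ".",
            ),
        )
        try:
            rec.score = float(feat.score)
        except (TypeError, ValueError):
            pass
        rec.exons.append((feat.start - 1, feat.end))
    for rec in by_tx.values():
        rec.exons.sort()
    return sorted(by_tx.values(), key=lambda r: (r.chrom, r.start, r.transcript_id))


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def write_fasta(
    records: list[TranscriptRecord], genome_path: str | Path, path: str | Path
) -> None:
    """Emit spliced transcript sequences ('-' strand reverse-complemented)."""
    genome = Fasta(str(genome_path))
    with open(path, "w") as fh:
        for rec in records:
            if rec.chrom not in genome:
                logger.error("chromosome %s missing from genome; %s skipped",
                             rec.chrom, rec.transcript_id)
                continue
            seq = "".join(str(genome[rec.chrom][s:e]) for s, e in rec.exons)
            if rec.strand == "-":
                seq = seq.translate(_COMPLEMENT)[::-1]
            fh.write(f">{rec.transcript_id}\n")
            if seq:
                fh.write(_wrap(seq) + "\n")
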