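"""Transcript annotation from BED12 and exon/intron localization.

Transcript models come from a UCSC-table-browser-style BED12 file: each line
is one transcript, with exons encoded as blocks (0-based, half-open). Blocks
are converted to 1-based inclusive exon intervals:

    exon_start = chromStart + blockStart + 1
    exon_end   = exon_start + blockSize - 1

Exon numbering follows transcription order, so on the minus strand exon 1 is
the genomically last block — the convention used in clinical variant
reporting. A genomic position inside a transcript's span is therefore either
in exon k or in intron k (the intron following transcription-order exon k);
the two cases partition the span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .errors import AnnotationParseError

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptAnnotation",
    "TranscriptLocation",
    "build_annotation",
    "locate",
    "read_gene_map",
]


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript: ordered, non-overlapping 1-based inclusive exons."""

    transcript_id: str
    gene: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]  # sorted by genomic start

    def __post_init__(self) -> None:
        for start, end in self.exons:
            if start > end:
                raise AnnotationParseError(
                    f"{self.transcript_id}: exon start {start} > end {end}"
                )
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise AnnotationParseError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class TranscriptLocation:
    """Where a position falls within one transcript.

    ``region`` is "exon", "intron" or "outside"; ``k`` is the 1-based index in
    transcription order (0 for "outside").
    """

    transcript_id: str
    gene: str
    region: str
    k: int

    def render(self) -> str:
        if self.region == "outside":
            return f"{self.transcript_id}: outside"
        return f"{self.transcript_id}: {self.region} {self.k}"


def build_annotation(
    bed_path: str | Path,
    gene_map: dict[str, str] | None = None,
    bed_columns_offset: int = 0,
) -> list[TranscriptAnnotation]:
    """Parse a BED12 file into transcript annotations.

    ``gene_map`` (transcript id → gene symbol) overrides the gene symbol,
    which otherwise falls back to the BED name field. Extra columns that a
    table-browser export prepends are skipped with ``bed_columns_offset``.
    """
    gene_map = gene_map or {}
    out: list[TranscriptAnnotation] = []
    with open(bed_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")[bed_columns_offset:]
            if len(fields) < 12:
                raise AnnotationParseError(
                    f"expected 12 BED columns, found {len(fields)}",
                    line_number=lineno,
                )
            out.append(_parse_bed12_line(fields, gene_map, lineno))
    logger.info("Built annotation for %d transcripts from %s", len(out), bed_path)
    return out


def _parse_bed12_line(
    fields: list[str], gene_map: dict[str, str], lineno: int
) -> TranscriptAnnotation:
    chrom = fields[0]
    try:
        chrom_start = int(fields[1])
        chrom_end = int(fields[2])
        block_count = int(fields[9])
    except ValueError as exc:
        raise AnnotationParseError(f"non-integer BED field: {exc}", line_number=lineno)
    name = fields[3]
    strand = fields[5]
    if strand not in ("+", "-"):
        raise AnnotationParseError(
            f"strand must be + or -, found {strand!r}", line_number=lineno
        )
    sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x != ""]
    starts = [int(x) for x in fields[11].rstrip(",").split(",") if x != ""]
    if len(sizes) != block_count or len(starts) != block_count:
        raise AnnotationParseError(
            f"blockCount={block_count} but {len(sizes)} blockSizes and "
            f"{len(starts)} blockStarts",
            line_number=lineno,
        )
    exons = []
    for size, start in zip(sizes, starts):
        exon_start = chrom_start + start + 1
        exon_end = exon_start + size - 1
        if exon_end > chrom_end:
            raise AnnotationParseError(
                f"block [{exon_start},{exon_end}] extends past chromEnd {chrom_end}",
                line_number=lineno,
            )
        exons.append((exon_start, exon_end))
    return TranscriptAnnotation(
        transcript_id=name,
        gene=gene_map.get(name, name),
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
    )


def locate(
    annotations: list[TranscriptAnnotation], chrom: str, pos: int
) -> list[TranscriptLocation]:
    """Localize a 1-based genomic position within every overlapping transcript.

    For each transcript on ``chrom`` whose span contains ``pos``, returns
    exon k (transcription order) if the position is inside the k-th exon,
    else intron k where k indexes the transcription-order exon preceding the
    gap. Transcripts not containing the position are omitted.
    """
    hits: list[TranscriptLocation] = []
    for tx in annotations:
        if tx.chrom != chrom:
            continue
        span_start, span_end = tx.span
        if not span_start <= pos <= span_end:
            continue
        hits.append(_locate_in_transcript(tx, pos))
    return hits


def _locate_in_transcript(tx: TranscriptAnnotation, pos: int) -> TranscriptLocation:
    n = tx.n_exons
    for genomic_idx, (start, end) in enumerate(tx.exons):
        if start <= pos <= end:
            k = genomic_idx + 1 if tx.strand == "+" else n - genomic_idx
            return TranscriptLocation(tx.transcript_id, tx.gene, "exon", k)
        if pos < start:
            # pos is in the intron before this exon (genomically)
            k = genomic_idx if tx.strand == "+" else n - genomic_idx
            return TranscriptLocation(tx.transcript_id, tx.gene, "intron", k)
    raise AssertionError("position inside span but not located")  # pragma: no cover


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Two-column headerless TSV: transcript id → gene symbol."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                out[parts[0].strip()] = parts[1].strip()
    return out
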