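"""VCF ingest and the internal variant table.

The whole workflow operates on a small in-memory model of a VCF file: per-site
records with resolved per-sample genotypes. Only CHROM/POS/ID/REF/ALT/QUAL/
FILTER and the GT subfield of FORMAT are interpreted; INFO and the remaining
FORMAT subfields are carried as opaque strings so records can be round-tripped.
Positions are 1-based throughout, exactly as printed in a VCF.

Genotype semantics:

* ``/`` and ``|`` separators are treated identically (phase is recorded but
  never consulted downstream).
* any missing allele index (``./.``, ``./1``) makes the genotype a no-call;
* a single-index genotype (haploid, e.g. Y or mitochondria) is modelled with
  an absent second allele and classed as hemizygous downstream.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from .errors import DataError, VcfParseError

logger = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "VariantRecord",
    "FileAttributes",
    "VcfTable",
    "ChromosomeMap",
    "read_vcf",
    "write_vcf",
    "rename_chromosomes",
    "extract_sample",
    "read_chromosome_map",
]


@dataclass(frozen=True)
class Genotype:
    """One sample's genotype at one site.

    ``alleles`` holds 1 (haploid) or 2 allele indices; ``None`` marks a
    missing index. A genotype with any missing index is a no-call.
    """

    alleles: tuple[int | None, ...]
    phased: bool = False

    @property
    def is_called(self) -> bool:
        return all(a is not None for a in self.alleles)

    @property
    def is_haploid(self) -> bool:
        return len(self.alleles) == 1

    @property
    def is_diploid_call(self) -> bool:
        return len(self.alleles) == 2 and self.is_called

    @property
    def is_het(self) -> bool:
        """True for a fully-called diploid genotype with two distinct alleles."""
        return self.is_diploid_call and self.alleles[0] != self.alleles[1]

    def to_gt_string(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)

    @classmethod
    def from_gt_string(cls, gt: str) -> "Genotype":
        phased = "|" in gt
        parts = gt.replace("|", "/").split("/")
        if not 1 <= len(parts) <= 2:
            raise VcfParseError(f"cannot interpret GT field {gt!r}")
        alleles = tuple(None if p in (".", "") else int(p) for p in parts)
        return cls(alleles=alleles, phased=phased)


@dataclass
class VariantRecord:
    """One VCF data line with per-sample genotypes in table sample order."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: list[str]
    qual: float | None
    filter: str
    genotypes: list[Genotype]
    info: str = "."
    format: str = "GT"
    extra_format_fields: list[str] = field(default_factory=list)

    def allele_string(self, index: int) -> str:
        """Resolve an allele index against REF/ALT."""
        if index == 0:
            return self.ref
        if 1 <= index <= len(self.alt):
            return self.alt[index - 1]
        raise DataError(
            f"allele index {index} out of range at {self.chrom}:{self.pos} "
            f"(REF {self.ref}, {len(self.alt)} ALT allele(s))"
        )


@dataclass
class FileAttributes:
    """The bookkeeping echoed to the console after ingest."""

    n_meta_lines: int
    n_header_lines: int
    n_variants: int
    n_columns: int

    def render(self) -> str:
        return (
            f"meta lines: {self.n_meta_lines}\n"
            f"header lines: {self.n_header_lines}\n"
            f"variants: {self.n_variants}\n"
            f"columns: {self.n_columns}"
        )


@dataclass
class VcfTable:
    """A parsed VCF: ordered records, sample names, file attributes.

    Records are kept in file order; the table never re-sorts.
    """

    sample_names: list[str]
    records: list[VariantRecord]
    attributes: FileAttributes

    def __post_init__(self) -> None:
        if len(set(self.sample_names)) != len(self.sample_names):
            raise VcfParseError("duplicate sample names in #CHROM header")

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def sample_index(self, sample_name: str) -> int:
        try:
            return self.sample_names.index(sample_name)
        except ValueError:
            raise DataError(
                f"unknown sample {sample_name!r}; available samples: "
                + ", ".join(self.sample_names)
            ) from None

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.chrom)
        return list(seen)


@dataclass
class ChromosomeMap:
    """Source→target chromosome renaming; injective on its domain."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        targets = list(self.entries.values())
        if len(set(targets)) != len(targets):
            dupes = sorted({t for t in targets if targets.count(t) > 1})
            raise DataError(
                "chromosome map is not injective; duplicated target(s): "
                + ", ".join(dupes)
            )

    def inverse(self) -> "ChromosomeMap":
        return ChromosomeMap({v: k for k, v in self.entries.items()})


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    raw = open(path, "rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    raw.seek(0)
    return io.TextIOWrapper(raw, encoding="utf-8")


_FIXED_COLUMNS = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]


def read_vcf(path: str | Path) -> VcfTable:
    """Parse a plain or gzipped VCF v4.x file into a :class:`VcfTable`.

    The file must start with a ``##fileformat=VCF`` meta line and contain a
    ``#CHROM`` header line. Data lines whose column count disagrees with the
    header raise :class:`VcfParseError` with the offending line number.
    """
    n_meta = 0
    header_cols: list[str] | None = None
    records: list[VariantRecord] = []
    sample_names: list[str] = []

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if lineno == 1 and not line.startswith("##fileformat=VCF"):
                raise VcfParseError(
                    f"not a VCF file: expected '##fileformat=VCF...' as the "
                    f"first line, found {line[:60]!r}",
                    line_number=1,
                )
            if line.startswith("##"):
                if header_cols is not None:
                    raise VcfParseError(
                        "meta line after the #CHROM header", line_number=lineno
                    )
                n_meta += 1
                continue
            if line.startswith("#CHROM"):
                header_cols = line.split("\t")
                if header_cols[: len(_FIXED_COLUMNS)] != _FIXED_COLUMNS:
                    raise VcfParseError(
                        "malformed #CHROM header line: expected columns "
                        + "\\t".join(_FIXED_COLUMNS),
                        line_number=lineno,
                    )
                if len(header_cols) > 8:
                    if header_cols[8] != "FORMAT":
                        raise VcfParseError(
                            "9th header column must be FORMAT", line_number=lineno
                        )
                    sample_names = header_cols[9:]
                continue
            # data line
            if header_cols is None:
                raise VcfParseError(
                    "data line before the #CHROM header", line_number=lineno
                )
            fields = line.split("\t")
            if len(fields) != len(header_cols):
                raise VcfParseError(
                    f"expected {len(header_cols)} columns, found {len(fields)}",
                    line_number=lineno,
                )
            records.append(_parse_data_line(fields, sample_names, lineno))

    if header_cols is None:
        raise VcfParseError("no #CHROM header line found")

    attributes = FileAttributes(
        n_meta_lines=n_meta,
        n_header_lines=1,
        n_variants=len(records),
        n_columns=len(header_cols),
    )
    logger.info("Read VCF %s\n%s", path, attributes.render())
    return VcfTable(
        sample_names=list(sample_names), records=records, attributes=attributes
    )


def _parse_data_line(
    fields: list[str], sample_names: list[str], lineno: int
) -> VariantRecord:
    chrom, pos_s, vid, ref, alt_s, qual_s, filt, info = fields[:8]
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfParseError(f"non-integer POS {pos_s!r}", line_number=lineno)
    if pos < 1:
        raise VcfParseError(f"POS must be >= 1, found {pos}", line_number=lineno)
    if not ref:
        raise VcfParseError("empty REF allele", line_number=lineno)
    alt = [] if alt_s in (".", "") else alt_s.split(",")
    qual = None if qual_s in (".", "") else float(qual_s)

    genotypes: list[Genotype] = []
    fmt = "GT"
    extras: list[list[str]] = []
    if sample_names:
        fmt = fields[8]
        fmt_keys = fmt.split(":")
        try:
            gt_at = fmt_keys.index("GT")
        except ValueError:
            raise VcfParseError("FORMAT lacks a GT subfield", line_number=lineno)
        for col in fields[9:]:
            sub = col.split(":")
            genotypes.append(Genotype.from_gt_string(sub[gt_at]))
            extras.append(sub)
        n_alleles = 1 + len(alt)
        for sample, gt in zip(sample_names, genotypes):
            for a in gt.alleles:
                if a is not None and not 0 <= a < n_alleles:
                    raise VcfParseError(
                        f"sample {sample}: allele index {a} out of range "
                        f"for a site with {n_alleles - 1} ALT allele(s)",
                        line_number=lineno,
                    )
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        id=vid,
        ref=ref,
        alt=alt,
        qual=qual,
        filter=filt,
        genotypes=genotypes,
        info=info,
        format=fmt,
        extra_format_fields=[":".join(e) for e in extras],
    )


def write_vcf(table: VcfTable, path: str | Path, contigs: Iterable[str] | None = None) -> None:
    """Write a table back out as a minimal VCF (``##fileformat``, ``##contig``
    lines and the ``#CHROM`` header). Genotypes are emitted as bare GT."""
    path = Path(path)
    if contigs is None:
        contigs = table.chromosomes()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        cols = _FIXED_COLUMNS[:]
        if table.sample_names:
            cols += ["FORMAT"] + table.sample_names
        fh.write("\t".join(cols) + "\n")
        for rec in table.records:
            alt = ",".join(rec.alt) if rec.alt else "."
            qual = "." if rec.qual is None else f"{rec.qual:g}"
            fields = [rec.chrom, str(rec.pos), rec.id, rec.ref, alt, qual, rec.filter, rec.info]
            if table.sample_names:
                fields.append("GT")
                fields += [gt.to_gt_string() for gt in rec.genotypes]
            fh.write("\t".join(fields) + "\n")


def rename_chromosomes(
    table: VcfTable, cmap: ChromosomeMap
) -> tuple[VcfTable, list[str]]:
    """Apply a chromosome-name map to every record.

    Returns the renamed table and the chromosome names that had no entry in
    the map (deduplicated, first-seen order). Record order is preserved and
    unmapped records are left untouched; an unmapped name is a report, not an
    error.
    """
    if not cmap.entries:
        raise DataError("chromosome map is empty")
    unmapped: dict[str, None] = {}
    new_records = []
    for rec in table.records:
        target = cmap.entries.get(rec.chrom)
        if target is None:
            unmapped.setdefault(rec.chrom)
            new_records.append(rec)
        else:
            new_records.append(replace(rec, chrom=target))
    renamed = VcfTable(
        sample_names=list(table.sample_names),
        records=new_records,
        attributes=table.attributes,
    )
    if unmapped:
        logger.warning(
            "chromosome names without a map entry (left unchanged): %s",
            ", ".join(unmapped),
        )
    return renamed, list(unmapped)


def extract_sample(table: VcfTable, sample_name: str) -> VcfTable:
    """Single-sample view of a multi-sample table.

    All records are preserved — including sites where this sample is
    homozygous-reference or a no-call — because the downstream report must
    account for every locus of interest.
    """
    idx = table.sample_index(sample_name)
    records = [
        replace(rec, genotypes=[rec.genotypes[idx]], extra_format_fields=[])
        for rec in table.records
    ]
    attrs = FileAttributes(
        n_meta_lines=table.attributes.n_meta_lines,
        n_header_lines=table.attributes.n_header_lines,
        n_variants=table.attributes.n_variants,
        n_columns=10,
    )
    return VcfTable(sample_names=[sample_name], records=records, attributes=attrs)


def read_chromosome_map(path: str | Path) -> ChromosomeMap:
    """Read a two-column headerless TSV (source name, target name)."""
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(
                    f"chromosome map {path}, line {lineno}: expected two "
                    f"tab-separated columns, found {len(parts)}"
                )
            entries[parts[0].strip()] = parts[1].strip()
    return ChromosomeMap(entries)
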