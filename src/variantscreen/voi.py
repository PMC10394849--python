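"""Variants-of-interest catalogue: parsing, schema adaptation and QC.

A VOI table lists known phenotype-associated variants — at minimum the
chromosome, 1-based position, gene symbol and genome assembly each variant was
mapped to. Catalogues exported from OMIA (Online Mendelian Inheritance in
Animals) are adapted automatically through a built-in column preset;
user-defined files supply an explicit column map when their headers differ
from the canonical schema.

Because such catalogues are curated by hand, they are screened before
filtering: rows missing the chromosome, position or assembly are dropped,
rows mapped to a different assembly than the VCF's are excluded, and — when a
reference FASTA is supplied — the catalogued reference base is checked against
the genome. Mismatches are flagged for manual review, never silently dropped.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .errors import VoiFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "InheritancePattern",
    "VariantOfInterest",
    "VoiTable",
    "VoiQcReport",
    "parse_voi",
    "qc_voi",
    "CANONICAL_COLUMNS",
    "OMIA_COLUMN_MAP",
]


class InheritancePattern(Enum):
    AUTOSOMAL_DOMINANT = "Autosomal dominant"
    AUTOSOMAL_RECESSIVE = "Autosomal recessive"
    MITOCHONDRIAL = "Mitochondrial"
    X_LINKED_DOMINANT = "X linked dominant"
    X_LINKED_RECESSIVE = "X linked recessive"
    Y_LINKED = "Y linked"
    UNKNOWN = "NA"

    @classmethod
    def from_text(cls, text: str | None) -> "InheritancePattern":
        """Map a free-text inheritance cell onto the enum; blank or
        unrecognized values become UNKNOWN (which triggers the 'NA' advice)."""
        if text is None:
            return cls.UNKNOWN
        norm = re.sub(r"[\s_-]+", " ", text.strip().lower())
        table = {
            "autosomal dominant": cls.AUTOSOMAL_DOMINANT,
            "autosomal recessive": cls.AUTOSOMAL_RECESSIVE,
            "mitochondrial": cls.MITOCHONDRIAL,
            "x linked dominant": cls.X_LINKED_DOMINANT,
            "x linked recessive": cls.X_LINKED_RECESSIVE,
            "y linked": cls.Y_LINKED,
        }
        return table.get(norm, cls.UNKNOWN)


@dataclass
class VariantOfInterest:
    """One catalogued phenotype-associated variant."""

    chrom: str
    pos: int | None  # 1-based; None if the cell was blank (dropped in QC)
    gene: str
    ref_allele: str | None
    var_allele: str | None
    inheritance: InheritancePattern
    phenotype: str
    breeds: list[str]
    assembly: str
    species: str = ""
    source_row: int = 0  # 1-based data-row number in the input file
    extras: dict[str, str] = field(default_factory=dict)
    ref_mismatch: tuple[str, str] | None = None  # (expected base, genome base)

    @property
    def is_complete(self) -> bool:
        return bool(self.chrom.strip()) and self.pos is not None and bool(
            self.assembly.strip()
        )


@dataclass
class VoiTable:
    rows: list[VariantOfInterest]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self.rows:
            seen.setdefault(row.chrom)
        return list(seen)


@dataclass
class VoiQcReport:
    """What QC did, row by row: dropped, excluded, and flagged-but-retained."""

    n_input: int
    dropped_incomplete: list[int]
    excluded_assembly: list[int]
    mismatched_reference: list[tuple[int, str, str]]
    unverifiable: list[int] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - len(self.dropped_incomplete) - len(self.excluded_assembly)

    def render(self) -> str:
        lines = [
            f"VOI rows read: {self.n_input}",
            f"dropped (missing chromosome/position/assembly): "
            f"{len(self.dropped_incomplete)} {self.dropped_incomplete or ''}".rstrip(),
            f"excluded (other assembly): "
            f"{len(self.excluded_assembly)} {self.excluded_assembly or ''}".rstrip(),
            f"reference-base mismatches (retained, check manually): "
            f"{len(self.mismatched_reference)}",
        ]
        for row, expected, found in self.mismatched_reference:
            lines.append(
                f"  row {row}: catalogue says {expected!r}, genome has {found!r}"
                " — please check this location manually"
            )
        if self.unverifiable:
            lines.append(
                f"rows on chromosomes absent from the reference (unverifiable): "
                f"{self.unverifiable}"
            )
        lines.append(f"rows retained: {self.n_retained}")
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["source_row", "category", "detail"])
            for r in self.dropped_incomplete:
                w.writerow([r, "dropped_incomplete", ""])
            for r in self.excluded_assembly:
                w.writerow([r, "excluded_assembly", ""])
            for r, expected, found in self.mismatched_reference:
                w.writerow([r, "mismatched_reference", f"expected={expected};found={found}"])
            for r in self.unverifiable:
                w.writerow([r, "unverifiable", "chromosome absent from reference"])


CANONICAL_COLUMNS = {
    "chrom": ("chrom", "chromosome", "chr"),
    "pos": ("pos", "position", "location", "start"),
    "gene": ("gene", "gene symbol"),
    "ref_allele": ("ref", "ref_allele", "reference", "reference allele"),
    "var_allele": ("alt", "var_allele", "variant", "variant allele"),
    "inheritance": ("inheritance", "inheritance pattern", "mode of inheritance"),
    "phenotype": ("phenotype", "phene", "disease", "trait"),
    "breeds": ("breed", "breeds"),
    "assembly": ("assembly", "genome assembly", "reference genome", "genome_build"),
    "species": ("species",),
}

# Header preset for catalogues exported from OMIA. OMIA's export dialect is
# not under our control, so the preset is data, not logic: override any entry
# with an explicit column_map if the export format changes.
OMIA_COLUMN_MAP = {
    "chrom": "Chr",
    "pos": "g. or m. (pos)",
    "gene": "Gene",
    "ref_allele": "Reference Allele",
    "var_allele": "Variant Allele",
    "inheritance": "Mode of Inheritance",
    "phenotype": "Phene",
    "breeds": "Breed(s)",
    "assembly": "Genome Assembly",
    "species": "Species Name",
}

_BREED_SPLIT = re.compile(r"[;,/]| and ")


def _parse_breeds(cell: str) -> list[str]:
    return [b.strip() for b in _BREED_SPLIT.split(cell) if b.strip()]


def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override:
        return override
    return "," if path.suffix.lower() == ".csv" else "\t"


def parse_voi(
    path: str | Path,
    source: str = "USER",
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> VoiTable:
    """Read a delimited VOI catalogue into the canonical schema.

    ``source`` is ``"OMIA"`` (apply the built-in OMIA header preset) or
    ``"USER"``. ``column_map`` maps canonical field names to this file's
    header names and, for USER files, is merged over a case-insensitive match
    of common synonyms. Unrecognized columns are preserved as opaque extras;
    the breeds cell is split on ``;``, ``,``, ``/`` or `` and ``.
    """
    path = Path(path)
    source = source.upper()
    if source not in ("OMIA", "USER"):
        raise VoiFormatError(f"source must be OMIA or USER, got {source!r}")
    delim = _sniff_delimiter(path, delimiter)

    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise VoiFormatError(f"{path}: empty file") from None
        raw_rows = [row for row in reader if any(cell.strip() for cell in row)]

    header = [h.strip() for h in header]
    mapping = _resolve_columns(header, source, column_map, path)

    rows: list[VariantOfInterest] = []
    mapped_headers = set(mapping.values())
    for i, raw in enumerate(raw_rows, start=1):
        cells = dict(zip(header, raw + [""] * (len(header) - len(raw))))

        def get(field_name: str) -> str:
            col = mapping.get(field_name)
            return cells.get(col, "").strip() if col else ""

        pos_text = get("pos").replace(",", "")
        pos = int(pos_text) if re.fullmatch(r"\d+", pos_text) else None
        rows.append(
            VariantOfInterest(
                chrom=get("chrom"),
                pos=pos,
                gene=get("gene"),
                ref_allele=get("ref_allele") or None,
                var_allele=get("var_allele") or None,
                inheritance=InheritancePattern.from_text(get("inheritance")),
                phenotype=get("phenotype"),
                breeds=_parse_breeds(get("breeds")),
                assembly=get("assembly"),
                species=get("species"),
                source_row=i,
                extras={
                    h: cells.get(h, "") for h in header if h not in mapped_headers
                },
            )
        )
    logger.info("Parsed %d VOI rows from %s (%s dialect)", len(rows), path, source)
    return VoiTable(rows)


def _resolve_columns(
    header: list[str],
    source: str,
    column_map: dict[str, str] | None,
    path: Path,
) -> dict[str, str]:
    mapping: dict[str, str] = {}
    if source == "OMIA":
        preset = dict(OMIA_COLUMN_MAP)
        if column_map:
            preset.update(column_map)
        present = {k: v for k, v in preset.items() if v in header}
        if not present:
            raise VoiFormatError(
                f"{path}: none of the expected OMIA headers "
                f"({', '.join(sorted(preset.values()))}) are present; "
                "if this is a user-defined file, use source=USER with an "
                "explicit column_map"
            )
        mapping = present
    else:
        lower = {h.lower(): h for h in header}
        for field_name, synonyms in CANONICAL_COLUMNS.items():
            for syn in synonyms:
                if syn in lower:
                    mapping[field_name] = lower[syn]
                    break
        if column_map:
            for field_name, col in column_map.items():
                if col in header:
                    mapping[field_name] = col
    missing = [f for f in ("chrom", "pos", "gene") if f not in mapping]
    if missing:
        raise VoiFormatError(
            f"{path}: required column(s) not found after mapping: "
            + ", ".join(missing)
        )
    return mapping


def qc_voi(
    voi: VoiTable,
    assembly: str | None = None,
    reference=None,
) -> tuple[VoiTable, VoiQcReport]:
    """Quality-control a parsed VOI table.

    Rows missing chromosome, position or assembly are dropped. If ``assembly``
    is given, rows labelled with a different assembly (compared after
    trimming and case-folding; no alias table) are excluded. If ``reference``
    (a ``pyfaidx.Fasta`` or any mapping of chromosome → indexable sequence)
    is given, the first base of each row's catalogued reference allele is
    compared case-insensitively with the genome base at its position;
    mismatching rows are flagged on the row and listed in the report but kept
    — the user is asked to check those locations manually. Input order is
    preserved; QC is idempotent.
    """
    clean: list[VariantOfInterest] = []
    dropped: list[int] = []
    excluded: list[int] = []
    mismatched: list[tuple[int, str, str]] = []
    unverifiable: list[int] = []

    want = assembly.strip().casefold() if assembly else None
    for row in voi:
        if not row.is_complete:
            dropped.append(row.source_row)
            continue
        if want is not None and row.assembly.strip().casefold() != want:
            excluded.append(row.source_row)
            continue
        # rows already flagged on a previous pass stay flagged but are not
        # re-reported, so a second QC pass over clean output is a no-op
        if reference is not None and row.ref_allele and row.ref_mismatch is None:
            found = _genome_base(reference, row.chrom, row.pos)
            if found is None:
                unverifiable.append(row.source_row)
            else:
                expected = row.ref_allele[0]
                if expected.upper() != found.upper():
                    mismatched.append((row.source_row, expected, found))
                    row.ref_mismatch = (expected, found)
        clean.append(row)

    report = VoiQcReport(
        n_input=len(voi),
        dropped_incomplete=dropped,
        excluded_assembly=excluded,
        mismatched_reference=mismatched,
        unverifiable=unverifiable,
    )
    logger.info("%s", report.render())
    return VoiTable(clean), report


def _genome_base(reference, chrom: str, pos: int) -> str | None:
    """Fetch the base at a 1-based position; None if the chromosome (or the
    position) is absent from the reference."""
    try:
        seq = reference[chrom]
    except (KeyError, IndexError):
        return None
    try:
        base = seq[pos - 1]
    except (IndexError, ValueError):
        return None
    base = str(base)
    return base if base else None
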