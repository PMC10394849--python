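"""The screening engine: zygosity calling at catalogued loci and breed-aware
partitioning of the results.

For one sample, every clean catalogue locus ends up in exactly one of three
variant tables:

* **priority** — the sample carries the variant (heterozygous, homozygous
  non-reference or hemizygous non-reference) or the locus could not be
  called, and the genotype–phenotype association is established in the
  queried breed;
* **other_breed** — same genotype classes, but the association is not known
  to segregate in that breed (requires careful interpretation — the
  association may be breed-specific);
* **hom_ref** — the sample is homozygous (or hemizygous) reference; the
  variant segregates elsewhere in the multi-sample VCF.

No locus is ever silently dropped: loci without a usable genotype — whether
the GT was missing or the site is absent from the VCF altogether — are
reported with an explicit no-call text, so the reader can never mistake "not
assessable" for "variant absent". Two advice lists pair each non-reference
row with the verbatim breeding-advice text for its inheritance pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable

from .advice import HETEROZYGOUS, HOMOZYGOUS, breeding_advice
from .annotation import TranscriptAnnotation, TranscriptLocation, locate
from .errors import DataError
from .vcf import VariantRecord, VcfTable
from .voi import InheritancePattern, VariantOfInterest, VoiTable

logger = logging.getLogger(__name__)

__all__ = [
    "Zygosity",
    "LocusStatus",
    "VariantReportRow",
    "FilterResult",
    "NO_CALL_TEXT",
    "NO_CALL_ZYGOSITY_TEXT",
    "call_zygosity",
    "filter_variants",
    "extra_filter",
]

NO_CALL_TEXT = "A call could not be made for this sample at this given locus"
NO_CALL_ZYGOSITY_TEXT = "Zygosity could not be determined"


class Zygosity(Enum):
    HOM_REF = "Homozygous reference"
    HET = "Heterozygous"
    HOM_NONREF = "Homozygous"
    HEMI_REF = "Hemizygous reference"
    HEMI_NONREF = "Hemizygous"
    NO_CALL = NO_CALL_ZYGOSITY_TEXT

    @property
    def is_nonref(self) -> bool:
        return self in (Zygosity.HET, Zygosity.HOM_NONREF, Zygosity.HEMI_NONREF)

    @property
    def is_ref(self) -> bool:
        return self in (Zygosity.HOM_REF, Zygosity.HEMI_REF)


class LocusStatus(Enum):
    CALLED = "called"
    MISSING_GT = "no call"            # site present, GT missing for this sample
    ABSENT_FROM_VCF = "not in VCF"    # site absent from the VCF entirely

    @property
    def is_no_call(self) -> bool:
        return self is not LocusStatus.CALLED


@dataclass
class VariantReportRow:
    """One report line: a catalogue locus as observed in one sample."""

    chrom: str
    pos: int
    gene: str
    ref_allele: str
    allele_1: str
    allele_2: str
    zygosity: Zygosity
    inheritance: InheritancePattern
    phenotype: str
    locus_status: LocusStatus
    annotations: list[TranscriptLocation] = field(default_factory=list)
    allele_mismatch: bool = False
    breeds: list[str] = field(default_factory=list)


@dataclass
class FilterResult:
    """The full partition of clean catalogue loci for one sample."""

    sample_name: str
    breed: str
    priority: list[VariantReportRow] = field(default_factory=list)
    other_breed: list[VariantReportRow] = field(default_factory=list)
    hom_ref: list[VariantReportRow] = field(default_factory=list)
    advice_hom: list[tuple[VariantReportRow, str]] = field(default_factory=list)
    advice_het: list[tuple[VariantReportRow, str]] = field(default_factory=list)

    @property
    def n_loci(self) -> int:
        return len(self.priority) + len(self.other_breed) + len(self.hom_ref)

    def no_call_rows(self) -> list[VariantReportRow]:
        return [
            r
            for r in self.priority + self.other_breed
            if r.locus_status.is_no_call
        ]


def call_zygosity(
    record: VariantRecord, sample_index: int, voi: VariantOfInterest | None = None
) -> tuple[Zygosity, str, str]:
    """Resolve one sample's genotype at one site into (zygosity, allele 1,
    allele 2) with allele indices mapped to allele strings.

    Any missing allele index is a no-call and both allele texts become the
    verbatim no-call sentence. A haploid genotype is hemizygous; its second
    allele renders as "-".
    """
    gt = record.genotypes[sample_index]
    if not gt.is_called:
        return Zygosity.NO_CALL, NO_CALL_TEXT, NO_CALL_TEXT
    if gt.is_haploid:
        zyg = Zygosity.HEMI_REF if gt.alleles[0] == 0 else Zygosity.HEMI_NONREF
        return zyg, record.allele_string(gt.alleles[0]), "-"
    i1, i2 = sorted(gt.alleles)  # 1/0 reports the same pair as 0/1
    a1, a2 = record.allele_string(i1), record.allele_string(i2)
    if i1 != i2:
        return Zygosity.HET, a1, a2
    if i1 == 0:
        return Zygosity.HOM_REF, a1, a2
    return Zygosity.HOM_NONREF, a1, a2


def _normalize_breed(name: str) -> str:
    return " ".join(name.split()).casefold()


def _breed_matches(query: str, breeds: Iterable[str]) -> bool:
    q = _normalize_breed(query)
    return any(q == _normalize_breed(b) for b in breeds)


def filter_variants(
    sample_view: VcfTable,
    voi: VoiTable,
    annotations: list[TranscriptAnnotation] | None = None,
    breed: str = "",
    progress: Callable[[int, int], None] | None = None,
) -> FilterResult:
    """Screen one sample against the clean catalogue.

    ``sample_view`` must be a single-sample table (see
    :func:`variantscreen.vcf.extract_sample`). Loci are matched on
    chromosome + position; a catalogued reference allele that disagrees with
    the VCF REF flags the row (``allele_mismatch``) but never changes the
    routing. ``progress``, if given, is called as ``progress(done, total)``
    after each catalogue row.
    """
    if len(sample_view.sample_names) != 1:
        raise DataError(
            f"filter_variants needs a single-sample view, got "
            f"{len(sample_view.sample_names)} samples"
        )
    if not len(voi):
        raise DataError("the clean variants-of-interest table is empty")

    vcf_chroms = set(sample_view.chromosomes())
    voi_chroms = set(voi.chromosomes())
    if vcf_chroms and not (voi_chroms & vcf_chroms):
        raise DataError(
            "no catalogue chromosome appears in the VCF — the two files "
            "likely use different chromosome nomenclatures; apply a "
            "chromosome-name map first "
            f"(VCF: {sorted(vcf_chroms)[:5]}..., catalogue: {sorted(voi_chroms)[:5]}...)"
        )
    if not breed.strip():
        logger.warning(
            "no breed given — all non-reference loci will be reported in the "
            "'not known to segregate in this breed' table"
        )

    by_locus: dict[tuple[str, int], VariantRecord] = {}
    for rec in sample_view.records:
        by_locus.setdefault((rec.chrom, rec.pos), rec)

    result = FilterResult(sample_name=sample_view.sample_names[0], breed=breed)
    total = len(voi)
    for done, voi_row in enumerate(voi, start=1):
        row = _report_row(by_locus.get((voi_row.chrom, voi_row.pos)), voi_row, annotations)
        if row.zygosity.is_ref:
            result.hom_ref.append(row)
        elif breed.strip() and _breed_matches(breed, voi_row.breeds):
            result.priority.append(row)
        else:
            result.other_breed.append(row)
        if row.zygosity in (Zygosity.HOM_NONREF, Zygosity.HEMI_NONREF):
            result.advice_hom.append(
                (row, breeding_advice(row.inheritance, HOMOZYGOUS))
            )
        elif row.zygosity is Zygosity.HET:
            result.advice_het.append(
                (row, breeding_advice(row.inheritance, HETEROZYGOUS))
            )
        if progress is not None:
            progress(done, total)

    logger.info(
        "sample %s: %d priority, %d other-breed, %d homozygous-reference, "
        "%d no-call",
        result.sample_name,
        len(result.priority),
        len(result.other_breed),
        len(result.hom_ref),
        len(result.no_call_rows()),
    )
    return result


def _report_row(
    record: VariantRecord | None,
    voi_row: VariantOfInterest,
    annotations: list[TranscriptAnnotation] | None,
) -> VariantReportRow:
    if record is None:
        zyg, a1, a2 = Zygosity.NO_CALL, NO_CALL_TEXT, NO_CALL_TEXT
        status = LocusStatus.ABSENT_FROM_VCF
        ref = voi_row.ref_allele or ""
        mismatch = False
    else:
        zyg, a1, a2 = call_zygosity(record, 0, voi_row)
        status = LocusStatus.MISSING_GT if zyg is Zygosity.NO_CALL else LocusStatus.CALLED
        ref = record.ref
        mismatch = bool(
            voi_row.ref_allele
            and voi_row.ref_allele[0].upper() != record.ref[0].upper()
        )
    locations = (
        locate(annotations, voi_row.chrom, voi_row.pos) if annotations else []
    )
    return VariantReportRow(
        chrom=voi_row.chrom,
        pos=voi_row.pos,
        gene=voi_row.gene,
        ref_allele=ref,
        allele_1=a1,
        allele_2=a2,
        zygosity=zyg,
        inheritance=voi_row.inheritance,
        phenotype=voi_row.phenotype,
        locus_status=status,
        annotations=locations,
        allele_mismatch=mismatch,
        breeds=list(voi_row.breeds),
    )


def extra_filter(
    sample_view: VcfTable,
    voi: VoiTable,
    annotations: list[TranscriptAnnotation],
) -> list[VariantReportRow]:
    """Collect every other variant inside the genes that carry catalogue loci.

    Useful under genetic heterogeneity: the causal variant may be absent from
    the catalogue but sit in a gene already associated with the phenotype.
    Returns all VCF records whose position falls within the union of
    transcript spans of any catalogue gene, excluding exact chrom+pos matches
    to catalogue rows, sorted by chromosome then position. Catalogue genes
    with no transcript in the annotation are skipped with a warning.
    """
    if len(sample_view.sample_names) != 1:
        raise DataError("extra_filter needs a single-sample view")
    voi_genes = {row.gene for row in voi if row.gene}
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    annotated_genes: set[str] = set()
    for tx in annotations:
        if tx.gene in voi_genes:
            annotated_genes.add(tx.gene)
            spans_by_chrom.setdefault(tx.chrom, []).append(tx.span)
    skipped = sorted(voi_genes - annotated_genes)
    if skipped:
        logger.warning(
            "no transcript annotation for catalogue gene(s): %s — skipped",
            ", ".join(skipped),
        )

    voi_loci = {(row.chrom, row.pos) for row in voi}
    rows: list[VariantReportRow] = []
    for rec in sample_view.records:
        if (rec.chrom, rec.pos) in voi_loci:
            continue
        spans = spans_by_chrom.get(rec.chrom, ())
        if not any(s <= rec.pos <= e for s, e in spans):
            continue
        zyg, a1, a2 = call_zygosity(rec, 0)
        locations = locate(annotations, rec.chrom, rec.pos)
        gene = locations[0].gene if locations else ""
        rows.append(
            VariantReportRow(
                chrom=rec.chrom,
                pos=rec.pos,
                gene=gene,
                ref_allele=rec.ref,
                allele_1=a1,
                allele_2=a2,
                zygosity=zyg,
                inheritance=InheritancePattern.UNKNOWN,
                phenotype="",
                locus_status=(
                    LocusStatus.MISSING_GT if zyg is Zygosity.NO_CALL else LocusStatus.CALLED
                ),
                annotations=locations,
            )
        )
    rows.sort(key=lambda r: (r.chrom, r.pos))
    return rows
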