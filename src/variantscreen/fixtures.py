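"""Deterministic synthetic test bundles: VCF + catalogue + BED12 + FASTA.

Every module of the package is exercisable without any download: this module
writes a coherent bundle of input files — a multi-sample VCF, a
variants-of-interest catalogue in the canonical schema, a BED12 transcript
annotation covering the catalogue genes, a small reference FASTA and a
chromosome-name map — together with the ground truth (expected
heterozygosity, filter-partition sizes, QC counts) computed by direct
bookkeeping *during* generation, before any module under test runs.

Genotypes are independent per-locus, per-sample draws (no linkage or
population structure): with probability ``missing_rate`` the genotype is
``./.``; otherwise it is heterozygous ``0/1`` with probability ``het_rate``,
else homozygous reference or non-reference with equal odds. All randomness
flows from one seeded generator, so identical specs give byte-identical
files.

:func:`labrador_example` writes the fixed one-sample worked example used in
the documentation: five catalogued loci in a yellow female Labrador
retriever, three of them segregating in the breed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .vcf import FileAttributes, Genotype, VariantRecord, VcfTable, write_vcf

__all__ = ["FixtureSpec", "FixtureTruth", "FixtureBundle", "generate", "labrador_example"]

_BASES = "ACGT"
VOI_HEADER = [
    "chrom", "pos", "gene", "ref", "alt", "inheritance",
    "phenotype", "breed", "assembly", "species",
]

_INHERITANCE_CYCLE = [
    "Autosomal recessive",
    "Autosomal dominant",
    "X linked recessive",
    "",  # blank → UNKNOWN, exercises the 'NA' advice path
    "Mitochondrial",
    "X linked dominant",
    "Y linked",
]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic bundle. Counts must be mutually
    consistent (``n_voi + n_extra_in_gene <= n_loci``)."""

    seed: int = 0
    n_samples: int = 4
    n_loci: int = 50
    missing_rate: float = 0.1
    het_rate: float = 0.4
    n_voi: int = 10
    n_breed_match: int = 5
    n_voi_absent: int = 0          # catalogue rows at loci absent from the VCF
    n_extra_in_gene: int = 3       # non-catalogue VCF records inside gene spans
    n_incomplete_rows: int = 0     # planted QC defects: blank position
    n_wrong_assembly_rows: int = 0 # planted QC defects: other assembly label
    n_ref_mismatch_rows: int = 0   # planted QC defects: catalogue ref != genome
    transcripts_per_gene: int = 1
    exons_per_transcript: int = 3
    breed: str = "Labrador retriever"
    other_breed: str = "Beagle"
    assembly: str = "canFam3"
    plain_chrom_names: bool = False  # VCF uses "1".."N" instead of "chr1"..

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_loci < 1:
            raise ValueError("n_samples and n_loci must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_voi > self.n_loci:
            raise ValueError("n_voi cannot exceed n_loci")
        if self.n_voi + self.n_extra_in_gene > self.n_loci:
            raise ValueError("n_voi + n_extra_in_gene cannot exceed n_loci")
        if self.n_voi == 0 and self.n_extra_in_gene > 0:
            raise ValueError("in-gene extras need at least one catalogue gene")
        if self.n_breed_match > self.n_voi + self.n_voi_absent:
            raise ValueError("n_breed_match cannot exceed the catalogue size")
        if self.n_ref_mismatch_rows > self.n_voi:
            raise ValueError("n_ref_mismatch_rows cannot exceed n_voi")


@dataclass
class FixtureTruth:
    """Ground truth recorded while generating, for exact assertions."""

    n_shared: int
    n_het: dict[str, int]                    # per sample, over shared loci
    he: dict[str, Fraction]
    n_priority: int                          # partition for the first sample
    n_other_breed: int
    n_hom_ref: int
    n_no_call: int                           # no-call rows among priority+other
    n_clean_voi: int
    qc_counts: tuple[int, int, int]          # (incomplete, wrong assembly, mismatches)
    n_extra_in_gene: int


@dataclass
class FixtureBundle:
    vcf: Path
    voi: Path
    bed: Path
    fasta: Path
    chrom_map: Path
    truth: FixtureTruth | None = None
    sample_names: list[str] = field(default_factory=list)
    breed: str = ""
    gene_map: Path | None = None


def _sample_gt(rng: random.Random, missing_rate: float, het_rate: float) -> Genotype:
    if rng.random() < missing_rate:
        return Genotype(alleles=(None, None))
    if rng.random() < het_rate:
        return Genotype(alleles=(0, 1))
    if rng.random() < 0.5:
        return Genotype(alleles=(0, 0))
    return Genotype(alleles=(1, 1))


def generate(spec: FixtureSpec, out_dir: str | Path) -> tuple[FixtureBundle, FixtureTruth]:
    """Write one synthetic bundle and return its paths plus the ground truth."""
    spec.validate()
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_chroms = min(4, spec.n_voi) or 1
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]

    # --- lay out genes (one per catalogue locus present in the VCF) -------
    exon_len, intron_len, gap = 120, 80, 400
    cursors = {c: 1000 for c in chrom_names}
    genes = []  # (gene, chrom, exons, voi_pos)
    n_voi_total = spec.n_voi + spec.n_voi_absent
    for i in range(n_voi_total):
        chrom = chrom_names[i % n_chroms]
        start = cursors[chrom]
        exons = []
        pos = start
        for _ in range(spec.exons_per_transcript):
            exons.append((pos, pos + exon_len - 1))
            pos += exon_len + intron_len
        span_end = exons[-1][1]
        cursors[chrom] = span_end + gap
        exon_idx = rng.randrange(len(exons))
        e_start, e_end = exons[exon_idx]
        voi_pos = rng.randint(e_start, e_end)
        genes.append((f"GENE{i + 1}", chrom, exons, voi_pos))

    # --- extra (non-catalogue) records inside gene spans ------------------
    extra_positions = []  # (chrom, pos)
    present_genes = genes[: spec.n_voi]
    for j in range(spec.n_extra_in_gene):
        gene, chrom, exons, voi_pos = present_genes[j % len(present_genes)]
        span = (exons[0][0], exons[-1][1])
        while True:
            p = rng.randint(*span)
            if p != voi_pos and (chrom, p) not in extra_positions:
                extra_positions.append((chrom, p))
                break

    # --- background records outside every gene span -----------------------
    n_background = spec.n_loci - spec.n_voi - spec.n_extra_in_gene
    background = []
    for _ in range(n_background):
        chrom = chrom_names[rng.randrange(n_chroms)]
        background.append((chrom, cursors[chrom]))
        cursors[chrom] += rng.randint(20, 60)

    loci = (
        [(c, p) for _, c, _, p in present_genes]
        + extra_positions
        + background
    )
    order = {c: i for i, c in enumerate(chrom_names)}
    loci.sort(key=lambda cp: (order[cp[0]], cp[1]))

    # --- reference sequence and alleles ------------------------------------
    contig_len = {c: cursors[c] + 100 for c in chrom_names}
    seqs = {c: [rng.choice(_BASES) for _ in range(contig_len[c])] for c in chrom_names}
    ref_at = {}
    alt_at = {}
    for chrom, pos in loci:
        ref = seqs[chrom][pos - 1]
        ref_at[(chrom, pos)] = ref
        alt_at[(chrom, pos)] = rng.choice([b for b in _BASES if b != ref])

    # --- genotypes + diversity truth ---------------------------------------
    sample_names = [f"dog{i + 1}" for i in range(spec.n_samples)]
    genotypes = {}
    for locus in loci:
        genotypes[locus] = [
            _sample_gt(rng, spec.missing_rate, spec.het_rate)
            for _ in range(spec.n_samples)
        ]
    shared = [
        locus for locus in loci
        if all(gt.is_diploid_call for gt in genotypes[locus])
    ]
    n_het = {
        name: sum(1 for locus in shared if genotypes[locus][i].is_het)
        for i, name in enumerate(sample_names)
    }

    # --- catalogue rows + filter truth for the first sample ----------------
    voi_rows = []  # rows of the TSV
    n_priority = n_other = n_hom_ref = n_no_call = 0
    voi_loci = []
    for i, (gene, chrom, exons, voi_pos) in enumerate(genes):
        in_vcf = i < spec.n_voi
        locus = (chrom, voi_pos)
        if in_vcf:
            ref, alt = ref_at[locus], alt_at[locus]
        else:
            ref = seqs[chrom][voi_pos - 1]
            alt = rng.choice([b for b in _BASES if b != ref])
        catalogue_ref = ref
        if i < spec.n_ref_mismatch_rows:
            catalogue_ref = rng.choice([b for b in _BASES if b != ref])
        breed = spec.breed if i < spec.n_breed_match else spec.other_breed
        inheritance = _INHERITANCE_CYCLE[i % len(_INHERITANCE_CYCLE)]
        voi_rows.append([
            chrom, str(voi_pos), gene, catalogue_ref, alt, inheritance,
            f"Phenotype {i + 1}", breed, spec.assembly, "dog",
        ])
        voi_loci.append(locus)
        # expected routing for dog1
        if not in_vcf:
            zclass = "nocall"
        else:
            gt = genotypes[locus][0]
            if not gt.is_called:
                zclass = "nocall"
            elif gt.is_het or gt.alleles[0] != 0:
                zclass = "nonref"
            else:
                zclass = "ref"
        if zclass == "ref":
            n_hom_ref += 1
        elif breed == spec.breed:
            n_priority += 1
        else:
            n_other += 1
        if zclass == "nocall":
            n_no_call += 1

    # planted QC-defect rows, appended after the clean rows
    for k in range(spec.n_incomplete_rows):
        voi_rows.append([
            chrom_names[0], "", f"BADROW{k + 1}", "A", "C",
            "Autosomal recessive", "Incomplete row", spec.breed,
            spec.assembly, "dog",
        ])
    for m in range(spec.n_wrong_assembly_rows):
        voi_rows.append([
            chrom_names[0], str(500 + m), f"OLDMAP{m + 1}", "A", "C",
            "Autosomal recessive", "Wrong assembly row", spec.breed,
            "canFam4", "dog",
        ])

    truth = FixtureTruth(
        n_shared=len(shared),
        n_het=n_het,
        he={
            name: Fraction(n_het[name], len(shared)) if shared else Fraction(0)
            for name in sample_names
        },
        n_priority=n_priority,
        n_other_breed=n_other,
        n_hom_ref=n_hom_ref,
        n_no_call=n_no_call,
        n_clean_voi=n_voi_total,
        qc_counts=(
            spec.n_incomplete_rows,
            spec.n_wrong_assembly_rows,
            spec.n_ref_mismatch_rows,
        ),
        n_extra_in_gene=spec.n_extra_in_gene,
    )

    # --- write files --------------------------------------------------------
    def vcf_name(chrom: str) -> str:
        return chrom[3:] if spec.plain_chrom_names else chrom

    records = [
        VariantRecord(
            chrom=vcf_name(chrom),
            pos=pos,
            id=".",
            ref=ref_at[(chrom, pos)],
            alt=[alt_at[(chrom, pos)]],
            qual=None,
            filter="PASS",
            genotypes=genotypes[(chrom, pos)],
        )
        for chrom, pos in loci
    ]
    table = VcfTable(
        sample_names=sample_names,
        records=records,
        attributes=FileAttributes(0, 1, len(records), 9 + spec.n_samples),
    )
    vcf_path = out_dir / "sample.vcf"
    write_vcf(table, vcf_path, contigs=[vcf_name(c) for c in chrom_names])

    voi_path = out_dir / "voi.tsv"
    with open(voi_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(VOI_HEADER) + "\n")
        for row in voi_rows:
            fh.write("\t".join(row) + "\n")

    bed_path = out_dir / "annotation.bed"
    with open(bed_path, "w", encoding="utf-8") as fh:
        for i, (gene, chrom, exons, _) in enumerate(genes):
            for t in range(spec.transcripts_per_gene):
                chrom_start = exons[0][0] - 1
                chrom_end = exons[-1][1]
                sizes = ",".join(str(e - s + 1) for s, e in exons)
                starts = ",".join(str(s - 1 - chrom_start) for s, _ in exons)
                strand = "+" if (i + t) % 2 == 0 else "-"
                fh.write(
                    "\t".join([
                        chrom, str(chrom_start), str(chrom_end),
                        f"{gene}.t{t + 1}", "0", strand,
                        str(chrom_start), str(chrom_end), "0",
                        str(len(exons)), sizes, starts,
                    ]) + "\n"
                )

    fasta_path = out_dir / "reference.fa"
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for chrom in chrom_names:
            fh.write(f">{chrom}\n")
            seq = "".join(seqs[chrom])
            for ofs in range(0, len(seq), 70):
                fh.write(seq[ofs:ofs + 70] + "\n")
    _write_fai(fasta_path)

    map_path = out_dir / "chrom_map.tsv"
    with open(map_path, "w", encoding="utf-8") as fh:
        for chrom in chrom_names:
            fh.write(f"{chrom[3:]}\t{chrom}\n")

    # a transcript→gene map so annotation reports gene symbols, not tx ids
    gene_map_path = out_dir / "gene_map.tsv"
    with open(gene_map_path, "w", encoding="utf-8") as fh:
        for gene, _, _, _ in genes:
            for t in range(spec.transcripts_per_gene):
                fh.write(f"{gene}.t{t + 1}\t{gene}\n")

    bundle = FixtureBundle(
        vcf=vcf_path, voi=voi_path, bed=bed_path, fasta=fasta_path,
        chrom_map=map_path, truth=truth, sample_names=sample_names,
        breed=spec.breed, gene_map=gene_map_path,
    )
    return bundle, truth


def _write_fai(fasta_path: Path) -> None:
    from pyfaidx import Faidx

    fai = fasta_path.with_suffix(fasta_path.suffix + ".fai")
    if fai.exists():
        fai.unlink()
    Faidx(str(fasta_path))


# --- the fixed worked example ------------------------------------------------

_EXAMPLE_SITES = [
    # chrom, pos, gene, ref, alt, gt, inheritance, phenotype, breeds
    ("chr12", 22_652_874, "COL11A2", "C", "G", "0/1",
     "Autosomal recessive", "Skeletal dysplasia 2", "Labrador retriever"),
    ("chr5", 63_694_334, "MC1R", "G", "A", "1/1",
     "Autosomal recessive", "Red/yellow coat", "Labrador retriever"),
    ("chrX", 60_279_238, "ATP7A", "C", "T", "0/1",
     "X linked recessive", "Menkes disease", "Labrador retriever"),
    ("chr3", 24_509_367, "FGF5", "G", "A", "./.",
     "Autosomal recessive", "Long hair", "Afghan Hound"),
    ("chr5", 63_694_460, "MC1R", "C", "T", "1/1",
     "Autosomal dominant", "Black melanistic mask", "Afghan Hound"),
]


def labrador_example(out_dir: str | Path) -> FixtureBundle:
    """Write the fixed one-sample worked example (sample ``dog1``).

    Five catalogued loci with real canine coordinates: a COL11A2
    heterozygote (skeletal dysplasia 2 carrier), an MC1R homozygote (yellow
    coat), an ATP7A heterozygote on the X, an uncalled FGF5 locus and an MC1R
    melanistic-mask homozygote not known to segregate in the Labrador
    retriever. The minimal BED12 places every locus inside an exon of a
    two-exon transcript per gene.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = [
        VariantRecord(
            chrom=chrom, pos=pos, id=".", ref=ref, alt=[alt], qual=None,
            filter="PASS", genotypes=[Genotype.from_gt_string(gt)],
        )
        for chrom, pos, _, ref, alt, gt, *_ in _EXAMPLE_SITES
    ]
    table = VcfTable(
        sample_names=["dog1"],
        records=records,
        attributes=FileAttributes(0, 1, len(records), 10),
    )
    vcf_path = out_dir / "dog1.vcf"
    write_vcf(table, vcf_path)

    voi_path = out_dir / "voi.tsv"
    with open(voi_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(VOI_HEADER) + "\n")
        for chrom, pos, gene, ref, alt, _, inh, phen, breeds in _EXAMPLE_SITES:
            fh.write("\t".join([
                chrom, str(pos), gene, ref, alt, inh, phen, breeds,
                "canFam3", "dog",
            ]) + "\n")

    bed_path = out_dir / "annotation.bed"
    with open(bed_path, "w", encoding="utf-8") as fh:
        for i, (chrom, pos, gene, *_rest) in enumerate(_EXAMPLE_SITES):
            # two 150-bp exons; the catalogue locus sits mid-exon-1
            chrom_start = pos - 76          # 0-based; exon 1 covers pos-75..pos+74
            chrom_end = chrom_start + 150 + 100 + 150
            fh.write("\t".join([
                chrom, str(chrom_start), str(chrom_end), f"{gene}.t{i + 1}",
                "0", "+", str(chrom_start), str(chrom_end), "0",
                "2", "150,150", "0,250",
            ]) + "\n")

    map_path = out_dir / "chrom_map.tsv"
    with open(map_path, "w", encoding="utf-8") as fh:
        for name in ("12", "5", "X", "3"):
            fh.write(f"{name}\tchr{name}\n")

    gene_map_path = out_dir / "gene_map.tsv"
    with open(gene_map_path, "w", encoding="utf-8") as fh:
        for i, (_, _, gene, *_rest) in enumerate(_EXAMPLE_SITES):
            fh.write(f"{gene}.t{i + 1}\t{gene}\n")

    return FixtureBundle(
        vcf=vcf_path, voi=voi_path, bed=bed_path,
        fasta=Path(""), chrom_map=map_path,
        sample_names=["dog1"], breed="Labrador retriever",
        gene_map=gene_map_path,
    )
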