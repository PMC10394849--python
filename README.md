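# variantscreen

Screening of VCF files for **known phenotype-associated variants**, with
breed-aware clinical reporting, breeding advice and per-sample genetic
diversity — built for veterinary clinical genetics, where WES/WGS is entering
routine diagnostics but most variant-interpretation tooling assumes human
data and human databases.

## What it does

Given three files —

1. a (multi-sample) **VCF** from the sequencing facility,
2. a **variants-of-interest (VOI) catalogue** of known phenotype-associated
   variants (an OMIA species export or a user-defined table; at minimum
   chromosome, position, gene and genome assembly per variant),
3. a UCSC-table-browser-style **BED12** transcript annotation,

— the tool screens one sample's genotypes at every catalogued locus, calls
the zygosity, and partitions the findings into three variant tables:

* **priority** — non-reference (or uncallable) loci whose genotype–phenotype
  association is established in the animal's breed: the clinically
  actionable list;
* **other breed** — same genotype classes, but the association is not known
  to segregate in that breed (it may be breed-specific, or simply not yet
  established);
* **homozygous reference** — catalogue loci where this sample is wild type
  (the variant was called in another sample of the multi-sample file);

plus two **breeding-advice tables** pairing every non-reference finding with
standardized advice texts keyed by inheritance pattern (autosomal
dominant/recessive, X-linked dominant/recessive, Y-linked, mitochondrial, or
unknown) and by zygosity class. A locus that could not be genotyped is never
dropped: it is reported with an explicit
*"A call could not be made for this sample at this given locus"* so that "not
assessable" can never be mistaken for "variant absent".

From the multi-sample VCF the tool also estimates each individual's
**average heterozygosity**

```
He = n_het / n_shared
```

where `n_het` is the number of heterozygous loci in that sample and
`n_shared` the number of loci fully called in *every* sample — a shared
denominator that makes the estimates comparable across individuals. Low
within-individual heterozygosity is the everyday warning sign of the narrow
breeding pools common in domestic animals, so the report includes per-sample
tables and annotated bar charts alongside the variant screen.

Helpers cover the usual format friction: chromosome-name mapping
(`1` ↔ `chr1`), catalogue QC against a reference FASTA (incomplete rows,
wrong-assembly rows, reference-base mismatches — flagged, never silently
dropped), BED12 → exon/intron annotation of every hit, and a gene-wide
"extra" scan that collects all remaining variants inside the catalogue genes
for heterogeneous phenotypes.

## Worked example

The package ships a deterministic generator for coherent input bundles,
including a fixed one-sample example — a healthy, yellow, female Labrador
retriever screened against five catalogued loci:

```bash
variantscreen fixtures --out example --worked-example
variantscreen scan --vcf example/dog1.vcf --voi example/voi.tsv \
    --bed example/annotation.bed --gene-map example/gene_map.tsv \
    --breed "Labrador retriever" --sample dog1 --out report
```

`report/priority.tsv` then contains (annotation columns elided):

```
Chromosome  Location  Gene     Reference  Allele 1  Allele 2  Zygosity      Inheritance          Phenotype
chr12       22652874  COL11A2  C          C         G         Heterozygous  Autosomal recessive  Skeletal dysplasia 2
chr5        63694334  MC1R     G          A         A         Homozygous    Autosomal recessive  Red/yellow coat
chrX        60279238  ATP7A    C          C         T         Heterozygous  X linked recessive   Menkes disease
```

Reading it: the dog is a *carrier* of the recessive skeletal-dysplasia-2
variant (no phenotype, but decisive for mate choice), *homozygous* for the
recessive MC1R variant (hence the yellow coat), and heterozygous for an
X-linked locus. The other-breed table holds two more rows — an FGF5 locus
reported with the verbatim no-call text because its genotype was `./.`, and
an MC1R melanistic-mask variant not known to segregate in Labradors. The
advice table pairs the homozygous MC1R finding with
*"ONLY combine with wild type animal! …"*. Five HTML tables plus a combined
sortable report and TSV mirrors of every table land in `report/`.

Diversity on a generated 4-sample bundle:

```bash
variantscreen fixtures --out bundle --seed 3
variantscreen diversity --vcf bundle/sample.vcf --out diversity
```

```
dog1    0.296296296296296    all
dog2    0.407407407407407    all
dog3    0.481481481481481    all
dog4    0.222222222222222    all
```

Each value is that sample's heterozygous fraction over the loci called in
all four dogs (here 27 of 50 generated loci survive the shared-call filter);
four chart variants (plain, labelled, sample-of-interest, maximum
highlighted) are written next to the table.

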