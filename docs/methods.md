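# Methods

## The screening model

The tool treats clinical variant interpretation as a *lookup* problem, not a
discovery problem: the unit of evidence is a catalogued variant with an
established genotype–phenotype association, and the question per sample is
only "which of these known variants does this animal carry, and in what
zygosity?". Matching between the catalogue and the VCF is therefore by
genomic coordinate (chromosome + 1-based position) alone. A catalogued
reference allele that disagrees with the VCF REF does not change the match —
it sets an `allele_mismatch` flag on the report row, because coordinate
errors are a curation problem to be surfaced, not silently resolved.
Multi-allelic sites are not split or normalized; zygosity is computed on the
allele strings the VCF itself asserts. Records failing FILTER are kept and
the FILTER value is carried along: the workflow does not impose a quality
policy of its own on a VCF the caller already accepted.

### Zygosity and the no-call contract

Only the GT subfield of FORMAT is interpreted. `/` and `|` are equivalent
(phase is recorded but unused). The classes are: homozygous reference,
heterozygous (two called, distinct alleles — including a multi-allelic 1/2),
homozygous non-reference, hemizygous reference / non-reference (haploid GT,
e.g. Y or mitochondria), and no-call. *Any* missing allele index — `./.` but
also the half-call `./1` — is a no-call: a half-called genotype cannot
distinguish heterozygous from homozygous, so it must not be reported as
either. No-call loci, and loci absent from the VCF entirely, stay in the
report with a fixed sentence in the allele columns; the two causes are
distinguished in a status column (useful when debugging a truncated VCF)
but share the same user-facing text. Heterozygous allele pairs are reported
in allele-index order, so `0/1` and `1/0` render identically.

### Breed routing and advice

A non-reference or no-call locus goes to the **priority** table when the
queried breed matches any of the row's catalogue breeds; the comparison is
case-insensitive and whitespace-normalized, with deliberately *no* fuzzy
matching — in a clinical report, a near-miss breed name should fail loudly
rather than match silently. An empty breed routes everything to the
other-breed table (with a warning). Homozygous/hemizygous-reference loci go
to the reference table regardless of breed.

Advice texts are fixed strings keyed by (inheritance pattern, homozygous |
heterozygous). They keep their conditional phrasing ("If animal is female:
…") verbatim: the tool never infers sex from the VCF, and an optional
`--sex` flag only annotates report metadata. The homozygous table has no
Y-linked entry of its own because a Y variant is haploid; the hemizygous
case reuses the Y-linked text. Unrecognized or blank inheritance maps to an
UNKNOWN pattern whose advice text says explicitly that no advice can be
given. The lookup is total by construction and tested as such.

## Catalogue QC

Rows missing chromosome, position or assembly are dropped (they cannot be
matched); rows labelled with a different assembly than the run's are
excluded (exact string comparison after trimming and case-folding — no alias
table, since `canFam3.1` vs `canFam4` is precisely the kind of difference
that must not be papered over). With a reference FASTA, the first base of
each catalogued reference allele is compared with the genome base at the
row's position — first base only, so indels with a VCF-style anchor base are
checked sensibly. Mismatches are *flagged and retained*: a mismatch usually
means a mis-curated coordinate, and the right response is manual review, not
deletion. Rows on chromosomes the FASTA lacks are reported as unverifiable.
QC is idempotent: a second pass over its own output drops and reports
nothing new.

## Exon/intron annotation

BED12 is the sole annotation dialect. Blocks convert to 1-based inclusive
exons via `exon_start = chromStart + blockStart + 1`,
`exon_end = exon_start + blockSize − 1`; internal inconsistencies
(blockCount vs list lengths, blocks past chromEnd) are parse errors with
line numbers. Exon numbering follows transcription order — on the minus
strand exon 1 is the genomically last block — matching clinical reporting
convention. Within a transcript's span, every position is in exactly one
exon k or intron k (the intron after transcription-order exon k); this
partition is property-tested position by position. Positions outside all
transcripts are reported as such, keeping the catalogue's own gene symbol. A
variant hitting several transcripts yields one annotation entry per
transcript.

## Average heterozygosity

`He = n_het / n_shared` per sample, where the shared set contains loci whose
genotype is a *full diploid call in every sample*. Haploid genotypes cannot
be heterozygous, so a locus haploid in any sample is excluded from the
shared set — otherwise samples would be compared over denominators with
different information content. A multi-allelic genotype with two different
ALT alleles counts as heterozygous (its alleles differ). The ratio is kept
as an exact `Fraction` and formatted to 15 decimal places; with zero shared
loci the statistic is undefined and the code raises rather than returning a
0/0 artifact. Shared-set intersection is monotone: removing a sample can
only grow it, which the tests assert directly.

## Synthetic data

The fixture generator exists so that every path — including planted QC
defects and no-call handling — is testable offline with exact expected
values. It emulates: a multi-sample VCF of biallelic SNVs whose REF bases
agree with a small generated FASTA; a catalogue whose loci sit inside
generated gene models (one gene per catalogue row, configurable transcripts
and exon counts); background variants outside all gene spans plus a chosen
number planted inside them (the ground truth for the gene-wide extra scan);
optional catalogue rows at loci absent from the VCF; and planted QC defects
(blank positions, wrong assembly labels, reference-base mismatches) in known
numbers. Genotypes are independent draws per locus and sample: missing with
probability `missing_rate` (default 0.1, a plausible WES no-call rate),
else heterozygous with probability `het_rate` (default 0.4, chosen so both
zygosity classes are well represented at the default 50-locus scale), else
homozygous reference or non-reference with equal odds. Defaults are 4
samples × 50 loci — small enough for sub-second tests, large enough that
every table is non-trivially populated.

What the generator does **not** emulate: linkage, allele-frequency spectra,
population structure, indels/structural variants, genotype-quality fields,
and real chromosome lengths. Passing tests therefore demonstrate the
*bookkeeping* correctness of the workflow (matching, routing, counting,
formatting, determinism) — not robustness to the messiness of real calling
pipelines, which is bounded instead by the strict parse errors and the QC
surface.

A fixed worked-example bundle reproduces the documentation scenario: one
sample, five catalogued loci at real canine coordinates (kept verbatim; the
example needs no FASTA, so no padded contigs are written), three loci
flagged for the Labrador retriever, one locus uncalled. Its expected report
is known row for row and is asserted byte-level in the acceptance tests.

## Numerical and formatting choices

* Positions are 1-based everywhere internally; BED's 0-based half-open
  coordinates are converted at parse time and never leak.
* He is exact rational arithmetic; rounding to 15 decimals happens only at
  the formatting boundary (round half up on the 16th digit).
* Report tables are pure functions of their inputs: row order is catalogue
  input order, timestamps and file digests live only in `metadata.json`, so
  two runs on identical inputs are byte-identical — asserted in tests.
* Ties for the maximum-He highlight go to the first sample in table order,
  and the tie is logged.
* The "interactive" combined report is a single self-contained HTML page
  with client-side column sorting; no server, no browser auto-open (file
  paths are printed instead).

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
the sweep covers 2–8 samples × 50–500 loci × 0–30 % missingness (18–22
bundles), sizes at which every quantity can be cross-checked against an
independent brute-force recount in seconds while still exercising all code
paths. At 30 % missingness and 8 samples a 50-locus bundle can legitimately
have an empty shared set; the acceptance script treats "both routes agree
the statistic is undefined" as the correct outcome there.

## Known limitations

* Coordinate-only matching cannot detect a catalogue row whose position is
  right but whose variant allele differs from the sample's ALT; the
  mismatch flag surfaces REF disagreements only.
* No liftover: catalogue rows from another assembly are excluded, not
  converted.
* Compound heterozygosity and gene–gene interactions (e.g. a protective
  variant in one copper-transport gene masking another) are interpretation,
  not computation; the report presents the loci side by side and leaves the
  judgement to the clinician.
* Breeding advice is generic per inheritance pattern; it does not weigh
  phenotype severity, penetrance or heteroplasmy level (the mitochondrial
  footnote states the caveat verbatim).
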