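"""Zygosity calling, breed-aware partitioning and breeding advice."""

import pytest

from variantscreen.advice import (
    HETEROZYGOUS,
    HOMOZYGOUS,
    breeding_advice,
)
from variantscreen.annotation import build_annotation, read_gene_map
from variantscreen.errors import DataError
from variantscreen.filtering import (
    NO_CALL_TEXT,
    LocusStatus,
    Zygosity,
    call_zygosity,
    extra_filter,
    filter_variants,
)
from variantscreen.fixtures import FixtureSpec, generate, labrador_example
from variantscreen.vcf import Genotype, VariantRecord, extract_sample, read_vcf
from variantscreen.voi import InheritancePattern, parse_voi, qc_voi


def record(ref="C", alt=("G",), gt="0/1"):
    return VariantRecord(
        chrom="chr1", pos=100, id=".", ref=ref, alt=list(alt), qual=None,
        filter="PASS", genotypes=[Genotype.from_gt_string(gt)],
    )


class TestCallZygosity:
    @pytest.mark.parametrize(
        "ref,alt,gt,zyg,a1,a2",
        [
            ("C", ("G",), "0/1", Zygosity.HET, "C", "G"),
            ("G", ("A",), "1/1", Zygosity.HOM_NONREF, "A", "A"),
            ("C", ("G",), "0/0", Zygosity.HOM_REF, "C", "C"),
            ("C", ("G",), "./.", Zygosity.NO_CALL, NO_CALL_TEXT, NO_CALL_TEXT),
            ("C", ("G",), "./1", Zygosity.NO_CALL, NO_CALL_TEXT, NO_CALL_TEXT),
            ("C", ("G",), "1", Zygosity.HEMI_NONREF, "G", "-"),
            ("C", ("G",), "0", Zygosity.HEMI_REF, "C", "-"),
            ("G", ("A", "T"), "1/2", Zygosity.HET, "A", "T"),
        ],
    )
    def test_resolution(self, ref, alt, gt, zyg, a1, a2):
        assert call_zygosity(record(ref, alt, gt), 0) == (zyg, a1, a2)

    def test_symmetric_in_allele_order(self):
        assert call_zygosity(record(gt="1/0"), 0) == call_zygosity(record(gt="0/1"), 0)

    def test_out_of_range_index_names_the_site(self):
        rec = record()
        rec.genotypes = [Genotype(alleles=(0, 5))]
        with pytest.raises(DataError, match="chr1:100"):
            call_zygosity(rec, 0)


class TestBreedingAdvice:
    def test_totality(self):
        for pattern in InheritancePattern:
            for cls in (HOMOZYGOUS, HETEROZYGOUS):
                text = breeding_advice(pattern, cls)
                assert isinstance(text, str) and text

    def test_key_texts(self):
        assert breeding_advice(
            InheritancePattern.AUTOSOMAL_RECESSIVE, HOMOZYGOUS
        ).startswith("ONLY combine with wild type animal!")
        assert breeding_advice(
            InheritancePattern.AUTOSOMAL_DOMINANT, HETEROZYGOUS
        ) == "Animal can NOT be used for breeding purposes"
        assert breeding_advice(InheritancePattern.UNKNOWN, HETEROZYGOUS) == (
            "Not able to provide breeding advice because inheritance pattern "
            "was not included in the input file"
        )

    def test_y_linked_homozygous_reuses_y_text(self):
        assert breeding_advice(
            InheritancePattern.Y_LINKED, HOMOZYGOUS
        ) == breeding_advice(InheritancePattern.Y_LINKED, HETEROZYGOUS)


@pytest.fixture(scope="module")
def example_result(tmp_path_factory):
    bundle = labrador_example(tmp_path_factory.mktemp("ex"))
    table = read_vcf(bundle.vcf)
    voi, _ = qc_voi(parse_voi(bundle.voi), assembly="canFam3")
    ann = build_annotation(bundle.bed, gene_map=read_gene_map(bundle.gene_map))
    view = extract_sample(table, "dog1")
    return filter_variants(view, voi, ann, breed="Labrador retriever")


class TestWorkedExample:
    def test_priority_spans_three_genes(self, example_result):
        genes = [r.gene for r in example_result.priority]
        assert genes == ["COL11A2", "MC1R", "ATP7A"]
        zygs = [r.zygosity for r in example_result.priority]
        assert zygs == [Zygosity.HET, Zygosity.HOM_NONREF, Zygosity.HET]

    def test_other_breed_holds_the_uncalled_locus(self, example_result):
        assert len(example_result.other_breed) == 2
        fgf5 = example_result.other_breed[0]
        assert fgf5.gene == "FGF5"
        assert fgf5.zygosity is Zygosity.NO_CALL
        assert fgf5.allele_1 == fgf5.allele_2 == NO_CALL_TEXT
        assert fgf5.locus_status is LocusStatus.MISSING_GT

    def test_advice_pairs(self, example_result):
        hom = {(r.gene, r.pos): a for r, a in example_result.advice_hom}
        assert hom[("MC1R", 63_694_334)].startswith("ONLY combine with wild type animal!")
        assert hom[("MC1R", 63_694_460)] == (
            "Animal can NOT be used for breeding purposes. Offspring would be "
            "carrier or homozygous and might develop symptoms"
        )
        het = {r.gene: a for r, a in example_result.advice_het}
        assert het["COL11A2"].startswith("Animal can be used for breeding purposes")

    def test_loci_fall_in_annotated_exons(self, example_result):
        for row in example_result.priority:
            assert row.annotations
            assert all(loc.region == "exon" for loc in row.annotations)


class TestPartition:
    def test_completeness_across_seeds(self, tmp_path):
        for seed in range(6):
            spec = FixtureSpec(seed=seed, missing_rate=0.2, n_voi_absent=2)
            bundle, truth = generate(spec, tmp_path / str(seed))
            table = read_vcf(bundle.vcf)
            voi, _ = qc_voi(parse_voi(bundle.voi), assembly="canFam3")
            view = extract_sample(table, "dog1")
            result = filter_variants(view, voi, breed=bundle.breed)
            assert result.n_loci == len(voi) == truth.n_clean_voi
            assert len(result.priority) == truth.n_priority
            assert len(result.other_breed) == truth.n_other_breed
            assert len(result.hom_ref) == truth.n_hom_ref
            assert len(result.no_call_rows()) == truth.n_no_call

    def test_no_call_rows_carry_verbatim_text(self, tmp_path):
        spec = FixtureSpec(seed=4, missing_rate=0.4, n_voi_absent=3)
        bundle, truth = generate(spec, tmp_path)
        table = read_vcf(bundle.vcf)
        voi, _ = qc_voi(parse_voi(bundle.voi))
        result = filter_variants(
            extract_sample(table, "dog1"), voi, breed=bundle.breed
        )
        no_calls = result.no_call_rows()
        assert len(no_calls) == truth.n_no_call >= 3
        for row in no_calls:
            assert row.allele_1 == row.allele_2 == NO_CALL_TEXT
            assert row.zygosity is Zygosity.NO_CALL
        absent = [r for r in no_calls if r.locus_status is LocusStatus.ABSENT_FROM_VCF]
        assert len(absent) == 3

    def test_breed_change_moves_rows_without_changing_counts(self, tmp_path):
        spec = FixtureSpec(seed=8, missing_rate=0.1)
        bundle, _ = generate(spec, tmp_path)
        table = read_vcf(bundle.vcf)
        voi, _ = qc_voi(parse_voi(bundle.voi))
        view = extract_sample(table, "dog1")
        match = filter_variants(view, voi, breed="  labrador   RETRIEVER ")
        nomatch = filter_variants(view, voi, breed="Poodle")
        assert match.n_loci == nomatch.n_loci
        assert len(match.hom_ref) == len(nomatch.hom_ref)
        assert len(match.priority) + len(match.other_breed) == len(
            nomatch.priority
        ) + len(nomatch.other_breed)
        assert nomatch.priority == []

    def test_blank_breed_routes_everything_to_other_breed(self, tmp_path):
        spec = FixtureSpec(seed=8)
        bundle, _ = generate(spec, tmp_path)
        table = read_vcf(bundle.vcf)
        voi, _ = qc_voi(parse_voi(bundle.voi))
        result = filter_variants(extract_sample(table, "dog1"), voi, breed="")
        assert result.priority == []

    def test_nomenclature_mismatch_is_an_error(self, tmp_path):
        spec = FixtureSpec(seed=8, plain_chrom_names=True)
        bundle, _ = generate(spec, tmp_path)
        table = read_vcf(bundle.vcf)  # chromosomes "1".."4"
        voi, _ = qc_voi(parse_voi(bundle.voi))  # chromosomes "chr1".."chr4"
        with pytest.raises(DataError, match="nomenclature"):
            filter_variants(extract_sample(table, "dog1"), voi, breed="x")

    def test_allele_mismatch_is_flagged_but_routed_normally(self, tmp_path):
        spec = FixtureSpec(seed=6, n_ref_mismatch_rows=3, missing_rate=0.0)
        bundle, truth = generate(spec, tmp_path)
        table = read_vcf(bundle.vcf)
        voi, _ = qc_voi(parse_voi(bundle.voi))
        result = filter_variants(extract_sample(table, "dog1"), voi, breed=bundle.breed)
        flagged = [
            r
            for r in result.priority + result.other_breed + result.hom_ref
            if r.allele_mismatch
        ]
        assert len(flagged) == 3
        assert result.n_loci == truth.n_clean_voi


class TestExtraFilter:
    def test_planted_in_gene_count(self, tmp_path):
        for seed in (0, 5, 12):
            spec = FixtureSpec(seed=seed, n_extra_in_gene=4)
            bundle, truth = generate(spec, tmp_path / str(seed))
            table = read_vcf(bundle.vcf)
            voi, _ = qc_voi(parse_voi(bundle.voi))
            ann = build_annotation(bundle.bed, gene_map=read_gene_map(bundle.gene_map))
            rows = extra_filter(extract_sample(table, "dog1"), voi, ann)
            assert len(rows) == truth.n_extra_in_gene == 4

    def test_voi_loci_are_excluded(self, tmp_path):
        spec = FixtureSpec(seed=2, n_extra_in_gene=3)
        bundle, _ = generate(spec, tmp_path)
        table = read_vcf(bundle.vcf)
        voi, _ = qc_voi(parse_voi(bundle.voi))
        ann = build_annotation(bundle.bed, gene_map=read_gene_map(bundle.gene_map))
        rows = extra_filter(extract_sample(table, "dog1"), voi, ann)
        voi_loci = {(r.chrom, r.pos) for r in voi}
        assert all((r.chrom, r.pos) not in voi_loci for r in rows)
        assert rows == sorted(rows, key=lambda r: (r.chrom, r.pos))

    def test_no_in_gene_records_gives_empty_list(self, tmp_path):
        spec = FixtureSpec(seed=2, n_extra_in_gene=0)
        bundle, _ = generate(spec, tmp_path)
        table = read_vcf(bundle.vcf)
        voi, _ = qc_voi(parse_voi(bundle.voi))
        ann = build_annotation(bundle.bed, gene_map=read_gene_map(bundle.gene_map))
        assert extra_filter(extract_sample(table, "dog1"), voi, ann) == []
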