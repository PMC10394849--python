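"""Average heterozygosity over the shared fully-called locus set."""

from fractions import Fraction

import pytest

from variantscreen.diversity import (
    DiversityRow,
    diversity_outputs,
    heterozygosity,
    shared_called_loci,
)
from variantscreen.errors import DataError
from variantscreen.fixtures import FixtureSpec, generate
from variantscreen.vcf import (
    FileAttributes,
    Genotype,
    VariantRecord,
    VcfTable,
    read_vcf,
)


def make_table(gt_rows, n_samples):
    """gt_rows: list of per-sample GT strings, one list per locus."""
    records = [
        VariantRecord(
            chrom="chr1", pos=100 + i, id=".", ref="A", alt=["C"], qual=None,
            filter="PASS",
            genotypes=[Genotype.from_gt_string(g) for g in gts],
        )
        for i, gts in enumerate(gt_rows)
    ]
    return VcfTable(
        sample_names=[f"s{i + 1}" for i in range(n_samples)],
        records=records,
        attributes=FileAttributes(0, 1, len(records), 9 + n_samples),
    )


def brute_force_recount(vcf_path):
    """Independent recount straight off the written VCF text: shared loci are
    rows whose every GT has two non-missing indices; het means they differ."""
    samples, rows = [], []
    for line in open(vcf_path):
        line = line.rstrip("\n")
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            samples = line.split("\t")[9:]
            continue
        fields = line.split("\t")
        gts = [f.split(":")[0].replace("|", "/") for f in fields[9:]]
        rows.append(gts)
    shared_rows = [
        gts for gts in rows
        if all(
            len(g.split("/")) == 2 and "." not in g.split("/") for g in gts
        )
    ]
    n_shared = len(shared_rows)
    n_het = [
        sum(1 for gts in shared_rows if gts[i].split("/")[0] != gts[i].split("/")[1])
        for i in range(len(samples))
    ]
    return samples, n_shared, n_het


class TestSharedCalledLoci:
    def test_no_call_in_any_sample_drops_the_locus(self):
        table = make_table([["0/1", "0/0"], ["1/1", "./."], ["0/0", "0/1"]], 2)
        assert shared_called_loci(table) == [("chr1", 100), ("chr1", 102)]

    def test_no_missingness_keeps_every_locus(self):
        table = make_table([["0/1"], ["1/1"], ["0/0"]], 1)
        assert len(shared_called_loci(table)) == 3

    def test_haploid_locus_is_excluded(self):
        table = make_table([["0/1", "1"], ["0/1", "0/1"]], 2)
        assert shared_called_loci(table) == [("chr1", 101)]

    def test_matches_independent_recount(self, tmp_path):
        spec = FixtureSpec(seed=3, missing_rate=0.1)
        bundle, _ = generate(spec, tmp_path)
        table = read_vcf(bundle.vcf)
        _, n_shared, _ = brute_force_recount(bundle.vcf)
        assert len(shared_called_loci(table)) == n_shared


class TestHeterozygosity:
    def test_counts_and_ratio(self):
        table = make_table([["0/1"], ["0/0"], ["1/1"], ["0/1"]], 1)
        summary = heterozygosity(table)
        row = summary.rows[0]
        assert (row.n_het, row.n_shared) == (2, 4)
        assert row.he == Fraction(1, 2)

    def test_all_homozygous_sample_scores_zero(self):
        table = make_table([["0/0", "0/1"], ["1/1", "0/1"]], 2)
        summary = heterozygosity(table)
        assert summary.rows[0].he == 0
        assert summary.rows[1].he == 1

    def test_multiallelic_het_counts_as_heterozygous(self):
        records = [
            VariantRecord(
                chrom="chr1", pos=100, id=".", ref="G", alt=["A", "T"],
                qual=None, filter="PASS",
                genotypes=[Genotype(alleles=(1, 2))],
            )
        ]
        table = VcfTable(["s1"], records, FileAttributes(0, 1, 1, 10))
        assert heterozygosity(table).rows[0].n_het == 1

    def test_zero_shared_loci_is_an_error(self):
        table = make_table([["./.", "0/1"], ["0/1", "./."]], 2)
        with pytest.raises(DataError, match="undefined"):
            heterozygosity(table)

    def test_fixture_agrees_with_brute_force(self, tmp_path):
        for seed in (11, 12):
            spec = FixtureSpec(seed=seed, missing_rate=0.2)
            bundle, truth = generate(spec, tmp_path / str(seed))
            table = read_vcf(bundle.vcf)
            summary = heterozygosity(table)
            samples, n_shared, n_het = brute_force_recount(bundle.vcf)
            for row, name, count in zip(summary.rows, samples, n_het):
                assert row.sample_name == name
                assert row.n_shared == n_shared
                assert row.n_het == count == truth.n_het[name]
                assert row.he == truth.he[name]

    def test_invariant_under_record_reordering(self):
        rows = [["0/1", "0/0"], ["1/1", "0/1"], ["0/0", "./."], ["0/1", "1/1"]]
        fwd = heterozygosity(make_table(rows, 2))
        rev = heterozygosity(make_table(rows[::-1], 2))
        assert [r.he for r in fwd.rows] == [r.he for r in rev.rows]

    def test_dropping_a_sample_never_shrinks_the_shared_set(self, tmp_path):
        spec = FixtureSpec(seed=9, n_samples=4, missing_rate=0.3)
        bundle, _ = generate(spec, tmp_path)
        table = read_vcf(bundle.vcf)
        full = set(shared_called_loci(table))
        for drop in range(4):
            sub = VcfTable(
                sample_names=[n for i, n in enumerate(table.sample_names) if i != drop],
                records=[
                    VariantRecord(
                        chrom=r.chrom, pos=r.pos, id=r.id, ref=r.ref, alt=r.alt,
                        qual=r.qual, filter=r.filter,
                        genotypes=[g for i, g in enumerate(r.genotypes) if i != drop],
                    )
                    for r in table.records
                ],
                attributes=table.attributes,
            )
            assert full <= set(shared_called_loci(sub))

    def test_population_map_labels_rows(self):
        table = make_table([["0/1", "0/1"]], 2)
        summary = heterozygosity(table, populations={"s1": "popA"})
        assert summary.rows[0].population == "popA"
        assert summary.rows[1].population == "all"


class TestFormatting:
    def test_he_text_has_15_decimals(self):
        row = DiversityRow("s", "p", 1, 6)
        assert row.he_text == "0.166666666666667"
        assert DiversityRow("s", "p", 0, 7).he_text == "0.000000000000000"
        assert DiversityRow("s", "p", 7, 7).he_text == "1.000000000000000"


class TestOutputs:
    def test_files_and_per_sample_folders(self, tmp_path):
        spec = FixtureSpec(seed=1, n_samples=4, missing_rate=0.0)
        bundle, _ = generate(spec, tmp_path / "fx")
        table = read_vcf(bundle.vcf)
        summary = heterozygosity(table)
        out = tmp_path / "div"
        files = diversity_outputs(summary, out, sample_of_interest="dog2")
        assert (out / "heterozygosity.tsv").is_file()
        for chart in ("he_overview", "he_annotated", "he_sample_of_interest", "he_maximum"):
            assert (out / f"{chart}.png").is_file()
        for name in table.sample_names:
            assert (out / name / "heterozygosity.tsv").is_file()
            assert (out / name / "he.png").is_file()
        header, line = (out / "heterozygosity.tsv").read_text().splitlines()[:2]
        assert header == "ID\tHeterozygosity\tPopulation"
        assert line.split("\t")[0] == "dog1"

    def test_unknown_sample_of_interest_is_an_error(self, tmp_path):
        table = make_table([["0/1"]], 1)
        with pytest.raises(DataError, match="unknown sample"):
            diversity_outputs(heterozygosity(table), tmp_path, sample_of_interest="zz")

    def test_single_sample_chart_renders(self, tmp_path):
        table = make_table([["0/1"], ["0/0"]], 1)
        files = diversity_outputs(heterozygosity(table), tmp_path)
        assert files["chart_plain"].is_file()

    def test_max_he_tie_breaks_to_first_sample(self):
        table = make_table([["0/1", "0/1"]], 2)
        assert heterozygosity(table).max_he_row().sample_name == "s1"
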