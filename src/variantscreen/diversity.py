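"""Within-individual diversity from a multi-sample VCF.

The statistic is the average heterozygosity of each sample,

    He = n_het / n_shared,

where ``n_het`` is the number of heterozygous loci in that sample and
``n_shared`` the number of loci genotyped in *every* sample of the file. The
restriction to the shared, fully-called locus set makes the denominator — and
hence the estimates — comparable across samples: adding samples can only
shrink the shared set, never bias one sample's denominator. The ratio is kept
as an exact rational and formatted to 15 decimal places in tables.

Haploid genotypes cannot be heterozygous, so any locus that is haploid in at
least one sample is excluded from the shared set; a multi-allelic genotype
with two different ALT alleles (e.g. 1/2) counts as heterozygous, since the
two alleles differ.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from .errors import DataError
from .vcf import VcfTable

logger = logging.getLogger(__name__)

__all__ = [
    "DiversityRow",
    "DiversitySummary",
    "shared_called_loci",
    "heterozygosity",
    "diversity_outputs",
    "read_population_map",
]


@dataclass
class DiversityRow:
    sample_name: str
    population: str
    n_het: int
    n_shared: int

    @property
    def he(self) -> Fraction:
        return Fraction(self.n_het, self.n_shared)

    @property
    def he_text(self) -> str:
        """He formatted to 15 decimal places (exact decimal expansion of the
        rational, rounded half-even)."""
        scaled = self.he * 10**15
        q = scaled.numerator // scaled.denominator
        if 2 * (scaled.numerator % scaled.denominator) >= scaled.denominator:
            q += 1
        return f"{q // 10**15}.{q % 10**15:015d}"


@dataclass
class DiversitySummary:
    rows: list[DiversityRow]

    @property
    def n_shared(self) -> int:
        return self.rows[0].n_shared if self.rows else 0

    def row(self, sample_name: str) -> DiversityRow:
        for r in self.rows:
            if r.sample_name == sample_name:
                return r
        raise DataError(
            f"unknown sample {sample_name!r}; available: "
            + ", ".join(r.sample_name for r in self.rows)
        )

    def max_he_row(self) -> DiversityRow:
        best = self.rows[0]
        tied = False
        for r in self.rows[1:]:
            if r.he > best.he:
                best, tied = r, False
            elif r.he == best.he:
                tied = True
        if tied:
            logger.info(
                "tie for maximum heterozygosity; highlighting the first "
                "sample in table order (%s)", best.sample_name,
            )
        return best


def shared_called_loci(table: VcfTable) -> list[tuple[str, int]]:
    """Loci (chrom, pos) genotyped in every sample, in file order.

    A locus is retained only if every sample's genotype is a full diploid
    call — no missing allele index anywhere, no haploid genotypes.
    """
    if not table.sample_names or not table.records:
        raise DataError("diversity needs at least one sample and one record")
    return [
        (rec.chrom, rec.pos)
        for rec in table.records
        if all(gt.is_diploid_call for gt in rec.genotypes)
    ]


def heterozygosity(
    table: VcfTable, populations: dict[str, str] | None = None
) -> DiversitySummary:
    """Per-sample average heterozygosity over the shared-locus set.

    ``populations`` maps sample name → population label; unmapped samples
    (and the default) fall into population "all".
    """
    shared = set(shared_called_loci(table))
    n_shared = len(shared)
    if n_shared == 0:
        raise DataError(
            "no locus is called in every sample — average heterozygosity is "
            "undefined (0/0); check missingness in the multi-sample VCF"
        )
    populations = populations or {}
    counts = [0] * table.n_samples
    for rec in table.records:
        if (rec.chrom, rec.pos) not in shared:
            continue
        for i, gt in enumerate(rec.genotypes):
            if gt.is_het:
                counts[i] += 1
    rows = [
        DiversityRow(
            sample_name=name,
            population=populations.get(name, "all"),
            n_het=counts[i],
            n_shared=n_shared,
        )
        for i, name in enumerate(table.sample_names)
    ]
    return DiversitySummary(rows)


def _write_table(summary: DiversitySummary, path: Path, rows=None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ID", "Heterozygosity", "Population"])
        for r in rows if rows is not None else summary.rows:
            w.writerow([r.sample_name, r.he_text, r.population])


def _bar_chart(
    summary: DiversitySummary,
    path: Path,
    title: str,
    label_all: bool = False,
    highlight: str | None = None,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [r.sample_name for r in summary.rows]
    values = [float(r.he) for r in summary.rows]
    colors = [
        "#d95f02" if name == highlight else "#1f77b4" for name in names
    ]
    fig, ax = plt.subplots(figsize=(max(4, 0.9 * len(names) + 2), 4))
    ax.bar(range(len(names)), values, color=colors)
    ax.set_ylabel("Heterozygosity (He)")
    ax.set_title(title)
    if label_all or highlight is not None:
        ticks = [
            n if (label_all or n == highlight) else "" for n in names
        ]
        ax.set_xticks(range(len(names)), ticks, rotation=45, ha="right")
    else:
        ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def diversity_outputs(
    summary: DiversitySummary,
    out_dir: str | Path,
    sample_of_interest: str | None = None,
) -> dict[str, Path]:
    """Write the diversity tables and the four bar-chart variants.

    Per population a TSV table (ID, Heterozygosity, Population); charts:
    (A) plain, (B) every sample labelled, (C) the sample of interest
    highlighted, (D) the maximum-He sample highlighted. A sub-folder per
    sample holds that sample's table row and its highlighted chart. On a tie
    for the maximum, the first sample in table order is highlighted and the
    tie is logged.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    table_path = out_dir / "heterozygosity.tsv"
    _write_table(summary, table_path)
    files["table"] = table_path

    _bar_chart(summary, out_dir / "he_overview.png", "Heterozygosity per population")
    files["chart_plain"] = out_dir / "he_overview.png"
    _bar_chart(
        summary, out_dir / "he_annotated.png",
        "Heterozygosity per population", label_all=True,
    )
    files["chart_annotated"] = out_dir / "he_annotated.png"
    if sample_of_interest is not None:
        summary.row(sample_of_interest)  # validates the name
        _bar_chart(
            summary, out_dir / "he_sample_of_interest.png",
            f"Sample of interest: {sample_of_interest}",
            highlight=sample_of_interest,
        )
        files["chart_sample"] = out_dir / "he_sample_of_interest.png"
    max_row = summary.max_he_row()
    _bar_chart(
        summary, out_dir / "he_maximum.png",
        f"Highest heterozygosity: {max_row.sample_name}",
        highlight=max_row.sample_name,
    )
    files["chart_max"] = out_dir / "he_maximum.png"

    for r in summary.rows:
        sub = out_dir / r.sample_name
        sub.mkdir(exist_ok=True)
        _write_table(summary, sub / "heterozygosity.tsv", rows=[r])
        _bar_chart(
            summary, sub / "he.png",
            f"Sample {r.sample_name}", highlight=r.sample_name,
        )
    logger.info("diversity outputs written to %s", out_dir)
    return files


def read_population_map(path: str | Path) -> dict[str, str]:
    """Two-column headerless TSV: sample name → population label."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0].strip():
                out[parts[0].strip()] = parts[1].strip()
    return out
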