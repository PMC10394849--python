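"""Standardized clinical report rendering.

Each screening run produces five HTML tables — priority variants,
variants not known to segregate in the breed, homozygous-reference loci, and
the two breeding-advice tables — combined into one self-contained report with
client-side column sorting. A machine-readable TSV mirror of every table is
written alongside the HTML, and run metadata (sample, breed, tool version,
input digests, timestamp) goes into a separate ``metadata.json`` so the table
bodies themselves are a pure function of the inputs: identical inputs give
byte-identical tables.
"""

from __future__ import annotations

import csv
import hashlib
import html
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .advice import HETEROPLASMY_NOTE, HOMOZYGOUS_GENERAL_NOTE
from .diversity import DiversitySummary
from .errors import DataError
from .filtering import FilterResult, VariantReportRow

logger = logging.getLogger(__name__)

__all__ = ["ReportBundle", "render_report"]

VARIANT_COLUMNS = [
    "Chromosome", "Location", "Gene", "Reference", "Allele 1", "Allele 2",
    "Zygosity", "Inheritance", "Phenotype", "Annotation", "Status",
    "Allele mismatch",
]
ADVICE_COLUMNS = [
    "Chromosome", "Location", "Gene", "Zygosity", "Inheritance",
    "Phenotype", "Breeding advice",
]

_TABLE_TITLES = {
    "priority": "Variants found in the sample and known to segregate in the breed",
    "other_breed": "Variants found in the sample but not known to segregate in the breed",
    "hom_ref": "Catalogue loci where the sample is homozygous reference",
    "advice_hom": "Breeding advice for variants found in a homozygous state",
    "advice_het": "Breeding advice for variants found in a heterozygous state",
}

_STYLE = """
body { font-family: sans-serif; margin: 1.5em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 4px 8px; text-align: left; }
th { background: #eee; cursor: pointer; }
caption { font-weight: bold; text-align: left; padding: 4px 0; }
.placeholder td { font-style: italic; color: #666; }
.note { font-size: 0.9em; color: #444; white-space: pre-line; }
"""

_SORT_JS = """
document.querySelectorAll("th").forEach(function (th) {
  th.addEventListener("click", function () {
    var table = th.closest("table");
    var idx = Array.prototype.indexOf.call(th.parentNode.children, th);
    var rows = Array.prototype.slice.call(table.querySelectorAll("tbody tr"));
    var asc = th.dataset.asc !== "true";
    th.dataset.asc = asc;
    rows.sort(function (a, b) {
      var x = a.children[idx].textContent, y = b.children[idx].textContent;
      var nx = parseFloat(x.replace(/,/g, "")), ny = parseFloat(y.replace(/,/g, ""));
      if (!isNaN(nx) && !isNaN(ny)) return asc ? nx - ny : ny - nx;
      return asc ? x.localeCompare(y) : y.localeCompare(x);
    });
    rows.forEach(function (r) { table.querySelector("tbody").appendChild(r); });
  });
});
"""


@dataclass
class ReportBundle:
    """Paths of one rendered report: five tables plus the combined page."""

    out_dir: Path
    tables: dict[str, Path]          # name → HTML path (the five tables)
    tsv_mirrors: dict[str, Path]
    combined: Path
    metadata: Path
    diversity_files: dict[str, Path] = field(default_factory=dict)


def _variant_row_cells(row: VariantReportRow) -> list[str]:
    return [
        row.chrom,
        str(row.pos),
        row.gene,
        row.ref_allele,
        row.allele_1,
        row.allele_2,
        row.zygosity.value,
        row.inheritance.value,
        row.phenotype,
        "; ".join(loc.render() for loc in row.annotations),
        row.locus_status.value,
        "yes" if row.allele_mismatch else "",
    ]


def _advice_row_cells(row: VariantReportRow, advice: str) -> list[str]:
    return [
        row.chrom,
        str(row.pos),
        row.gene,
        row.zygosity.value,
        row.inheritance.value,
        row.phenotype,
        advice,
    ]


def _write_tsv(path: Path, columns: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for cells in rows:
            w.writerow([c.replace("\n", " / ") for c in cells])


def _html_table(
    title: str, columns: list[str], rows: list[list[str]],
    pretty_location: bool = True,
) -> str:
    loc_idx = columns.index("Location") if "Location" in columns else -1
    parts = [f"<table>\n<caption>{html.escape(title)}</caption>\n<thead><tr>"]
    parts += [f"<th>{html.escape(c)}</th>" for c in columns]
    parts.append("</tr></thead>\n<tbody>\n")
    if not rows:
        parts.append(
            f'<tr class="placeholder"><td colspan="{len(columns)}">'
            "No variants</td></tr>\n"
        )
    for cells in rows:
        parts.append("<tr>")
        for i, cell in enumerate(cells):
            text = cell
            if pretty_location and i == loc_idx and text.isdigit():
                text = f"{int(text):,}"
            parts.append(f"<td>{html.escape(text)}</td>")
        parts.append("</tr>\n")
    parts.append("</tbody></table>\n")
    return "".join(parts)


def _html_page(title: str, body: str) -> str:
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title)}</title>"
        f"<style>{_STYLE}</style></head>\n<body>\n"
        f"<h1>{html.escape(title)}</h1>\n{body}"
        f"<script>{_SORT_JS}</script>\n</body></html>\n"
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def render_report(
    result: FilterResult,
    out_dir: str | Path,
    diversity: DiversitySummary | None = None,
    extra_rows: list[VariantReportRow] | None = None,
    input_digests: dict[str, str] | None = None,
    sex: str | None = None,
) -> ReportBundle:
    """Write the five table files, their TSV mirrors and the combined report.

    ``input_digests`` (name → sha256) and ``sex`` only annotate the metadata;
    they never change table content. Raises before writing anything if the
    output directory cannot be created or written (all-or-nothing).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise DataError(f"cannot write to output directory {out_dir}: {exc}") from exc

    table_rows: dict[str, tuple[list[str], list[list[str]], list[str]]] = {
        "priority": (
            VARIANT_COLUMNS,
            [_variant_row_cells(r) for r in result.priority],
            [],
        ),
        "other_breed": (
            VARIANT_COLUMNS,
            [_variant_row_cells(r) for r in result.other_breed],
            [],
        ),
        "hom_ref": (
            VARIANT_COLUMNS,
            [_variant_row_cells(r) for r in result.hom_ref],
            [],
        ),
        "advice_hom": (
            ADVICE_COLUMNS,
            [_advice_row_cells(r, a) for r, a in result.advice_hom],
            [HOMOZYGOUS_GENERAL_NOTE],
        ),
        "advice_het": (
            ADVICE_COLUMNS,
            [_advice_row_cells(r, a) for r, a in result.advice_het],
            [HETEROPLASMY_NOTE],
        ),
    }

    tables: dict[str, Path] = {}
    mirrors: dict[str, Path] = {}
    combined_parts: list[str] = [
        f"<p>Sample: <b>{html.escape(result.sample_name)}</b> — breed: "
        f"<b>{html.escape(result.breed or '(not given)')}</b></p>\n"
    ]
    for name, (columns, rows, notes) in table_rows.items():
        fragment = _html_table(_TABLE_TITLES[name], columns, rows)
        for note in notes:
            fragment += f'<p class="note">{html.escape(note)}</p>\n'
        html_path = out_dir / f"{name}.html"
        html_path.write_text(_html_page(_TABLE_TITLES[name], fragment), encoding="utf-8")
        tables[name] = html_path
        tsv_path = out_dir / f"{name}.tsv"
        _write_tsv(tsv_path, columns, rows)
        mirrors[name] = tsv_path
        combined_parts.append(fragment)

    if extra_rows is not None:
        fragment = _html_table(
            "Other variants in the catalogue genes",
            VARIANT_COLUMNS,
            [_variant_row_cells(r) for r in extra_rows],
        )
        (out_dir / "extra.html").write_text(
            _html_page("Other variants in the catalogue genes", fragment),
            encoding="utf-8",
        )
        _write_tsv(
            out_dir / "extra.tsv",
            VARIANT_COLUMNS,
            [_variant_row_cells(r) for r in extra_rows],
        )
        combined_parts.append(fragment)

    diversity_files: dict[str, Path] = {}
    if diversity is not None:
        div_rows = [
            [r.sample_name, r.he_text, r.population] for r in diversity.rows
        ]
        fragment = _html_table(
            "Diversity: average heterozygosity per sample",
            ["ID", "Heterozygosity", "Population"],
            div_rows,
            pretty_location=False,
        )
        for key in ("chart_annotated", "chart_sample", "chart_max"):
            # charts are written by diversity_outputs into out_dir/diversity
            img = out_dir / "diversity" / {
                "chart_annotated": "he_annotated.png",
                "chart_sample": "he_sample_of_interest.png",
                "chart_max": "he_maximum.png",
            }[key]
            if img.exists():
                fragment += (
                    f'<p><img src="diversity/{img.name}" '
                    f'alt="heterozygosity chart" width="480"></p>\n'
                )
                diversity_files[key] = img
        combined_parts.append(fragment)
        _write_tsv(
            out_dir / "diversity.tsv",
            ["ID", "Heterozygosity", "Population"],
            div_rows,
        )

    combined = out_dir / "report.html"
    combined.write_text(
        _html_page(f"Variant screening report — {result.sample_name}",
                   "".join(combined_parts)),
        encoding="utf-8",
    )

    metadata_path = out_dir / "metadata.json"
    metadata = {
        "tool": "variantscreen",
        "version": __version__,
        "sample": result.sample_name,
        "breed": result.breed,
        "sex": sex,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "input_digests": input_digests or {},
        "tables": {name: path.name for name, path in tables.items()},
    }
    metadata_path.write_text(json.dumps(metadata, indent=2) + "\n", encoding="utf-8")

    logger.info("report written: %s", combined)
    return ReportBundle(
        out_dir=out_dir,
        tables=tables,
        tsv_mirrors=mirrors,
        combined=combined,
        metadata=metadata_path,
        diversity_files=diversity_files,
    )


def compute_input_digests(paths: dict[str, str | Path]) -> dict[str, str]:
    """sha256 of each named input file (missing files are skipped)."""
    out = {}
    for name, path in paths.items():
        p = Path(path)
        if p.is_file():
            out[name] = _sha256(p)
    return out
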