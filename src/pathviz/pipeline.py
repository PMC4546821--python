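"""End-to-end orchestration: data + pathways + mapping -> scored, rendered,
exported analysis.  Shared by the CLI and the RPC service."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .dataset import MeasurementTable, import_data, link_to_pathway
from .export_html import HtmlReport, ReportEntry, export_report
from .idmapper import MappingStore, load_mapping_table
from .model import PathwayDoc, read_gpml
from .stats import RankedResult, rank_pathways, write_results_tsv
from .visualize import VisualizationSpec, render_pathway

__all__ = ["AnalysisResult", "collect_pathway_files", "run_analysis"]


@dataclass
class AnalysisResult:
    ranked: RankedResult
    report: Optional[HtmlReport]
    results_tsv: Optional[Path]


def collect_pathway_files(source) -> list[Path]:
    """A single GPML file, or every *.gpml under a directory (sorted)."""
    p = Path(source)
    if p.is_dir():
        files = sorted(p.glob("*.gpml"))
        if not files:
            raise FileNotFoundError(f"no .gpml files in {p}")
        return files
    if not p.exists():
        raise FileNotFoundError(str(p))
    return [p]


def run_analysis(
    data_path,
    id_column: str,
    syscode: str,
    pathway_source,
    mapping_path,
    criterion: Optional[str],
    spec: Optional[VisualizationSpec],
    out_dir,
) -> AnalysisResult:
    """Load everything, link, optionally score, render, and export HTML.

    When ``criterion`` is None the pathways are rendered and exported
    without a ranking block (visualisation-only run); otherwise the full
    ranked report plus a results.tsv is written to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = import_data(data_path, id_column, syscode)
    store = load_mapping_table(mapping_path)
    files = collect_pathway_files(pathway_source)
    docs: list[tuple[PathwayDoc, str]] = [(read_gpml(f), str(f)) for f in files]

    entries: dict[str, ReportEntry] = {}
    for doc, _src in docs:
        link = link_to_pathway(table, doc, store)
        rendered = render_pathway(doc, link, table, spec)
        entries[doc.name] = ReportEntry(doc=doc, rendered=rendered, link=link)

    if criterion is None:
        # visualisation-only run: standalone page(s), no ranking block
        from .export_html import export_pathway_html, slugify

        report = None
        for doc, _src in docs:
            entry = entries[doc.name]
            dest = out_dir / "html" if len(docs) == 1 else out_dir / "html" / slugify(doc.name)
            report = export_pathway_html(
                doc, entry.rendered, dest, table=table,
                link=entry.link, spec=spec,
            )
        return AnalysisResult(ranked=None, report=report, results_tsv=None)  # type: ignore[arg-type]

    ranked = rank_pathways(docs, table, store, criterion)
    results_tsv = out_dir / "results.tsv"
    write_results_tsv(ranked, results_tsv)
    report = export_report(ranked, entries, out_dir / "html", table=table, spec=spec)
    return AnalysisResult(ranked=ranked, report=report, results_tsv=results_tsv)
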