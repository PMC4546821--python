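"""Hyperlinked HTML report assembly.

The report is a self-contained mini-website: an index with the analysis
settings, the ranked clickable pathway list and the legend in a sidebar,
plus a content iframe; one page per pathway embedding its PNG with an
image map; and one back page per data node showing the node's annotation
(with database links where a URL template is known for its system code)
and the measurement rows matched to it.

Layout under the output directory::

    index.html
    pathways/<slug>.html
    backpages/<slug>/<element_id>.html
    assets/<slug>.png, assets/legend.svg

Slugs are sanitised pathway names with collision suffixes.  Output is
deterministic: re-export over an existing directory writes identical
bytes (no timestamps).
"""

from __future__ import annotations

import html
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .dataset import MISSING, MeasurementTable, NodeDataLink
from .model import DataNode, PathwayDoc
from .stats import RankedResult
from .visualize import RenderedPathway, VisualizationSpec, make_legend

__all__ = [
    "HtmlReport",
    "ReportEntry",
    "ExportError",
    "export_report",
    "export_pathway_html",
    "DATABASE_URL_TEMPLATES",
    "slugify",
]


class ExportError(Exception):
    pass


#: per-system-code URL templates for back-page database links; extensible.
DATABASE_URL_TEMPLATES: dict[str, str] = {
    "L": "https://www.ncbi.nlm.nih.gov/gene/{id}",
    "En": "https://www.ensembl.org/id/{id}",
    "H": "https://www.genenames.org/data/gene-symbol-report/#!/symbol/{id}",
    "S": "https://www.uniprot.org/uniprotkb/{id}",
    "Ce": "https://www.ebi.ac.uk/chebi/searchId.do?chebiId={id}",
    "Ch": "https://hmdb.ca/metabolites/{id}",
}


@dataclass
class ReportEntry:
    """Everything the exporter needs for one pathway."""

    doc: PathwayDoc
    rendered: RenderedPathway
    link: Optional[NodeDataLink] = None


@dataclass
class HtmlReport:
    out_dir: Path
    index: Path
    pathway_pages: dict[str, Path]
    backpage_dirs: dict[str, Path]


def slugify(name: str) -> str:
    slug = re.sub(r"[^A-Za-z0-9._-]+", "-", name).strip("-").lower()
    return slug or "pathway"


def _unique_slugs(names: list[str]) -> dict[str, str]:
    slugs: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        base = slugify(name)
        slug, k = base, 2
        while slug in used:
            slug, k = f"{base}-{k}", k + 1
        used.add(slug)
        slugs[name] = slug
    return slugs


def _write(path: Path, data) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(data, str):
        data = data.encode("utf-8")
    path.write_bytes(data)


_PAGE = """<!DOCTYPE html>
<html lang="en">
<head><meta charset="utf-8"><title>{title}</title>
<style>body{{font-family:sans-serif;margin:1em}}table{{border-collapse:collapse}}
td,th{{border:1px solid #999;padding:2px 8px}}</style></head>
<body>
{body}
</body>
</html>
"""


def _esc(text) -> str:
    return html.escape(str(text), quote=True)


def _fmt_cell(v) -> str:
    if v is MISSING:
        return "NA"
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def _backpage_html(
    node: DataNode,
    table: Optional[MeasurementTable],
    row_indices: list[int],
) -> str:
    parts = [f"<h1>{_esc(node.label)}</h1>"]
    parts.append("<h2>Annotation</h2><table>")
    parts.append(f"<tr><th>Label</th><td>{_esc(node.label)}</td></tr>")
    parts.append(f"<tr><th>Type</th><td>{_esc(node.node_type)}</td></tr>")
    if node.xref is not None:
        template = DATABASE_URL_TEMPLATES.get(node.xref.system_code)
        ident = _esc(node.xref.identifier)
        shown = (
            f'<a href="{template.format(id=node.xref.identifier)}">{ident}</a>'
            if template
            else ident
        )
        parts.append(
            f"<tr><th>Identifier</th><td>{shown} "
            f"(system {_esc(node.xref.system_code)})</td></tr>"
        )
    else:
        parts.append("<tr><th>Identifier</th><td>none</td></tr>")
    parts.append("</table>")

    parts.append("<h2>Data</h2>")
    if table is None or not row_indices:
        parts.append("<p>No data uploaded for this element.</p>")
    else:
        if len(row_indices) > 1:
            parts.append(
                f"<p>{len(row_indices)} dataset rows match this element; "
                "the first (in file order) is shown on the diagram.</p>"
            )
        parts.append("<table><tr><th>identifier</th><th>system</th>")
        for col in table.column_names:
            parts.append(f"<th>{_esc(col)}</th>")
        parts.append("</tr>")
        for i in row_indices:
            parts.append(
                f"<tr><td>{_esc(table.identifiers[i])}</td>"
                f"<td>{_esc(table.system_codes[i])}</td>"
            )
            for col in table.column_names:
                parts.append(f"<td>{_fmt_cell(table.rows[i][col])}</td>")
            parts.append("</tr>")
        parts.append("</table>")
    return _PAGE.format(title=_esc(node.label), body="\n".join(parts))


def _pathway_page_html(
    name: str,
    slug: str,
    entry: ReportEntry,
    table: Optional[MeasurementTable],
) -> str:
    areas = []
    for node in entry.doc.data_nodes():
        region = entry.rendered.hit_regions.get(node.element_id)
        if region is None:
            continue
        x0, y0, x1, y1 = region
        areas.append(
            f'<area shape="rect" coords="{x0},{y0},{x1},{y1}" '
            f'href="../backpages/{slug}/{node.element_id}.html" '
            f'target="_blank" alt={_q(node.label)}>'
        )
    body = (
        f"<h1>{_esc(name)}</h1>\n"
        f'<img src="../assets/{slug}.png" usemap="#pathwaymap" '
        f'width="{entry.rendered.width_px}" height="{entry.rendered.height_px}" '
        f'alt={_q(name)}>\n'
        f'<map name="pathwaymap">\n' + "\n".join(areas) + "\n</map>"
    )
    return _PAGE.format(title=_esc(name), body=body)


def _q(text: str) -> str:
    return '"' + _esc(text) + '"'


def _export_backpages(
    out_dir: Path,
    slug: str,
    entry: ReportEntry,
    table: Optional[MeasurementTable],
) -> Path:
    bp_dir = out_dir / "backpages" / slug
    for node in entry.doc.data_nodes():
        rows = entry.link.node_rows.get(node.element_id, []) if entry.link else []
        _write(bp_dir / f"{node.element_id}.html", _backpage_html(node, table, rows))
    return bp_dir


def export_report(
    ranked: RankedResult,
    entries: dict[str, ReportEntry],
    out_dir,
    table: Optional[MeasurementTable] = None,
    spec: Optional[VisualizationSpec] = None,
) -> HtmlReport:
    """Write the full ranked report.

    ``entries`` maps each ranked pathway name to its ReportEntry; the key
    sets must match exactly.
    """
    ranked_names = [s.name for s in ranked.scores]
    if set(ranked_names) != set(entries):
        raise ExportError(
            f"ranked pathways {sorted(set(ranked_names))} do not match "
            f"rendered entries {sorted(entries)}"
        )
    out_dir = Path(out_dir)
    slugs = _unique_slugs(ranked_names)

    pathway_pages: dict[str, Path] = {}
    backpage_dirs: dict[str, Path] = {}
    for score in ranked.scores:
        name, slug = score.name, slugs[score.name]
        entry = entries[name]
        _write(out_dir / "assets" / f"{slug}.png", entry.rendered.png)
        page = out_dir / "pathways" / f"{slug}.html"
        _write(page, _pathway_page_html(name, slug, entry, table))
        pathway_pages[name] = page
        backpage_dirs[name] = _export_backpages(out_dir, slug, entry, table)

    if spec is not None:
        _write(out_dir / "assets" / "legend.svg", make_legend(spec))

    # index: settings overview + ranked clickable list + content iframe
    rows = []
    for rank, score in enumerate(ranked.scores, start=1):
        z_text = "NaN" if not score.z_defined else f"{score.z:.3f}"
        c = score.counts
        rows.append(
            f'<tr><td>{rank}</td>'
            f'<td><a href="pathways/{slugs[score.name]}.html" target="content">'
            f"{_esc(score.name)}</a></td>"
            f"<td>{c.n}</td><td>{c.r}</td><td>{z_text}</td></tr>"
        )
    legend_block = (
        '<h2>Legend</h2><img src="assets/legend.svg" alt="legend">'
        if spec is not None
        else ""
    )
    body = f"""<h1>Pathway over-representation results</h1>
<h2>Settings</h2>
<table>
<tr><th>Criterion</th><td>{_esc(ranked.criterion_text)}</td></tr>
<tr><th>Dataset</th><td>{_esc(os.path.basename(ranked.dataset_source) or "(in memory)")}</td></tr>
<tr><th>Measured genes (N)</th><td>{ranked.N}</td></tr>
<tr><th>Genes meeting criterion (R)</th><td>{ranked.R}</td></tr>
<tr><th>Pathways scored</th><td>{len(ranked.scores)}</td></tr>
<tr><th>Unmappable rows excluded</th><td>{ranked.excluded_unmappable_rows}</td></tr>
</table>
<h2>Pathways ranked by Z score</h2>
<table>
<tr><th>rank</th><th>pathway</th><th>n</th><th>r</th><th>Z</th></tr>
{chr(10).join(rows)}
</table>
{legend_block}
<h2>Pathway view</h2>
<iframe name="content" style="width:100%;height:600px;border:1px solid #999"></iframe>"""
    index = out_dir / "index.html"
    _write(index, _PAGE.format(title="Pathway analysis report", body=body))
    return HtmlReport(out_dir, index, pathway_pages, backpage_dirs)


def export_pathway_html(
    doc: PathwayDoc,
    rendered: RenderedPathway,
    out_dir,
    table: Optional[MeasurementTable] = None,
    link: Optional[NodeDataLink] = None,
    spec: Optional[VisualizationSpec] = None,
) -> HtmlReport:
    """Standalone single-pathway export: one page plus its back pages,
    no ranking block."""
    out_dir = Path(out_dir)
    slug = slugify(doc.name)
    entry = ReportEntry(doc=doc, rendered=rendered, link=link)
    _write(out_dir / "assets" / f"{slug}.png", rendered.png)
    page = out_dir / "pathways" / f"{slug}.html"
    _write(page, _pathway_page_html(doc.name, slug, entry, table))
    backpage_dir = _export_backpages(out_dir, slug, entry, table)
    if spec is not None:
        _write(out_dir / "assets" / "legend.svg", make_legend(spec))
    body = (
        f"<h1>{_esc(doc.name)}</h1>"
        f'<p><a href="pathways/{slug}.html" target="content">{_esc(doc.name)}</a></p>'
        + (f'<h2>Legend</h2><img src="assets/legend.svg" alt="legend">' if spec else "")
        + '\n<iframe name="content" style="width:100%;height:600px;'
        'border:1px solid #999"></iframe>'
    )
    index = out_dir / "index.html"
    _write(index, _PAGE.format(title=_esc(doc.name), body=body))
    return HtmlReport(out_dir, index, {doc.name: page}, {doc.name: backpage_dir})
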