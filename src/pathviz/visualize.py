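"""Colour computation and pathway rendering with per-node data stripes.

Measurements are painted onto pathway diagrams the way PathVisio does it:
each visualised column gets either a colour gradient (piecewise-linear
value-to-colour interpolation between 2 or 3 anchors, e.g. blue/white/red
at -1/0/1 for log2 fold changes) or an ordered list of colour rules
(criterion -> fixed colour, e.g. green when P <= 0.05, white otherwise).
A mapped data node is split into k equal-width vertical stripes, one per
visualised column, left to right in spec order; nodes absent from the
dataset are painted light grey.

Rendering produces a deterministic SVG 1.1 document, a PNG raster at a
fixed 2 px per diagram unit, and per-node rectangular hit regions in
raster pixel coordinates for HTML image maps.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union
from xml.sax.saxutils import escape, quoteattr

from PIL import Image, ImageDraw

from .dataset import (
    CriterionAST,
    MeasurementTable,
    MISSING,
    NodeDataLink,
    criterion_met,
    parse_criterion,
)
from .model import DataNode, FreeLabel, Interaction, PathwayDoc

__all__ = [
    "RGB",
    "ColorGradient",
    "ColorRule",
    "VisualizationSpec",
    "RenderedPathway",
    "VisualizationError",
    "interpolate_color",
    "apply_rules",
    "render_pathway",
    "make_legend",
    "legend_png",
    "parse_color",
    "gradient_from_text",
    "stripe_bounds",
    "UNMAPPED_COLOR",
    "RULE_FALLBACK_COLOR",
    "RASTER_SCALE",
]

RGB = tuple[int, int, int]

UNMAPPED_COLOR: RGB = (211, 211, 211)      # light grey: node absent from dataset
NO_DATA_CELL_COLOR: RGB = (211, 211, 211)  # missing cell within a mapped node
RULE_FALLBACK_COLOR: RGB = (255, 255, 255)
RASTER_SCALE = 2  # raster pixels per diagram unit


class VisualizationError(Exception):
    pass


_NAMED_COLORS = {
    "white": (255, 255, 255),
    "black": (0, 0, 0),
    "red": (255, 0, 0),
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
    "yellow": (255, 255, 0),
    "orange": (255, 165, 0),
    "purple": (128, 0, 128),
    "grey": (128, 128, 128),
    "gray": (128, 128, 128),
    "lightgrey": UNMAPPED_COLOR,
    "lightgray": UNMAPPED_COLOR,
}


def parse_color(text: Union[str, Sequence[int]]) -> RGB:
    """Accepts '#rrggbb', 'r,g,b', a colour name, or an RGB triple."""
    if not isinstance(text, str):
        r, g, b = text
        return (int(r), int(g), int(b))
    t = text.strip().lower()
    if t in _NAMED_COLORS:
        return _NAMED_COLORS[t]
    if t.startswith("#") and len(t) == 7:
        return (int(t[1:3], 16), int(t[3:5], 16), int(t[5:7], 16))
    if "," in t:
        parts = [int(p) for p in t.split(",")]
        if len(parts) == 3 and all(0 <= p <= 255 for p in parts):
            return (parts[0], parts[1], parts[2])
    raise VisualizationError(f"cannot parse colour {text!r}")


def gradient_from_text(text: str) -> "ColorGradient":
    """Parse ``"blue@-1,white@0,red@1"`` into a ColorGradient."""
    anchors = []
    for part in text.split(","):
        if "@" not in part:
            raise VisualizationError(f"gradient anchor {part!r} must be colour@value")
        color_text, value_text = part.rsplit("@", 1)
        anchors.append((float(value_text), parse_color(color_text)))
    return ColorGradient(tuple(anchors))


# ---------------------------------------------------------------------------
# Gradients and rules

@dataclass(frozen=True)
class ColorGradient:
    """2 or 3 (value, colour) anchors with strictly increasing values."""

    anchors: tuple[tuple[float, RGB], ...]

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise VisualizationError("gradient needs at least 2 anchors")
        values = [v for v, _ in self.anchors]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise VisualizationError("gradient anchor values must be strictly increasing")


@dataclass(frozen=True)
class ColorRule:
    """criterion -> colour; first matching rule in a list wins."""

    criterion: CriterionAST
    color: RGB
    text: str = ""  # original criterion text for legends / provenance

    @classmethod
    def from_text(cls, criterion_text: str, color) -> "ColorRule":
        return cls(parse_criterion(criterion_text), parse_color(color), criterion_text)


@dataclass
class VisualizationSpec:
    """Ordered (column name, gradient-or-rule-list) entries plus defaults."""

    column_entries: list[tuple[str, Union[ColorGradient, list[ColorRule]]]]
    unmapped_color: RGB = UNMAPPED_COLOR
    no_data_color: RGB = NO_DATA_CELL_COLOR
    fallback_color: RGB = RULE_FALLBACK_COLOR

    def __post_init__(self):
        names = [name for name, _ in self.column_entries]
        if len(set(names)) != len(names):
            raise VisualizationError("visualisation columns must be distinct")

    @property
    def columns(self) -> list[str]:
        return [name for name, _ in self.column_entries]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def interpolate_color(gradient: ColorGradient, value: float) -> RGB:
    """Piecewise-linear per-channel interpolation between bracketing anchors.

    Values outside the anchor range clamp to the end anchors; channels are
    rounded half-up to integers 0-255.
    """
    if not math.isfinite(value):
        raise VisualizationError(f"cannot interpolate non-finite value {value!r}")
    anchors = gradient.anchors
    if value <= anchors[0][0]:
        return anchors[0][1]
    if value >= anchors[-1][0]:
        return anchors[-1][1]
    for (v0, c0), (v1, c1) in zip(anchors, anchors[1:]):
        if v0 <= value <= v1:
            t = (value - v0) / (v1 - v0)
            return tuple(_round_half_up(a + t * (b - a)) for a, b in zip(c0, c1))  # type: ignore[return-value]
    raise VisualizationError("unreachable: anchors not bracketing")  # pragma: no cover


def apply_rules(rules: Sequence[ColorRule], row: dict, fallback: RGB = RULE_FALLBACK_COLOR) -> RGB:
    """First rule whose criterion evaluates true wins; missing or false falls
    through; no rule true -> fallback colour."""
    for rule in rules:
        if criterion_met(rule.criterion, row):
            return rule.color
    return fallback


def _cell_color(entry, row: Optional[dict], column: str, spec: VisualizationSpec) -> RGB:
    if row is None:
        return spec.unmapped_color
    value = row.get(column, MISSING)
    if isinstance(entry, ColorGradient):
        if value is MISSING or isinstance(value, str):
            return spec.no_data_color
        return interpolate_color(entry, value)
    return apply_rules(entry, row, spec.fallback_color)


def stripe_bounds(x0: int, width: int, k: int) -> list[tuple[int, int]]:
    """Split [x0, x0+width) into k stripes whose widths sum exactly to width."""
    edges = [x0 + _round_half_up(i * width / k) for i in range(k + 1)]
    return list(zip(edges, edges[1:]))


# ---------------------------------------------------------------------------
# Rendering

@dataclass
class RenderedPathway:
    svg: str
    png: bytes
    hit_regions: dict[str, tuple[int, int, int, int]]  # element_id -> px rect
    width_px: int
    height_px: int


def _svg_rect(x, y, w, h, fill: RGB, stroke: Optional[RGB] = None) -> str:
    s = (
        f'<rect x="{x}" y="{y}" width="{w}" height="{h}" '
        f'fill="rgb({fill[0]},{fill[1]},{fill[2]})"'
    )
    if stroke is not None:
        s += f' stroke="rgb({stroke[0]},{stroke[1]},{stroke[2]})" stroke-width="1"'
    return s + " />"


def _svg_text(x, y, text: str, size: int = 10, anchor: str = "middle") -> str:
    return (
        f'<text x="{x}" y="{y}" font-family="sans-serif" font-size="{size}" '
        f'text-anchor="{anchor}" dominant-baseline="middle">{escape(text)}</text>'
    )


def _node_cell_colors(
    node: DataNode,
    link: Optional[NodeDataLink],
    table: Optional[MeasurementTable],
    spec: Optional[VisualizationSpec],
) -> Optional[list[RGB]]:
    """Per-stripe colours for a node, or None for 'no data overlay'."""
    if spec is None or not spec.column_entries:
        return None
    row_idx = link.first_row(node.element_id) if link is not None else None
    row = table.rows[row_idx] if (row_idx is not None and table is not None) else None
    return [
        _cell_color(entry, row, column, spec)
        for column, entry in spec.column_entries
    ]


def render_pathway(
    doc: PathwayDoc,
    link: Optional[NodeDataLink] = None,
    table: Optional[MeasurementTable] = None,
    spec: Optional[VisualizationSpec] = None,
) -> RenderedPathway:
    """Render a pathway with an optional data overlay.

    Each mapped node shows k equal-width vertical stripes (k = number of
    spec entries) coloured from the node's first matching row; unmapped
    nodes are solid light grey; without a spec, nodes are plain white.
    Returns SVG text, PNG bytes, and per-node pixel hit regions.
    """
    if spec is not None and table is not None:
        missing_cols = [c for c in spec.columns if c not in table.column_names]
        if missing_cols:
            raise VisualizationError(
                f"spec references absent columns: {missing_cols}; "
                f"table has {table.column_names}"
            )

    s = RASTER_SCALE
    width_px = max(1, int(math.ceil(doc.board_width * s)))
    height_px = max(1, int(math.ceil(doc.board_height * s)))

    svg_parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width_px}" height="{height_px}" '
        f'viewBox="0 0 {width_px} {height_px}">',
        _svg_rect(0, 0, width_px, height_px, (255, 255, 255)),
    ]
    img = Image.new("RGB", (width_px, height_px), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    hit_regions: dict[str, tuple[int, int, int, int]] = {}

    # edges first, under the nodes
    centers = {
        e.element_id: (e.cx * s, e.cy * s)
        for e in doc.elements
        if isinstance(e, (DataNode, FreeLabel))
    }
    for it in doc.interactions():
        if it.source_ref not in centers or it.target_ref not in centers:
            continue
        (x1, y1), (x2, y2) = centers[it.source_ref], centers[it.target_ref]
        x1, y1, x2, y2 = (int(round(v)) for v in (x1, y1, x2, y2))
        svg_parts.append(
            f'<line x1="{x1}" y1="{y1}" x2="{x2}" y2="{y2}" '
            'stroke="rgb(64,64,64)" stroke-width="1" />'
        )
        draw.line([(x1, y1), (x2, y2)], fill=(64, 64, 64), width=1)

    for node in doc.data_nodes():
        x0, y0, x1, y1 = (int(round(v * s)) for v in node.bounds)
        w, h = x1 - x0, y1 - y0
        colors = _node_cell_colors(node, link, table, spec)
        if colors is None:
            fills = [(x0, x1, (255, 255, 255))]
        else:
            fills = [
                (sx0, sx1, color)
                for (sx0, sx1), color in zip(stripe_bounds(x0, w, len(colors)), colors)
            ]
        for sx0, sx1, color in fills:
            svg_parts.append(_svg_rect(sx0, y0, sx1 - sx0, h, color))
            draw.rectangle([sx0, y0, max(sx0, sx1 - 1), y1 - 1], fill=color)
        svg_parts.append(
            f'<rect x="{x0}" y="{y0}" width="{w}" height="{h}" '
            'fill="none" stroke="rgb(0,0,0)" stroke-width="1" />'
        )
        draw.rectangle([x0, y0, x1 - 1, y1 - 1], outline=(0, 0, 0), width=1)
        cx_px, cy_px = int(round(node.cx * s)), int(round(node.cy * s))
        svg_parts.append(_svg_text(cx_px, cy_px, node.label))
        draw.text((cx_px, cy_px), node.label, fill=(0, 0, 0), anchor="mm")
        hit_regions[node.element_id] = (x0, y0, x1, y1)

    for lab in doc.labels():
        cx_px, cy_px = int(round(lab.cx * s)), int(round(lab.cy * s))
        svg_parts.append(_svg_text(cx_px, cy_px, lab.text))
        draw.text((cx_px, cy_px), lab.text, fill=(0, 0, 0), anchor="mm")

    svg_parts.append("</svg>")
    svg = "\n".join(svg_parts) + "\n"

    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return RenderedPathway(
        svg=svg,
        png=buf.getvalue(),
        hit_regions=hit_regions,
        width_px=width_px,
        height_px=height_px,
    )


# ---------------------------------------------------------------------------
# Legend

def make_legend(spec: VisualizationSpec) -> str:
    """Legend SVG: one swatch block per column entry — a labelled gradient
    bar, or the rule list with colours and criterion text."""
    block_h, bar_w, pad = 46, 220, 10
    rows: list[str] = []
    y = pad
    for column, entry in spec.column_entries:
        rows.append(_svg_text(pad, y + 8, column, size=11, anchor="start"))
        if isinstance(entry, ColorGradient):
            # sampled gradient bar with anchor value labels
            n_seg = 60
            lo, hi = entry.anchors[0][0], entry.anchors[-1][0]
            seg_w = bar_w / n_seg
            for i in range(n_seg):
                v = lo + (hi - lo) * (i + 0.5) / n_seg
                c = interpolate_color(entry, v)
                x = pad + i * seg_w
                rows.append(
                    f'<rect x="{x:.2f}" y="{y + 16}" width="{seg_w + 0.5:.2f}" height="14" '
                    f'fill="rgb({c[0]},{c[1]},{c[2]})" />'
                )
            for v, _c in entry.anchors:
                x = pad + (v - lo) / (hi - lo) * bar_w
                label = f"{v:g}"
                rows.append(_svg_text(x, y + 38, label, size=9))
        else:
            x = pad
            for rule in entry:
                c = rule.color
                rows.append(
                    f'<rect x="{x}" y="{y + 16}" width="14" height="14" '
                    f'fill="rgb({c[0]},{c[1]},{c[2]})" stroke="rgb(0,0,0)" />'
                )
                rows.append(_svg_text(x + 20, y + 23, rule.text or "rule", size=9, anchor="start"))
                x += 20 + 7 * max(4, len(rule.text)) + 12
            fc = spec.fallback_color
            rows.append(
                f'<rect x="{x}" y="{y + 16}" width="14" height="14" '
                f'fill="rgb({fc[0]},{fc[1]},{fc[2]})" stroke="rgb(0,0,0)" />'
            )
            rows.append(_svg_text(x + 20, y + 23, "otherwise", size=9, anchor="start"))
        y += block_h
    width = bar_w + 260
    height = max(y + pad, pad * 2)
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" viewBox="0 0 {width} {height}">\n'
        + "\n".join(rows)
        + "\n</svg>\n"
    )


def legend_png(spec: VisualizationSpec) -> bytes:
    """Raster legend matching :func:`make_legend` content (simplified)."""
    block_h, bar_w, pad = 46, 220, 10
    height = max(len(spec.column_entries) * block_h + 2 * pad, 2 * pad)
    width = bar_w + 260
    img = Image.new("RGB", (width, height), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    y = pad
    for column, entry in spec.column_entries:
        draw.text((pad, y), column, fill=(0, 0, 0))
        if isinstance(entry, ColorGradient):
            lo, hi = entry.anchors[0][0], entry.anchors[-1][0]
            for i in range(bar_w):
                v = lo + (hi - lo) * (i + 0.5) / bar_w
                draw.line(
                    [(pad + i, y + 16), (pad + i, y + 30)],
                    fill=interpolate_color(entry, v),
                )
            for v, _c in entry.anchors:
                x = pad + (v - lo) / (hi - lo) * bar_w
                draw.text((x, y + 32), f"{v:g}", fill=(0, 0, 0))
        else:
            x = pad
            for rule in entry:
                draw.rectangle([x, y + 16, x + 14, y + 30], fill=rule.color, outline=(0, 0, 0))
                draw.text((x + 20, y + 17), rule.text or "rule", fill=(0, 0, 0))
                x += 20 + 7 * max(4, len(rule.text)) + 12
            draw.rectangle([x, y + 16, x + 14, y + 30], fill=spec.fallback_color, outline=(0, 0, 0))
            draw.text((x + 20, y + 17), "otherwise", fill=(0, 0, 0))
        y += block_h
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()
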