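"""In-memory pathway document model and GPML-dialect reader/writer.

A pathway is a diagram of typed, database-annotated nodes (genes, proteins,
metabolites, ...) connected by interactions (activation, inhibition,
conversion, catalysis), as drawn in PathVisio/WikiPathways.  Documents are
stored in a GPML-2013a-like XML dialect:

* root ``<Pathway Name=... Organism=...>`` (no xmlns -- see docs/methods.md),
* ``<Graphics BoardWidth=... BoardHeight=...>`` child for the drawing board,
* ``<DataNode GraphId=... TextLabel=... Type=...>`` with a ``<Graphics>``
  child carrying centre-based geometry and an optional ``<Xref>`` child,
* ``<Interaction>`` with two ``<Point GraphRef=...>`` endpoints,
* ``<Label>`` for free text.

Unrecognised root children survive read/write as opaque pass-through blobs,
re-emitted verbatim, so foreign GPML extensions are not destroyed by a
round trip.  Coordinates are centre-based abstract diagram units with y
increasing downward (the GPML convention).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import BinaryIO, Iterable, Optional, Union
from xml.sax.saxutils import escape, quoteattr

from lxml import etree

__all__ = [
    "Xref",
    "DataNode",
    "Interaction",
    "FreeLabel",
    "PathwayDoc",
    "PathwayError",
    "ValidationError",
    "ReferenceError_",
    "GpmlFormatError",
    "GpmlParseError",
    "create_pathway",
    "add_data_node",
    "add_interaction",
    "add_label",
    "remove_element",
    "read_gpml",
    "write_gpml",
    "write_gpml_bytes",
    "NODE_TYPES",
    "INTERACTION_TYPES",
    "DEFAULT_NODE_WIDTH",
    "DEFAULT_NODE_HEIGHT",
]

# ---------------------------------------------------------------------------
# Errors

class PathwayError(Exception):
    """Base class for pathway-model errors."""


class ValidationError(PathwayError):
    """An argument or document violates a model invariant."""


class ReferenceError_(PathwayError):
    """An element id does not resolve within the document."""


class GpmlFormatError(PathwayError):
    """Well-formed XML, but not a supported pathway document."""


class GpmlParseError(PathwayError):
    """Malformed XML; carries line information from the parser."""


# ---------------------------------------------------------------------------
# Constants

NODE_TYPES = ("GeneProduct", "Protein", "Metabolite", "Rna", "Pathway", "Unknown")

#: interaction type -> ArrowHead attribute on the end point ("" = plain line)
INTERACTION_TYPES = {
    "line": "",
    "arrow": "Arrow",
    "t-bar": "TBar",
    "conversion": "mim-conversion",
    "catalysis": "mim-catalysis",
}
_ARROWHEAD_TO_TYPE = {v: k for k, v in INTERACTION_TYPES.items()}

DEFAULT_NODE_WIDTH = 80.0   # GPML-typical datanode extent, diagram units
DEFAULT_NODE_HEIGHT = 20.0

DEFAULT_BOARD_WIDTH = 1200.0
DEFAULT_BOARD_HEIGHT = 800.0

# auto-layout grid for nodes added without coordinates
_GRID_COLS = 10
_GRID_PITCH_X = 100.0
_GRID_PITCH_Y = 40.0
_GRID_ORIGIN_X = 60.0
_GRID_ORIGIN_Y = 40.0


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class Xref:
    """External database cross-reference: (accession, datasource system code)."""

    identifier: str
    system_code: str

    def __post_init__(self):
        if self.system_code and not self.identifier:
            raise ValidationError("Xref identifier must be non-empty when a system code is set")


@dataclass
class DataNode:
    """A biological entity on the diagram (gene product, protein, metabolite...)."""

    element_id: str
    label: str
    node_type: str = "GeneProduct"
    xref: Optional[Xref] = None
    cx: float = 0.0
    cy: float = 0.0
    width: float = DEFAULT_NODE_WIDTH
    height: float = DEFAULT_NODE_HEIGHT

    def __post_init__(self):
        if self.node_type not in NODE_TYPES:
            raise ValidationError(
                f"unknown node type {self.node_type!r}; expected one of {NODE_TYPES}"
            )
        if not (self.width > 0 and self.height > 0):
            raise ValidationError("node width and height must be positive")
        for v in (self.cx, self.cy, self.width, self.height):
            if not math.isfinite(v):
                raise ValidationError("node geometry must be finite")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) axis-aligned bounding box."""
        return (
            self.cx - self.width / 2,
            self.cy - self.height / 2,
            self.cx + self.width / 2,
            self.cy + self.height / 2,
        )


@dataclass
class Interaction:
    """A directed edge between two diagram elements."""

    element_id: str
    source_ref: str
    target_ref: str
    interaction_type: str = "line"
    xref: Optional[Xref] = None
    dangling: bool = False  # endpoint no longer resolves (set on element removal / read)

    def __post_init__(self):
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValidationError(
                f"unknown interaction type {self.interaction_type!r}; "
                f"expected one of {tuple(INTERACTION_TYPES)}"
            )


@dataclass
class FreeLabel:
    """Free-floating text label with geometry but no database annotation."""

    element_id: str
    text: str
    cx: float = 0.0
    cy: float = 0.0
    width: float = DEFAULT_NODE_WIDTH
    height: float = DEFAULT_NODE_HEIGHT


Element = Union[DataNode, Interaction, FreeLabel]


@dataclass
class PathwayDoc:
    """A pathway diagram: named, organism-tagged, ordered elements on a board."""

    name: str
    organism: str = ""
    elements: list[Element] = field(default_factory=list)
    board_width: float = DEFAULT_BOARD_WIDTH
    board_height: float = DEFAULT_BOARD_HEIGHT
    #: verbatim XML snippets of unrecognised root children (pass-through)
    foreign_blobs: list[str] = field(default_factory=list)
    _next_id: int = 1

    # -- lookup helpers ----------------------------------------------------
    def element_ids(self) -> set[str]:
        return {e.element_id for e in self.elements}

    def get(self, element_id: str) -> Element:
        for e in self.elements:
            if e.element_id == element_id:
                return e
        raise ReferenceError_(f"no element with id {element_id!r}")

    def data_nodes(self) -> list[DataNode]:
        return [e for e in self.elements if isinstance(e, DataNode)]

    def interactions(self) -> list[Interaction]:
        return [e for e in self.elements if isinstance(e, Interaction)]

    def labels(self) -> list[FreeLabel]:
        return [e for e in self.elements if isinstance(e, FreeLabel)]

    def fresh_id(self, prefix: str = "e") -> str:
        ids = self.element_ids()
        while True:
            candidate = f"{prefix}{self._next_id}"
            self._next_id += 1
            if candidate not in ids:
                return candidate

    def validate(self) -> list[str]:
        """Return a list of human-readable problems (empty = valid).

        Self-loops and dangling interactions are reported but are not fatal;
        duplicate ids are fatal for writing.
        """
        problems = []
        seen: set[str] = set()
        for e in self.elements:
            if e.element_id in seen:
                problems.append(f"duplicate element id {e.element_id!r}")
            seen.add(e.element_id)
        node_ids = self.element_ids()
        for it in self.interactions():
            if it.source_ref == it.target_ref:
                problems.append(f"interaction {it.element_id!r} is a self-loop")
            for ref in (it.source_ref, it.target_ref):
                if ref not in node_ids:
                    problems.append(
                        f"interaction {it.element_id!r} has dangling endpoint {ref!r}"
                    )
        return problems


# ---------------------------------------------------------------------------
# Operations

def create_pathway(name: str, organism: str = "") -> PathwayDoc:
    """Create an empty pathway document.

    >>> doc = create_pathway("Glycolysis", "Homo sapiens")
    >>> len(doc.elements)
    0
    """
    if not name:
        raise ValidationError("pathway name must be non-empty")
    return PathwayDoc(name=name, organism=organism)


def _auto_position(doc: PathwayDoc) -> tuple[float, float]:
    # grid layout, left-to-right, rows of _GRID_COLS, fixed pitch
    i = len([e for e in doc.elements if isinstance(e, (DataNode, FreeLabel))])
    row, col = divmod(i, _GRID_COLS)
    return (_GRID_ORIGIN_X + col * _GRID_PITCH_X, _GRID_ORIGIN_Y + row * _GRID_PITCH_Y)


def _grow_board(doc: PathwayDoc, x1: float, y1: float) -> None:
    doc.board_width = max(doc.board_width, x1 + _GRID_ORIGIN_X / 2)
    doc.board_height = max(doc.board_height, y1 + _GRID_ORIGIN_Y / 2)


def add_data_node(
    doc: PathwayDoc,
    label: str,
    node_type: str = "GeneProduct",
    xref: Optional[Xref] = None,
    cx: Optional[float] = None,
    cy: Optional[float] = None,
    width: float = DEFAULT_NODE_WIDTH,
    height: float = DEFAULT_NODE_HEIGHT,
) -> str:
    """Add a data node; omitted coordinates fall into an auto-layout grid.

    Returns the new element id (unique within the document).
    """
    if cx is None or cy is None:
        cx, cy = _auto_position(doc)
    node = DataNode(
        element_id=doc.fresh_id("n"),
        label=label,
        node_type=node_type,
        xref=xref,
        cx=float(cx),
        cy=float(cy),
        width=float(width),
        height=float(height),
    )
    doc.elements.append(node)
    _grow_board(doc, node.bounds[2], node.bounds[3])
    return node.element_id


def add_label(
    doc: PathwayDoc,
    text: str,
    cx: Optional[float] = None,
    cy: Optional[float] = None,
    width: float = DEFAULT_NODE_WIDTH,
    height: float = DEFAULT_NODE_HEIGHT,
) -> str:
    if cx is None or cy is None:
        cx, cy = _auto_position(doc)
    lab = FreeLabel(doc.fresh_id("lab"), text, float(cx), float(cy), float(width), float(height))
    doc.elements.append(lab)
    return lab.element_id


def add_interaction(
    doc: PathwayDoc,
    source_id: str,
    target_id: str,
    interaction_type: str = "line",
    xref: Optional[Xref] = None,
) -> str:
    """Connect two existing elements.  Self-loops are accepted (flagged by
    :meth:`PathwayDoc.validate`); unresolved endpoints raise."""
    ids = doc.element_ids()
    for ref in (source_id, target_id):
        if ref not in ids:
            raise ReferenceError_(f"interaction endpoint {ref!r} not in document")
    it = Interaction(
        element_id=doc.fresh_id("i"),
        source_ref=source_id,
        target_ref=target_id,
        interaction_type=interaction_type,
        xref=xref,
    )
    doc.elements.append(it)
    return it.element_id


def remove_element(doc: PathwayDoc, element_id: str) -> PathwayDoc:
    """Remove an element in place.  Interactions that referenced it are kept
    but marked ``dangling`` rather than silently deleted."""
    target = doc.get(element_id)  # raises ReferenceError_ if absent
    doc.elements.remove(target)
    for it in doc.interactions():
        if element_id in (it.source_ref, it.target_ref):
            it.dangling = True
    return doc


# ---------------------------------------------------------------------------
# GPML writing
#
# The writer builds XML text directly so that (a) output is byte-deterministic
# and (b) foreign blobs are spliced in verbatim.

def _fnum(v: float) -> str:
    """Canonical float formatting: integral values without trailing .0 noise."""
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def _xref_xml(xref: Optional[Xref], indent: str) -> str:
    if xref is None:
        return ""
    from .idmapper import SYSTEM_CODES  # local import to avoid cycle at module load

    database = SYSTEM_CODES.get(xref.system_code, xref.system_code)
    return (
        f"{indent}<Xref Database={quoteattr(database)} "
        f"ID={quoteattr(xref.identifier)} />\n"
    )


def write_gpml_bytes(doc: PathwayDoc) -> bytes:
    """Serialise a document to GPML-dialect bytes (UTF-8, deterministic)."""
    problems = [p for p in doc.validate() if p.startswith("duplicate")]
    if problems:
        raise ValidationError("; ".join(problems))

    out = io.StringIO()
    out.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    out.write(
        f"<Pathway Name={quoteattr(doc.name)} Organism={quoteattr(doc.organism)} "
        'License="" Version="pathviz-gpml-1">\n'
    )
    out.write(
        f'  <Graphics BoardWidth="{_fnum(doc.board_width)}" '
        f'BoardHeight="{_fnum(doc.board_height)}" />\n'
    )
    for e in doc.elements:
        if isinstance(e, DataNode):
            out.write(
                f"  <DataNode GraphId={quoteattr(e.element_id)} "
                f"TextLabel={quoteattr(e.label)} Type={quoteattr(e.node_type)}>\n"
            )
            out.write(
                f'    <Graphics CenterX="{_fnum(e.cx)}" CenterY="{_fnum(e.cy)}" '
                f'Width="{_fnum(e.width)}" Height="{_fnum(e.height)}" />\n'
            )
            out.write(_xref_xml(e.xref, "    "))
            out.write("  </DataNode>\n")
        elif isinstance(e, FreeLabel):
            out.write(
                f"  <Label GraphId={quoteattr(e.element_id)} "
                f"TextLabel={quoteattr(e.text)}>\n"
            )
            out.write(
                f'    <Graphics CenterX="{_fnum(e.cx)}" CenterY="{_fnum(e.cy)}" '
                f'Width="{_fnum(e.width)}" Height="{_fnum(e.height)}" />\n'
            )
            out.write("  </Label>\n")
        elif isinstance(e, Interaction):
            dangling = ' Dangling="true"' if e.dangling else ""
            out.write(f"  <Interaction GraphId={quoteattr(e.element_id)}{dangling}>\n")
            out.write("    <Graphics>\n")
            out.write(f"      <Point GraphRef={quoteattr(e.source_ref)} />\n")
            head = INTERACTION_TYPES[e.interaction_type]
            head_attr = f" ArrowHead={quoteattr(head)}" if head else ""
            out.write(f"      <Point GraphRef={quoteattr(e.target_ref)}{head_attr} />\n")
            out.write("    </Graphics>\n")
            out.write(_xref_xml(e.xref, "    "))
            out.write("  </Interaction>\n")
    for blob in doc.foreign_blobs:
        out.write("  " + blob.strip() + "\n")
    out.write("</Pathway>\n")
    return out.getvalue().encode("utf-8")


def write_gpml(doc: PathwayDoc, destination) -> None:
    """Write GPML to a path or binary stream."""
    data = write_gpml_bytes(doc)
    if hasattr(destination, "write"):
        destination.write(data)
    else:
        with open(destination, "wb") as fh:
            fh.write(data)


# ---------------------------------------------------------------------------
# GPML reading

_KNOWN_TAGS = {"Graphics", "DataNode", "Label", "Interaction", "Xref", "Point"}


def _localname(tag) -> str:
    # tolerate namespaced input (e.g. real GPML-2013a files)
    if isinstance(tag, str) and tag.startswith("{"):
        return tag.split("}", 1)[1]
    return tag if isinstance(tag, str) else ""


def _parse_xref(el) -> Optional[Xref]:
    from .idmapper import database_to_code

    ident = el.get("ID", "")
    database = el.get("Database", "")
    if not ident:
        return None
    return Xref(identifier=ident, system_code=database_to_code(database))


def read_gpml(source) -> PathwayDoc:
    """Read a GPML-dialect document from a path, bytes, or binary stream.

    Recognised elements populate the model; everything else is preserved as
    an opaque blob and re-emitted by :func:`write_gpml`.
    """
    if isinstance(source, (bytes, bytearray)):
        data = bytes(source)
    elif hasattr(source, "read"):
        data = source.read()
    else:
        with open(source, "rb") as fh:
            data = fh.read()

    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise GpmlParseError(f"malformed XML: {exc}") from exc

    if _localname(root.tag) != "Pathway":
        raise GpmlFormatError(
            f"unsupported root element {_localname(root.tag)!r}; expected 'Pathway'"
        )

    doc = PathwayDoc(
        name=root.get("Name", ""),
        organism=root.get("Organism", ""),
        elements=[],
    )
    if not doc.name:
        raise GpmlFormatError("Pathway root lacks a Name attribute")

    for child in root:
        tag = _localname(child.tag)
        if tag == "Graphics":
            doc.board_width = float(child.get("BoardWidth", DEFAULT_BOARD_WIDTH))
            doc.board_height = float(child.get("BoardHeight", DEFAULT_BOARD_HEIGHT))
        elif tag == "DataNode":
            geom = _first_child(child, "Graphics")
            xref_el = _first_child(child, "Xref")
            doc.elements.append(
                DataNode(
                    element_id=child.get("GraphId") or doc.fresh_id("n"),
                    label=child.get("TextLabel", ""),
                    node_type=child.get("Type", "Unknown")
                    if child.get("Type", "Unknown") in NODE_TYPES
                    else "Unknown",
                    xref=_parse_xref(xref_el) if xref_el is not None else None,
                    cx=float(geom.get("CenterX", 0)) if geom is not None else 0.0,
                    cy=float(geom.get("CenterY", 0)) if geom is not None else 0.0,
                    width=float(geom.get("Width", DEFAULT_NODE_WIDTH))
                    if geom is not None
                    else DEFAULT_NODE_WIDTH,
                    height=float(geom.get("Height", DEFAULT_NODE_HEIGHT))
                    if geom is not None
                    else DEFAULT_NODE_HEIGHT,
                )
            )
        elif tag == "Label":
            geom = _first_child(child, "Graphics")
            doc.elements.append(
                FreeLabel(
                    element_id=child.get("GraphId") or doc.fresh_id("lab"),
                    text=child.get("TextLabel", ""),
                    cx=float(geom.get("CenterX", 0)) if geom is not None else 0.0,
                    cy=float(geom.get("CenterY", 0)) if geom is not None else 0.0,
                    width=float(geom.get("Width", DEFAULT_NODE_WIDTH))
                    if geom is not None
                    else DEFAULT_NODE_WIDTH,
                    height=float(geom.get("Height", DEFAULT_NODE_HEIGHT))
                    if geom is not None
                    else DEFAULT_NODE_HEIGHT,
                )
            )
        elif tag == "Interaction":
            geom = _first_child(child, "Graphics")
            points = (
                [p for p in geom if _localname(p.tag) == "Point"] if geom is not None else []
            )
            source_ref = points[0].get("GraphRef", "") if points else ""
            target_ref = points[-1].get("GraphRef", "") if len(points) > 1 else ""
            head = points[-1].get("ArrowHead", "") if len(points) > 1 else ""
            xref_el = _first_child(child, "Xref")
            doc.elements.append(
                Interaction(
                    element_id=child.get("GraphId") or doc.fresh_id("i"),
                    source_ref=source_ref,
                    target_ref=target_ref,
                    interaction_type=_ARROWHEAD_TO_TYPE.get(head, "line"),
                    xref=_parse_xref(xref_el) if xref_el is not None else None,
                    dangling=child.get("Dangling") == "true",
                )
            )
        elif isinstance(child.tag, str):
            blob = etree.tostring(child, encoding="unicode")
            doc.foreign_blobs.append(blob.strip())

    # flag interactions whose endpoints do not resolve
    ids = doc.element_ids()
    for it in doc.interactions():
        if it.source_ref not in ids or it.target_ref not in ids:
            it.dangling = True
    return doc


def _first_child(el, localname: str):
    for c in el:
        if _localname(c.tag) == localname:
            return c
    return None


# ---------------------------------------------------------------------------
# Semantic equality (used by tests and callers; not __eq__, which is dataclass
# field equality and too strict about _next_id bookkeeping)

def docs_equal(a: PathwayDoc, b: PathwayDoc, tol: float = 1e-9) -> bool:
    """Semantic document equality: names, organisms, element ids, xrefs and
    geometry (within ``tol``), ignoring id-counter bookkeeping."""
    if (a.name, a.organism) != (b.name, b.organism):
        return False
    if len(a.elements) != len(b.elements):
        return False
    for ea, eb in zip(a.elements, b.elements):
        if type(ea) is not type(eb) or ea.element_id != eb.element_id:
            return False
        if isinstance(ea, DataNode):
            if (ea.label, ea.node_type, ea.xref) != (eb.label, eb.node_type, eb.xref):
                return False
            if any(
                abs(x - y) > tol
                for x, y in zip(
                    (ea.cx, ea.cy, ea.width, ea.height),
                    (eb.cx, eb.cy, eb.width, eb.height),
                )
            ):
                return False
        elif isinstance(ea, FreeLabel):
            if ea.text != eb.text:
                return False
            if any(
                abs(x - y) > tol
                for x, y in zip(
                    (ea.cx, ea.cy, ea.width, ea.height),
                    (eb.cx, eb.cy, eb.width, eb.height),
                )
            ):
                return False
        else:
            if (ea.source_ref, ea.target_ref, ea.interaction_type, ea.xref, ea.dangling) != (
                eb.source_ref,
                eb.target_ref,
                eb.interaction_type,
                eb.xref,
                eb.dangling,
            ):
                return False
    return a.foreign_blobs == b.foreign_blobs
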