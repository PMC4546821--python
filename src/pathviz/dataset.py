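"""Measurement tables, node linking, and the criterion expression language.

A measurement table is a delimited text file with one identifier column, an
optional system-code column (or one fixed code for the whole file), and any
number of value columns (logFC, P-values, concentrations...).  Rows are
linked to pathway nodes through the identifier mapper, so data annotates
nodes irrespective of the identifier scheme either side uses.

Criteria are boolean expressions over a row's columns, written in the
bracketed-column dialect, e.g.::

    [P.Value] < 0.05
    [logFC_d1] > 1 AND NOT [P.Value_d1] >= 0.05

Precedence: NOT > comparison > AND > OR; parentheses override.  Evaluation
is three-valued: any comparison touching a missing cell yields MISSING;
AND(false, missing) = false and OR(true, missing) = true, otherwise MISSING
propagates.  At counting boundaries (statistics, colour rules) MISSING is
treated as "criterion not met".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd

from .idmapper import MappingStore, map_identifier, _check_code
from .model import PathwayDoc

__all__ = [
    "MISSING",
    "Missing",
    "MeasurementTable",
    "NodeDataLink",
    "DataFormatError",
    "CriterionSyntaxError",
    "CriterionEvalError",
    "import_data",
    "link_to_pathway",
    "parse_criterion",
    "evaluate_criterion",
    "criterion_met",
]


class DataFormatError(Exception):
    """Input table malformed (no header, missing id column, empty...)."""


class CriterionSyntaxError(Exception):
    """Criterion text does not parse; carries a character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class CriterionEvalError(Exception):
    """Criterion references a column absent from the row."""


class Missing:
    """Singleton marker for a missing cell / unknown truth value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        raise TypeError("MISSING has no plain truth value; use criterion_met()")


MISSING = Missing()

Cell = Union[float, str, Missing]


# ---------------------------------------------------------------------------
# Measurement table

@dataclass
class MeasurementTable:
    """Ordered rows of (identifier, system_code, named cells)."""

    column_names: list[str]
    identifiers: list[str]
    system_codes: list[str]
    rows: list[dict]  # column name -> Cell
    source: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, i: int) -> dict:
        return self.rows[i]


_MISSING_MARKERS = {"", "NA", "NaN", "nan", "N/A"}


def _parse_cell(text: str) -> Cell:
    if text.strip() in _MISSING_MARKERS:
        return MISSING
    try:
        v = float(text)
    except ValueError:
        return text  # unparseable cells retained as text
    return v if math.isfinite(v) else MISSING


def _sniff_delimiter(header_line: str) -> str:
    # tab preferred, comma fallback
    return "\t" if "\t" in header_line else ","


def import_data(path, id_column: str, syscode: str) -> MeasurementTable:
    """Import a delimited measurement table.

    ``syscode`` is either the name of the column holding per-row system
    codes, or a fixed code (e.g. ``"L"``) applied to every row; column names
    win over code names when both match.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise DataFormatError(f"{path}: empty file")
    delim = _sniff_delimiter(first)

    df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False, engine="python")
    header = list(df.columns)
    if any(name.startswith("Unnamed:") for name in header):
        raise DataFormatError(f"{path}: header has unnamed columns")
    if id_column not in header:
        raise DataFormatError(f"{path}: identifier column {id_column!r} not in header {header}")
    if len(df) == 0:
        raise DataFormatError(f"{path}: no data rows")

    syscode_column = syscode if syscode in header else None
    if syscode_column is None:
        _check_code(syscode)  # fixed code must be registered

    value_names = [c for c in header if c != id_column and c != syscode_column]
    identifiers = [v.strip() for v in df[id_column]]
    if syscode_column:
        system_codes = [v.strip() for v in df[syscode_column]]
    else:
        system_codes = [syscode] * len(df)
    values = {c: df[c].tolist() for c in value_names}
    rows = [
        {name: _parse_cell(values[name][i]) for name in value_names}
        for i in range(len(df))
    ]

    return MeasurementTable(
        column_names=value_names,
        identifiers=identifiers,
        system_codes=system_codes,
        rows=rows,
        source=str(path),
    )


# ---------------------------------------------------------------------------
# Linking rows to pathway nodes

@dataclass
class NodeDataLink:
    """Match relation between table rows and pathway data nodes.

    ``node_rows`` lists matching row indices per node id (file order);
    ``row_nodes`` the matched node ids per row; ``unmapped_nodes`` the ids of
    data nodes with no matching row (drawn light grey downstream).
    """

    node_rows: dict[str, list[int]] = field(default_factory=dict)
    row_nodes: dict[int, list[str]] = field(default_factory=dict)
    unmapped_nodes: list[str] = field(default_factory=list)

    def first_row(self, node_id: str) -> Optional[int]:
        rows = self.node_rows.get(node_id)
        return rows[0] if rows else None


def link_to_pathway(table: MeasurementTable, doc: PathwayDoc, store: MappingStore) -> NodeDataLink:
    """Link table rows to document nodes through the mapping store.

    A row matches a node iff the mapper connects the row's (system code,
    identifier) to the node's xref (identity counts when systems agree).
    Nodes without an xref never match.  Deterministic and invariant to row /
    node order: matches are recorded in file order per node.
    """
    link = NodeDataLink()
    nodes = doc.data_nodes()
    for node in nodes:
        link.node_rows[node.element_id] = []

    # row system+id -> ids per target system, cached per (code, id, target)
    cache: dict[tuple[str, str, str], set[str]] = {}
    for node in nodes:
        if node.xref is None:
            continue
        target_code = node.xref.system_code
        for i, (ident, code) in enumerate(zip(table.identifiers, table.system_codes)):
            if not ident:
                continue
            key = (code, ident, target_code)
            if key not in cache:
                try:
                    cache[key] = map_identifier(store, ident, code, target_code)
                except Exception:
                    cache[key] = set()
            if node.xref.identifier in cache[key]:
                link.node_rows[node.element_id].append(i)
                link.row_nodes.setdefault(i, []).append(node.element_id)

    link.unmapped_nodes = [n.element_id for n in nodes if not link.node_rows[n.element_id]]
    return link


# ---------------------------------------------------------------------------
# Criterion language: tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<column>\[[^\]\[]+\])
  | (?P<number>[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?)
  | (?P<string>"[^"]*"|'[^']*')
  | (?P<op><=|>=|<>|<|>|=)
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<word>[A-Za-z_]+)
    """,
    re.VERBOSE,
)

_KEYWORDS = {"AND", "OR", "NOT", "TRUE", "FALSE"}


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise CriterionSyntaxError(f"unknown token {text[pos]!r}", pos)
        kind = m.lastgroup
        value = m.group()
        if kind != "ws":
            if kind == "word":
                up = value.upper()
                if up not in _KEYWORDS:
                    raise CriterionSyntaxError(f"unknown word {value!r}", pos)
                tokens.append((up, up, pos))
            else:
                tokens.append((kind, value, pos))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


# AST node types (plain dataclasses; evaluate via evaluate_criterion)

@dataclass(frozen=True)
class ColumnRef:
    name: str


@dataclass(frozen=True)
class Literal:
    value: Union[float, str, bool]


@dataclass(frozen=True)
class Comparison:
    op: str  # < <= > >= = <>
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Not:
    operand: "Expr"


@dataclass(frozen=True)
class And:
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Or:
    left: "Expr"
    right: "Expr"


Expr = Union[ColumnRef, Literal, Comparison, Not, And, Or]
CriterionAST = Expr


class _Parser:
    """Recursive-descent parser; precedence NOT > comparison > AND > OR."""

    def __init__(self, tokens):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def take(self, kind=None):
        tok = self.tokens[self.i]
        if kind is not None and tok[0] != kind:
            raise CriterionSyntaxError(f"expected {kind}, found {tok[1]!r}", tok[2])
        self.i += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        tok = self.peek()
        if tok[0] != "eof":
            raise CriterionSyntaxError(f"unexpected trailing {tok[1]!r}", tok[2])
        return expr

    def parse_or(self) -> Expr:
        left = self.parse_and()
        while self.peek()[0] == "OR":
            self.take()
            left = Or(left, self.parse_and())
        return left

    def parse_and(self) -> Expr:
        left = self.parse_not()
        while self.peek()[0] == "AND":
            self.take()
            left = And(left, self.parse_not())
        return left

    def parse_not(self) -> Expr:
        if self.peek()[0] == "NOT":
            self.take()
            return Not(self.parse_not())
        return self.parse_comparison()

    def parse_comparison(self) -> Expr:
        left = self.parse_primary()
        if self.peek()[0] == "op":
            op = self.take()[1]
            right = self.parse_primary()
            return Comparison(op, left, right)
        return left

    def parse_primary(self) -> Expr:
        kind, value, pos = self.peek()
        if kind == "lparen":
            self.take()
            inner = self.parse_or()
            self.take("rparen")
            return inner
        if kind == "column":
            self.take()
            return ColumnRef(value[1:-1])
        if kind == "number":
            self.take()
            return Literal(float(value))
        if kind == "string":
            self.take()
            return Literal(value[1:-1])
        if kind == "TRUE":
            self.take()
            return Literal(True)
        if kind == "FALSE":
            self.take()
            return Literal(False)
        raise CriterionSyntaxError(f"expected value, found {value!r}" if value else "unexpected end of expression", pos)


def parse_criterion(text: str) -> CriterionAST:
    """Parse criterion text into an AST; raises CriterionSyntaxError with a
    character position on bad input."""
    if not text or not text.strip():
        raise CriterionSyntaxError("empty criterion", 0)
    return _Parser(_tokenize(text)).parse()


# ---------------------------------------------------------------------------
# Evaluation (three-valued)

def _eval_operand(expr: Expr, row: dict) -> Cell:
    if isinstance(expr, ColumnRef):
        if expr.name not in row:
            raise CriterionEvalError(f"criterion references unknown column {expr.name!r}")
        return row[expr.name]
    if isinstance(expr, Literal):
        return expr.value
    raise CriterionEvalError("comparison operands must be columns or literals")


def _compare(op: str, a: Cell, b: Cell) -> Union[bool, Missing]:
    if a is MISSING or b is MISSING:
        return MISSING
    if op == "=":
        return a == b
    if op == "<>":
        return a != b
    if isinstance(a, str) != isinstance(b, str):
        return MISSING  # ordering a number against text is unknowable
    return {"<": a < b, "<=": a <= b, ">": a > b, ">=": a >= b}[op]


def evaluate_criterion(ast: CriterionAST, row: dict) -> Union[bool, Missing]:
    """Evaluate an AST against a row (mapping of column name -> cell).

    Three-valued: returns True, False, or MISSING.
    """
    if isinstance(ast, Literal):
        if isinstance(ast.value, bool):
            return ast.value
        raise CriterionEvalError("a bare literal is not a boolean criterion")
    if isinstance(ast, ColumnRef):
        raise CriterionEvalError("a bare column reference is not a boolean criterion")
    if isinstance(ast, Comparison):
        return _compare(ast.op, _eval_operand(ast.left, row), _eval_operand(ast.right, row))
    if isinstance(ast, Not):
        v = evaluate_criterion(ast.operand, row)
        return MISSING if v is MISSING else (not v)
    if isinstance(ast, And):
        left = evaluate_criterion(ast.left, row)
        right = evaluate_criterion(ast.right, row)
        if left is False or right is False:
            return False
        if left is MISSING or right is MISSING:
            return MISSING
        return True
    if isinstance(ast, Or):
        left = evaluate_criterion(ast.left, row)
        right = evaluate_criterion(ast.right, row)
        if left is True or right is True:
            return True
        if left is MISSING or right is MISSING:
            return MISSING
        return False
    raise CriterionEvalError(f"cannot evaluate {ast!r}")


def criterion_met(ast: CriterionAST, row: dict) -> bool:
    """Two-valued boundary: MISSING counts as 'criterion not met'.

    This is the semantics used for counting (a gene with missing statistics
    is measured but not changed) and for colour rules.
    """
    return evaluate_criterion(ast, row) is True


def criterion_columns(ast: CriterionAST) -> set[str]:
    """All column names referenced by an AST."""
    if isinstance(ast, ColumnRef):
        return {ast.name}
    if isinstance(ast, Literal):
        return set()
    if isinstance(ast, Comparison):
        return criterion_columns(ast.left) | criterion_columns(ast.right)
    if isinstance(ast, Not):
        return criterion_columns(ast.operand)
    return criterion_columns(ast.left) | criterion_columns(ast.right)
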