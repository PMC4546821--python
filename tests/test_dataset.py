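"""Measurement import, node linking, and the criterion language."""

import itertools
import random

import pytest

from pathviz import (
    MISSING,
    Xref,
    add_data_node,
    create_pathway,
    evaluate_criterion,
    import_data,
    link_to_pathway,
    parse_criterion,
)
from pathviz.dataset import (
    CriterionEvalError,
    CriterionSyntaxError,
    DataFormatError,
    And,
    Comparison,
    ColumnRef,
    Literal,
    Not,
    Or,
    criterion_met,
)


# ---------------------------------------------------------------------------
# Import

class TestImport:
    def _write(self, tmp_path, text, name="t.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_six_value_columns(self, tmp_path):
        header = "id\tsys\tlogFC_1\tlogFC_2\tlogFC_3\tP_1\tP_2\tP_3"
        p = self._write(tmp_path, header + "\n1\tL\t0.5\t-1\t2\t0.01\t0.2\tNA\n")
        t = import_data(p, "id", "sys")
        assert t.column_names == ["logFC_1", "logFC_2", "logFC_3", "P_1", "P_2", "P_3"]
        assert t.rows[0]["logFC_2"] == -1.0
        assert t.rows[0]["P_3"] is MISSING

    def test_fixed_system_code(self, tmp_path):
        p = self._write(tmp_path, "id\tv\n10\t1\n20\t2\n")
        t = import_data(p, "id", "L")
        assert t.system_codes == ["L", "L"]

    def test_comma_fallback_and_text_cells(self, tmp_path):
        p = self._write(tmp_path, "id,v,note\n10,1.5,up\n", name="t.csv")
        t = import_data(p, "id", "L")
        assert t.rows[0]["v"] == 1.5
        assert t.rows[0]["note"] == "up"  # unparseable retained as text

    def test_header_only_is_format_error(self, tmp_path):
        p = self._write(tmp_path, "id\tv\n")
        with pytest.raises(DataFormatError):
            import_data(p, "id", "L")

    def test_missing_id_column_is_format_error(self, tmp_path):
        p = self._write(tmp_path, "gene\tv\n1\t2\n")
        with pytest.raises(DataFormatError):
            import_data(p, "id", "L")


# ---------------------------------------------------------------------------
# Linking

class TestLink:
    def _table(self, tmp_path, rows):
        p = tmp_path / "d.tsv"
        p.write_text("id\tsys\tv\n" + "".join(f"{i}\t{s}\t{v}\n" for i, s, v in rows))
        return import_data(p, "id", "sys")

    def test_direct_identity_match(self, tmp_path, tiny_mapping):
        doc = create_pathway("p")
        nid = add_data_node(doc, "FOS", xref=Xref("1234", "L"))
        table = self._table(tmp_path, [("1234", "L", 1)])
        link = link_to_pathway(table, doc, tiny_mapping)
        assert link.node_rows[nid] == [0]

    def test_cross_system_match(self, tmp_path, tiny_mapping):
        doc = create_pathway("p")
        nid = add_data_node(doc, "FOS", xref=Xref("ENSG000001", "En"))
        table = self._table(tmp_path, [("1234", "L", 1)])
        link = link_to_pathway(table, doc, tiny_mapping)
        assert link.node_rows[nid] == [0]

    def test_node_without_xref_unmapped(self, tmp_path, tiny_mapping):
        doc = create_pathway("p")
        nid = add_data_node(doc, "nameless")
        table = self._table(tmp_path, [("1234", "L", 1)])
        link = link_to_pathway(table, doc, tiny_mapping)
        assert nid in link.unmapped_nodes

    def test_invariant_to_row_and_node_order(self, tmp_path, tiny_mapping):
        rows = [("5678", "L", 1), ("1234", "L", 2), ("none", "L", 3)]
        doc = create_pathway("p")
        a = add_data_node(doc, "FOS", xref=Xref("ENSG000001", "En"))
        b = add_data_node(doc, "B", xref=Xref("ENSG000002", "En"))
        link1 = link_to_pathway(self._table(tmp_path, rows), doc, tiny_mapping)

        doc2 = create_pathway("p")
        b2 = add_data_node(doc2, "B", xref=Xref("ENSG000002", "En"))
        a2 = add_data_node(doc2, "FOS", xref=Xref("ENSG000001", "En"))
        link2 = link_to_pathway(self._table(tmp_path, rows), doc2, tiny_mapping)
        assert link1.node_rows[a] == link2.node_rows[a2]
        assert link1.node_rows[b] == link2.node_rows[b2]


# ---------------------------------------------------------------------------
# Criterion language

class TestCriterionParsing:
    def test_simple_comparison(self):
        ast = parse_criterion("[P.Value] < 0.05")
        assert isinstance(ast, Comparison) and ast.op == "<"
        assert ast.left == ColumnRef("P.Value")
        assert ast.right == Literal(0.05)

    def test_precedence_or_at_root(self):
        ast = parse_criterion("[a] < 1 AND [b] > 2 OR [c] = 3")
        assert isinstance(ast, Or)
        assert isinstance(ast.left, And)

    def test_parentheses_override(self):
        ast = parse_criterion("[a] < 1 AND ([b] > 2 OR [c] = 3)")
        assert isinstance(ast, And)
        assert isinstance(ast.right, Or)

    def test_not_binds_tightest(self):
        ast = parse_criterion("NOT [a] = 1 AND [b] = 2")
        assert isinstance(ast, And)
        assert isinstance(ast.left, Not)

    @pytest.mark.parametrize("bad", ["[a] <", "", "   ", "[a] < 1 AND", "1 <* 2", "foo"])
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(CriterionSyntaxError):
            parse_criterion(bad)


class TestCriterionEvaluation:
    def test_true_false_missing(self):
        ast = parse_criterion("[P.Value] < 0.05")
        assert evaluate_criterion(ast, {"P.Value": 0.01}) is True
        assert evaluate_criterion(ast, {"P.Value": 0.2}) is False
        assert evaluate_criterion(ast, {"P.Value": MISSING}) is MISSING

    def test_contradiction_is_false(self):
        ast = parse_criterion("[x] < 1 AND [x] > 1")
        assert evaluate_criterion(ast, {"x": 0.0}) is False

    def test_kleene_shortcuts(self):
        assert evaluate_criterion(
            parse_criterion("[a] = 1 AND [b] = 1"), {"a": 0.0, "b": MISSING}
        ) is False
        assert evaluate_criterion(
            parse_criterion("[a] = 1 OR [b] = 1"), {"a": 1.0, "b": MISSING}
        ) is True
        assert evaluate_criterion(
            parse_criterion("NOT [a] = 1"), {"a": MISSING}
        ) is MISSING

    def test_unknown_column_is_eval_error(self):
        with pytest.raises(CriterionEvalError):
            evaluate_criterion(parse_criterion("[zz] < 1"), {"a": 1.0})

    def test_missing_never_meets_criterion(self):
        assert criterion_met(parse_criterion("[a] < 1"), {"a": MISSING}) is False


# ---------------------------------------------------------------------------
# Truth-table oracle property

def _random_ast(rng, columns, depth):
    if depth == 0 or rng.random() < 0.35:
        op = rng.choice(["<", "<=", ">", ">=", "=", "<>"])
        return Comparison(op, ColumnRef(rng.choice(columns)), Literal(float(rng.choice([0, 1]))))
    kind = rng.choice(["and", "or", "not"])
    if kind == "not":
        return Not(_random_ast(rng, columns, depth - 1))
    cls = And if kind == "and" else Or
    return cls(_random_ast(rng, columns, depth - 1), _random_ast(rng, columns, depth - 1))


def _ast_to_text(ast):
    if isinstance(ast, Comparison):
        return f"([{ast.left.name}] {ast.op} {ast.right.value:g})"
    if isinstance(ast, Not):
        return f"(NOT {_ast_to_text(ast.operand)})"
    joiner = " AND " if isinstance(ast, And) else " OR "
    return f"({_ast_to_text(ast.left)}{joiner}{_ast_to_text(ast.right)})"


def _oracle(ast, row):
    """Independent Kleene evaluation: F=0, unknown=0.5, T=1; AND=min, OR=max,
    NOT=1-x; a comparison on a missing cell is unknown."""
    if isinstance(ast, Comparison):
        v = row[ast.left.name]
        if v is MISSING:
            return 0.5
        w = ast.right.value
        return float({
            "<": v < w, "<=": v <= w, ">": v > w, ">=": v >= w,
            "=": v == w, "<>": v != w,
        }[ast.op])
    if isinstance(ast, Not):
        return 1.0 - _oracle(ast.operand, row)
    if isinstance(ast, And):
        return min(_oracle(ast.left, row), _oracle(ast.right, row))
    return max(_oracle(ast.left, row), _oracle(ast.right, row))


_ENCODE = {True: 1.0, False: 0.0, MISSING: 0.5}


def test_evaluation_matches_truth_table_oracle():
    rng = random.Random(101)
    columns = ["a", "b", "c", "d"]
    for _ in range(60):
        ast = _random_ast(rng, columns, depth=3)
        reparsed = parse_criterion(_ast_to_text(ast))
        for values in itertools.product([0.0, 1.0, MISSING], repeat=len(columns)):
            row = dict(zip(columns, values))
            got = evaluate_criterion(reparsed, row)
            assert _ENCODE[got] == _oracle(ast, row)
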