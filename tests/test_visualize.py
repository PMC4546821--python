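"""Colour computation and rendering contracts."""

import math
import random

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from pathviz import (
    ColorGradient,
    ColorRule,
    MISSING,
    VisualizationSpec,
    Xref,
    add_data_node,
    apply_rules,
    create_pathway,
    interpolate_color,
    make_legend,
    render_pathway,
)
from pathviz.dataset import NodeDataLink, MeasurementTable
from pathviz.visualize import (
    RASTER_SCALE,
    UNMAPPED_COLOR,
    VisualizationError,
    gradient_from_text,
    stripe_bounds,
)

BWR = ColorGradient(((-1.0, (0, 0, 255)), (0.0, (255, 255, 255)), (1.0, (255, 0, 0))))


class TestGradient:
    def test_anchor_values_exact(self):
        assert interpolate_color(BWR, -1.0) == (0, 0, 255)
        assert interpolate_color(BWR, 0.0) == (255, 255, 255)
        assert interpolate_color(BWR, 1.0) == (255, 0, 0)

    def test_clamps_outside_range(self):
        assert interpolate_color(BWR, 2.0) == (255, 0, 0)
        assert interpolate_color(BWR, -7.5) == (0, 0, 255)

    def test_linear_midpoint_rounds_half_up(self):
        g = ColorGradient(((0.0, (255, 255, 255)), (1.0, (255, 0, 0))))
        assert interpolate_color(g, 0.5) == (255, 128, 128)

    def test_monotone_between_anchors(self):
        previous = interpolate_color(BWR, 0.0)
        for k in range(1, 101):
            current = interpolate_color(BWR, k / 100)
            assert current[1] <= previous[1] and current[2] <= previous[2]
            previous = current

    def test_matches_direct_formula_on_random_cases(self):
        rng = random.Random(41)
        for _ in range(300):
            v0, v1 = sorted(rng.sample(range(-50, 50), 2))
            c0 = tuple(rng.randrange(256) for _ in range(3))
            c1 = tuple(rng.randrange(256) for _ in range(3))
            g = ColorGradient(((float(v0), c0), (float(v1), c1)))
            value = rng.uniform(v0, v1)
            t = (value - v0) / (v1 - v0)
            expected = tuple(
                int(math.floor(a + t * (b - a) + 0.5)) for a, b in zip(c0, c1)
            )
            assert interpolate_color(g, value) == expected

    def test_nonfinite_value_rejected(self):
        with pytest.raises(VisualizationError):
            interpolate_color(BWR, float("nan"))

    def test_anchor_ordering_enforced(self):
        with pytest.raises(VisualizationError):
            ColorGradient(((1.0, (0, 0, 0)), (0.0, (255, 255, 255))))

    def test_from_text(self):
        assert gradient_from_text("blue@-1,white@0,red@1") == BWR


class TestRules:
    GREEN = (0, 255, 0)

    def test_first_true_rule_wins_else_fallback(self):
        rules = [ColorRule.from_text("[P] <= 0.05", "green")]
        assert apply_rules(rules, {"P": 0.01}) == self.GREEN
        assert apply_rules(rules, {"P": 0.2}) == (255, 255, 255)
        assert apply_rules(rules, {"P": MISSING}) == (255, 255, 255)

    def test_rule_order(self):
        rules = [
            ColorRule.from_text("[P] <= 0.001", "red"),
            ColorRule.from_text("[P] <= 0.05", "green"),
        ]
        assert apply_rules(rules, {"P": 0.0005}) == (255, 0, 0)
        assert apply_rules(rules, {"P": 0.01}) == self.GREEN


class TestStripes:
    @given(
        x0=st.integers(-1000, 1000),
        width=st.integers(1, 2000),
        k=st.integers(1, 12),
    )
    @settings(derandomize=True, max_examples=200)
    def test_partition_properties(self, x0, width, k):
        """Stripes tile [x0, x0+width) without gaps or overlap whenever the
        node is wide enough to give every stripe at least one pixel."""
        assume(width >= k)
        bounds = stripe_bounds(x0, width, k)
        assert len(bounds) == k
        assert bounds[0][0] == x0 and bounds[-1][1] == x0 + width
        assert sum(b1 - b0 for b0, b1 in bounds) == width
        assert all(a[1] == b[0] for a, b in zip(bounds, bounds[1:]))

    def test_partition_exact(self):
        for width in [37, 80, 160, 121]:
            for k in [1, 2, 3, 6, 7]:
                bounds = stripe_bounds(10, width, k)
                assert len(bounds) == k
                assert bounds[0][0] == 10 and bounds[-1][1] == 10 + width
                assert all(b0 < b1 for b0, b1 in bounds)
                assert sum(b1 - b0 for b0, b1 in bounds) == width
                assert all(a[1] == b[0] for a, b in zip(bounds, bounds[1:]))


def _one_node_setup(n_cols):
    doc = create_pathway("viz")
    nid = add_data_node(doc, "Fos", xref=Xref("1", "L"), cx=100, cy=50)
    cols = [f"c{i}" for i in range(n_cols)]
    table = MeasurementTable(
        column_names=cols,
        identifiers=["1"],
        system_codes=["L"],
        rows=[{c: 0.5 for c in cols}],
    )
    link = NodeDataLink(node_rows={nid: [0]}, row_nodes={0: [nid]}, unmapped_nodes=[])
    spec = VisualizationSpec(
        [(c, ColorGradient(((0.0, (0, 0, 0)), (1.0, (255, 255, 255))))) for c in cols]
    )
    return doc, nid, table, link, spec


class TestRender:
    def test_six_column_spec_gives_six_stripes(self):
        doc, nid, table, link, spec = _one_node_setup(6)
        rendered = render_pathway(doc, link, table, spec)
        node = doc.get(nid)
        # six stripe rects drawn within the node's hit region
        x0, y0, x1, y1 = rendered.hit_regions[nid]
        assert (x1 - x0) == int(node.width) * RASTER_SCALE
        stripe_rects = [
            ln for ln in rendered.svg.splitlines()
            if ln.startswith("<rect") and f'y="{y0}"' in ln and "rgb(128,128,128)" in ln
        ]
        assert len(stripe_rects) == 6

    def test_single_entry_stripe_spans_node(self):
        doc, nid, table, link, spec = _one_node_setup(1)
        rendered = render_pathway(doc, link, table, spec)
        x0, _, x1, _ = rendered.hit_regions[nid]
        assert f'x="{x0}"' in rendered.svg
        assert (x1 - x0) == 160  # 80 units * 2 px/unit

    def test_unmapped_node_solid_light_grey(self):
        doc, nid, table, link, spec = _one_node_setup(3)
        empty_link = NodeDataLink(node_rows={nid: []}, row_nodes={}, unmapped_nodes=[nid])
        rendered = render_pathway(doc, empty_link, table, spec)
        r, g, b = UNMAPPED_COLOR
        assert rendered.svg.count(f"rgb({r},{g},{b})") >= 3  # all stripes grey

    def test_hit_region_per_node_inside_canvas(self):
        doc, nid, table, link, spec = _one_node_setup(2)
        rendered = render_pathway(doc, link, table, spec)
        assert set(rendered.hit_regions) == {nid}
        x0, y0, x1, y1 = rendered.hit_regions[nid]
        assert 0 <= x0 < x1 <= rendered.width_px
        assert 0 <= y0 < y1 <= rendered.height_px

    def test_rendering_is_deterministic(self):
        doc, nid, table, link, spec = _one_node_setup(4)
        r1 = render_pathway(doc, link, table, spec)
        r2 = render_pathway(doc, link, table, spec)
        assert r1.svg == r2.svg and r1.png == r2.png

    def test_spec_with_absent_column_rejected(self):
        doc, nid, table, link, spec = _one_node_setup(2)
        bad = VisualizationSpec([("nope", BWR)])
        with pytest.raises(VisualizationError):
            render_pathway(doc, link, table, bad)


class TestLegend:
    def test_block_per_entry(self):
        spec = VisualizationSpec(
            [
                ("logFC", BWR),
                ("P", [ColorRule.from_text("[P] <= 0.05", "green")]),
            ]
        )
        svg = make_legend(spec)
        assert "logFC" in svg and "P" in svg
        assert "0,255,0" in svg  # the rule swatch

    def test_three_anchor_gradient_labels(self):
        svg = make_legend(VisualizationSpec([("logFC", BWR)]))
        for label in (">-1<", ">0<", ">1<"):
            assert label in svg

    def test_empty_spec_empty_legend(self):
        svg = make_legend(VisualizationSpec([]))
        assert svg.startswith("<?xml") and "<rect" not in svg
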