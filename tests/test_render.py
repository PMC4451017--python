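"""Overlay computation and SVG/HTML rendering: conservation, determinism."""

import xml.etree.ElementTree as ET

import pytest

from pathannot import (
    ConfigError,
    IconRegistry,
    PathwayNode,
    PathwayTopology,
    RenderOptions,
    attach_icon,
    compute_overlay,
    default_registry,
    register_icon,
    render_html,
    render_svg,
)
from pathannot.annotations import AnnotationRow, AnnotationTable
from pathannot.fixtures import make_icon_fixture


def _topology():
    return PathwayTopology((
        PathwayNode("n1", "TP53", genes=("TP53",), x=10, y=10),
        PathwayNode("n2", "KRAS", genes=("KRAS",), x=200, y=10),
        PathwayNode("n3", "ATP", genes=(), x=100, y=120),
    ))


def _aset(name, symbols, registry, icon="pill"):
    rows = tuple(AnnotationRow(s, (f"v{i}", f"w{i}")) for i, s in enumerate(symbols))
    table = AnnotationTable(name, ("Gene", "a", "b"), rows, True)
    return attach_icon(table, icon, registry)


def _count(svg_text, cls):
    root = ET.fromstring(svg_text)
    return sum(1 for e in root.iter() if cls in (e.get("class") or "").split())


class TestIconRegistry:
    def test_builtin_retrievable(self):
        reg = IconRegistry()
        register_icon(reg, "pill", "pill")
        assert reg.get("pill").kind == "builtin"

    def test_user_image_png(self, tmp_path):
        path = make_icon_fixture(tmp_path, "mine", "png")
        reg = IconRegistry()
        asset = register_icon(reg, "mine", path)
        assert asset.kind == "image" and asset.image_format == "png"
        assert asset.data_uri().startswith("data:image/png;base64,")

    @pytest.mark.parametrize("fmt", ["png", "jpg", "gif"])
    def test_allowed_raster_formats(self, tmp_path, fmt):
        path = make_icon_fixture(tmp_path, f"icon_{fmt}", fmt)
        assert register_icon(IconRegistry(), "x", path).image_format == fmt

    def test_disallowed_format_rejected(self, tmp_path):
        bad = tmp_path / "icon.bmp"
        bad.write_bytes(b"BM")
        with pytest.raises(ConfigError, match="not allowed"):
            register_icon(IconRegistry(), "x", bad)

    def test_reregister_replaces(self, tmp_path):
        reg = IconRegistry()
        register_icon(reg, "x", "pill")
        register_icon(reg, "x", "star")
        assert reg.get("x").glyph == "star"


class TestComputeOverlay:
    def test_zero_sets(self):
        doc = compute_overlay(_topology(), [])
        assert doc.total_hits == 0 and doc.legend == ()

    def test_gene_in_two_sets_two_hits(self, registry):
        sets = [_aset("mut", ["TP53"], registry),
                _aset("omim", ["TP53", "KRAS"], registry, icon="star")]
        doc = compute_overlay(_topology(), sets)
        n1 = doc.overlay_for("n1")
        assert [h.set_name for h in n1.hits] == ["mut", "omim"]
        assert doc.total_hits == 3

    def test_hits_equal_brute_force_double_loop(self, registry):
        topo = _topology()
        sets = [_aset("a", ["TP53", "KRAS"], registry),
                _aset("b", ["KRAS"], registry, icon="star"),
                _aset("c", ["BRCA2"], registry, icon="circle")]
        doc = compute_overlay(topo, sets)
        expected = sum(
            1 for node in topo.nodes for s in sets
            if any(g in s.gene_index for g in node.genes))
        assert doc.total_hits == expected

    def test_non_gene_nodes_get_no_hits(self, registry):
        doc = compute_overlay(_topology(), [_aset("a", ["TP53"], registry)])
        assert doc.overlay_for("n3") is None or not doc.overlay_for("n3").hits

    def test_multi_row_gene_aggregates_one_hit(self, registry):
        doc = compute_overlay(
            _topology(), [_aset("a", ["TP53", "TP53", "TP53"], registry)])
        (hit,) = doc.overlay_for("n1").hits
        assert len(hit.tooltip_rows) == 3
        assert hit.tooltip_header == ("Gene", "a", "b")

    def test_legend_lists_every_set_once(self, registry):
        sets = [_aset("a", [], registry), _aset("b", ["TP53"], registry, icon="star")]
        doc = compute_overlay(_topology(), sets)
        assert doc.legend == (("pill", "a"), ("star", "b"))


class TestRenderSvg:
    def test_zero_hits_zero_icon_elements(self, registry):
        doc = compute_overlay(_topology(), [])
        assert _count(render_svg(doc, registry), "hit-icon") == 0

    def test_icon_conservation(self, registry):
        sets = [_aset("a", ["TP53", "KRAS"], registry),
                _aset("b", ["KRAS"], registry, icon="star")]
        doc = compute_overlay(_topology(), sets)
        svg = render_svg(doc, registry)
        assert _count(svg, "hit-icon") == doc.total_hits == 3

    def test_well_formed_xml(self, registry):
        svg = render_svg(compute_overlay(
            _topology(), [_aset("a", ["TP53"], registry)]), registry)
        ET.fromstring(svg)  # raises on malformed output

    def test_byte_identical_reruns(self, registry):
        sets = [_aset("a", ["TP53", "KRAS"], registry)]
        doc = compute_overlay(_topology(), sets)
        assert render_svg(doc, registry) == render_svg(doc, registry)

    def test_genecards_link_substituted(self, registry):
        svg = render_svg(compute_overlay(
            _topology(), [_aset("a", ["TP53"], registry)]), registry)
        assert "carddisp.pl?gene=TP53" in svg

    def test_custom_link_template(self, registry):
        doc = compute_overlay(_topology(), [], link_template="https://x.test/{gene}")
        assert "https://x.test/KRAS" in render_svg(doc, registry)

    def test_tooltip_payload_embeds_header_and_rows(self, registry):
        doc = compute_overlay(_topology(), [_aset("a", ["TP53", "TP53"], registry)])
        root = ET.fromstring(render_svg(doc, registry))
        titles = [e.text for e in root.iter("{http://www.w3.org/2000/svg}title")]
        (tooltip,) = [t for t in titles if t.startswith("a\n")]
        lines = tooltip.split("\n")
        assert lines[1] == "Gene\ta\tb"
        assert len(lines) == 2 + 2  # header line + 2 data rows

    def test_legend_block_one_entry_per_set(self, registry):
        sets = [_aset("a", ["TP53"], registry),
                _aset("b", [], registry, icon="star")]
        svg = render_svg(compute_overlay(_topology(), sets), registry)
        assert _count(svg, "legend-icon") == 2

    def test_unregistered_icon_fails_before_output(self):
        reg = IconRegistry()  # empty: 'pill' not registered
        full = default_registry()
        doc = compute_overlay(_topology(), [_aset("a", ["TP53"], full)])
        with pytest.raises(ConfigError, match="pill"):
            render_svg(doc, reg)

    def test_user_image_icon_embedded(self, tmp_path):
        reg = default_registry()
        register_icon(reg, "mut", make_icon_fixture(tmp_path, "mut", "png"))
        doc = compute_overlay(_topology(), [_aset("a", ["TP53"], reg, icon="mut")])
        assert "data:image/png;base64," in render_svg(doc, reg)


class TestRenderHtml:
    def test_empty_doc_valid_html_no_tooltips(self, registry):
        html = render_html(compute_overlay(_topology(), []), registry)
        assert html.startswith("<!DOCTYPE html>")
        assert 'class="tooltip"' not in html

    def test_one_tooltip_block_per_hit(self, registry):
        sets = [_aset("a", ["TP53", "KRAS"], registry),
                _aset("b", ["KRAS"], registry, icon="star")]
        doc = compute_overlay(_topology(), sets)
        html = render_html(doc, registry)
        assert html.count('class="tooltip"') == doc.total_hits == 3

    def test_two_row_tooltip_shows_both_rows(self, registry):
        doc = compute_overlay(_topology(), [_aset("a", ["TP53", "TP53"], registry)])
        html = render_html(doc, registry)
        svg_start = html.index("<svg")
        root = ET.fromstring(html[svg_start:html.index("</svg>") + 6])
        tooltip = next(e for e in root.iter()
                       if (e.get("class") or "") == "tooltip")
        texts = [t.text for t in tooltip.iter("{http://www.w3.org/2000/svg}text")]
        assert texts[0] == "a"                 # set name heading
        assert texts[1] == "Gene  a  b"        # header names from the '#' line
        assert len(texts) == 2 + 2             # heading + header + 2 rows

    def test_deterministic(self, registry):
        doc = compute_overlay(_topology(), [_aset("a", ["TP53"], registry)])
        assert render_html(doc, registry) == render_html(doc, registry)

    def test_hover_styling_is_declarative(self, registry):
        html = render_html(compute_overlay(
            _topology(), [_aset("a", ["TP53"], registry)]), registry)
        assert "g.hit-icon:hover .tooltip" in html
        assert "<script" not in html
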