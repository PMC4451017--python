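"""Static icon-overlay rendering of pathway diagrams.

The overlay join is a double loop: for every topology node carrying at least
one gene and every annotation set containing any of those genes, one *hit* is
recorded. A hit aggregates all matching rows of the set into a single tooltip
payload (header names plus row values) and renders as one icon in a
horizontal strip anchored at the node box's top-right corner — 14x14 units
per icon, left-to-right in set load order, wrapping after four icons.

Output is plain SVG 1.1 (or a self-contained HTML page embedding it) with:
node boxes and labels, gene labels hyperlinked to a per-gene page (GeneCards
search by default), one icon element per hit carrying a ``<title>`` tooltip,
and a legend listing each loaded set's icon. Rendering is deterministic:
identical inputs yield byte-identical output.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .annotations import AnnotationSet
from .errors import ConfigError
from .icons import IconRegistry, glyph_element
from .pathways import PathwayTopology

__all__ = [
    "Hit",
    "NodeOverlay",
    "OverlayDocument",
    "RenderOptions",
    "compute_overlay",
    "render_svg",
    "render_html",
    "GENECARDS_TEMPLATE",
]

GENECARDS_TEMPLATE = "https://www.genecards.org/cgi-bin/carddisp.pl?gene={gene}"

ICON_SIZE = 14.0
ICONS_PER_ROW = 4
LEGEND_GUTTER = 170.0  # legend column on the left, like the viewer's icon rail
MARGIN = 20.0


@dataclass(frozen=True)
class Hit:
    set_name: str
    icon: str
    tooltip_header: tuple[str, ...]
    tooltip_rows: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class NodeOverlay:
    node_id: str
    genes: tuple[str, ...]
    hits: tuple[Hit, ...]  # ordered by set load order; one hit per set


@dataclass(frozen=True)
class OverlayDocument:
    topology: PathwayTopology
    overlays: tuple[NodeOverlay, ...]
    legend: tuple[tuple[str, str], ...]  # (icon name, set name), load order
    link_template: str = GENECARDS_TEMPLATE

    @property
    def total_hits(self) -> int:
        return sum(len(o.hits) for o in self.overlays)

    def overlay_for(self, node_id: str) -> NodeOverlay | None:
        for o in self.overlays:
            if o.node_id == node_id:
                return o
        return None


@dataclass(frozen=True)
class RenderOptions:
    icon_size: float = ICON_SIZE
    icons_per_row: int = ICONS_PER_ROW
    show_legend: bool = True
    node_fill: str = "#eef3f8"
    node_stroke: str = "#4a6785"
    font_family: str = "Helvetica, Arial, sans-serif"
    font_size: float = 11.0
    extra_style: str = ""


def compute_overlay(topology: PathwayTopology, sets: list[AnnotationSet],
                    link_template: str = GENECARDS_TEMPLATE) -> OverlayDocument:
    """Join annotation sets onto a topology.

    For each gene-bearing node and each set whose index holds any of the
    node's genes, emit exactly one hit containing every matching row (rows
    for all of the node's genes, in row order). Nodes without genes get no
    hits; every set appears once in the legend regardless of hit count.
    """
    overlays: list[NodeOverlay] = []
    for node in topology.nodes:
        if not node.genes:
            continue
        hits: list[Hit] = []
        for s in sets:
            row_ix = sorted({i for g in node.genes for i in s.gene_index.get(g, ())})
            if not row_ix:
                continue
            rows = tuple(s.table.rows[i].fields() for i in row_ix)
            hits.append(Hit(set_name=s.name, icon=s.icon,
                            tooltip_header=s.table.columns, tooltip_rows=rows))
        overlays.append(NodeOverlay(node.node_id, node.genes, tuple(hits)))
    legend = tuple((s.icon, s.name) for s in sets)
    return OverlayDocument(topology, tuple(overlays), legend, link_template)


def _tooltip_text(hit: Hit) -> str:
    lines = [hit.set_name, "\t".join(hit.tooltip_header)]
    lines += ["\t".join(r) for r in hit.tooltip_rows]
    return "\n".join(lines)


def _check_icons(doc: OverlayDocument, registry: IconRegistry) -> None:
    needed = {icon for icon, _ in doc.legend}
    needed |= {h.icon for o in doc.overlays for h in o.hits}
    for icon in sorted(needed):
        registry.get(icon)  # raises ConfigError before any output is built


def _icon_position(node, i: int, opt: RenderOptions) -> tuple[float, float]:
    """Slot *i* of the strip at the node's top-right corner (wraps in rows)."""
    row, col = divmod(i, opt.icons_per_row)
    gap = opt.icon_size + 1.0
    return node.x + node.width + 2.0 + col * gap, node.y - gap + row * gap


def _build_svg_tree(doc: OverlayDocument, registry: IconRegistry,
                    opt: RenderOptions, with_hover_tooltips: bool) -> ET.Element:
    _check_icons(doc, registry)
    topo = doc.topology
    off_x = (LEGEND_GUTTER if opt.show_legend else 0.0) + MARGIN
    off_y = MARGIN + opt.icon_size + 2.0

    max_x = max((n.x + n.width for n in topo.nodes), default=200.0)
    max_y = max((n.y + n.height for n in topo.nodes), default=100.0)
    width = off_x + max_x + 6 * opt.icon_size + MARGIN
    height = off_y + max(max_y + MARGIN,
                         len(doc.legend) * (opt.icon_size + 8.0) + MARGIN)

    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "xmlns:xlink": "http://www.w3.org/1999/xlink",
        "version": "1.1",
        "width": f"{width:g}", "height": f"{height:g}",
        "viewBox": f"0 0 {width:g} {height:g}"})
    style = ET.SubElement(svg, "style")
    style.text = (
        f"text{{font-family:{opt.font_family};font-size:{opt.font_size:g}px}}"
        ".tooltip{visibility:hidden}"
        "g.hit-icon:hover .tooltip{visibility:visible}"
        + opt.extra_style)

    if topo.background_image:
        ET.SubElement(svg, "image", {"x": f"{off_x:g}", "y": f"{off_y:g}",
                                     "href": topo.background_image})

    if opt.show_legend and doc.legend:
        legend_g = ET.SubElement(svg, "g", {"class": "legend"})
        for i, (icon, set_name) in enumerate(doc.legend):
            ly = MARGIN + i * (opt.icon_size + 8.0)
            e = glyph_element(registry.get(icon), MARGIN, ly, opt.icon_size)
            cls = e.get("class", "")
            e.set("class", (cls + " legend-icon").strip())
            legend_g.append(e)
            txt = ET.SubElement(legend_g, "text", {
                "x": f"{MARGIN + opt.icon_size + 6.0:g}",
                "y": f"{ly + opt.icon_size - 3.0:g}"})
            txt.text = set_name

    # edges beneath nodes
    for e in topo.edges:
        s, t = topo.node(e.source), topo.node(e.target)
        line = ET.SubElement(svg, "line", {
            "x1": f"{off_x + s.x + s.width / 2:g}", "y1": f"{off_y + s.y + s.height / 2:g}",
            "x2": f"{off_x + t.x + t.width / 2:g}", "y2": f"{off_y + t.y + t.height / 2:g}",
            "stroke": "#999999", "stroke-width": "1"})
        if e.interaction:
            line.set("data-interaction", e.interaction)

    for node in topo.nodes:
        g = ET.SubElement(svg, "g", {"class": "node", "data-node-id": node.node_id})
        ET.SubElement(g, "rect", {
            "x": f"{off_x + node.x:g}", "y": f"{off_y + node.y:g}",
            "width": f"{node.width:g}", "height": f"{node.height:g}",
            "fill": opt.node_fill, "stroke": opt.node_stroke, "rx": "3"})
        tx = f"{off_x + node.x + node.width / 2:g}"
        ty = f"{off_y + node.y + node.height / 2 + opt.font_size / 3:g}"
        label = ET.Element("text", {"x": tx, "y": ty, "text-anchor": "middle"})
        label.text = node.label
        if node.genes:
            a = ET.SubElement(g, "a", {
                "href": doc.link_template.format(gene=node.genes[0]),
                "target": "_blank"})
            a.append(label)
        else:
            g.append(label)

        overlay = doc.overlay_for(node.node_id)
        if overlay is None:
            continue
        for i, hit in enumerate(overlay.hits):
            ix, iy = _icon_position(node, i, opt)
            ix, iy = ix + off_x, iy + off_y
            hit_g = ET.SubElement(g, "g", {
                "class": "hit-icon", "data-set": hit.set_name})
            title = ET.SubElement(hit_g, "title")
            title.text = _tooltip_text(hit)
            hit_g.append(glyph_element(registry.get(hit.icon), ix, iy, opt.icon_size))
            if with_hover_tooltips:
                hit_g.append(_tooltip_box(hit, ix, iy + opt.icon_size + 4.0, opt))
    return svg


def _tooltip_box(hit: Hit, x: float, y: float, opt: RenderOptions) -> ET.Element:
    """Grey hover box showing the set's header and matched rows."""
    lines = ["\t".join(hit.tooltip_header)] + ["\t".join(r) for r in hit.tooltip_rows]
    line_h = opt.font_size + 3.0
    box_w = 8.0 + max(len(t) for t in [hit.set_name] + lines) * opt.font_size * 0.62
    box_h = (len(lines) + 1) * line_h + 8.0
    g = ET.Element("g", {"class": "tooltip"})
    ET.SubElement(g, "rect", {
        "x": f"{x:g}", "y": f"{y:g}", "width": f"{box_w:.1f}", "height": f"{box_h:.1f}",
        "fill": "#e8e8e8", "stroke": "#666666"})
    head = ET.SubElement(g, "text", {
        "x": f"{x + 4.0:g}", "y": f"{y + line_h:g}", "font-weight": "bold"})
    head.text = hit.set_name
    for j, text in enumerate(lines, start=1):
        t = ET.SubElement(g, "text", {"x": f"{x + 4.0:g}",
                                      "y": f"{y + (j + 1) * line_h:g}"})
        t.text = text.replace("\t", "  ")
    return g


def render_svg(doc: OverlayDocument, registry: IconRegistry,
               options: RenderOptions | None = None) -> str:
    """Serialize the overlay to standalone SVG text (deterministic)."""
    opt = options or RenderOptions()
    svg = _build_svg_tree(doc, registry, opt, with_hover_tooltips=False)
    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(svg, encoding="unicode") + "\n")


def render_html(doc: OverlayDocument, registry: IconRegistry,
                options: RenderOptions | None = None,
                title: str = "Pathway overlay") -> str:
    """Self-contained HTML page: inline SVG with CSS hover tooltips.

    No scripts, no network fetches; each hit carries one hidden grey tooltip
    box made visible on hover, mirroring the interactive viewer statically.
    """
    opt = options or RenderOptions()
    svg = _build_svg_tree(doc, registry, opt, with_hover_tooltips=True)
    body = ET.tostring(svg, encoding="unicode")
    return ("<!DOCTYPE html>\n"
            "<html lang=\"en\"><head><meta charset=\"utf-8\"/>"
            f"<title>{title}</title></head>\n"
            f"<body>\n{body}\n</body></html>\n")
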