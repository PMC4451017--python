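"""Render an icon-overlay pathway diagram to SVG and HTML.

Two annotation sets ("mutations" and "drugs") are joined onto a small
hand-built topology; genes present in both sets get two icons. The HTML
output is self-contained: hovering an icon reveals the grey tooltip box with
the set's header and matched rows.
"""

from pathlib import Path

from pathannot import (
    PathwayEdge, PathwayNode, PathwayTopology, attach_icon, compute_overlay,
    default_registry, render_html, render_svg,
)
from pathannot.annotations import AnnotationRow, AnnotationTable

topology = PathwayTopology(
    nodes=(
        PathwayNode("n1", "TP53", genes=("TP53",), x=40, y=30),
        PathwayNode("n2", "CDK4", genes=("CDK4",), x=220, y=30),
        PathwayNode("n3", "CCND1", genes=("CCND1",), x=130, y=140),
        PathwayNode("n4", "ATP", genes=(), x=40, y=140),  # compound node
    ),
    edges=(
        PathwayEdge("n1", "n2", "inhibits"),
        PathwayEdge("n2", "n3", "activates"),
    ),
)

registry = default_registry()


def aset(name, icon, rows):
    table = AnnotationTable(name, ("Gene", "detail", "value"),
                            tuple(AnnotationRow(g, v) for g, v in rows), True)
    return attach_icon(table, icon, registry)


mutations = aset("mutations", "cross", [
    ("TP53", ("splice variant", "LOH")),
    ("CCND1", ("P287T", "allele-specific expression")),
])
drugs = aset("drugs", "pill", [
    ("CDK4", ("palbociclib", "inhibitor")),
    ("CCND1", ("indirect via CDK4/6", "inhibitor")),
])

doc = compute_overlay(topology, [mutations, drugs])
print(f"{doc.total_hits} icon hits "
      f"(CCND1 is in both sets, so its node carries two icons)")
for overlay in doc.overlays:
    if overlay.hits:
        print(f"  node {overlay.node_id} ({'/'.join(overlay.genes)}): "
              + ", ".join(h.set_name for h in overlay.hits))

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
(out / "overlay.svg").write_text(render_svg(doc, registry))
(out / "overlay.html").write_text(render_html(doc, registry))
print(f"wrote {out / 'overlay.svg'} and {out / 'overlay.html'} "
      f"(gene labels link to GeneCards)")
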