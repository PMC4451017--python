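"""Pathway collections: gene membership and drawable topology.

Two carriers are supported. GMT files (one gene set per line:
``name<TAB>description<TAB>gene1<TAB>...``) carry membership only and feed the
summary table and enrichment. XGMML files exported from Cytoscape carry a
drawable topology — nodes with labels and screen coordinates, edges with
optional interaction labels — and feed the overlay renderer.

A topology node's gene identity comes from its label: the label is split on
``/`` and ``,`` (KEGG-style boxes often hold gene families like "CDK4/6") and
each token is run through the HGNC normalizer. Tokens with no HGNC match are
fine: compound and process nodes (e.g. "ATP") are retained, they just carry
no genes. Coordinates are continuous screen units, y growing downward, as in
both Cytoscape exports and SVG; nodes lacking coordinates fall onto a
deterministic row-major grid so a topology is always renderable.
"""

from __future__ import annotations

import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._io import atomic_write_text
from .errors import FormatError, InputError
from .normalize import Normalizer, normalize_symbols

__all__ = [
    "Pathway",
    "PathwayNode",
    "PathwayEdge",
    "PathwayTopology",
    "PathwayCollection",
    "read_gmt",
    "write_gmt",
    "read_xgmml",
    "pathway_from_topology",
    "filter_pathways",
]

# fallback grid for nodes without coordinates (row-major)
_GRID_COLS = 4
_GRID_CELL_W = 150.0
_GRID_CELL_H = 80.0
_DEFAULT_W = 70.0
_DEFAULT_H = 28.0

_LABEL_SPLIT = re.compile(r"[/,]")


@dataclass(frozen=True)
class PathwayNode:
    node_id: str
    label: str
    genes: tuple[str, ...] = ()  # approved symbols; empty for non-gene nodes
    x: float = 0.0
    y: float = 0.0
    width: float = _DEFAULT_W
    height: float = _DEFAULT_H

    def __post_init__(self):
        for v in (self.x, self.y, self.width, self.height):
            if not math.isfinite(v):
                raise FormatError(f"node {self.node_id!r}: non-finite coordinate {v!r}")


@dataclass(frozen=True)
class PathwayEdge:
    source: str
    target: str
    interaction: str | None = None


@dataclass(frozen=True)
class PathwayTopology:
    nodes: tuple[PathwayNode, ...]
    edges: tuple[PathwayEdge, ...] = ()
    background_image: str | None = None

    def __post_init__(self):
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate node id {dup!r} in topology")
        known = set(ids)
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in known:
                    raise FormatError(
                        f"edge {e.source!r}->{e.target!r} references unknown node "
                        f"{endpoint!r}")

    def node(self, node_id: str) -> PathwayNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)


@dataclass(frozen=True)
class Pathway:
    id: str
    display_name: str
    source: str
    genes: frozenset[str]
    topology: PathwayTopology | None = None

    def __post_init__(self):
        if not self.genes:
            raise InputError(f"pathway {self.id!r} has no genes")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PathwayCollection:
    pathways: tuple[Pathway, ...]

    def __init__(self, pathways: Iterable[Pathway]):
        pw = tuple(pathways)
        ids = [p.id for p in pw]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise InputError(f"duplicate pathway id {dup!r} in collection")
        object.__setattr__(self, "pathways", pw)

    @property
    def universe(self) -> frozenset[str]:
        """Union of genes across all pathways: the enrichment background."""
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)


def _pass_through(norm: Normalizer | None, symbols: Sequence[str]) -> list[str]:
    """Map symbols to approved form where matched; keep unmatched as written."""
    if norm is None:
        return [s.strip() for s in symbols]
    out = []
    for s, res in zip(symbols, normalize_symbols(norm, symbols)):
        out.append(res.approved_symbol if res.approved_symbol is not None else s.strip())
    return out


def read_gmt(path: str | Path, source_label: str,
             norm: Normalizer | None = None) -> list[Pathway]:
    """Read a GMT gene-set file: one pathway per non-blank line.

    Duplicate genes within a line are deduplicated; symbols are passed
    through the normalizer when one is given.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8-sig").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: GMT line needs >=3 fields "
                              f"(name, description, genes), got {len(fields)}")
        name = fields[0].strip()
        description = fields[1].strip()
        genes = frozenset(g for g in _pass_through(norm, fields[2:]) if g)
        if not genes:
            raise FormatError(f"{path}: line {lineno}: pathway {name!r} has no genes")
        pathways.append(Pathway(id=name, display_name=description or name,
                                source=source_label, genes=genes))
    return pathways


def write_gmt(pathways: Iterable[Pathway], path: str | Path) -> None:
    lines = []
    for p in pathways:
        lines.append("\t".join([p.id, p.display_name] + sorted(p.genes)))
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _atts(elem: ET.Element) -> dict[str, str]:
    out = {}
    for child in elem:
        if _local(child.tag) == "att":
            name = child.get("name")
            value = child.get("value")
            if name is not None and value is not None:
                out[name] = value
    return out


def _node_genes(label: str, norm: Normalizer | None) -> tuple[str, ...]:
    tokens = [t for t in (s.strip() for s in _LABEL_SPLIT.split(label)) if t]
    if norm is None or not tokens:
        return ()
    # family shorthand: in "CDK4/6" the token "6" means CDK6
    stem = re.sub(r"\d+$", "", tokens[0])
    genes: list[str] = []
    for i, res in enumerate(normalize_symbols(norm, tokens)):
        symbol = res.approved_symbol
        if symbol is None and i > 0 and stem and tokens[i].isdigit():
            retry = normalize_symbols(norm, [stem + tokens[i]])[0]
            symbol = retry.approved_symbol
        if symbol is not None and symbol not in genes:
            genes.append(symbol)
    return tuple(genes)


def read_xgmml(path: str | Path, norm: Normalizer | None = None,
               background_image: str | None = None) -> PathwayTopology:
    """Parse a Cytoscape XGMML export into a topology.

    Coordinates are read from each node's ``graphics`` child (x, y, w, h),
    falling back to node-level ``att`` elements; nodes still lacking a
    position are laid out on the fallback grid. Edges must reference
    existing node ids.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "graph":
        raise FormatError(f"{path}: root element is {_local(root.tag)!r}, expected 'graph'")

    graph_atts = _atts(root)
    bg = background_image if background_image is not None else graph_atts.get("backgroundImage")

    nodes: list[PathwayNode] = []
    missing_coords: list[int] = []
    edges: list[PathwayEdge] = []
    for elem in root.iter():
        kind = _local(elem.tag)
        if kind == "node":
            node_id = elem.get("id") or elem.get("label")
            if node_id is None:
                raise FormatError(f"{path}: node without id or label")
            atts = _atts(elem)
            label = elem.get("label") or atts.get("label") or node_id
            gx = gy = gw = gh = None
            for child in elem:
                if _local(child.tag) == "graphics":
                    gx, gy = child.get("x"), child.get("y")
                    gw, gh = child.get("w"), child.get("h")
                    break
            if gx is None:
                gx, gy = atts.get("x"), atts.get("y")
            if gw is None:
                gw, gh = atts.get("w"), atts.get("h")
            try:
                x = float(gx) if gx is not None else None
                y = float(gy) if gy is not None else None
                w = float(gw) if gw is not None else _DEFAULT_W
                h = float(gh) if gh is not None else _DEFAULT_H
            except ValueError as exc:
                raise FormatError(f"{path}: node {node_id!r}: bad coordinate: {exc}") from exc
            if x is None or y is None:
                missing_coords.append(len(nodes))
                x, y = 0.0, 0.0
            nodes.append(PathwayNode(node_id=node_id, label=label,
                                     genes=_node_genes(label, norm),
                                     x=x, y=y, width=w, height=h))
        elif kind == "edge":
            src, tgt = elem.get("source"), elem.get("target")
            if src is None or tgt is None:
                raise FormatError(f"{path}: edge missing source/target")
            interaction = elem.get("label") or _atts(elem).get("interaction")
            edges.append(PathwayEdge(src, tgt, interaction))

    # deterministic row-major grid for coordinate gaps
    for slot, idx in enumerate(missing_coords):
        row, col = divmod(slot, _GRID_COLS)
        n = nodes[idx]
        nodes[idx] = PathwayNode(n.node_id, n.label, n.genes,
                                 x=20.0 + col * _GRID_CELL_W,
                                 y=20.0 + row * _GRID_CELL_H,
                                 width=n.width, height=n.height)
    return PathwayTopology(tuple(nodes), tuple(edges), background_image=bg)


def write_xgmml(topology: PathwayTopology, path: str | Path, label: str = "pathway") -> None:
    """Write a minimal XGMML document (round-trip partner of read_xgmml)."""
    root = ET.Element("graph", {"label": label, "directed": "1"})
    if topology.background_image:
        ET.SubElement(root, "att", {"name": "backgroundImage",
                                    "value": topology.background_image})
    for n in topology.nodes:
        ne = ET.SubElement(root, "node", {"id": n.node_id, "label": n.label})
        ET.SubElement(ne, "graphics", {"x": repr(n.x), "y": repr(n.y),
                                       "w": repr(n.width), "h": repr(n.height)})
    for e in topology.edges:
        attrs = {"source": e.source, "target": e.target}
        if e.interaction:
            attrs["label"] = e.interaction
        ET.SubElement(root, "edge", attrs)
    ET.indent(root)
    atomic_write_text(path, ET.tostring(root, encoding="unicode") + "\n")


def pathway_from_topology(topology: PathwayTopology, id: str, name: str,
                          source: str) -> Pathway:
    """Derive countable membership from a drawable topology.

    Genes are the union over gene-bearing nodes; a topology with zero gene
    nodes cannot participate in counting and is an error.
    """
    genes: set[str] = set()
    for n in topology.nodes:
        genes.update(n.genes)
    if not genes:
        raise InputError(f"topology for {id!r} has no gene-bearing nodes")
    return Pathway(id=id, display_name=name, source=source,
                   genes=frozenset(genes), topology=topology)


def filter_pathways(collection: PathwayCollection,
                    query_genes: Iterable[str]) -> PathwayCollection:
    """Restrict a collection to pathways containing any query gene.

    Query symbols are assumed normalized. Ordering is preserved; an empty
    result is valid.
    """
    query = set(query_genes)
    return PathwayCollection(p for p in collection if p.genes & query)
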