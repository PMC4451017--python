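"""Icon registry: builtin vector glyphs plus user-uploaded raster images.

Every annotation set displays through exactly one icon. A small builtin
palette of glyphs (pill, circle, square, triangle, diamond, star, cross,
drop) covers the common data types — drugs, variants, expression, phenotype —
and users may register their own .png/.jpg/.gif images, which are embedded
into the rendered document as base64 data URIs so output stays
self-contained.
"""

from __future__ import annotations

import base64
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError

__all__ = ["IconAsset", "IconRegistry", "register_icon", "BUILTIN_GLYPHS",
           "default_registry", "glyph_element"]

ALLOWED_IMAGE_FORMATS = {"png", "jpg", "jpeg", "gif"}

# name -> fill color; shape is drawn by glyph_element
BUILTIN_GLYPHS: dict[str, str] = {
    "pill": "#d9534f",
    "circle": "#337ab7",
    "square": "#5cb85c",
    "triangle": "#f0ad4e",
    "diamond": "#9b59b6",
    "star": "#e6b800",
    "cross": "#555555",
    "drop": "#17a2b8",
}


@dataclass(frozen=True)
class IconAsset:
    name: str
    kind: str  # "builtin" or "image"
    glyph: str | None = None          # builtin glyph id
    image_format: str | None = None   # png/jpg/gif for user images
    data: bytes | None = None         # raw image bytes

    def data_uri(self) -> str:
        if self.kind != "image" or self.data is None:
            raise ConfigError(f"icon {self.name!r} has no image data")
        mime = "jpeg" if self.image_format == "jpg" else self.image_format
        return f"data:image/{mime};base64,{base64.b64encode(self.data).decode('ascii')}"


class IconRegistry:
    """Named icon store; re-registering a name replaces the asset."""

    def __init__(self):
        self._assets: dict[str, IconAsset] = {}

    def register(self, name: str, source: str | Path) -> IconAsset:
        return register_icon(self, name, source)

    def add(self, asset: IconAsset) -> None:
        self._assets[asset.name] = asset

    def get(self, name: str) -> IconAsset:
        try:
            return self._assets[name]
        except KeyError:
            raise ConfigError(f"unknown icon {name!r}; registered: "
                              f"{sorted(self._assets) or 'none'}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._assets

    def names(self) -> list[str]:
        return sorted(self._assets)


def register_icon(registry: IconRegistry, name: str, source: str | Path) -> IconAsset:
    """Register a builtin glyph id or a .png/.jpg/.gif image file under *name*.

    Any other image format (.bmp, .svg uploads, ...) is rejected.
    """
    if isinstance(source, str) and source in BUILTIN_GLYPHS:
        asset = IconAsset(name=name, kind="builtin", glyph=source)
        registry.add(asset)
        return asset
    path = Path(source)
    fmt = path.suffix.lower().lstrip(".")
    if fmt not in ALLOWED_IMAGE_FORMATS:
        raise ConfigError(
            f"icon {name!r}: format {path.suffix!r} not allowed "
            f"(accepted: .png, .jpg, .gif)")
    if not path.is_file():
        raise ConfigError(f"icon {name!r}: file not found: {path}")
    asset = IconAsset(name=name, kind="image", image_format=fmt,
                      data=path.read_bytes())
    registry.add(asset)
    return asset


def default_registry() -> IconRegistry:
    """Registry pre-populated with every builtin glyph under its own name."""
    reg = IconRegistry()
    for glyph in BUILTIN_GLYPHS:
        reg.register(glyph, glyph)
    return reg


def glyph_element(asset: IconAsset, x: float, y: float, size: float) -> ET.Element:
    """Render one icon as an SVG element with top-left corner (x, y)."""
    if asset.kind == "image":
        return ET.Element("image", {
            "x": f"{x:g}", "y": f"{y:g}",
            "width": f"{size:g}", "height": f"{size:g}",
            "href": asset.data_uri()})
    fill = BUILTIN_GLYPHS[asset.glyph]
    cx, cy, r = x + size / 2, y + size / 2, size / 2
    if asset.glyph == "circle" or asset.glyph == "drop":
        e = ET.Element("circle", {"cx": f"{cx:g}", "cy": f"{cy:g}",
                                  "r": f"{r:g}", "fill": fill})
    elif asset.glyph == "square":
        e = ET.Element("rect", {"x": f"{x:g}", "y": f"{y:g}",
                                "width": f"{size:g}", "height": f"{size:g}",
                                "fill": fill})
    elif asset.glyph == "pill":
        e = ET.Element("rect", {"x": f"{x:g}", "y": f"{y + size * 0.2:g}",
                                "width": f"{size:g}", "height": f"{size * 0.6:g}",
                                "rx": f"{size * 0.3:g}", "fill": fill})
    elif asset.glyph == "triangle":
        pts = f"{cx:g},{y:g} {x + size:g},{y + size:g} {x:g},{y + size:g}"
        e = ET.Element("polygon", {"points": pts, "fill": fill})
    elif asset.glyph == "diamond":
        pts = f"{cx:g},{y:g} {x + size:g},{cy:g} {cx:g},{y + size:g} {x:g},{cy:g}"
        e = ET.Element("polygon", {"points": pts, "fill": fill})
    elif asset.glyph == "star":
        # 5-point star on two concentric radii
        import math
        pts = []
        for i in range(10):
            rad = r if i % 2 == 0 else r * 0.45
            ang = -math.pi / 2 + i * math.pi / 5
            pts.append(f"{cx + rad * math.cos(ang):.2f},{cy + rad * math.sin(ang):.2f}")
        e = ET.Element("polygon", {"points": " ".join(pts), "fill": fill})
    elif asset.glyph == "cross":
        t = size * 0.3
        d = (f"M {x + (size - t) / 2:g} {y:g} h {t:g} v {(size - t) / 2:g} "
             f"h {(size - t) / 2:g} v {t:g} h -{(size - t) / 2:g} v {(size - t) / 2:g} "
             f"h -{t:g} v -{(size - t) / 2:g} h -{(size - t) / 2:g} v -{t:g} "
             f"h {(size - t) / 2:g} Z")
        e = ET.Element("path", {"d": d, "fill": fill})
    else:  # pragma: no cover - every builtin is handled above
        raise ConfigError(f"no renderer for glyph {asset.glyph!r}")
    return e
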