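"""Deterministic SVG rendering of the labeled map.

The visual grammar follows the large-format map product: patch boundary
geometry is drawn for the first dominance level only, while labels for the
first few levels are layered on top, distinguished by color (level 1 blue,
level 2 green, level 3 red-orange) and sized by the placement policy's font
sizes.  Output is plain SVG text, byte-for-byte reproducible for fixed
inputs (all coordinates are formatted at fixed precision).
"""

from __future__ import annotations

from dataclasses import dataclass

from .clustering import PatchSet, dissolve_geometry
from .lattice import HexLattice
from .placement import LabelSolution

__all__ = ["RenderSpec", "render_map"]

DEFAULT_COLORS = {1: "#2b5fb8", 2: "#2e8b57", 3: "#e2552d"}


@dataclass(frozen=True)
class RenderSpec:
    levels_shown: frozenset[int] = frozenset({1, 2, 3})
    geometry_levels: frozenset[int] = frozenset({1})
    level_colors: tuple[tuple[int, str], ...] = tuple(DEFAULT_COLORS.items())
    frame: tuple[float, float, float, float] | None = None
    scale: float = 20.0  # pixels per lattice unit

    def __post_init__(self) -> None:
        if not self.geometry_levels <= self.levels_shown:
            raise ValueError("geometry_levels must be a subset of levels_shown")

    def color(self, level: int) -> str:
        for lv, c in self.level_colors:
            if lv == level:
                return c
        return "#555555"


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _poly_paths(geom) -> list[str]:
    """SVG path strings (exterior + holes) for a shapely (Multi)Polygon."""
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    paths = []
    for poly in polys:
        parts = []
        for ring in [poly.exterior, *poly.interiors]:
            pts = list(ring.coords)
            d = "M " + " L ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts) + " Z"
            parts.append(d)
        paths.append(" ".join(parts))
    return paths


def render_map(
    patchsets: list[PatchSet],
    solution: LabelSolution,
    lattice: HexLattice,
    spec: RenderSpec | None = None,
) -> str:
    """Render patch geometry and placed labels to an SVG document string."""
    spec = spec or RenderSpec()
    have_levels = {ps.rank_level for ps in patchsets}
    sol_levels = {b.level for b in solution.boxes}
    if solution.boxes and not sol_levels <= have_levels:
        raise ValueError(
            "label solution references levels absent from the patch sets"
        )
    if spec.frame is not None:
        x0, y0, x1, y1 = spec.frame
    else:
        xs, ys = lattice.centers[:, 0], lattice.centers[:, 1]
        x0, y0, x1, y1 = xs.min() - 1, ys.min() - 1, xs.max() + 1, ys.max() + 1
    s = spec.scale
    width, height = (x1 - x0) * s, (y1 - y0) * s

    def tx(x: float) -> float:
        return (x - x0) * s

    def ty(y: float) -> float:
        return (y1 - y) * s  # SVG y grows downward

    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
        f'<rect x="0" y="0" width="{_fmt(width)}" height="{_fmt(height)}" '
        'fill="white"/>',
    ]
    for ps in sorted(patchsets, key=lambda p: p.rank_level):
        if ps.rank_level not in spec.geometry_levels:
            continue
        for patch in ps.patches:
            geom = dissolve_geometry(patch, lattice)
            for d in _poly_paths(geom):
                # transform coordinates into pixel space
                coords = []
                for tok in d.split():
                    if "," in tok:
                        x, y = tok.split(",")
                        coords.append(f"{_fmt(tx(float(x)))},{_fmt(ty(float(y)))}")
                    else:
                        coords.append(tok)
                out.append(
                    f'<path d="{" ".join(coords)}" fill="#eef1f5" '
                    'stroke="#9aa4b0" stroke-width="0.8" fill-rule="evenodd"/>'
                )
    for b in solution.boxes:
        if not b.placed or b.level not in spec.levels_shown:
            continue
        x, y = tx(b.anchor[0]), ty(b.anchor[1])
        out.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" text-anchor="middle" '
            f'dominant-baseline="middle" font-family="monospace" '
            f'font-size="{_fmt(b.font_size * s)}" fill="{spec.color(b.level)}">'
            f"{_escape(b.term)}</text>"
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )
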