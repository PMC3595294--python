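"""Hierarchical, conflict-free label placement across dominance rank levels.

Labels are placed greedily, level by level: rank-1 patch labels first, then
rank-2 labels constrained by the rank-1 boxes, then rank-3 labels constrained
by both, and so forth -- higher-level labels act as exclusion masks for lower
levels, so a level's placement never depends on the levels below it.  Within
a level, patches are processed by descending neuron count (larger regions
label first).

A label anchors at its patch's pole of inaccessibility (the interior point
farthest from the boundary); if the text box does not fit there, up to eight
fallback anchors around the pole are tried before the label is recorded as
unplaced.  Placement requires the box to (a) lie inside the display frame,
(b) intersect its own patch, and (c) avoid every already-placed box.

Text metrics use a fixed-width glyph model (advance = 0.6 x font size per
character) so collision geometry is font-independent and reproducible; a
curved, shape-following baseline is purely a rendering flag and collisions
always use the straight bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .clustering import Patch, PatchSet, dissolve_geometry
from .lattice import HexLattice

__all__ = [
    "SizePolicy",
    "LabelBox",
    "LabelSolution",
    "font_size_for",
    "place_labels",
    "placement_stats",
    "round_half_up",
]

#: glyph advance as a fraction of font size (fixed-width text model)
CHAR_ASPECT = 0.6


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 74.05 -> 74.1), used for printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SizePolicy:
    """Font-size bands per rank level, in lattice units.

    The size of a label grows with the log of its patch's neuron count,
    saturating at ``ref_count`` neurons:

        size(n, level) = lo + (hi - lo) * min(1, log10(max(n, 1)) / log10(ref_count))

    With the default level-1 band (0.5, 2.0) and ref_count 1000 this gives the
    piecewise table n=1 -> 0.5, n=10 -> 1.0, n=100 -> 1.5, n>=1000 -> 2.0.
    Bands shrink with level so lower-rank labels are systematically smaller.
    The bands are expressed in lattice units (hex spacings): at the saturated
    level-1 size a ten-character label spans ~12 hex cells, comfortably inside
    the patches that reach such sizes.
    """

    level_bands: tuple[tuple[int, tuple[float, float]], ...] = (
        (1, (0.5, 2.0)),
        (2, (0.4, 1.4)),
        (3, (0.3, 1.0)),
    )
    default_band: tuple[float, float] = (0.25, 0.8)
    ref_count: int = 1000

    def band(self, level: int) -> tuple[float, float]:
        for lv, b in self.level_bands:
            if lv == level:
                return b
        return self.default_band


@dataclass
class LabelBox:
    term: str
    level: int
    patch_id: int
    anchor: tuple[float, float]
    font_size: float
    box: Polygon | None
    placed: bool
    curved: bool = False


@dataclass
class LabelSolution:
    boxes: list[LabelBox]
    masks: dict[int, object] = field(default_factory=dict)  # level -> geometry

    def placed_boxes(self, level: int | None = None) -> list[LabelBox]:
        return [
            b
            for b in self.boxes
            if b.placed and (level is None or b.level == level)
        ]


def font_size_for(patch: Patch, level: int, policy: SizePolicy | None = None) -> float:
    """Font size in lattice units: grows with patch size, shrinks with level."""
    if patch.n_neurons < 1:
        raise ValueError("empty patch")
    policy = policy or SizePolicy()
    lo, hi = policy.band(level)
    frac = min(1.0, np.log10(max(patch.n_neurons, 1)) / np.log10(policy.ref_count))
    return lo + (hi - lo) * frac


def _text_box(anchor: tuple[float, float], term: str, font_size: float) -> Polygon:
    w = CHAR_ASPECT * font_size * len(term)
    h = font_size
    x, y = anchor
    return box(x - w / 2, y - h / 2, x + w / 2, y + h / 2)


def _pole_of_inaccessibility(poly) -> tuple[float, float]:
    from shapely.ops import polylabel

    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    try:
        p = polylabel(poly, tolerance=0.1)
    except Exception:
        p = poly.representative_point()
    return (p.x, p.y)


def place_labels(
    patchsets: list[PatchSet],
    lattice: HexLattice,
    policy: SizePolicy | None = None,
    frame: tuple[float, float, float, float] | None = None,
) -> LabelSolution:
    """Greedy hierarchical label placement (see module docstring).

    ``frame`` is the display rectangle (xmin, ymin, xmax, ymax); by default
    the lattice bounding box padded by one hexagon.  Deterministic.
    """
    policy = policy or SizePolicy()
    if frame is None:
        xs, ys = lattice.centers[:, 0], lattice.centers[:, 1]
        frame = (xs.min() - 1, ys.min() - 1, xs.max() + 1, ys.max() + 1)
    fx0, fy0, fx1, fy1 = frame
    if fx1 <= fx0 or fy1 <= fy0:
        raise ValueError("empty display frame")
    frame_poly = box(fx0, fy0, fx1, fy1)

    solution = LabelSolution(boxes=[])
    placed_geoms: list[Polygon] = []
    for ps in sorted(patchsets, key=lambda p: p.rank_level):
        level_geoms: list[Polygon] = []
        order = sorted(ps.patches, key=lambda p: (-p.n_neurons, p.patch_id))
        for patch in order:
            term = ps.term_name(patch)
            fs = font_size_for(patch, ps.rank_level, policy)
            poly = dissolve_geometry(patch, lattice)
            pole = _pole_of_inaccessibility(poly)
            minx, miny, maxx, maxy = poly.bounds
            r = 0.25 * max(maxx - minx, maxy - miny)
            candidates = [pole] + [
                (pole[0] + r * dx, pole[1] + r * dy)
                for dx, dy in (
                    (1, 0), (-1, 0), (0, 1), (0, -1),
                    (1, 1), (-1, 1), (1, -1), (-1, -1),
                )
            ]
            placed = False
            chosen_anchor, chosen_box = pole, None
            for anchor in candidates:
                b = _text_box(anchor, term, fs)
                if not frame_poly.contains(b):
                    continue
                if not b.intersects(poly):
                    continue
                if any(b.intersects(g) for g in placed_geoms):
                    continue
                placed = True
                chosen_anchor, chosen_box = anchor, b
                break
            solution.boxes.append(
                LabelBox(
                    term=term,
                    level=ps.rank_level,
                    patch_id=patch.patch_id,
                    anchor=chosen_anchor,
                    font_size=fs,
                    box=chosen_box,
                    placed=placed,
                )
            )
            if placed:
                placed_geoms.append(chosen_box)
                level_geoms.append(chosen_box)
        solution.masks[ps.rank_level] = (
            unary_union(level_geoms) if level_geoms else None
        )
    return solution


def placement_stats(solution: LabelSolution) -> pd.DataFrame:
    """Per-level placed/unplaced counts and percentages (half-up, 1 decimal)."""
    rows = []
    levels = sorted({b.level for b in solution.boxes})
    for lv in levels:
        boxes = [b for b in solution.boxes if b.level == lv]
        placed = sum(b.placed for b in boxes)
        total = len(boxes)
        unplaced = total - placed
        rows.append(
            {
                "level": lv,
                "patch_count": total,
                "placed": placed,
                "unplaced": unplaced,
                "placed_pct": round_half_up(100.0 * placed / total) if total else None,
                "unplaced_pct": round_half_up(100.0 * unplaced / total)
                if total
                else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "level",
            "patch_count",
            "placed",
            "unplaced",
            "placed_pct",
            "unplaced_pct",
        ],
    )
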