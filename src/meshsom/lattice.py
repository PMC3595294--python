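"""Hexagonal neuron lattice: indexing, geometry, adjacency, grid distances.

One convention is fixed and used by every subsystem (training kernel,
patch clustering, rendering) so they can never disagree:

* odd-r horizontal offset layout, pointy-top hexagons, unit spacing between
  adjacent hex centers;
* 0-based row-major linear index, ``i = row * cols + col``;
* grid distance is the Euclidean distance between hex centers (the SOM-PAK
  convention), not a hex step count.

Center coordinates: ``x = col + 0.5 * (row % 2)``, ``y = row * sqrt(3)/2``.
Every adjacent pair of neurons is exactly distance 1 apart.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

__all__ = ["HexLattice", "HEX_AREA"]

_SQRT3 = float(np.sqrt(3.0))
#: circumradius of a unit-spacing pointy-top hexagon
_R = 1.0 / _SQRT3
#: area of one hexagon cell (unit spacing)
HEX_AREA = _SQRT3 / 2.0

# Pointy-top hexagon vertex offsets from the center, counter-clockwise.
_VERTS = np.array(
    [
        (0.0, _R),
        (-0.5, _R / 2),
        (-0.5, -_R / 2),
        (0.0, -_R),
        (0.5, -_R / 2),
        (0.5, _R / 2),
    ]
)

# Odd-r offset neighbor deltas (drow, dcol), keyed by row parity.
_NEIGHBOR_OFFSETS = {
    0: ((0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)),
    1: ((0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)),
}


class HexLattice:
    """``rows x cols`` hexagonal lattice in odd-r offset layout."""

    def __init__(self, rows: int, cols: int):
        if rows < 1 or cols < 1:
            raise ValueError("rows and cols must be >= 1")
        self.rows = rows
        self.cols = cols
        self.layout = "odd-r"
        r, c = np.divmod(np.arange(rows * cols), cols)
        self.centers = np.column_stack(
            [c + 0.5 * (r % 2), r * (_SQRT3 / 2.0)]
        ).astype(np.float64)

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def _check(self, i: int) -> None:
        if not 0 <= i < self.n_neurons:
            raise IndexError(f"neuron index {i} out of range [0, {self.n_neurons})")

    def rowcol(self, i: int) -> tuple[int, int]:
        self._check(i)
        return divmod(i, self.cols)

    def grid_distance(self, a: int, b: int) -> float:
        """Euclidean distance between hex centers; 0 iff ``a == b``."""
        self._check(a)
        self._check(b)
        dx = self.centers[a] - self.centers[b]
        return float(np.hypot(dx[0], dx[1]))

    def distances_from(self, i: int) -> np.ndarray:
        """Grid distance from neuron ``i`` to every neuron (vectorized)."""
        self._check(i)
        d = self.centers - self.centers[i]
        return np.hypot(d[:, 0], d[:, 1])

    def neighbors(self, i: int) -> list[int]:
        """Lattice-adjacent neurons (2-6 of them), ascending linear index."""
        row, col = self.rowcol(i)
        out = []
        for dr, dc in _NEIGHBOR_OFFSETS[row % 2]:
            r, c = row + dr, col + dc
            if 0 <= r < self.rows and 0 <= c < self.cols:
                out.append(r * self.cols + c)
        return sorted(out)

    def adjacency_pairs(self) -> np.ndarray:
        """All adjacent pairs ``(i, j)`` with ``i < j``, shape (E, 2)."""
        pairs = []
        for i in range(self.n_neurons):
            for j in self.neighbors(i):
                if j > i:
                    pairs.append((i, j))
        return np.array(pairs, dtype=np.int64).reshape(-1, 2)

    def hex_polygon(self, i: int) -> Polygon:
        """Pointy-top hexagon cell of neuron ``i``.

        Vertex coordinates are snapped to 1e-9 so adjacent cells share edges
        with exactly identical coordinates, which keeps polygon dissolution
        numerically clean.
        """
        self._check(i)
        verts = np.round(self.centers[i] + _VERTS, 9)
        return Polygon(verts)

    def metadata(self) -> dict:
        return {"rows": self.rows, "cols": self.cols, "layout": self.layout}

    @classmethod
    def from_metadata(cls, meta: dict) -> "HexLattice":
        if meta.get("layout", "odd-r") != "odd-r":
            raise ValueError(f"unsupported lattice layout: {meta.get('layout')!r}")
        return cls(int(meta["rows"]), int(meta["cols"]))
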