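"""Hexagonal lattice of element locations.

Every stimulus is built on a hexagonally close-packed grid of line-segment
centers covering a square canvas (default 384 px).  Horizontal center-to-center
spacing is 16 px, vertical spacing 14 px, with alternate rows shifted by half
the horizontal spacing — the classic arrangement for contour-integration
displays, where the spacing:element-size ratio is about 2:1.

Centers keep a margin of ``segment_len_px // 2`` pixels from every canvas edge
so that a segment centered on any location is rendered without clipping.  For
the default geometry this yields 27 rows alternating 24 and 23 columns, i.e.
635 locations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["GridSpec", "GridLocation", "HexGrid", "build_grid", "neighbors"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the element lattice.

    Parameters
    ----------
    image_size_px:
        Side of the square canvas, pixels.
    dx_px, dy_px:
        Horizontal / vertical center-to-center spacing.
    row_offset_px:
        Horizontal shift applied to odd rows (half of ``dx_px`` by default).
    segment_len_px:
        Number of lit pixels per line segment; odd, so a segment centers on
        a pixel.
    """

    image_size_px: int = 384
    dx_px: int = 16
    dy_px: int = 14
    row_offset_px: int = 8
    segment_len_px: int = 7

    def __post_init__(self) -> None:
        if self.image_size_px < 1:
            raise ValueError("image_size_px must be >= 1")
        if self.dx_px < 1 or self.dy_px < 1:
            raise ValueError("spacings must be >= 1")
        if self.segment_len_px % 2 != 1 or self.segment_len_px < 1:
            raise ValueError("segment_len_px must be a positive odd integer")
        if not 0 <= self.row_offset_px < self.dx_px:
            raise ValueError("row_offset_px must lie in [0, dx_px)")

    @property
    def margin_px(self) -> int:
        """Clearance kept between segment centers and the canvas edge."""
        return self.segment_len_px // 2


@dataclass(frozen=True, order=True)
class GridLocation:
    """One lattice site: row/col index plus its pixel center (origin top-left,
    y increasing downward)."""

    row: int
    col: int
    x_px: int
    y_px: int


def _axis_layout(size: int, spacing: int, margin: int) -> tuple[int, int]:
    """Return (count, start) of evenly spaced centers along one axis,
    centered in [margin, size-1-margin]; remainder margin goes to the far
    side.  Degenerates to a single center when the usable span is empty."""
    usable = size - 1 - 2 * margin
    if usable < 0:
        return 1, size // 2
    n = usable // spacing + 1
    start = margin + (usable - (n - 1) * spacing) // 2
    return n, start


class HexGrid:
    """The ordered set of grid locations plus their adjacency structure."""

    def __init__(self, spec: GridSpec | None = None):
        self.spec = spec or GridSpec()
        self.locations: list[GridLocation] = self._enumerate(self.spec)
        self._index = {(loc.x_px, loc.y_px): i for i, loc in enumerate(self.locations)}
        self._by_rowcol = {(loc.row, loc.col): loc for loc in self.locations}

    @staticmethod
    def _enumerate(spec: GridSpec) -> list[GridLocation]:
        m = spec.margin_px
        n_rows, y0 = _axis_layout(spec.image_size_px, spec.dy_px, m)
        _, x0 = _axis_layout(spec.image_size_px, spec.dx_px, m)
        hi = spec.image_size_px - 1 - m
        if hi < 0:  # tiny canvas: single centered location
            hi = spec.image_size_px - 1
        locs: list[GridLocation] = []
        for r in range(n_rows):
            y = y0 + r * spec.dy_px
            x = x0 + (r % 2) * spec.row_offset_px
            c = 0
            while x <= hi:
                locs.append(GridLocation(r, c, x, y))
                c += 1
                x += spec.dx_px
            if c == 0:  # offset pushed the row past the margin; keep one
                locs.append(GridLocation(r, 0, x0, y))
        return locs

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self):
        return iter(self.locations)

    def __contains__(self, loc: GridLocation) -> bool:
        return self._by_rowcol.get((loc.row, loc.col)) == loc

    def at(self, row: int, col: int) -> GridLocation:
        return self._by_rowcol[(row, col)]

    @cached_property
    def centers(self) -> np.ndarray:
        """(n, 2) array of (x, y) pixel centers, row-major order."""
        return np.array([(l.x_px, l.y_px) for l in self.locations], dtype=float)

    @cached_property
    def _adjacency(self) -> list[set[int]]:
        # Geometric neighborhood: everything within 1.05 * dx of a center.
        # For the 16/14 spacing this captures the two same-row and four
        # adjacent-row nearest sites (diagonal distance sqrt(8^2+14^2) ~ 16.1)
        # and nothing else.
        radius = 1.05 * self.spec.dx_px
        tree = cKDTree(self.centers)
        pairs = tree.query_pairs(radius)
        adj: list[set[int]] = [set() for _ in self.locations]
        for i, j in pairs:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def neighbors(self, loc: GridLocation) -> set[GridLocation]:
        """Hexagonal neighborhood of *loc* (6 sites for interior locations)."""
        if loc not in self:
            raise ValueError(f"location {loc} is not on this grid")
        i = self._index[(loc.x_px, loc.y_px)]
        return {self.locations[j] for j in self._adjacency[i]}

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        """All unordered adjacent index pairs (i < j), each exactly once."""
        out = []
        for i, nbrs in enumerate(self._adjacency):
            out.extend((i, j) for j in nbrs if j > i)
        return out

    def to_csv(self, path=None) -> str | None:
        buf = io.StringIO()
        buf.write("row,col,x_px,y_px\n")
        for l in self.locations:
            buf.write(f"{l.row},{l.col},{l.x_px},{l.y_px}\n")
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def build_grid(spec: GridSpec | None = None) -> list[GridLocation]:
    """Enumerate the lattice row-major; the default spec yields 635 sites."""
    return HexGrid(spec).locations


def neighbors(grid: HexGrid, loc: GridLocation) -> set[GridLocation]:
    return grid.neighbors(loc)
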