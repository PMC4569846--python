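"""Nested equal-area grids on a planar rectangle.

The world is a flat ``width x height`` rectangle of unit-square base cells,
standing in for an equal-area grid (base cell ~ the 110-km cell of global
analyses). Coarser grains double the cell edge, so grain level ``g`` has
cells of edge ``2**(g-1)`` base-cell widths and every coarse cell contains
exactly four children at the next finer grain.

Conventions (fixed, relied on everywhere downstream):

* cell ids are row-major, 0-based, origin at the lower-left corner;
* a cell at grain ``g`` covers the half-open square
  ``[x0, x0 + 2**(g-1)) x [y0, y0 + 2**(g-1))`` in world units, so a point
  on an interior boundary belongs to the higher-indexed cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSystem", "build_grid"]


@dataclass(frozen=True)
class GridSystem:
    """A stack of nested grids over a ``width x height`` rectangle.

    Grain levels run from 1 (base) to ``n_grains``; the cell edge at level
    ``g`` is ``2**(g-1)`` base-cell widths.
    """

    width: int
    height: int
    n_grains: int
    _parent_maps: dict[tuple[int, int], np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def grains(self) -> range:
        return range(1, self.n_grains + 1)

    def cell_edge(self, grain: int) -> int:
        """Cell edge length at ``grain``, in base-cell widths."""
        self._check_grain(grain)
        return 2 ** (grain - 1)

    def shape(self, grain: int) -> tuple[int, int]:
        """(n_cols, n_rows) at ``grain``."""
        f = self.cell_edge(grain)
        return self.width // f, self.height // f

    def n_cells(self, grain: int) -> int:
        w, h = self.shape(grain)
        return w * h

    def cell_id(self, ix: np.ndarray | int, iy: np.ndarray | int, grain: int) -> np.ndarray | int:
        w, _ = self.shape(grain)
        return np.asarray(iy) * w + np.asarray(ix) if isinstance(ix, np.ndarray) else iy * w + ix

    def cell_xy(self, cell: np.ndarray | int, grain: int):
        """Column/row indices of cells at ``grain``."""
        w, _ = self.shape(grain)
        c = np.asarray(cell)
        return c % w, c // w

    def cell_of_point(self, x: np.ndarray, y: np.ndarray, grain: int = 1) -> np.ndarray:
        """Cell ids of points; -1 for points outside the extent.

        Cells are half-open, so a point on an interior boundary goes to the
        higher-indexed cell; points on the outer right/top edge are outside.
        """
        f = self.cell_edge(grain)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = (x >= 0) & (x < self.width) & (y >= 0) & (y < self.height)
        ix = np.floor(x / f).astype(int)
        iy = np.floor(y / f).astype(int)
        w, _ = self.shape(grain)
        out = iy * w + ix
        return np.where(inside, out, -1)

    def parents(self, from_grain: int, to_grain: int) -> np.ndarray:
        """Vector mapping each cell at ``from_grain`` to its ancestor at ``to_grain``."""
        self._check_grain(from_grain)
        self._check_grain(to_grain)
        if to_grain < from_grain:
            raise ValueError("to_grain must be coarser (>=) than from_grain")
        key = (from_grain, to_grain)
        if key not in self._parent_maps:
            wf, hf = self.shape(from_grain)
            wt, _ = self.shape(to_grain)
            f = 2 ** (to_grain - from_grain)
            ids = np.arange(wf * hf)
            ix, iy = ids % wf, ids // wf
            self._parent_maps[key] = (iy // f) * wt + (ix // f)
        return self._parent_maps[key]

    def children(self, cell: int, grain: int, child_grain: int) -> np.ndarray:
        """Ids of cells at ``child_grain`` contained in ``cell`` at ``grain``."""
        pm = self.parents(child_grain, grain)
        return np.flatnonzero(pm == cell)

    def centroids(self, grain: int) -> np.ndarray:
        """(n_cells, 2) array of cell centroids in world units."""
        f = self.cell_edge(grain)
        w, h = self.shape(grain)
        ids = np.arange(w * h)
        ix, iy = ids % w, ids // w
        return np.column_stack([(ix + 0.5) * f, (iy + 0.5) * f]).astype(float)

    def cell_polygon(self, cell: int, grain: int) -> list[list[float]]:
        """Closed ring of the cell's square, counter-clockwise, world units."""
        f = self.cell_edge(grain)
        ix, iy = self.cell_xy(cell, grain)
        x0, y0 = int(ix) * f, int(iy) * f
        return [[x0, y0], [x0 + f, y0], [x0 + f, y0 + f], [x0, y0 + f], [x0, y0]]

    def _check_grain(self, grain: int) -> None:
        if not 1 <= grain <= self.n_grains:
            raise ValueError(f"grain {grain} outside 1..{self.n_grains}")


def build_grid(width: int, height: int, n_grains: int = 4) -> GridSystem:
    """Build a nested grid system.

    Parameters
    ----------
    width, height
        Extent of the base grid in base cells. Both must be divisible by
        ``2**(n_grains - 1)`` so every coarsening tiles exactly.
    n_grains
        Number of nested grain levels (default 4, mirroring grids whose
        edges double from the base grain three times).
    """
    if width <= 0 or height <= 0:
        raise ValueError("grid extent must be positive")
    if n_grains < 1:
        raise ValueError("n_grains must be >= 1")
    divisor = 2 ** (n_grains - 1)
    if width % divisor or height % divisor:
        raise ValueError(
            f"extent {width}x{height} not divisible by {divisor} "
            f"(required for {n_grains} nested grains)"
        )
    return GridSystem(width=width, height=height, n_grains=n_grains)
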