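"""Planar grid geometry shared by elevation grids and reflectance stacks.

Conventions (asserted throughout the package):

* coordinates are planar meters, ``x`` east and ``y`` north;
* ``values[row, col]`` with row 0 the *southernmost* row (row index grows
  northward, column index grows eastward);
* ``origin`` is the lower-left corner of cell ``(0, 0)``;
* a cell is sampled at its center, ``origin + (index + 0.5) * cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .errors import InvalidParameterError

__all__ = ["GridGeometry", "cells_in_polygon"]


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular grid: cell size, lower-left origin and shape.

    Parameters
    ----------
    cell_size
        Edge length of the square cells, meters. Must be positive.
    origin
        ``(x0, y0)`` of the lower-left corner of cell ``(0, 0)``, meters.
    shape
        ``(n_rows, n_cols)``.
    """

    cell_size: float
    origin: tuple[float, float]
    shape: tuple[int, int]

    def __post_init__(self):
        if self.cell_size <= 0:
            raise InvalidParameterError(f"cell_size must be > 0, got {self.cell_size}")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise InvalidParameterError(f"grid shape must be >= 1x1, got {self.shape}")

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """``(xmin, ymin, xmax, ymax)`` of the full grid footprint."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    @property
    def x_centers(self) -> np.ndarray:
        """Cell-center x coordinates, one per column."""
        x0 = self.origin[0]
        return x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        """Cell-center y coordinates, one per row."""
        y0 = self.origin[1]
        return y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, x, y):
        """Map world coordinates to ``(row, col)`` indices (floor rule)."""
        x = np.asarray(x)
        y = np.asarray(y)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(np.int64)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(np.int64)
        return row, col

    def center_of(self, row, col):
        """Map ``(row, col)`` indices to world cell-center coordinates."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (row + 0.5) * self.cell_size
        return x, y

    def contains_cell(self, row, col):
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def matches(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        """True if two geometries coincide within ``tol`` meters."""
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )


def cells_in_polygon(geom: GridGeometry, polygon: shapely.Polygon):
    """Indices ``(rows, cols)`` of cells whose *centers* fall inside ``polygon``.

    Only the polygon's bounding box is scanned, so the cost is proportional
    to the plant footprint, not the whole field.
    """
    xmin, ymin, xmax, ymax = polygon.bounds
    r0, c0 = geom.cell_of(xmin, ymin)
    r1, c1 = geom.cell_of(xmax, ymax)
    r0 = int(np.clip(r0, 0, geom.n_rows - 1))
    r1 = int(np.clip(r1, 0, geom.n_rows - 1))
    c0 = int(np.clip(c0, 0, geom.n_cols - 1))
    c1 = int(np.clip(c1, 0, geom.n_cols - 1))
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    cc, rr = np.meshgrid(cols, rows)
    x, y = geom.center_of(rr.ravel(), cc.ravel())
    inside = shapely.contains_xy(polygon, x, y)
    return rr.ravel()[inside], cc.ravel()[inside]
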