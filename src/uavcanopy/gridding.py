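"""Point-cloud gridding and the canopy height model (CHM).

A growing-season surface scan is rasterized into a digital surface model
(DSM) and a post-harvest bare-ground scan into a digital terrain model
(DTM), both at 1 x 1 cm by default; the canopy height model is their
difference, CHM = DSM - DTM, with negative cells clamped to zero (negative
differences are positioning error, not vegetation).

Per-cell aggregation uses the maximum return elevation: with a single-echo
scanner the canopy top drives plant height, and a max surface is the
standard single-echo DSM. Cells without returns are filled from the nearest
populated cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, EmptyCloudError, InvalidParameterError
from .geometry import GridGeometry

__all__ = ["PointCloud", "ElevationGrid", "rasterize", "fill_empty", "compute_chm"]


@dataclass
class PointCloud:
    """A LiDAR point cloud: an ``(N, 3)`` array of x east / y north / z up (m).

    ``role`` tags the scan: ``"surface_scan"`` (growing season, ground +
    canopy) or ``"ground_scan"`` (bare ground after harvest).
    """

    xyz: np.ndarray
    role: str = "surface_scan"

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise InvalidParameterError(f"xyz must be (N, 3), got {self.xyz.shape}")
        if self.role not in ("surface_scan", "ground_scan"):
            raise InvalidParameterError(f"unknown cloud role {self.role!r}")
        if self.xyz.size and not np.all(np.isfinite(self.xyz)):
            raise InvalidParameterError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return self.xyz.shape[0]


@dataclass
class ElevationGrid:
    """A gridded elevation or height surface (DSM, DTM or CHM role)."""

    values: np.ndarray
    geom: GridGeometry
    role: str = "DSM"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geom.shape:
            raise AlignmentError(
                f"values shape {self.values.shape} != geometry shape {self.geom.shape}"
            )
        if self.role not in ("DSM", "DTM", "CHM"):
            raise InvalidParameterError(f"unknown grid role {self.role!r}")

    @property
    def cell_size(self) -> float:
        return self.geom.cell_size


def rasterize(
    cloud: PointCloud,
    cell_size: float,
    extent: tuple[float, float, float, float],
    fill: bool = True,
    role: str | None = None,
) -> ElevationGrid:
    """Grid a point cloud over ``extent`` keeping the max z per cell.

    Parameters
    ----------
    cloud
        Non-empty point cloud. Points outside ``extent`` are ignored.
    cell_size
        Grid resolution in meters (default pipeline value: 0.01).
    extent
        ``(xmin, ymin, xmax, ymax)``; the grid covers it exactly (the last
        row/column may overhang by less than one cell).
    fill
        If True (default), cells without points are filled from the nearest
        populated cell; otherwise they are NaN.

    Returns
    -------
    ElevationGrid with role inferred from the cloud role unless overridden.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("cannot rasterize an empty point cloud")
    if cell_size <= 0:
        raise InvalidParameterError(f"cell_size must be > 0, got {cell_size}")
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise InvalidParameterError(f"extent has zero area: {extent}")

    n_cols = int(np.ceil((xmax - xmin) / cell_size - 1e-9))
    n_rows = int(np.ceil((ymax - ymin) / cell_size - 1e-9))
    geom = GridGeometry(cell_size=cell_size, origin=(xmin, ymin), shape=(n_rows, n_cols))

    x, y, z = cloud.xyz.T
    row, col = geom.cell_of(x, y)
    ok = geom.contains_cell(row, col)
    if not np.any(ok):
        raise EmptyCloudError("no points fall inside the requested extent")

    values = np.full((n_rows, n_cols), -np.inf)
    np.maximum.at(values, (row[ok], col[ok]), z[ok])
    values[np.isinf(values)] = np.nan

    grid = ElevationGrid(
        values,
        geom,
        role=role or ("DTM" if cloud.role == "ground_scan" else "DSM"),
    )
    return fill_empty(grid) if fill else grid


def fill_empty(grid: ElevationGrid) -> ElevationGrid:
    """Replace NaN cells with the value of the nearest populated cell."""
    missing = np.isnan(grid.values)
    if not missing.any():
        return grid
    if missing.all():
        raise EmptyCloudError("grid has no populated cells to fill from")
    # EDT against the populated set gives, per empty cell, the indices of
    # its nearest populated cell (deterministic tie-break).
    idx = ndimage.distance_transform_edt(missing, return_distances=False, return_indices=True)
    filled = grid.values[tuple(idx)]
    return ElevationGrid(filled, grid.geom, role=grid.role)


def compute_chm(dsm: ElevationGrid, dtm: ElevationGrid) -> ElevationGrid:
    """Canopy height model: CHM = DSM - DTM, clamped at zero.

    Raises :class:`AlignmentError` unless the two grids share cell size,
    origin and shape.
    """
    if not dsm.geom.matches(dtm.geom):
        raise AlignmentError(
            f"DSM geometry {dsm.geom} does not match DTM geometry {dtm.geom}"
        )
    chm = dsm.values - dtm.values
    np.maximum(chm, 0.0, out=chm)
    return ElevationGrid(chm, dsm.geom, role="CHM")
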