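"""Per-plant band reflectance means and spectral vegetation indices.

The five bands follow the multispectral camera's layout: blue (475 nm),
green (560 nm), red (668 nm), red edge (717 nm) and near infrared
(842 nm), all as absolute reflectance in (0, 1).

Indices are computed *after* averaging reflectance over the plant polygon
(mean-then-index); soil pixels visible through canopy gaps inside the
polygon are included in the mean, a documented bias source. A per-pixel
(index-then-mean) alternative is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .canopy import CanopyPolygon
from .errors import InvalidParameterError, InvalidPolygonError, NumericDomainError
from .geometry import GridGeometry, cells_in_polygon

__all__ = [
    "BANDS",
    "SI_KINDS",
    "RasterStack",
    "BandReflectance",
    "mean_band_reflectance",
    "compute_index",
    "index_map",
]

BANDS = ("blue", "green", "red", "rededge", "nir")
SI_KINDS = ("RVI", "NDVI", "EVI", "NDRE")


@dataclass
class RasterStack:
    """A 5-band reflectance raster: ``values`` of shape (5, n_rows, n_cols)
    in band order ``BANDS``, sharing the grid conventions of
    :class:`~uavcanopy.geometry.GridGeometry`."""

    values: np.ndarray
    geom: GridGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(BANDS), *self.geom.shape):
            raise InvalidParameterError(
                f"raster shape {self.values.shape} != (5, {self.geom.shape})"
            )

    def band(self, name: str) -> np.ndarray:
        return self.values[BANDS.index(name)]


@dataclass
class BandReflectance:
    """Mean reflectance per band for one plant; all values must be > 0
    (zero red reflectance would make RVI infinite)."""

    blue: float
    green: float
    red: float
    rededge: float
    nir: float

    def __post_init__(self):
        for name in BANDS:
            v = getattr(self, name)
            if not np.all(np.asarray(v) > 0):
                raise InvalidParameterError(f"reflectance {name} must be > 0, got {v}")


def mean_band_reflectance(raster: RasterStack, polygon: CanopyPolygon) -> BandReflectance:
    """Arithmetic mean reflectance per band over pixels whose centers fall
    inside the plant polygon."""
    rows, cols = cells_in_polygon(raster.geom, polygon.shapely())
    if rows.size == 0:
        raise InvalidPolygonError(
            f"polygon of plant {polygon.plant_id} covers no pixel centers"
        )
    means = raster.values[:, rows, cols].mean(axis=1)
    return BandReflectance(*(float(v) for v in means))


def _evi(nir, red, blue):
    denom = nir + 6.0 * red - 7.5 * blue + 1.0
    if np.any(np.asarray(denom) <= 0):
        raise NumericDomainError(f"EVI denominator <= 0 (value {denom})")
    return 2.5 * (nir - red) / denom


def compute_index(bands: BandReflectance, kind: str):
    """One spectral index from band reflectances.

    RVI  = R_nir / R_red
    NDVI = (R_nir - R_red) / (R_nir + R_red)
    EVI  = 2.5 (R_nir - R_red) / (R_nir + 6 R_red - 7.5 R_blue + 1)
    NDRE = (R_nir - R_rededge) / (R_nir + R_rededge)
    """
    nir, red, blue, rededge = bands.nir, bands.red, bands.blue, bands.rededge
    if kind == "RVI":
        return nir / red
    if kind == "NDVI":
        return (nir - red) / (nir + red)
    if kind == "EVI":
        return _evi(nir, red, blue)
    if kind == "NDRE":
        return (nir - rededge) / (nir + rededge)
    raise InvalidParameterError(f"unknown spectral index {kind!r}; choose from {SI_KINDS}")


def index_map(raster: RasterStack, kind: str) -> np.ndarray:
    """Per-pixel index image (the index-then-mean sensitivity route)."""
    nir, red = raster.band("nir"), raster.band("red")
    if kind == "RVI":
        return nir / red
    if kind == "NDVI":
        return (nir - red) / (nir + red)
    if kind == "EVI":
        return _evi(nir, red, raster.band("blue"))
    if kind == "NDRE":
        rededge = raster.band("rededge")
        return (nir - rededge) / (nir + rededge)
    raise InvalidParameterError(f"unknown spectral index {kind!r}; choose from {SI_KINDS}")
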