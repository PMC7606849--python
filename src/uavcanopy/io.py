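"""File adapters: CSV point clouds and tables, multiband TIFF rasters with a
JSON georeferencing sidecar, and GeoJSON polygons.

Write-then-read round-trips reproduce coordinates to format precision
(text floats are written with ``repr``-level precision; TIFF stores
float64 losslessly). CSV schemas:

* point cloud: columns ``x,y,z`` (meters);
* layout: ``plant_id,genotype_id,n_treatment,center_x,center_y``;
* phenotypes: ``plant_id,cp,ca,ch_max,ch_mean,status`` plus optional band
  means (``r_blue`` ...) and index columns;
* manual: ``plant_id,manual_height,manual_perimeter,fresh_biomass,
  dry_to_fresh_ratio,dry_biomass``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .canopy import CanopyPolygon
from .errors import MissingInputError, SchemaError
from .geometry import GridGeometry
from .gridding import ElevationGrid, PointCloud
from .spectral import BANDS, RasterStack

__all__ = [
    "write_cloud_csv",
    "read_cloud_csv",
    "write_grid_tiff",
    "read_grid_tiff",
    "write_raster_tiff",
    "read_raster_tiff",
    "write_polygons_geojson",
    "read_polygons_geojson",
    "read_table",
]


def _require(path) -> Path:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"input file does not exist: {path}")
    return path


def write_cloud_csv(cloud: PointCloud, path) -> Path:
    path = Path(path)
    pd.DataFrame(cloud.xyz, columns=["x", "y", "z"]).to_csv(path, index=False)
    return path


def read_cloud_csv(path, role: str = "surface_scan") -> PointCloud:
    path = _require(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface parse position to the user
        raise SchemaError(f"cannot parse point cloud CSV {path}: {exc}") from exc
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise SchemaError(f"point cloud {path} is missing columns {sorted(missing)}")
    return PointCloud(df[["x", "y", "z"]].to_numpy(dtype=float), role=role)


def _write_sidecar(path: Path, geom: GridGeometry, extra: dict) -> None:
    meta = {
        "cell_size": geom.cell_size,
        "origin": list(geom.origin),
        "shape": list(geom.shape),
        **extra,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    sidecar = _require(path.with_suffix(path.suffix + ".json"))
    return json.loads(sidecar.read_text())


def write_grid_tiff(grid: ElevationGrid, path) -> Path:
    """Single-band float TIFF plus ``<name>.tif.json`` georeferencing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, grid.values.astype(np.float64))
    _write_sidecar(path, grid.geom, {"role": grid.role})
    return path


def read_grid_tiff(path) -> ElevationGrid:
    path = _require(path)
    meta = _read_sidecar(path)
    values = tifffile.imread(path)
    geom = GridGeometry(meta["cell_size"], tuple(meta["origin"]), tuple(meta["shape"]))
    return ElevationGrid(values, geom, role=meta.get("role", "DSM"))


def write_raster_tiff(raster: RasterStack, path) -> Path:
    """5-band float TIFF (band axis first) with georeferencing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, raster.values.astype(np.float64))
    _write_sidecar(path, raster.geom, {"bands": list(BANDS)})
    return path


def read_raster_tiff(path) -> RasterStack:
    path = _require(path)
    meta = _read_sidecar(path)
    values = tifffile.imread(path)
    geom = GridGeometry(meta["cell_size"], tuple(meta["origin"]), tuple(meta["shape"]))
    return RasterStack(values, geom)


def write_polygons_geojson(polygons, path) -> Path:
    """Canopy polygons as a GeoJSON FeatureCollection (planar meters)."""
    path = Path(path)
    features = []
    for poly in polygons:
        ring = [[float(x), float(y)] for x, y in poly.vertices]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "plant_id": int(poly.plant_id),
                    "cp": float(poly.cp),
                    "ca": float(poly.ca),
                },
            }
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))
    return path


def read_polygons_geojson(path) -> list[CanopyPolygon]:
    path = _require(path)
    try:
        data = json.loads(path.read_text())
        polygons = []
        for feat in data["features"]:
            ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)[:-1]
            props = feat["properties"]
            polygons.append(
                CanopyPolygon(
                    plant_id=props["plant_id"],
                    vertices=ring,
                    cp=props["cp"],
                    ca=props["ca"],
                )
            )
    except (KeyError, IndexError, ValueError, TypeError) as exc:
        raise SchemaError(f"malformed GeoJSON {path}: {exc}") from exc
    return polygons


def read_table(path, required: set[str]) -> pd.DataFrame:
    """CSV table with schema validation; missing columns raise SchemaError."""
    path = _require(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise SchemaError(f"cannot parse table {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"table {path} is missing columns {sorted(missing)}")
    return df
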