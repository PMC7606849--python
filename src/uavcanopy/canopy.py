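"""Per-plant canopy boundary extraction and phenotyping parameters.

The chain mirrors standard individual-plant CHM processing:

1. ``smooth_chm`` — a 5 x 5 order-statistic (25th percentile) filter fills
   within-canopy gaps so each plant becomes one connected patch;
2. ``binarize`` — height >= 10 cm marks canopy (lower values are treated as
   positioning error / ground relief, not vegetation);
3. ``trace_boundary`` — Moore-neighbor tracing of the exterior boundary of
   the 8-connected component at the plant center;
4. ``radial_scan`` — scanning lines of 2 m cast every 30 degrees from the
   center keep, per line, the farthest boundary intersection, simplifying
   the traced outline to at most 12 vertices;
5. ``polygon_metrics`` — canopy perimeter CP and area CA of the closed
   simplified polygon;
6. ``extract_phenotypes`` — CH_max and CH_mean read from the *unsmoothed*
   CHM over cells inside the polygon (the percentile filter biases heights
   low, so it serves boundary detection only).

Plants whose boundary meets fewer than three scanning lines are flagged
degenerate: CP and CA are undefined for them and they are excluded from
model fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage

from .errors import (
    DegenerateCanopyError,
    EmptyCanopyError,
    InvalidParameterError,
    InvalidPolygonError,
)
from .geometry import GridGeometry, cells_in_polygon
from .gridding import ElevationGrid

__all__ = [
    "CanopyMask",
    "CanopyPolygon",
    "PhenotypeRecord",
    "smooth_chm",
    "binarize",
    "trace_boundary",
    "radial_scan",
    "polygon_metrics",
    "extract_phenotypes",
    "extract_plant",
]


@dataclass
class CanopyMask:
    """Binary canopy map aligned to the CHM it came from."""

    values: np.ndarray
    geom: GridGeometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.geom.shape:
            raise InvalidParameterError(
                f"mask shape {self.values.shape} != geometry shape {self.geom.shape}"
            )


@dataclass
class CanopyPolygon:
    """Simplified per-plant canopy outline from the radial scan.

    ``vertices`` are angle-ordered world coordinates (3-12 points, closed
    implicitly); ``cp`` is the closed-polygon perimeter in meters and ``ca``
    the shoelace area in m^2.
    """

    plant_id: int
    vertices: np.ndarray
    cp: float
    ca: float

    def shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


@dataclass
class PhenotypeRecord:
    """Structural phenotype of one plant."""

    plant_id: int
    cp: float
    ca: float
    ch_max: float
    ch_mean: float
    status: str = "ok"


def smooth_chm(chm: ElevationGrid, window: int = 5, q: float = 0.25) -> ElevationGrid:
    """Order-statistic filter: each cell becomes the k-th smallest value in
    its ``window x window`` neighborhood, k = ceil(q * window^2).

    With the defaults (5, 0.25) this is the 7th order statistic of 25 — the
    25th-percentile rank filter used to fuse leaf-gap fragments of a plant
    into one component. Edges use reflect padding.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError(f"window must be odd and >= 3, got {window}")
    if not 0.0 < q < 1.0:
        raise InvalidParameterError(f"q must be in (0, 1), got {q}")
    k = math.ceil(q * window * window)  # 1-based order statistic
    smoothed = ndimage.rank_filter(chm.values, rank=k - 1, size=window, mode="reflect")
    return ElevationGrid(smoothed, chm.geom, role=chm.role)


def binarize(chm: ElevationGrid, threshold: float = 0.10) -> CanopyMask:
    """Canopy mask: height >= ``threshold`` (meters). The threshold itself
    counts as canopy; only values *below* it are invalid."""
    if threshold < 0:
        raise InvalidParameterError(f"threshold must be >= 0, got {threshold}")
    return CanopyMask(chm.values >= threshold, chm.geom)


# Moore neighborhood in (row, col) offsets, clockwise when viewed with the
# row axis pointing down (the order, not the viewing direction, matters).
_NEI = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_NEI_INDEX = {off: i for i, off in enumerate(_NEI)}


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Ordered exterior boundary pixels of a single 8-connected component.

    Moore-neighbor tracing with Jacob's stopping criterion, as in the
    classic binary-image boundary-following algorithms. Returns an (M, 2)
    array of (row, col); the polyline is closed implicitly.
    """
    pad = np.pad(mask, 1)
    rr, cc = np.nonzero(pad)
    start = (int(rr[0]), int(cc[0]))  # first foreground pixel in row-major order
    contour = [start]
    if rr.size == 1:
        return np.asarray(contour) - 1
    backtrack = (start[0], start[1] - 1)  # west of start is background by construction
    cur = start
    second = None
    for _ in range(4 * mask.size + 8):
        i0 = _NEI_INDEX[(backtrack[0] - cur[0], backtrack[1] - cur[1])]
        nxt = None
        for k in range(1, 9):
            off = _NEI[(i0 + k) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if pad[cand[0], cand[1]]:
                nxt = cand
                break
            backtrack = cand
        if nxt is None:  # isolated pixel
            break
        if cur == start and second is not None and nxt == second:
            break  # re-entered the start with the same exit: loop closed
        if second is None:
            second = nxt
        contour.append(nxt)
        cur = nxt
    if len(contour) > 1 and contour[-1] == start:
        contour.pop()
    return np.asarray(contour) - 1  # remove padding offset


def trace_boundary(
    mask: CanopyMask,
    center: tuple[float, float],
    search_radius: float = 2.0,
    plant_id=None,
) -> np.ndarray:
    """Exterior boundary of the canopy component at ``center``.

    The mask is windowed to ``search_radius`` meters around the center.
    The 8-connected component containing the center wins; if the center
    cell is background, the component of the nearest foreground cell is
    used instead. Returns an (M, 2) array of world (x, y) cell-center
    coordinates, ordered along the boundary (closed implicitly).

    Raises :class:`EmptyCanopyError` when no foreground exists in the
    search window.
    """
    geom = mask.geom
    r_c, c_c = geom.cell_of(*center)
    pad_cells = int(np.ceil(search_radius / geom.cell_size))
    r0 = max(int(r_c) - pad_cells, 0)
    r1 = min(int(r_c) + pad_cells + 1, geom.n_rows)
    c0 = max(int(c_c) - pad_cells, 0)
    c1 = min(int(c_c) + pad_cells + 1, geom.n_cols)
    if r1 <= r0 or c1 <= c0:
        raise EmptyCanopyError(
            f"plant center {center} lies outside the grid", plant_id=plant_id
        )
    window = mask.values[r0:r1, c0:c1]
    if not window.any():
        raise EmptyCanopyError(
            f"no canopy cells within {search_radius} m of {center}", plant_id=plant_id
        )
    labels, _ = ndimage.label(window, structure=np.ones((3, 3), dtype=int))
    rc, cc = int(r_c) - r0, int(c_c) - c0
    if 0 <= rc < window.shape[0] and 0 <= cc < window.shape[1] and labels[rc, cc] > 0:
        lab = labels[rc, cc]
    else:  # nearest foreground cell decides the component
        fr, fc = np.nonzero(window)
        d2 = (fr - rc) ** 2 + (fc - cc) ** 2
        nearest = int(np.argmin(d2))
        lab = labels[fr[nearest], fc[nearest]]
    comp = labels == lab
    rows_cols = _moore_trace(comp)
    x, y = geom.center_of(rows_cols[:, 0] + r0, rows_cols[:, 1] + c0)
    return np.column_stack([x, y])


def radial_scan(
    boundary: np.ndarray,
    center: tuple[float, float],
    n_rays: int = 12,
    ray_length: float = 2.0,
    plant_id=None,
) -> np.ndarray:
    """Simplify a traced boundary with radial scanning lines.

    A scanning line of ``ray_length`` meters is cast from the plant center
    at every ``360/n_rays`` degrees (counter-clockwise from east). Per
    line, the *farthest* intersection with the closed boundary within the
    line length is kept — when a neighboring plant's outline crosses a ray
    twice, this retains the focal plant's full extent. Lines that miss the
    boundary contribute nothing.

    Returns an (K, 2) array of world coordinates ordered by scan angle,
    K <= n_rays. Raises :class:`DegenerateCanopyError` if K < 3.
    """
    if n_rays < 3:
        raise InvalidParameterError(f"n_rays must be >= 3, got {n_rays}")
    boundary = np.asarray(boundary, dtype=float)
    if len(boundary) < 2:
        raise DegenerateCanopyError(
            "boundary polyline too short to intersect", plant_id=plant_id, n_points=0
        )
    ring = shapely.LinearRing(boundary) if len(boundary) >= 3 else shapely.LineString(boundary)
    cx, cy = center
    hits = []
    for j in range(n_rays):
        ang = 2.0 * np.pi * j / n_rays
        ray = shapely.LineString(
            [(cx, cy), (cx + ray_length * np.cos(ang), cy + ray_length * np.sin(ang))]
        )
        inter = ring.intersection(ray)
        if inter.is_empty:
            continue
        pts = []
        for part in getattr(inter, "geoms", [inter]):
            if isinstance(part, shapely.Point):
                pts.append((part.x, part.y))
            else:  # collinear overlap: keep its endpoints
                pts.extend(np.asarray(part.coords))
        if not pts:
            continue
        pts = np.asarray(pts, dtype=float)
        d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        hits.append(pts[np.argmax(d)])
    if len(hits) < 3:
        raise DegenerateCanopyError(
            f"only {len(hits)} scanning-line intersections (need >= 3)",
            plant_id=plant_id,
            n_points=len(hits),
        )
    return np.asarray(hits)


def polygon_metrics(points: np.ndarray) -> tuple[float, float]:
    """Perimeter CP and area CA of the closed polygon through ``points``.

    ``points`` must be at least three angle-ordered vertices; the polygon
    closes implicitly. CP sums consecutive Euclidean edge lengths, CA is
    the absolute shoelace area (shapely's exterior length/area).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 3 or points.shape[1] != 2:
        raise InvalidPolygonError(f"need >= 3 (x, y) vertices, got shape {points.shape}")
    poly = shapely.Polygon(points)
    return float(poly.exterior.length), float(abs(poly.area))


def extract_phenotypes(chm_raw: ElevationGrid, polygon: CanopyPolygon) -> PhenotypeRecord:
    """CH_max and CH_mean over raw-CHM cells whose centers fall inside the
    simplified polygon, bundled with the polygon's CP and CA."""
    rows, cols = cells_in_polygon(chm_raw.geom, polygon.shapely())
    if rows.size == 0:
        raise InvalidPolygonError(
            f"polygon of plant {polygon.plant_id} contains no cell centers"
        )
    heights = chm_raw.values[rows, cols]
    return PhenotypeRecord(
        plant_id=polygon.plant_id,
        cp=polygon.cp,
        ca=polygon.ca,
        ch_max=float(np.max(heights)),
        ch_mean=float(np.mean(heights)),
    )


def extract_plant(
    chm_raw: ElevationGrid,
    mask: CanopyMask,
    center: tuple[float, float],
    plant_id: int,
    n_rays: int = 12,
    ray_length: float = 2.0,
) -> tuple[CanopyPolygon | None, PhenotypeRecord]:
    """Run steps 3-6 for one plant; degenerate plants yield a flagged record.

    Degenerate means: no canopy near the center, fewer than three scanning
    line intersections, or a polygon so small it covers no cell centers.
    Such plants carry ``status`` ``"empty"`` or ``"degenerate"`` and NaN
    metrics, and are excluded from model fitting downstream.
    """
    try:
        boundary = trace_boundary(mask, center, search_radius=ray_length, plant_id=plant_id)
        points = radial_scan(boundary, center, n_rays=n_rays, ray_length=ray_length,
                             plant_id=plant_id)
        cp, ca = polygon_metrics(points)
        polygon = CanopyPolygon(plant_id=plant_id, vertices=points, cp=cp, ca=ca)
        return polygon, extract_phenotypes(chm_raw, polygon)
    except EmptyCanopyError:
        status = "empty"
    except (DegenerateCanopyError, InvalidPolygonError):
        status = "degenerate"
    nan = float("nan")
    return None, PhenotypeRecord(plant_id, nan, nan, nan, nan, status=status)
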