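"""Synthetic field experiment generator.

Emulates the study system end to end so every downstream stage is testable
without field data: a honeycomb (triangular-lattice) common garden of
clonal plants under two nitrogen levels, dome-shaped crowns with irregular
boundaries on gently undulating ground, LiDAR sampling of the canopy and
bare-ground surfaces with +/- 3 cm vertical noise, a 5-band reflectance
raster whose vegetation signal saturates with leaf density, and noisy
"manual" ground truth including dry biomass.

Scene construction enforces the biomass model by design: per scene (one
acquisition date) the true biomass of plant i is

    biomass_i = m_true x SI_i x CP_i x CH_i x eps_i

with CH_i the plant's *mean* crown height (exactly half the peak height
for the parabolic dome), m_true = slope x median(SI) + intercept linking
the coefficient to the date's phenological stage through the index
itself, and eps_i multiplicative lognormal noise with mean one (biomass
spans three orders of magnitude in the field, so the error model must
keep values positive).

Crown model: height field h = H (1 - (d / R(theta))^2) with boundary
radius R(theta) = R0 (1 + rho P(theta)), P a smooth random periodic
perturbation — dome crowns with irregular outlines. Reflectance uses a
linear two-endmember mixture: pixel = f x vegetation + (1 - f) x soil with
cover fraction f = 1 - exp(-k LAI), which makes every index a monotone
saturating function of leaf density. The background is near-uniform
(weed-cloth covered soil) with small multiplicative noise.

All randomness flows from one seed through ``numpy.random.SeedSequence``;
there is no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .canopy import polygon_metrics
from .errors import EmptyCloudError, InvalidParameterError
from .geometry import GridGeometry
from .gridding import PointCloud
from .spectral import BANDS, BandReflectance, RasterStack, compute_index

__all__ = [
    "PlantLayout",
    "SceneConfig",
    "SceneTruth",
    "generate_field",
    "generate_scene",
    "generate_season",
    "sample_lidar",
    "render_reflectance",
    "emulate_manual",
]


@dataclass
class PlantLayout:
    """Field layout: one row per plant (plant_id, genotype_id, n_treatment,
    center_x, center_y), the nominal spacing, and the field extent."""

    plants: pd.DataFrame
    spacing: float
    extent: tuple[float, float]  # (width, height), meters

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def centers(self) -> np.ndarray:
        return self.plants[["center_x", "center_y"]].to_numpy()


@dataclass
class SceneConfig:
    """Tunable scene parameters; the defaults are the study conditions.

    Plant size scale follows the field statistics (mean perimeter ~4.15 m
    hence mean crown radius ~0.66 m, mean height ~1.28 m, dry biomass mean
    ~386 g) with a common lognormal size factor per plant.
    """

    # crown geometry
    crown_radius_mean: float = 0.62   # m, final-season mean boundary radius
    height_mean: float = 1.28         # m, final-season mean peak height
    size_sigma: float = 0.35          # lognormal sigma of the per-plant size factor
    height_exponent: float = 0.6      # height ~ size_factor ** exponent
    height_jitter_sigma: float = 0.08
    boundary_roughness: float = 0.15  # rho: radial perturbation amplitude
    boundary_harmonics: tuple[int, int] = (2, 5)  # angular orders of P(theta)
    n_boundary_angles: int = 72       # boundary sampling (5 degree steps)
    # phenology
    struct_saturation: float = 0.6    # stage at which structure stops growing
    degreen_fraction: float = 0.6     # LAI lost between peak and season end
    lai_mean: float = 3.0
    lai_exponent: float = 0.3
    lai_jitter_sigma: float = 0.10
    # optics
    cover_extinction: float = 0.5     # k in f = 1 - exp(-k LAI)
    soil_reflectance: tuple[float, ...] = (0.08, 0.10, 0.12, 0.14, 0.16)
    veg_reflectance: tuple[float, ...] = (0.04, 0.10, 0.06, 0.28, 0.42)
    reflectance_noise_sd: float = 0.02
    # biomass model truth
    si_kind: str = "EVI"
    m_slope: float = -800.0           # g per (SI CP CH) per unit SI
    m_intercept: float = 680.0
    biomass_noise_sd: float = 0.2     # lognormal sigma of eps
    # ground surface
    ground_base: float = 100.0        # m elevation datum
    ground_amplitude: float = 0.05    # m relief amplitude


@dataclass
class SceneTruth:
    """Ground truth for one acquisition date of one field."""

    layout: PlantLayout
    growth_stage: float
    config: SceneConfig
    angles: np.ndarray          # (n_angles,)
    radii: np.ndarray           # (n_plants, n_angles) boundary radius r(theta)
    max_height: np.ndarray      # (n_plants,) true peak crown height, m
    mean_height: np.ndarray     # (n_plants,) mean crown height (= max/2), m
    perimeter: np.ndarray       # (n_plants,) closed-polygon perimeter of r(theta)
    area: np.ndarray            # (n_plants,) shoelace area of r(theta)
    lai: np.ndarray             # (n_plants,) leaf-density scalar
    cover: np.ndarray           # (n_plants,) canopy cover fraction f in [0, 1)
    si: np.ndarray              # (n_plants,) true spectral index (config.si_kind)
    m_true: float
    biomass: np.ndarray         # (n_plants,) grams dry weight
    ground_waves: np.ndarray    # (n_waves, 4): amplitude, kx, ky, phase

    @property
    def field_extent(self) -> tuple[float, float, float, float]:
        w, h = self.layout.extent
        return (0.0, 0.0, w, h)

    def ground_elevation(self, x, y):
        """Smooth bare-ground elevation at (x, y), meters."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.full(np.broadcast(x, y).shape, self.config.ground_base, dtype=float)
        for amp, kx, ky, phase in self.ground_waves:
            z += amp * np.sin(kx * x + ky * y + phase)
        return z

    def crown_height(self, x, y):
        """Canopy height above ground at (x, y): max over overlapping crowns."""
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        h = np.zeros_like(x)
        centers = self.layout.centers
        rmax = self.radii.max(axis=1) if self.radii.size else np.zeros(0)
        for i in range(self.layout.n_plants):
            if self.max_height[i] <= 0 or rmax[i] <= 0:
                continue
            cx, cy = centers[i]
            near = (np.abs(x - cx) <= rmax[i]) & (np.abs(y - cy) <= rmax[i])
            if not near.any():
                continue
            dx, dy = x[near] - cx, y[near] - cy
            d = np.hypot(dx, dy)
            theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
            r_theta = np.interp(theta, self.angles, self.radii[i], period=2.0 * np.pi)
            with np.errstate(divide="ignore", invalid="ignore"):
                hi = self.max_height[i] * (1.0 - (d / r_theta) ** 2)
            hi = np.where(r_theta > 0, np.maximum(hi, 0.0), 0.0)
            h[near] = np.maximum(h[near], hi)
        return h

    def surface_elevation(self, x, y):
        return self.ground_elevation(x, y) + self.crown_height(x, y)


def generate_field(
    n_genotypes: int,
    reps_per_treatment: int,
    spacing: float,
    seed: int = 0,
    jitter: float = 0.05,
) -> PlantLayout:
    """Honeycomb field layout: ``n_genotypes x 2 x reps_per_treatment``
    plants on a triangular lattice with the given interplant spacing.

    Treatment plots split the field into a west (low N) and an east
    (moderate N) half with equal plant counts; every genotype appears
    ``reps_per_treatment`` times in each half. A small uniform position
    jitter (default +/- 5 cm) emulates transplanting tolerance while
    preserving the honeycomb neighbor structure.
    """
    if n_genotypes < 1 or reps_per_treatment < 1:
        raise InvalidParameterError("n_genotypes and reps_per_treatment must be >= 1")
    if spacing <= 0:
        raise InvalidParameterError(f"spacing must be > 0, got {spacing}")
    if not 0 <= jitter < 0.45 * spacing:
        raise InvalidParameterError("jitter must be small relative to spacing")
    rng = np.random.default_rng(seed)
    total = n_genotypes * 2 * reps_per_treatment
    n_cols = int(math.ceil(math.sqrt(total)))
    n_rows = int(math.ceil(total / n_cols))
    dy = spacing * math.sqrt(3.0) / 2.0

    rows = np.arange(total) // n_cols
    cols = np.arange(total) % n_cols
    x = (cols + 0.5 + 0.5 * (rows % 2)) * spacing
    y = (rows + 0.5) * dy
    x = x + rng.uniform(-jitter, jitter, size=total)
    y = y + rng.uniform(-jitter, jitter, size=total)

    # west half low N, east half moderate N, equal counts
    order = np.argsort(x, kind="stable")
    treatment = np.empty(total, dtype=object)
    treatment[order[: total // 2]] = "low"
    treatment[order[total // 2 :]] = "moderate"

    genotype = np.empty(total, dtype=np.int64)
    base = np.repeat(np.arange(n_genotypes), reps_per_treatment)
    for level in ("low", "moderate"):
        idx = np.nonzero(treatment == level)[0]
        genotype[idx] = rng.permutation(base)

    plants = pd.DataFrame(
        {
            "plant_id": np.arange(1, total + 1),
            "genotype_id": genotype,
            "n_treatment": treatment,
            "center_x": x,
            "center_y": y,
        }
    )
    extent = ((n_cols + 1) * spacing, (n_rows + 1) * dy)
    return PlantLayout(plants=plants, spacing=spacing, extent=extent)


def _phenology(stage: float, cfg: SceneConfig) -> tuple[float, float]:
    """(structure, greenness) multipliers in [0, 1] at a growth stage."""
    s = cfg.struct_saturation
    struct = min(stage / s, 1.0) if s > 0 else 1.0
    if stage <= s:
        green = stage / s if s > 0 else 1.0
    else:
        green = 1.0 - cfg.degreen_fraction * (stage - s) / (1.0 - s)
    return struct, green


def generate_season(
    layout: PlantLayout,
    growth_stages,
    config: SceneConfig | None = None,
    seed: int = 0,
) -> list[SceneTruth]:
    """One SceneTruth per growth stage, sharing per-plant latent traits.

    Plant final size, crown outline shape and leaf density are drawn once,
    so the same plant grows consistently across acquisition dates; only
    phenology (structure growth, then de-greening) and per-scene noise
    differ between dates.
    """
    cfg = config or SceneConfig()
    stages = [float(g) for g in np.atleast_1d(growth_stages)]
    if any(not 0.0 <= g <= 1.0 for g in stages):
        raise InvalidParameterError(f"growth stages must lie in [0, 1]: {stages}")
    n = layout.n_plants
    ss = np.random.SeedSequence(seed)
    rng_traits, rng_ground, *rng_scenes = [
        np.random.default_rng(s) for s in ss.spawn(2 + len(stages))
    ]

    # --- per-plant latent traits (shared across dates) ---
    size = rng_traits.lognormal(mean=0.0, sigma=cfg.size_sigma, size=n)
    r_final = cfg.crown_radius_mean * size
    h_final = (
        cfg.height_mean
        * size**cfg.height_exponent
        * rng_traits.lognormal(0.0, cfg.height_jitter_sigma, size=n)
    )
    lai_final = (
        cfg.lai_mean
        * size**cfg.lai_exponent
        * rng_traits.lognormal(0.0, cfg.lai_jitter_sigma, size=n)
    )
    angles = np.arange(cfg.n_boundary_angles) * (2.0 * np.pi / cfg.n_boundary_angles)
    h_lo, h_hi = cfg.boundary_harmonics
    orders = np.arange(h_lo, h_hi + 1)
    amps = rng_traits.uniform(0.2, 1.0, size=(n, orders.size))
    phases = rng_traits.uniform(0.0, 2.0 * np.pi, size=(n, orders.size))
    pert = np.zeros((n, angles.size))
    for j, h in enumerate(orders):
        pert += amps[:, j, None] * np.cos(h * angles[None, :] + phases[:, j, None])
    peak = np.abs(pert).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    pert /= peak  # max |P| = 1 per plant
    shape_factor = 1.0 + cfg.boundary_roughness * pert  # (n, n_angles)

    # --- shared ground relief ---
    waves = []
    for _ in range(3):
        amp = cfg.ground_amplitude * rng_ground.uniform(0.3, 1.0) / math.sqrt(3.0)
        wavelength = rng_ground.uniform(15.0, 40.0)
        direction = rng_ground.uniform(0.0, 2.0 * np.pi)
        k = 2.0 * np.pi / wavelength
        waves.append((amp, k * math.cos(direction), k * math.sin(direction),
                      rng_ground.uniform(0.0, 2.0 * np.pi)))
    ground_waves = np.asarray(waves)

    soil = np.asarray(cfg.soil_reflectance)
    veg = np.asarray(cfg.veg_reflectance)
    scenes = []
    for stage, rng_scene in zip(stages, rng_scenes):
        struct, green = _phenology(stage, cfg)
        radii = r_final[:, None] * struct * shape_factor
        hmax = h_final * struct
        perimeter = np.zeros(n)
        area = np.zeros(n)
        if struct > 0:
            for i in range(n):
                verts = np.column_stack(
                    [radii[i] * np.cos(angles), radii[i] * np.sin(angles)]
                )
                perimeter[i], area[i] = polygon_metrics(verts)
        lai = lai_final * green
        cover = 1.0 - np.exp(-cfg.cover_extinction * lai)
        bands = soil[:, None] * (1.0 - cover[None, :]) + veg[:, None] * cover[None, :]
        si = np.asarray(
            compute_index(BandReflectance(*bands), cfg.si_kind), dtype=float
        )
        m_true = cfg.m_slope * float(np.median(si)) + cfg.m_intercept
        if m_true <= 0:
            raise InvalidParameterError(
                f"m_true = {m_true:.2f} <= 0 at stage {stage}; adjust m_slope/m_intercept"
            )
        sd = cfg.biomass_noise_sd
        eps = rng_scene.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=n) if sd > 0 else 1.0
        mean_height = hmax / 2.0  # exact for the parabolic dome, any boundary
        biomass = m_true * si * perimeter * mean_height * eps
        scenes.append(
            SceneTruth(
                layout=layout,
                growth_stage=stage,
                config=cfg,
                angles=angles,
                radii=radii,
                max_height=hmax,
                mean_height=mean_height,
                perimeter=perimeter,
                area=area,
                lai=lai,
                cover=cover,
                si=si,
                m_true=float(m_true),
                biomass=biomass,
                ground_waves=ground_waves,
            )
        )
    return scenes


def generate_scene(
    layout: PlantLayout,
    growth_stage: float,
    config: SceneConfig | None = None,
    seed: int = 0,
) -> SceneTruth:
    """Single-date convenience wrapper around :func:`generate_season`."""
    return generate_season(layout, [growth_stage], config=config, seed=seed)[0]


def sample_lidar(
    scene: SceneTruth,
    points_per_m2: float = 1000.0,
    sigma_z: float = 0.03,
    seed: int = 0,
) -> tuple[PointCloud, PointCloud]:
    """Simulate the two LiDAR acquisitions over the field.

    Returns ``(surface_cloud, ground_cloud)``: the growing-season scan
    samples ground + canopy, the bare-ground scan (after harvest) samples
    the ground only. Point counts are Poisson(density x area), positions
    uniform, and z carries Normal(0, sigma_z) positioning noise (the
    instrument's +/- 3 cm vertical accuracy, as a standard deviation of
    0.03 m by default).
    """
    if points_per_m2 <= 0:
        raise InvalidParameterError(f"points_per_m2 must be > 0, got {points_per_m2}")
    if sigma_z < 0:
        raise InvalidParameterError(f"sigma_z must be >= 0, got {sigma_z}")
    w, h = scene.layout.extent
    area = w * h
    if area <= 0:
        raise EmptyCloudError("scene extent has zero area; nothing to scan")
    rng = np.random.default_rng(seed)
    clouds = []
    for role in ("surface_scan", "ground_scan"):
        count = int(rng.poisson(points_per_m2 * area))
        if count == 0:
            raise EmptyCloudError("Poisson draw produced an empty cloud")
        x = rng.uniform(0.0, w, size=count)
        y = rng.uniform(0.0, h, size=count)
        z = scene.ground_elevation(x, y)
        if role == "surface_scan":
            z = z + scene.crown_height(x, y)
        if sigma_z > 0:
            z = z + rng.normal(0.0, sigma_z, size=count)
        clouds.append(PointCloud(np.column_stack([x, y, z]), role=role))
    return clouds[0], clouds[1]


def render_reflectance(
    scene: SceneTruth, cell_size: float = 0.01, seed: int = 0
) -> RasterStack:
    """Render the 5-band reflectance raster for a scene.

    Inside each crown the pixel is the vegetation/soil mixture at that
    plant's cover fraction (overlaps take the denser canopy); elsewhere it
    is the near-uniform soil/weed-cloth spectrum. Small multiplicative
    noise is applied per pixel and band; values are clipped to (0, 1).
    """
    if cell_size <= 0:
        raise InvalidParameterError(f"cell_size must be > 0, got {cell_size}")
    w, h = scene.layout.extent
    n_cols = int(math.ceil(w / cell_size - 1e-9))
    n_rows = int(math.ceil(h / cell_size - 1e-9))
    geom = GridGeometry(cell_size=cell_size, origin=(0.0, 0.0), shape=(n_rows, n_cols))

    cover_map = np.zeros((n_rows, n_cols))
    centers = scene.layout.centers
    xs, ys = geom.x_centers, geom.y_centers
    rmax = scene.radii.max(axis=1) if scene.radii.size else np.zeros(0)
    for i in range(scene.layout.n_plants):
        if rmax[i] <= 0 or scene.cover[i] <= 0:
            continue
        cx, cy = centers[i]
        c0 = max(int((cx - rmax[i]) / cell_size) - 1, 0)
        c1 = min(int((cx + rmax[i]) / cell_size) + 2, n_cols)
        r0 = max(int((cy - rmax[i]) / cell_size) - 1, 0)
        r1 = min(int((cy + rmax[i]) / cell_size) + 2, n_rows)
        if r1 <= r0 or c1 <= c0:
            continue
        dx = xs[c0:c1][None, :] - cx
        dy = ys[r0:r1][:, None] - cy
        d = np.hypot(dx, dy)
        theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
        r_theta = np.interp(theta, scene.angles, scene.radii[i], period=2.0 * np.pi)
        inside = d <= r_theta
        block = cover_map[r0:r1, c0:c1]
        block[inside] = np.maximum(block[inside], scene.cover[i])

    rng = np.random.default_rng(seed)
    soil = np.asarray(scene.config.soil_reflectance)
    veg = np.asarray(scene.config.veg_reflectance)
    values = np.empty((len(BANDS), n_rows, n_cols))
    sd = scene.config.reflectance_noise_sd
    for b in range(len(BANDS)):
        band = soil[b] * (1.0 - cover_map) + veg[b] * cover_map
        if sd > 0:
            band = band * rng.lognormal(-0.5 * sd * sd, sd, size=band.shape)
        values[b] = np.clip(band, 1e-4, 0.9999)
    return RasterStack(values, geom)


def emulate_manual(
    scene: SceneTruth,
    height_sd: float = 0.05,
    perimeter_sd: float = 0.30,
    biomass_sd: float = 0.10,
    ratio_range: tuple[float, float] = (0.35, 0.50),
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy manual ground-truth table for a scene.

    Height (tape to the tallest tiller) and perimeter get additive
    zero-mean Gaussian noise; dry biomass gets multiplicative lognormal
    noise with mean one; the dry-to-fresh ratio is drawn per plant and the
    fresh weight back-computed, so dry = fresh x ratio holds exactly.
    """
    rng = np.random.default_rng(seed)
    n = scene.layout.n_plants
    height = scene.max_height + (rng.normal(0.0, height_sd, n) if height_sd > 0 else 0.0)
    perim = scene.perimeter + (rng.normal(0.0, perimeter_sd, n) if perimeter_sd > 0 else 0.0)
    if biomass_sd > 0:
        dry = scene.biomass * rng.lognormal(-0.5 * biomass_sd**2, biomass_sd, n)
    else:
        dry = scene.biomass.copy()
    ratio = rng.uniform(*ratio_range, size=n)
    fresh = dry / ratio
    return pd.DataFrame(
        {
            "plant_id": scene.layout.plants["plant_id"].to_numpy(),
            "manual_height": np.maximum(height, 0.0),
            "manual_perimeter": np.maximum(perim, 0.0),
            "fresh_biomass": fresh,
            "dry_to_fresh_ratio": ratio,
            "dry_biomass": fresh * ratio,
        }
    )
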