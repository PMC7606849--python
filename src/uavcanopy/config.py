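"""Run configuration: one TOML file controls every tunable.

Unknown keys are rejected at parse time, so typos fail before any
computation. Defaults reproduce the reference processing chain: 1 x 1 cm
grids, a 5 x 5 / 25th-percentile filter, a 10 cm canopy threshold, and
twelve 2 m scanning lines.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, fields
from dataclasses import field as dc_field
from pathlib import Path

from .errors import InvalidParameterError
from .synthetic import SceneConfig

__all__ = ["RunConfig", "load_config", "config_to_dict"]


@dataclass
class FieldSection:
    n_genotypes: int = 20
    reps_per_treatment: int = 5
    spacing: float = 2.5
    jitter: float = 0.05


@dataclass
class LidarSection:
    points_per_m2: float = 1000.0
    sigma_z: float = 0.03


@dataclass
class GridSection:
    cell_size: float = 0.01


@dataclass
class ExtractSection:
    filter_window: int = 5
    filter_q: float = 0.25
    threshold: float = 0.10
    n_rays: int = 12
    ray_length: float = 2.0


@dataclass
class SpectralSection:
    si_kind: str = "EVI"
    per_pixel: bool = False


@dataclass
class ModelSection:
    estimator: str = "through_origin"
    date_si_stat: str = "median"


@dataclass
class ManualSection:
    height_sd: float = 0.05
    perimeter_sd: float = 0.30
    biomass_sd: float = 0.10
    ratio_low: float = 0.35
    ratio_high: float = 0.50


@dataclass
class RunSection:
    mode: str = "synthetic"  # "synthetic" or "files"
    seed: int = 0
    growth_stages: list[float] = dc_field(default_factory=lambda: [0.6, 0.7, 0.8, 0.9, 1.0])
    write_clouds: bool = False
    write_rasters: bool = False
    # files mode inputs
    surface_cloud: str = ""
    ground_cloud: str = ""
    reflectance: str = ""
    centers: str = ""
    manual: str = ""


@dataclass
class RunConfig:
    field: FieldSection = dc_field(default_factory=FieldSection)
    scene: SceneConfig = dc_field(default_factory=SceneConfig)
    lidar: LidarSection = dc_field(default_factory=LidarSection)
    grid: GridSection = dc_field(default_factory=GridSection)
    extract: ExtractSection = dc_field(default_factory=ExtractSection)
    spectral: SpectralSection = dc_field(default_factory=SpectralSection)
    model: ModelSection = dc_field(default_factory=ModelSection)
    manual: ManualSection = dc_field(default_factory=ManualSection)
    run: RunSection = dc_field(default_factory=RunSection)

    def validate(self) -> "RunConfig":
        if self.run.mode not in ("synthetic", "files"):
            raise InvalidParameterError(f"run.mode must be synthetic|files, got {self.run.mode}")
        if self.grid.cell_size <= 0:
            raise InvalidParameterError("grid.cell_size must be > 0")
        if self.extract.filter_window % 2 == 0 or self.extract.filter_window < 3:
            raise InvalidParameterError("extract.filter_window must be odd and >= 3")
        if not 0 < self.extract.filter_q < 1:
            raise InvalidParameterError("extract.filter_q must be in (0, 1)")
        if self.extract.threshold < 0:
            raise InvalidParameterError("extract.threshold must be >= 0")
        if self.extract.n_rays < 3:
            raise InvalidParameterError("extract.n_rays must be >= 3")
        if not self.run.growth_stages:
            raise InvalidParameterError("run.growth_stages must be non-empty")
        return self


def _build(cls, data: dict, where: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise InvalidParameterError(f"unknown config keys in [{where}]: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = known[key].type
        if isinstance(value, list) and "tuple" in str(ftype):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_SECTIONS = {
    "field": FieldSection,
    "scene": SceneConfig,
    "lidar": LidarSection,
    "grid": GridSection,
    "extract": ExtractSection,
    "spectral": SpectralSection,
    "model": ModelSection,
    "manual": ManualSection,
    "run": RunSection,
}


def load_config(path) -> RunConfig:
    """Parse and validate a TOML config file; unknown sections/keys raise."""
    data = tomllib.loads(Path(path).read_text())
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise InvalidParameterError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {
        name: _build(cls, data.get(name, {}), name) for name, cls in _SECTIONS.items()
    }
    return RunConfig(**kwargs).validate()


def config_to_dict(config: RunConfig) -> dict:
    """Plain-dict view of a config (tuples become lists), for manifests."""

    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: convert(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return convert(config)
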