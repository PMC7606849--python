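# uavcanopy

High-throughput phenotyping of individual field-grown plants from UAV
LiDAR and multispectral imagery, plus a standardized biomass yield model —
with a synthetic field-scene generator so the whole chain is testable and
reproducible without any field data.

The package targets perennial bunch-grass common gardens (the motivating
system is switchgrass, *Panicum virgatum*, planted on a honeycomb grid at
~2.5 m spacing under two nitrogen levels), but every stage operates on
generic point clouds, rasters and plant-center tables.

## What it computes

**Structural phenotypes from LiDAR.** A growing-season surface scan and a
post-harvest bare-ground scan are gridded at 1 × 1 cm into a digital
surface model (DSM) and digital terrain model (DTM); the canopy height
model is CHM = DSM − DTM (negatives clamped to zero). Per plant, the CHM
is smoothed with a 5 × 5 / 25th-percentile order-statistic filter,
binarized at 10 cm, the exterior boundary of the canopy component at the
plant center is traced (Moore-neighbor tracing), and twelve 2 m scanning
lines cast every 30° from the center simplify the outline to ≤ 12 points.
The closed polygon yields canopy perimeter CP (m) and area CA (m²);
canopy height CH is read from the *unsmoothed* CHM inside the polygon
(CH_max for validation against manual tape measurements, CH_mean for
modeling).

**Spectral indices.** Mean reflectance per plant polygon in five bands —
blue 475, green 560, red 668, red-edge 717, NIR 842 nm — feeds four
vegetation indices:

    RVI  = R_NIR / R_red
    NDVI = (R_NIR − R_red) / (R_NIR + R_red)
    EVI  = 2.5 (R_NIR − R_red) / (R_NIR + 6 R_red − 7.5 R_blue + 1)
    NDRE = (R_NIR − R_RE) / (R_NIR + R_RE)

**Biomass model.** Optical indices saturate over dense canopies, so the
structural terms carry the signal:

    biomass = (m × SI) × CP × CH        [grams]

`m` is an SI-sensitive coefficient calibrated per acquisition date as the
aggregate ratio between destructively measured biomass and the product
SI × CP × CH (through-origin least squares). Across dates, `m` varies
approximately linearly with the date's median index value, so it can be
predicted from the imagery itself. The package also fits the allometric
link CP = a × CA^b (log–log OLS; exact circles give a = 2√π, b = ½) and
reports Pearson r, rmse and relative error re = rmse / mean(obs) for
every comparison.

**Synthetic scenes.** `uavcanopy.synthetic` builds complete experiments:
honeycomb layouts, dome-shaped crowns with irregular boundaries on
undulating ground, Poisson LiDAR sampling with ±3 cm vertical noise,
reflectance rasters whose vegetation signal saturates with leaf density,
and noisy manual tables (heights, perimeters, fresh/dry biomass). Scene
truth satisfies the biomass model by construction, which turns the whole
pipeline into a parameter-recovery experiment.

## Worked example

```python
from uavcanopy import RunConfig, run_pipeline

config = RunConfig()
config.field.n_genotypes = 10          # 10 genotypes x 2 N levels x 5 reps = 100 plants
config.field.reps_per_treatment = 5
config.grid.cell_size = 0.02           # 2 cm grid for a quick desk-scale run
config.run.seed = 1

manifest = run_pipeline(config, "example_run")
```

Printing the headline numbers from the manifest gives:

```
plants extracted : 100/100
perimeter vs manual: r=0.98 rmse=0.56 m re=0.13
height    vs manual: r=0.98 rmse=0.10 m re=0.08
biomass model (EVI, peak date): m=404.9 g, r=0.93, rmse=112.8 g
m-SI line: m = -877.5 x EVI + 699.1  (r=-0.986, p=0.002)
allometry: CP = 3.673 x CA^0.498  (r2=1.000)
```

Reading: automated perimeters and heights agree with the simulated manual
measurements (r ≈ 0.98, with rmse of 0.56 m and 0.10 m respectively); the
calibrated model predicts dry biomass with r = 0.93; the per-date
coefficient m falls on a tight negative line against the date's median
EVI (de-greening raises m as the index falls); and the extracted canopies
follow the near-isoperimetric perimeter–area power law. The output
directory contains `phenotypes.csv`, `polygons.geojson`, `chm.tif` (+
`.json` georeferencing sidecar), `model_fits.csv`, `m_si_fit.json`,
`cp_ca_fit.json`, `validation.csv`, `treatment_summary.csv` and a
`manifest.json` with the config hash and seeds for exact reruns.

## Command line

```sh
uavcanopy all --config cfg.toml --seed 1 --out run/       # whole pipeline
uavcanopy simulate --config cfg.toml --seed 1 --out sim/  # synthetic inputs only
uavcanopy grid|extract|spectral|model ...                 # individual stages
```

A single TOML file controls every tunable (cell size, filter window and
percentile, binarization threshold, ray count/length, index kind, noise
levels, seeds); unknown keys are rejected. Point clouds are read/written
as CSV (x,y,z), rasters as multiband TIFF with a JSON sidecar, polygons
as GeoJSON.

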