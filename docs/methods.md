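# Methods

This note documents the models, the synthetic experiment the package
simulates, the numerical choices, and the known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The processing chain

**Gridding.** Point clouds are rasterized onto a regular planar grid
(x east, y north, lower-left origin, cell-center sampling; default cell
size 0.01 m). Each cell keeps the *maximum* return elevation: the sensor
modeled here records a single echo, canopy tops drive plant height, and a
max surface is the standard single-echo DSM choice. Cells without returns
are filled from the nearest populated cell via a Euclidean distance
transform (deterministic; ties broken by the transform's internal scan
order). CHM = DSM − DTM with negatives clamped to zero — sub-zero
differences are positioning error or ground-relief mismatch, not
vegetation.

**Boundary extraction.** The CHM is smoothed by an order-statistic
filter: each cell becomes the k-th smallest value in its 5 × 5 window
with k = ceil(q · 25) = 7 at q = 0.25. "25th percentile" is ambiguous
between the 6th and 7th order statistic; the ceil rule is used and both
`window` and `q` are configurable. Edges use scipy's reflect padding
(edge value duplicated). Binarization marks canopy where height
≥ 0.10 m — the threshold itself counts as canopy, since only values
*below* it are invalid. The 8-connected component containing the plant
center wins; if the center cell is background, the component of the
nearest foreground cell within the 2 m search window is used. Its
exterior boundary is traced with Moore-neighbor tracing (Jacob's
stopping criterion), giving an ordered closed polyline of boundary cell
centers.

**Radial scanning lines.** Rays of 2.0 m at 360°/12 intervals,
counter-clockwise from east, intersect the closed boundary; per ray the
*farthest* intersection within the ray length is kept. The farthest rule
resolves double crossings (e.g. a neighboring plant's outline) toward
retaining the focal plant's full extent; both the angular origin and the
rule are configurable. Plants with fewer than 3 retained points are
flagged `degenerate` (CP/CA undefined) and excluded from model fits;
plants with no canopy near the center are flagged `empty`.

**Phenotypes.** CP and CA come from the closed simplified polygon
(shapely exterior length / shoelace area). CH_max and CH_mean are read
from the *unsmoothed* CHM over cells whose centers fall inside the
polygon — the percentile filter biases heights low, so smoothing serves
boundary detection only. CH_max is compared with manual height (tape to
the tallest tiller); CH_mean drives the biomass model.

**Spectral indices.** Per-plant band means are computed before the index
(mean-then-index); a per-pixel index map is available for sensitivity
checks. Soil pixels visible through canopy gaps inside the polygon are
included in the mean — a known, documented bias source. The EVI "+1"
term assumes reflectance in [0, 1]; absolute calibration is assumed, not
verified.

## The biomass model

    biomass = (m × SI) × CP × CH,   CH = CH_mean

`m` (grams per unit SI·m·m) is calibrated per acquisition date. The
estimator is the least-squares slope through the origin of biomass on
x = SI × CP × CH: the paper-style definition of m is a per-plant ratio,
but a single field-level value per date is wanted, and the through-origin
slope is the aggregate ratio under squared loss, robust to
small-denominator plants. A per-plant ratio-median estimator is offered
as an option. Date-level SI for the m–SI regression is the median across
plants (mean offered as an option); slope/intercept confidence intervals
use the standard t-based OLS formulas, and p-values come from the
t-distribution of the correlation coefficient, uncorrected (single
fits). Evaluation reports Pearson r, rmse, and re = rmse / mean(obs);
"relative error" is an interpretation chosen because it reproduces the
usual magnitudes (rmse ≈ 0.1 m on a ≈ 1.3 m mean height gives
re ≈ 0.07). The CP–CA allometry is fitted by OLS on log CP vs log CA,
with r² reported on the log scale; exact circles give a = 2√π, b = ½
(verified to 1e-9 in the tests).

## The synthetic experiment

The generator emulates a honeycomb common garden of clonal bunch
grasses under two N levels and the two UAV acquisitions.

*Layout.* Triangular lattice at `spacing` (default 2.5 m) with ±5 cm
uniform transplanting jitter; west half low N, east half moderate N,
each genotype appearing `reps_per_treatment` times per level. Every
interior plant has six neighbors within 1.1 × spacing.

*Crowns.* Height field h = H·max(0, 1 − (d/R(θ))²), a dome with
irregular outline R(θ) = R₀(1 + ρ·P(θ)), where P is a normalized sum of
random angular harmonics of orders 2–5 and ρ = 0.15. A common lognormal
size factor (σ = 0.35) scales radius (mean 0.62 m), height
(mean 1.28 m, exponent 0.6) and leaf density, reproducing the field's
reported spread of perimeters (~4.15 ± 1.6 m), heights (~1.28 ± 0.3 m)
and dry biomass (mean ≈ 400 g, range two orders of magnitude).
Structure grows linearly until stage 0.6 and is static afterwards;
leaf density (LAI, mean 3.0) peaks at 0.6 and then de-greens by 60%
toward season end.

*Optics.* Pixel reflectance is a two-endmember linear mixture,
f·vegetation + (1 − f)·soil, with cover fraction f = 1 − exp(−k·LAI),
k = 0.5. This induces a monotone, saturating SI(LAI) — the saturation
phenomenon that motivates the structural model terms — and keeps scene
truth and rendered rasters exactly consistent: a pixel at a plant
center carries precisely the plant's truth mixture. The background is a
fixed near-uniform spectrum (weed-cloth covered soil) with 2%
multiplicative noise.

*Model truth.* Per scene (acquisition date), m_true = slope · median(SI)
+ intercept (defaults −800 and 680, chosen once so that simulated EVI
(~0.33–0.51 across dates) yields positive m and field-scale biomass),
and biomass_i = m_true · SI_i · CP_i · CH_i · ε_i with CH_i the *mean*
crown height — exactly H/2 for the parabolic dome, any outline — and
ε_i lognormal with mean 1 (σ = 0.2). The mean-height convention follows
the model's definition of CH; max height is kept separately for height
validation. Because each date's scene carries its own Eq.-consistent
biomass, per-date m is calibrated against that date's destructive
manual biomass, as in situ calibration would be.

*Sampling.* LiDAR point counts are Poisson(density × area), positions
uniform, z = surface + N(0, σ_z) with σ_z = 0.03 m (the instrument's
±3 cm vertical accuracy read as one standard deviation). The default
density of 1000 pts/m² is a deliberately reduced stand-in for the very
high single-pass densities of real scanners; at 1 cm cells roughly 90%
of cells are then nearest-filled, which the extraction chain tolerates.
Manual tables add zero-mean Gaussian noise to height (σ = 0.05 m) and
perimeter (σ = 0.30 m), mean-one lognormal noise to dry biomass
(σ = 0.10), and draw a dry-to-fresh ratio per plant in [0.35, 0.50] so
that dry = fresh × ratio holds exactly.

All randomness flows from one `numpy.random.SeedSequence`; identical
seeds give bit-identical layouts, clouds, rasters and tables, and two
pipeline runs with the same config produce byte-identical CSVs.

## Problem sizes and observed behavior

The end-to-end study in the test suite uses 200 plants, five acquisition
dates (stages 0.6–1.0), 1 cm grids and the noise levels above — chosen as
a desk-scale study that preserves the field experiment's statistical
structure. On it the pipeline reproduces the expected relationships:
extracted perimeter and height track truth with r > 0.95, the calibrated
model predicts true biomass with r ≥ 0.9, the m–SI regression covers the
generator's slope and intercept at 95% confidence, and the extracted
canopies follow CP ≈ a·CA^b with b near ½.

Two systematic effects of the 12-vertex simplification are worth
knowing. First, the polygon inscribes the true outline, so CA is bounded
by the inscribed 12-gon (for a circle, 3R² = 0.955·πR²) — CA is a
slightly conservative area measure by construction. Second, polygon-mean
CH is read over the inscribed region and therefore exceeds the
full-crown mean (≈ +13% for a dome), while soil gaps near the canopy
edge dilute SI in the opposite direction; the net calibration bias on m
is ~1% at the calibration (peak structural) date but can reach ~10–12%
at mid-season dates where the cancellation is weaker. Model *prediction*
quality is unaffected (the bias is absorbed into m), but recovered m
values should be compared across dates with this in mind.

## Limitations

- No radiative transfer, flight-path, overlap or mosaicking artifacts;
  reflectance calibration is out of scope.
- Crowns are radially star-shaped domes; heavily lobed or lodged plants
  and tiller-level structure are not modeled, so passing tests bound
  behavior on compact canopies only.
- Touching plants are separated only by the farthest-intersection ray
  rule, not by watershed/instance segmentation.
- The nitrogen treatment is a labeling device (no growth effect by
  default), matching the finding that treatment effects were negligible
  relative to genotype variation; the treatment summary is descriptive.
- Point clouds are exchanged as CSV and rasters as TIFF + JSON sidecar;
  LAS and Esri shapefile output are not produced.
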