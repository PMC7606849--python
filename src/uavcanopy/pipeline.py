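"""Pipeline orchestration: synthetic scene (or input files) to phenotype
tables, model fits and a run manifest.

Synthetic mode runs the whole study: the structural chain (LiDAR ->
DSM/DTM -> CHM -> per-plant polygons -> CP/CA/CH) once at the latest
acquisition date (structure is static after peak season), then a
reflectance render and spectral-index extraction per date, a per-date
calibration of the biomass coefficient m against that date's destructive
manual biomass, the m-SI line across dates, the CP-CA power law, and the
validation statistics of automated versus manual perimeter and height.

Files mode runs the same structural + spectral chain on user-supplied
point-cloud CSVs, a reflectance TIFF and a plant-center table.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomass import (
    calibrate_m,
    evaluate,
    fit_cp_ca_power,
    fit_m_si_relation,
    predict_biomass,
    summarize_treatments,
)
from .canopy import binarize, extract_plant, smooth_chm
from .config import RunConfig, config_to_dict
from .errors import InsufficientDataError, MissingInputError, SingularFitError
from .gridding import compute_chm, rasterize
from .io import (
    read_cloud_csv,
    read_raster_tiff,
    read_table,
    write_cloud_csv,
    write_grid_tiff,
    write_polygons_geojson,
    write_raster_tiff,
)
from .spectral import BANDS, SI_KINDS, mean_band_reflectance, compute_index
from .synthetic import (
    emulate_manual,
    generate_field,
    generate_season,
    render_reflectance,
    sample_lidar,
)

__all__ = ["run_pipeline"]


def _extract_all(chm_raw, mask, centers: pd.DataFrame, extract_cfg):
    """Per-plant polygons + phenotype table from a CHM and center table."""
    polygons, records = [], []
    for row in centers.itertuples(index=False):
        polygon, record = extract_plant(
            chm_raw,
            mask,
            (row.center_x, row.center_y),
            plant_id=int(row.plant_id),
            n_rays=extract_cfg.n_rays,
            ray_length=extract_cfg.ray_length,
        )
        if polygon is not None:
            polygons.append(polygon)
        records.append(record)
    table = pd.DataFrame([asdict(r) for r in records])
    return polygons, table


def _spectral_table(raster, polygons, si_kind: str) -> pd.DataFrame:
    rows = []
    for poly in polygons:
        bands = mean_band_reflectance(raster, poly)
        row = {"plant_id": poly.plant_id}
        row.update({f"r_{name}": getattr(bands, name) for name in BANDS})
        for kind in SI_KINDS:
            row[kind.lower()] = float(compute_index(bands, kind))
        row["si"] = row[si_kind.lower()]
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured run and write all outputs under ``out_dir``.

    Returns a result dictionary (also serialized in ``manifest.json``)
    with per-stage record counts, fit summaries and warnings.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if config.run.mode == "synthetic":
        results = _run_synthetic(config, out)
    else:
        results = _run_files(config, out)

    cfg_dict = config_to_dict(config)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.run.seed,
        "versions": {"uavcanopy": __version__, "numpy": np.__version__},
        "elapsed_s": round(time.time() - t0, 3),
        **results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return manifest


def _structural_stage(config, out, surface, ground, centers, extent):
    """Clouds -> DSM/DTM -> CHM -> smoothed/binarized -> per-plant polygons."""
    cell = config.grid.cell_size
    dsm = rasterize(surface, cell, extent, role="DSM")
    dtm = rasterize(ground, cell, extent, role="DTM")
    chm = compute_chm(dsm, dtm)
    smoothed = smooth_chm(chm, window=config.extract.filter_window, q=config.extract.filter_q)
    mask = binarize(smoothed, threshold=config.extract.threshold)
    polygons, phenotypes = _extract_all(chm, mask, centers, config.extract)
    write_grid_tiff(chm, out / "chm.tif")
    write_polygons_geojson(polygons, out / "polygons.geojson")
    return chm, polygons, phenotypes


def _run_synthetic(config: RunConfig, out: Path) -> dict:
    rng = np.random.default_rng(config.run.seed)
    seeds = iter(rng.integers(0, 2**31 - 1, size=4 + 2 * len(config.run.growth_stages)))
    fc = config.field
    layout = generate_field(
        fc.n_genotypes, fc.reps_per_treatment, fc.spacing,
        seed=int(next(seeds)), jitter=fc.jitter,
    )
    layout.plants.to_csv(out / "layout.csv", index=False)
    stages = sorted(config.run.growth_stages)
    scenes = generate_season(layout, stages, config.scene, seed=int(next(seeds)))
    peak = scenes[-1]

    surface, ground = sample_lidar(
        peak, config.lidar.points_per_m2, config.lidar.sigma_z, seed=int(next(seeds))
    )
    if config.run.write_clouds:
        write_cloud_csv(surface, out / "surface_cloud.csv")
        write_cloud_csv(ground, out / "ground_cloud.csv")
    chm, polygons, phenotypes = _structural_stage(
        config, out, surface, ground, layout.plants, peak.field_extent
    )
    degenerate = phenotypes.loc[phenotypes.status != "ok", "plant_id"].tolist()
    good = phenotypes[phenotypes.status == "ok"].set_index("plant_id")

    # spectral + per-date m calibration
    fits, si_medians, m_values, si_tables = [], [], [], []
    for scene, stage in zip(scenes, stages):
        raster = render_reflectance(scene, config.grid.cell_size, seed=int(next(seeds)))
        if config.run.write_rasters:
            write_raster_tiff(raster, out / f"reflectance_{stage:.2f}.tif")
        spectral = _spectral_table(raster, polygons, config.spectral.si_kind)
        spectral.insert(1, "growth_stage", stage)
        si_tables.append(spectral)
        manual = emulate_manual(
            scene,
            height_sd=config.manual.height_sd,
            perimeter_sd=config.manual.perimeter_sd,
            biomass_sd=config.manual.biomass_sd,
            ratio_range=(config.manual.ratio_low, config.manual.ratio_high),
            seed=int(next(seeds)),
        )
        joined = (
            spectral.merge(good[["cp", "ch_mean"]], on="plant_id")
            .merge(manual[["plant_id", "dry_biomass"]], on="plant_id")
        )
        label = f"stage_{stage:.2f}"
        fit = calibrate_m(
            joined.dry_biomass, joined.si, joined.cp, joined.ch_mean,
            si_kind=config.spectral.si_kind, date_label=label,
            estimator=config.model.estimator,
        )
        pred = predict_biomass(fit.m, joined.si, joined.cp, joined.ch_mean)
        stats_manual = evaluate(pred, joined.dry_biomass)
        truth = pd.DataFrame(
            {"plant_id": layout.plants.plant_id, "true_biomass": scene.biomass}
        )
        joined_truth = joined.merge(truth, on="plant_id")
        stats_truth = evaluate(
            predict_biomass(fit.m, joined_truth.si, joined_truth.cp, joined_truth.ch_mean),
            joined_truth.true_biomass,
        )
        stat = config.model.date_si_stat
        si_level = float(joined.si.median() if stat == "median" else joined.si.mean())
        si_medians.append(si_level)
        m_values.append(fit.m)
        fits.append(
            {
                "date_label": label, "growth_stage": stage,
                "si_kind": fit.si_kind, "m": fit.m, "m_true": scene.m_true,
                "n_plants": fit.n_plants, "si_level": si_level,
                "r_manual": stats_manual.r, "rmse_manual": stats_manual.rmse,
                "re_manual": stats_manual.re,
                "r_true": stats_truth.r, "rmse_true": stats_truth.rmse,
                "re_true": stats_truth.re,
            }
        )
        if scene is peak:
            peak_manual, peak_spectral = manual, spectral

    fits_df = pd.DataFrame(fits)
    fits_df.to_csv(out / "model_fits.csv", index=False)
    pd.concat(si_tables, ignore_index=True).to_csv(out / "spectral_by_date.csv", index=False)

    # phenotype CSV with peak-date band means/indices appended
    phenotypes = phenotypes.merge(
        peak_spectral.drop(columns=["growth_stage"]), on="plant_id", how="left"
    )
    phenotypes.to_csv(out / "phenotypes.csv", index=False)
    peak_manual.to_csv(out / "manual.csv", index=False)

    warnings = [f"degenerate plant {pid}" for pid in degenerate]
    results: dict = {
        "n_plants": layout.n_plants,
        "n_extracted": int((phenotypes.status == "ok").sum()),
        "n_degenerate": len(degenerate),
        "warnings": warnings,
        "fits": fits,
    }

    # cross-date m-SI relation
    if len(stages) >= 3:
        try:
            cal = fit_m_si_relation(m_values, si_medians)
            results["m_si_fit"] = asdict(cal)
            (out / "m_si_fit.json").write_text(json.dumps(asdict(cal), indent=1))
        except (InsufficientDataError, SingularFitError) as exc:
            results["m_si_fit"] = None
            results["warnings"].append(f"m-SI fit skipped: {exc}")

    # CP-CA allometry on extracted plants
    power = fit_cp_ca_power(good.cp, good.ca)
    results["cp_ca_fit"] = asdict(power)
    (out / "cp_ca_fit.json").write_text(json.dumps(asdict(power), indent=1))

    # validation of automated vs manual structure at the peak date
    val = good.join(peak_manual.set_index("plant_id"), how="inner")
    validation = {
        "perimeter": asdict(evaluate(val.cp, val.manual_perimeter)),
        "height": asdict(evaluate(val.ch_max, val.manual_height)),
    }
    truth_val = good.join(
        pd.DataFrame(
            {
                "plant_id": layout.plants.plant_id,
                "true_perimeter": peak.perimeter,
                "true_height": peak.max_height,
            }
        ).set_index("plant_id"),
        how="inner",
    )
    validation["perimeter_vs_truth"] = asdict(evaluate(truth_val.cp, truth_val.true_perimeter))
    validation["height_vs_truth"] = asdict(evaluate(truth_val.ch_max, truth_val.true_height))
    results["validation"] = validation
    pd.DataFrame(validation).T.rename_axis("comparison").to_csv(out / "validation.csv")

    summary = summarize_treatments(
        phenotypes[phenotypes.status == "ok"], peak_manual, layout.plants
    )
    summary.to_csv(out / "treatment_summary.csv", index=False)
    return results


def _run_files(config: RunConfig, out: Path) -> dict:
    run = config.run
    for name in ("surface_cloud", "ground_cloud", "centers"):
        if not getattr(run, name):
            raise MissingInputError(f"files mode requires run.{name}")
    surface = read_cloud_csv(run.surface_cloud, role="surface_scan")
    ground = read_cloud_csv(run.ground_cloud, role="ground_scan")
    centers = read_table(run.centers, {"plant_id", "center_x", "center_y"})
    xy = surface.xyz[:, :2]
    extent = (
        float(xy[:, 0].min()), float(xy[:, 1].min()),
        float(xy[:, 0].max()), float(xy[:, 1].max()),
    )
    chm, polygons, phenotypes = _structural_stage(config, out, surface, ground, centers, extent)
    results: dict = {
        "n_plants": len(centers),
        "n_extracted": int((phenotypes.status == "ok").sum()),
        "n_degenerate": int((phenotypes.status != "ok").sum()),
        "warnings": [
            f"degenerate plant {pid}"
            for pid in phenotypes.loc[phenotypes.status != "ok", "plant_id"]
        ],
    }
    if run.reflectance:
        raster = read_raster_tiff(run.reflectance)
        spectral = _spectral_table(raster, polygons, config.spectral.si_kind)
        phenotypes = phenotypes.merge(spectral, on="plant_id", how="left")
        if run.manual:
            manual = read_table(run.manual, {"plant_id", "dry_biomass"})
            joined = phenotypes[phenotypes.status == "ok"].merge(manual, on="plant_id")
            fit = calibrate_m(
                joined.dry_biomass, joined.si, joined.cp, joined.ch_mean,
                si_kind=config.spectral.si_kind, estimator=config.model.estimator,
            )
            pred = predict_biomass(fit.m, joined.si, joined.cp, joined.ch_mean)
            results["fit"] = {**asdict(fit), **asdict(evaluate(pred, joined.dry_biomass))}
    phenotypes.to_csv(out / "phenotypes.csv", index=False)
    return results
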