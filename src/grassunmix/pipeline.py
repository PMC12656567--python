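"""End-to-end orchestration of the synthetic two-year analysis.

``run_pipeline`` executes the stages in dependency order — simulate two
acquisition years, preprocess, build endmembers from high-purity regions,
unmix both years, map trends, summarise abundances and areas, validate
against purity-sampled reference points at each threshold, and run the
paired change tests — writing every artifact under one output directory
and returning a manifest (also written as JSON) with a content hash per
file, so a run is reproducible and any single stage can be re-run in
isolation from its recorded inputs.

Both years share one endmember library (the synthetic site's classes do
not change spectrally); change enters through the per-year fraction
fields. Reference points and the endmember regions are drawn from the
later year's ground truth, mirroring a validation campaign conducted
against the most recent imagery.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
import shapely.geometry

from . import abundance_summary, accuracy_assessment, change_trend
from . import endmember_library as eml
from . import linear_unmixing, preprocess, raster_io, stats_tests
from .config import RunConfig, validate_config
from .errors import GrassunmixError
from .synthetic_scene import (
    DEFAULT_CLASSES,
    SceneTruth,
    generate_endmember_spectra,
    generate_fraction_field,
    render_cube,
    sample_reference_points,
)
from .types import RegionSet

__all__ = ["run_pipeline", "simulate_two_years"]


def _subseeds(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def simulate_two_years(cfg: RunConfig):
    """Ground truth for both acquisition years from one master seed.

    Returns ``(truth_by_year, library)``: one shared endmember library and
    a SceneTruth per year whose fraction fields differ in their Dirichlet
    concentration (the configured compositional change).
    """
    sc = cfg.scene
    s_lib, s_f18, s_f22, s_r18, s_r22, s_defect = _subseeds(cfg.seed, 6)
    classes = DEFAULT_CLASSES[: len(sc.concentration_2018)]
    if len(classes) < len(sc.concentration_2018):
        raise GrassunmixError(
            "default class shapes support at most "
            f"{len(DEFAULT_CLASSES)} classes"
        )
    library = generate_endmember_spectra(sc.n_bands, classes, seed=s_lib)
    names = [c.name for c in classes]
    rng = np.random.default_rng(s_defect)
    n_defect = sc.n_nodata + sc.n_negative
    if n_defect:
        flat = rng.choice(sc.rows * sc.cols, size=n_defect, replace=False)
        defects = np.column_stack(np.unravel_index(flat, (sc.rows, sc.cols)))
    else:
        defects = np.empty((0, 2), int)
    truths = {}
    for year, conc, s_field, s_render in (
        (2018, sc.concentration_2018, s_f18, s_r18),
        (2022, sc.concentration_2022, s_f22, s_r22),
    ):
        field = generate_fraction_field(
            sc.rows,
            sc.cols,
            conc,
            smoothness_px=sc.smoothness_px,
            seed=s_field,
            class_names=names,
        )
        truths[year] = SceneTruth(
            fractions=field,
            library=library,
            noise_sd=sc.noise_sd,
            seed=s_render,
            corrupted_band_ranges=tuple(
                tuple(p) for p in cfg.preprocess.band_exclusions
            ),
            nodata_pixels=defects[: sc.n_nodata],
            negative_pixels=defects[sc.n_nodata :],
        )
    return truths, library


def _purity_regions(truth: SceneTruth, n_per_class: int, purity: float) -> RegionSet:
    """One-pixel square ROIs over the purest pixels of each class."""
    stack = truth.fractions
    frac = stack.fractions
    polygons, labels = [], []
    x0, y0 = stack.origin_xy
    p = stack.pixel_size_m
    excluded = np.zeros(stack.shape, dtype=bool)
    for r, c in np.concatenate([truth.nodata_pixels, truth.negative_pixels]):
        excluded[r, c] = True
    for ci, name in enumerate(stack.class_names):
        layer = np.where(excluded, -np.inf, frac[ci])
        order = np.argsort(layer, axis=None)[::-1][:n_per_class]
        rows, cols = np.unravel_index(order, stack.shape)
        if layer[rows[-1], cols[-1]] < purity:
            raise GrassunmixError(
                f"class {name!r} lacks {n_per_class} pixels of purity >= {purity}"
            )
        for r, c in zip(rows, cols):
            polygons.append(
                shapely.geometry.box(
                    x0 + c * p, y0 - (r + 1) * p, x0 + (c + 1) * p, y0 - r * p
                )
            )
            labels.append(name)
    return RegionSet(polygons=polygons, labels=labels)


def run_pipeline(config, out_dir: str, seed: int = None) -> dict:
    """Execute all stages; returns (and writes) the artifact manifest."""
    cfg = validate_config(config)
    if seed is not None:
        cfg.seed = int(seed)
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": {}, "files": {}}

    def record(stage, name, path, **summary):
        manifest["files"][os.path.relpath(path, out_dir)] = _sha256(path)
        manifest["stages"].setdefault(stage, {}).update(summary)

    def path_of(name):
        return os.path.join(out_dir, name)

    # ---- simulate -------------------------------------------------------
    truths, library = simulate_two_years(cfg)
    years = sorted(truths)
    cubes = {}
    for year in years:
        cube = render_cube(truths[year])
        cubes[year] = cube
        p = path_of(f"scene_{year}.tif")
        raster_io.write_cube(cube, p, dialect="geotiff")
        record("simulate", f"scene_{year}", p, noise_sd=cfg.scene.noise_sd)
        tp = path_of(f"truth_fractions_{year}.tif")
        raster_io.write_fraction_maps(truths[year].fractions, tp)
        record("simulate", f"truth_{year}", tp)
    lib_path = path_of("true_endmembers.csv")
    raster_io.write_library(library, lib_path)
    record("simulate", "library", lib_path, n_classes=library.n_classes)

    # ---- preprocess -----------------------------------------------------
    pre = {}
    for year in years:
        step1 = preprocess.exclude_bands(
            cubes[year], cfg.preprocess.band_exclusions
        )
        step2 = preprocess.mask_invalid(
            step1.cube, cfg.preprocess.sentinel, cfg.preprocess.min_valid
        )
        cube = step2.cube
        if cfg.preprocess.aoi:
            pts = json.load(open(cfg.preprocess.aoi))
            ring = pts["features"][0]["geometry"]["coordinates"][0]
            aoi = RegionSet(
                polygons=[shapely.geometry.Polygon(ring)], labels=["aoi"]
            )
            cube = preprocess.clip_to_polygon(cube, aoi).cube
        pre[year] = cube
        manifest["stages"].setdefault("preprocess", {})[str(year)] = {
            "n_valid_bands": step1.n_valid_bands,
            "n_masked_pixels": step2.n_newly_masked,
        }

    # ---- endmembers (from the later year, as a validation campaign would)
    regions = _purity_regions(
        truths[years[-1]], cfg.endmembers.n_regions_per_class, cfg.endmembers.purity
    )
    lib = eml.build_library(
        pre[years[-1]], regions, class_order=library.class_names
    )
    est_lib_path = path_of("estimated_endmembers.csv")
    raster_io.write_library(lib, est_lib_path)
    angles = eml.separability_matrix(lib)
    record(
        "endmembers",
        "library",
        est_lib_path,
        min_pairwise_angle_rad=float(
            angles[np.triu_indices(lib.n_classes, 1)].min()
        ),
    )

    # ---- unmix ----------------------------------------------------------
    stacks = {}
    for year in years:
        stack = linear_unmixing.unmix_cube(pre[year], lib, cfg.unmix.mode)
        stacks[year] = stack
        fp = path_of(f"fractions_{year}.tif")
        raster_io.write_fraction_maps(stack, fp)
        record(
            "unmix",
            f"fractions_{year}",
            fp,
            mode=cfg.unmix.mode,
            mean_rmse=float(
                np.nanmean(stack.residual_rmse[stack.pixel_valid])
            ),
        )

    # ---- trend ----------------------------------------------------------
    t1, t2 = cfg.trend.years
    trend_rows = []
    for name in lib.class_names:
        tr = change_trend.slope_map(
            stacks[years[0]].layer(name),
            stacks[years[-1]].layer(name),
            t1,
            t2,
            pixel_valid=stacks[years[0]].pixel_valid
            & stacks[years[-1]].pixel_valid,
            class_name=name,
        )
        _, counts = change_trend.classify_trend(tr, cfg.trend.breaks)
        mean, sd = change_trend.trend_summary(tr)
        trend_rows.append(
            {"class": name, "mean_slope": mean, "sd_slope": sd, **counts}
        )
    trend_path = path_of("trend_summary.csv")
    pd.DataFrame(trend_rows).to_csv(trend_path, index=False)
    record("trend", "summary", trend_path, years=[t1, t2])

    # ---- summarize ------------------------------------------------------
    histograms = []
    area_rows = []
    for year in years:
        stack = stacks[year]
        for i, name in enumerate(stack.class_names):
            h = abundance_summary.histogram_counts(
                stack.fractions[i],
                cfg.summary.n_bins,
                stack.pixel_valid,
                class_name=f"{name}_{year}",
            )
            histograms.append(h)
            area_rows.append(
                {
                    "class": name,
                    "year": year,
                    "area_ha": abundance_summary.weighted_area_ha(
                        stack.fractions[i],
                        stack.pixel_size_m**2,
                        stack.pixel_valid,
                    ),
                }
            )
    hist_path = path_of("abundance_bins.csv")
    abundance_summary.histogram_table(histograms).to_csv(hist_path, index=False)
    area_path = path_of("weighted_areas.csv")
    pd.DataFrame(area_rows).to_csv(area_path, index=False)
    record("summarize", "bins", hist_path, n_bins=cfg.summary.n_bins)
    record("summarize", "areas", area_path)

    # ---- validate -------------------------------------------------------
    s_points = _subseeds(cfg.seed + 1, 1)[0]
    points = sample_reference_points(
        truths[years[-1]],
        cfg.validate.n_per_class,
        cfg.validate.purity,
        seed=s_points,
    )
    pts_path = path_of("reference_points.csv")
    raster_io.write_points(points, pts_path)
    record("validate", "points", pts_path, n_points=len(points))
    for tau in cfg.validate.tau:
        predicted = accuracy_assessment.predicted_class_at_points(
            stacks[years[-1]], points, tau
        )
        cm = accuracy_assessment.confusion_matrix(
            points.labels, predicted, lib.class_names
        )
        table = accuracy_assessment.confusion_table(cm)
        cm_path = path_of(f"confusion_tau{int(round(tau * 100))}.csv")
        table.to_csv(cm_path)
        record(
            "validate",
            f"confusion_tau{tau}",
            cm_path,
            **{
                f"overall_accuracy_tau{tau}": table.attrs["overall_accuracy"],
                f"n_unclassified_tau{tau}": table.attrs["n_unclassified"],
            },
        )

    # ---- stats ----------------------------------------------------------
    by_class = {}
    for h in histograms:
        name, _, year = h.class_name.rpartition("_")
        by_class.setdefault(name, {})[int(year)] = h
    stats_rows = []
    for name, by_year in by_class.items():
        d = stats_tests.paired_bin_differences(
            by_year[years[0]], by_year[years[-1]]
        )
        sw = stats_tests.shapiro_wilk(d.astype(float))
        wx = stats_tests.wilcoxon_signed_rank_exact(
            by_year[years[0]].counts.astype(float),
            by_year[years[-1]].counts.astype(float),
        )
        stats_rows.append(
            {
                "class": name,
                "shapiro_W": sw.statistic,
                "shapiro_p": sw.p_two_sided,
                "wilcoxon_V": wx.statistic,
                "wilcoxon_p": wx.p_two_sided,
                "wilcoxon_method": wx.method,
            }
        )
    stats_path = path_of("change_tests.csv")
    pd.DataFrame(stats_rows).to_csv(stats_path, index=False)
    record("stats", "tests", stats_path)

    manifest_path = path_of("manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
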