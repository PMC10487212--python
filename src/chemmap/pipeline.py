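"""End-to-end pipeline: simulate -> preprocess -> register -> select ->
calibrate -> map -> evaluate.

Each stage reads its inputs from and writes its artifacts to one output
directory, so stages can be re-run individually; every stage derives its
own seed from the root seed and logs it.  The held-out validation fruit
never influence wavelength selection or model training: selection and
calibration see only the calibration and cross-validation rows.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import mapping as mp
from . import preprocess as pp
from . import registration as reg
from . import selection as sel
from . import synthetic as syn
from .config import PipelineConfig
from .envi import read_envi, write_envi
from .hypercube import Hypercube

log = logging.getLogger(__name__)

COMPOSITIONS = syn.COMPOSITIONS
METHODS = ("ranking_uncorrelatedness", "subset_selection")
MODALITIES = sel.MODALITIES


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_coerce))


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _mapped_fruit(cfg: PipelineConfig, plan: cal.PartitionPlan) -> list[tuple[int, int]]:
    """The validation fruit rendered as full hypercubes (first n_map_fruit)."""
    keys = [(o, f) for o in sorted(plan.validation_fruit)
            for f in plan.validation_fruit[o]]
    return keys[: cfg.n_map_fruit]


def _fruit_tag(origin: int, fruit: int) -> str:
    return f"o{origin}_f{fruit}"


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    """Reference table, availability table, partition plan, per-ROI spectra,
    and raw cubes for the fruit that will be mapped."""
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed("simulate")
    log.info("stage=simulate seed=%d", seed)

    ref = syn.generate_reference_table(
        design={"origins": cfg.origins, "fruit_per_origin": cfg.fruit_per_origin,
                "regions_per_fruit": cfg.regions_per_fruit},
        seed=seed,
    )
    syn.write_reference_table(ref, outdir / "reference_table.csv")

    avail = syn.generate_availability_table(cfg.availability_spec,
                                            seed=cfg.stage_seed("availability"))
    syn.write_availability_table(avail, outdir / "availability.csv")

    plan = cal.partition_dataset(
        ref, seed=cfg.stage_seed("partition"),
        validation_fruit_per_origin=cfg.validation_fruit_per_origin,
        calibration_frac=cfg.calibration_frac,
        cross_validation_frac=cfg.cross_validation_frac,
    )
    _json_dump(
        {"validation_fruit": plan.validation_fruit,
         "assignments": {k: v.tolist() for k, v in plan.assignments.items()},
         "seed": plan.seed},
        outdir / "partition.json",
    )

    optics = syn.default_optics(noise_sd=cfg.noise_sd)
    spectra = syn.simulate_roi_spectra(ref, optics, noise_sd=cfg.spectra_noise_sd,
                                       seed=cfg.stage_seed("spectra"))
    spectra.to_csv(outdir / "spectra.csv", index=False, float_format="%.8f")

    cube_dir = outdir / "cubes"
    cube_dir.mkdir(exist_ok=True)
    for origin, fruit in _mapped_fruit(cfg, plan):
        rows = ref[(ref["origin"] == origin) & (ref["fruit"] == fruit)]
        field = syn.generate_chemistry_field(
            rows, raster_shape=cfg.raster, mm_per_px=cfg.mm_per_px,
            gradient_spec={"ssc": {"axial": 0.8}, "cc": {"axial": 0.05}},
            seed=cfg.stage_seed(f"field_{origin}_{fruit}"),
            roi_diameter_mm=cfg.roi_diameter_mm,
        )
        tag = _fruit_tag(origin, fruit)
        np.savetxt(cube_dir / f"{tag}_roi_centers.csv",
                   np.column_stack([field.roi_centers, np.full(10, field.roi_radius_px)]),
                   delimiter=",", header="row,col,radius_px", comments="")
        for sensor in ("vis", "nir"):
            frames = syn.generate_hypercube(
                field, optics, sensor=sensor,
                seed=cfg.stage_seed(f"cube_{origin}_{fruit}_{sensor}"),
            )
            for kind, cube in frames.items():
                write_envi(cube_dir / f"{tag}_{sensor}_{kind}.hdr", cube)
        # landmark correspondences for the registration stage
        rng = np.random.default_rng(cfg.stage_seed(f"warp_{origin}_{fruit}"))
        true_t = _random_affine(rng, cfg.raster)
        scene = syn.generate_landmark_scene(field, true_t,
                                            seed=cfg.stage_seed(f"landmarks_{origin}_{fruit}"),
                                            jitter_sd=cfg.jitter_sd_px)
        syn.write_points_csv(cube_dir / f"{tag}_points.csv",
                             scene.control_pairs, scene.check_pairs)
        np.save(cube_dir / f"{tag}_distorted.npy", scene.image_distorted)


def _random_affine(rng, raster) -> reg.Transform2D:
    """Mild affine distortion: slight scale/rotation/shear plus translation."""
    cy, cx = (raster[0] - 1) / 2.0, (raster[1] - 1) / 2.0
    ang = np.deg2rad(rng.uniform(-4, 4))
    scale = rng.uniform(0.97, 1.03)
    shear = rng.uniform(0.03, 0.07) * rng.choice([-1, 1])
    A = scale * np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    A = A @ np.array([[1.0, shear], [0.0, 1.0]])
    t = rng.uniform(-4, 4, size=2)
    center = np.array([cx, cy])
    offset = center - A @ center + t
    M = np.eye(3)
    M[:2, :2] = A
    M[:2, 2] = offset
    return reg.Transform2D("affine", M)


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    """Calibrate, smooth, trim and fuse the rendered cubes to reflectance on
    the common 420-1600 nm grid."""
    seed = cfg.stage_seed("preprocess")
    log.info("stage=preprocess seed=%d", seed)
    cube_dir = outdir / "cubes"
    fused_dir = outdir / "fused"
    fused_dir.mkdir(exist_ok=True)

    tags = sorted({p.name.rsplit("_", 2)[0] for p in cube_dir.glob("*_vis_raw.hdr")})
    for tag in tags:
        per_sensor = {}
        for sensor in ("vis", "nir"):
            frames = {k: read_envi(cube_dir / f"{tag}_{sensor}_{k}.hdr")
                      for k in ("raw", "white", "black")}
            refl = pp.calibrate_reflectance(frames["raw"], frames["white"], frames["black"])
            refl = pp.smooth_savitzky_golay(refl, cfg.sg_window, cfg.sg_poly_order)
            per_sensor[sensor] = refl
        vis, nir = per_sensor["vis"], per_sensor["nir"]
        grid, fused, _ = pp.fuse_sensors(
            vis.wavelengths, vis.data, nir.wavelengths, nir.data,
            boundary=cfg.fusion_boundary_nm, lo=cfg.trim_lo_nm, hi=cfg.trim_hi_nm,
        )
        cube = Hypercube(fused, grid, sensor_id="fused", frame_kind="reflectance")
        write_envi(fused_dir / f"{tag}_fused.hdr", cube)


def stage_register(cfg: PipelineConfig, outdir: Path) -> None:
    """Fit the three transform families on each mapped fruit's landmarks,
    pick the winner, locate the sampling circles and build ROI masks."""
    seed = cfg.stage_seed("register")
    log.info("stage=register seed=%d", seed)
    cube_dir = outdir / "cubes"
    mask_dir = outdir / "roi_masks"
    mask_dir.mkdir(exist_ok=True)

    reports = {}
    for pts_path in sorted(cube_dir.glob("*_points.csv")):
        tag = pts_path.name.replace("_points.csv", "")
        control, check = syn.read_points_csv(pts_path)
        report = reg.compare_transforms(control, check)
        chosen = report.entries[report.chosen_kind]["transform"]
        reports[tag] = {
            "chosen": report.chosen_kind,
            **{k: {m: v[m] for m in ("rmse_reg", "mape_reg", "rmse_ch", "mape_ch")}
               for k, v in report.entries.items()},
        }

        distorted = np.load(cube_dir / f"{tag}_distorted.npy")
        radius = cfg.roi_diameter_mm / 2.0 / cfg.mm_per_px
        circles, _ = reg.detect_circles(
            distorted, (max(2, int(radius - 3)), int(radius + 3)), expected_count=10,
        )
        mask = reg.build_roi_mask(circles, cfg.raster, chosen)
        labelled = _relabel_by_layout(mask, cfg)
        write_envi(mask_dir / f"{tag}_roi.hdr",
                   Hypercube(labelled[:, :, None].astype(np.uint8), np.array([0.0]),
                             sensor_id="mask", frame_kind="reflectance"),
                   dtype=np.uint8)
    _json_dump(reports, outdir / "registration_report.json")


def _relabel_by_layout(mask: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Renumber detected discs to the canonical region layout by nearest
    expected centre."""
    expected = syn.roi_layout(cfg.raster, 0.47 * min(cfg.raster))
    out = np.zeros_like(mask)
    for label in np.unique(mask):
        if label == 0:
            continue
        member = mask == label
        centroid = np.array(np.nonzero(member)).mean(axis=1)
        region = int(np.argmin(np.sum((expected - centroid) ** 2, axis=1))) + 1
        out[member] = region
    return out


def stage_select(cfg: PipelineConfig, outdir: Path) -> None:
    """Availability-constrained wavelength selection per composition,
    modality and procedure, on the non-validation rows only."""
    seed = cfg.stage_seed("select")
    log.info("stage=select seed=%d", seed)
    spectra = pd.read_csv(outdir / "spectra.csv")
    avail = syn.read_availability_table(outdir / "availability.csv")
    plan = _load_plan(outdir)

    train_rows = np.concatenate([plan.rows("calibration"), plan.rows("cross_validation")])
    sub = spectra.iloc[np.sort(train_rows)]
    grid, X = pp.spectra_matrix(sub)

    results = []
    for comp in COMPOSITIONS:
        y = sub[syn.COLUMN_OF[comp]].to_numpy(dtype=float)
        for modality in MODALITIES:
            for method in METHODS:
                params = (
                    dict(top_n=cfg.top_n, r_threshold=cfg.r_threshold,
                         max_keep=cfg.max_keep, k_neighbors=cfg.k_neighbors)
                    if method == "ranking_uncorrelatedness"
                    else dict(stale_limit=cfg.stale_limit, max_size=cfg.max_keep)
                )
                res = sel.select_wavelengths(
                    X, y, grid, avail, modality, method=method, composition=comp,
                    random_state=seed, **params,
                )
                log.info("selected %d wavelengths for %s/%s/%s",
                         len(res.wavelengths_nm), comp, modality, method)
                results.append(res.to_dict())
    _json_dump(results, outdir / "selections.json")


def _load_plan(outdir: Path) -> cal.PartitionPlan:
    d = json.loads((outdir / "partition.json").read_text())
    return cal.PartitionPlan(
        validation_fruit={int(k): v for k, v in d["validation_fruit"].items()},
        assignments={k: np.array(v) for k, v in d["assignments"].items()},
        seed=d["seed"],
    )


def stage_calibrate(cfg: PipelineConfig, outdir: Path) -> None:
    """Replicate MLP training per candidate wavelength set; keep the winner
    per composition."""
    seed = cfg.stage_seed("calibrate")
    log.info("stage=calibrate seed=%d", seed)
    spectra = pd.read_csv(outdir / "spectra.csv")
    selections = json.loads((outdir / "selections.json").read_text())
    plan = _load_plan(outdir)

    model_dir = outdir / "models"
    model_dir.mkdir(exist_ok=True)
    hyper = dict(hidden_units=cfg.hidden_units, learning_rate=cfg.learning_rate,
                 max_val_fail=cfg.max_val_fail, mse_goal=cfg.mse_goal,
                 max_epochs=cfg.max_epochs)
    for comp in COMPOSITIONS:
        sets = {}
        for s in selections:
            if s["composition"] == comp and s["wavelengths_nm"]:
                name = f"{s['method']}_{s['modality']}"
                sets[name] = s["wavelengths_nm"]
        best, table = cal.replicate_and_select(
            sets, plan, spectra, comp, n_replicates=cfg.n_replicates,
            seed=seed, hyper=hyper,
        )
        (model_dir / f"{comp}.json").write_text(best.to_json())
        table.to_csv(model_dir / f"{comp}_metrics.csv", index=False)
        log.info("composition=%s winner=%s cv_R=%.3f", comp,
                 best.wavelengths_nm, best.metrics["cross_validation"]["R"])


def stage_map(cfg: PipelineConfig, outdir: Path) -> None:
    """Pixel-wise prediction maps for the mapped validation fruit."""
    seed = cfg.stage_seed("map")
    log.info("stage=map seed=%d", seed)
    fused_dir = outdir / "fused"
    mask_dir = outdir / "roi_masks"
    model_dir = outdir / "models"
    map_dir = outdir / "maps"
    map_dir.mkdir(exist_ok=True)

    models = {c: cal.CalibrationModel.from_json((model_dir / f"{c}.json").read_text())
              for c in COMPOSITIONS}
    stats = {}
    for fused_path in sorted(fused_dir.glob("*_fused.hdr")):
        tag = fused_path.name.replace("_fused.hdr", "")
        cube = read_envi(fused_path)
        flat, shape = mp.flatten_hypercube(cube)
        fg = mp.background_mask(cube, method=cfg.mask_method,
                                threshold=cfg.mask_threshold)
        for comp, model in models.items():
            dmap = mp.predict_map(model, flat, fg, shape, cube.wavelengths)
            dmap.units = syn.UNITS[comp]
            write_envi(map_dir / f"{tag}_{comp}.hdr",
                       Hypercube(np.nan_to_num(dmap.values, nan=0.0)[:, :, None],
                                 np.array([0.0]), sensor_id="map",
                                 frame_kind="reflectance"))
            mp.export_map_png(dmap, map_dir / f"{tag}_{comp}.png")
            stats[f"{tag}_{comp}"] = mp.map_histogram_stats(dmap)
    _json_dump(stats, outdir / "map_histogram_stats.json")


def stage_evaluate(cfg: PipelineConfig, outdir: Path) -> None:
    """Region-wise reliability of the maps plus the final pipeline report."""
    seed = cfg.stage_seed("evaluate")
    log.info("stage=evaluate seed=%d", seed)
    ref = syn.read_reference_table(outdir / "reference_table.csv")
    model_dir = outdir / "models"
    models = {c: cal.CalibrationModel.from_json((model_dir / f"{c}.json").read_text())
              for c in COMPOSITIONS}

    maps, roi_masks = {}, {}
    for fused_path in sorted((outdir / "fused").glob("*_fused.hdr")):
        tag = fused_path.name.replace("_fused.hdr", "")
        origin, fruit = (int(x[1:]) for x in tag.split("_"))
        cube = read_envi(fused_path)
        flat, shape = mp.flatten_hypercube(cube)
        fg = mp.background_mask(cube, method=cfg.mask_method,
                                threshold=cfg.mask_threshold)
        roi = read_envi(outdir / "roi_masks" / f"{tag}_roi.hdr").data[:, :, 0].astype(int)
        roi_masks[(origin, fruit)] = roi
        maps[(origin, fruit)] = {
            c: mp.predict_map(m, flat, fg, shape, cube.wavelengths)
            for c, m in models.items()
        }

    region_tables = {}
    tukey = {}
    for comp in COMPOSITIONS:
        comp_maps = {k: v[comp] for k, v in maps.items()}
        table, per_region = mp.regionwise_errors(comp_maps, roi_masks, ref, comp)
        table.to_csv(outdir / f"region_errors_{comp}.csv", index=False)
        region_tables[comp] = table.to_dict(orient="records")
        if all(len(v) >= 2 for v in per_region.values()):
            tukey[comp] = mp.tukey_regions(per_region, alpha=cfg.tukey_alpha)
        else:
            tukey[comp] = None  # needs >= 2 mapped fruit

    selections = json.loads((outdir / "selections.json").read_text())
    report = {
        "stage_seeds": {s: cfg.stage_seed(s) for s in
                        ("simulate", "preprocess", "register", "select",
                         "calibrate", "map", "evaluate")},
        "selections": selections,
        "models": {c: {"wavelengths_nm": models[c].wavelengths_nm,
                       "metrics": models[c].metrics} for c in COMPOSITIONS},
        "region_errors": region_tables,
        "tukey_letters": tukey,
    }
    _json_dump(report, outdir / "report.json")


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "register": stage_register,
    "select": stage_select,
    "calibrate": stage_calibrate,
    "map": stage_map,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage in order; returns the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    for name, fn in STAGES.items():
        try:
            fn(cfg, outdir)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {name!r} failed (seed {cfg.stage_seed(name)}): {exc}"
            ) from exc
    return outdir
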