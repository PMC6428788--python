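"""End-to-end orchestration: config handling, the plan pipeline, evaluation.

``run_plan`` executes segment-scar -> surface maps -> target planning ->
export from a single configuration mapping, writing the mesh (PLY plus a
per-vertex scalar CSV), the plan JSON, per-target DICOM treatment datasets
and a run manifest carrying the configuration hash.  ``run_evaluate`` scores
retrieved injection positions against the planned IBZ band and compares the
study groups on per-animal means.

All configuration defaults resolve without a config file; a YAML/JSON file
only overrides them.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cartoplan import dicom_io
from cartoplan.cardiac_maps import ContourStack, compute_surface_maps
from cartoplan.evaluation import (InjectionRecord, evaluate_injections,
                                  per_animal_summary)
from cartoplan.planner import PlannerConfig, TargetPlan, assign_targets
from cartoplan.scarseg import ScarSegmentation, myocardial_masks, segment_volume
from cartoplan.stats import GroupStats, ttest_from_summary

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "paths": {"image": None, "contours": None, "scar": None, "ra_cloud": None,
              "out_dir": "cartoplan_out"},
    "scarseg": {"min_component_px": 5, "reference": "min", "per_volume": False},
    "planner": {"transmurality_low": 1.0, "transmurality_high": 20.0, "wt_min": 5.0,
                "n_targets": 16, "sector_split": {"septal": 8, "anterior": 8},
                "needle_depth_fraction": 0.5, "septal_direction": [1.0, 0.0]},
    "maps": {"points_per_slice": 120},
    "registration": {"max_iter": 100, "tol": 1e-4, "trim_fraction": 0.2},
    "export": {"marker_radius_mm": 2.0, "endo_subsample": 4},
    "phantom": {},
    "seed": 0,
}


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults <- config file <- explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _deep_update(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


def planner_config(cfg: dict) -> PlannerConfig:
    p = cfg["planner"]
    return PlannerConfig(
        transmurality_low=p["transmurality_low"],
        transmurality_high=p["transmurality_high"],
        wt_min=p["wt_min"], n_targets=p["n_targets"],
        sector_split=dict(p["sector_split"]),
        needle_depth_fraction=p["needle_depth_fraction"],
        septal_direction=np.asarray(p["septal_direction"], dtype=float),
    )


def segment_from_config(volume, stack: ContourStack, cfg: dict) -> ScarSegmentation:
    """Rasterize the myocardial mask from contours and run FWHM segmentation."""
    sc = cfg["scarseg"]
    shape = volume.data.shape[1:]
    origin = volume.origin[:2]
    spacing = float(volume.spacing[0])
    myo = myocardial_masks(stack, shape, origin, spacing)
    return segment_volume(list(volume.data), myo, spacing, origin=origin,
                          zs=stack.zs, min_component_px=sc["min_component_px"],
                          reference=sc["reference"], per_volume=sc["per_volume"])


def scar_from_nifti(path, stack: ContourStack):
    """Load a scar mask volume (e.g. written by segment-scar) as ScarSegmentation."""
    from cartoplan.image import ImageVolume

    vol = ImageVolume.from_nifti(path)
    return ScarSegmentation(masks=[vol.data[k] > 0.5 for k in range(vol.n_slices)],
                            thresholds=[np.nan] * vol.n_slices,
                            origin=vol.origin[:2], spacing=float(vol.spacing[0]),
                            zs=stack.zs)


def run_plan(config: dict) -> TargetPlan:
    """Execute segment-scar -> maps -> plan -> export; returns the plan.

    Stage failures propagate with the stage name prefixed, so a pipeline
    error always says where it happened.
    """
    paths = config["paths"]
    if paths.get("image") is None or paths.get("contours") is None:
        raise FileNotFoundError("config must provide paths.image and paths.contours")
    for key in ("image", "contours"):
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"{key} path does not exist: {paths[key]}")
    out_dir = Path(paths.get("out_dir") or "cartoplan_out")
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    volume = stage("read-image", lambda: dicom_io.read_lge_series(paths["image"]))
    stack = stage("read-contours", lambda: ContourStack.from_json(paths["contours"]))
    scar = stage("segment-scar", lambda: segment_from_config(volume, stack, config))
    emap = stage("maps", lambda: compute_surface_maps(
        stack, scar, points_per_slice=config["maps"]["points_per_slice"]))
    pcfg = planner_config(config)
    plan = stage("plan", lambda: assign_targets(emap, pcfg))

    chash = dicom_io.config_hash(config)
    stage("export", lambda: _export_outputs(config, out_dir, volume, scar, emap,
                                            plan, chash))
    logger.info("plan complete: %d targets -> %s", len(plan.targets), out_dir)
    return plan


def _export_outputs(config, out_dir: Path, volume, scar, emap, plan, chash) -> None:
    emap.save_ply(out_dir / "endo_mesh.ply", scalar_csv=out_dir / "endo_map.csv")
    plan.to_json(out_dir / "plan.json")
    pd.DataFrame({"slice": np.arange(len(scar.thresholds)),
                  "threshold": scar.thresholds}).to_csv(
        out_dir / "fwhm_thresholds.csv", index=False)
    exp = config["export"]
    dicom_io.write_treatment_datasets(
        plan, emap, volume, out_dir / "treatment_datasets",
        marker_radius=exp["marker_radius_mm"], endo_subsample=exp["endo_subsample"],
        base_series_reference=str(config["paths"]["image"]), config_hash=chash)
    manifest = {"config": _jsonable(config), "config_hash": chash,
                "n_targets": len(plan.targets)}
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def read_injections_csv(path) -> list[InjectionRecord]:
    """Injections CSV: animal_id, group, x_mm, y_mm and z_mm or slice_index."""
    df = pd.read_csv(path)
    if df.empty:
        return []
    records = []
    for _, row in df.iterrows():
        if "z_mm" in df.columns and pd.notna(row.get("z_mm")):
            pos = [row["x_mm"], row["y_mm"], row["z_mm"]]
            sl = None
        else:
            pos = [row["x_mm"], row["y_mm"]]
            sl = int(row["slice_index"])
        records.append(InjectionRecord(
            animal_id=str(row["animal_id"]), position=np.asarray(pos, dtype=float),
            group_label=str(row.get("group", "planned")), slice_index=sl))
    return records


def run_evaluate(config: dict, injections_csv) -> dict:
    """Score injections and compare groups; writes the three summary tables.

    Returns a dict with the per-injection, per-animal and group-comparison
    DataFrames.  An empty injections file yields empty outputs with a
    warning rather than an error.
    """
    paths = config["paths"]
    out_dir = Path(paths.get("out_dir") or "cartoplan_out")
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_injections_csv(injections_csv)
    if not records:
        logger.warning("no injections in %s; writing empty outputs", injections_csv)
        empty = pd.DataFrame()
        empty.to_csv(out_dir / "injections_scored.csv", index=False)
        empty.to_csv(out_dir / "per_animal.csv", index=False)
        empty.to_csv(out_dir / "group_comparison.csv", index=False)
        return {"per_injection": empty, "per_animal": empty, "comparison": empty}

    volume = dicom_io.read_lge_series(paths["image"])
    stack = ContourStack.from_json(paths["contours"])
    if paths.get("scar"):
        scar = scar_from_nifti(paths["scar"], stack)
    else:
        scar = segment_from_config(volume, stack, config)
    emap = compute_surface_maps(stack, scar,
                                points_per_slice=config["maps"]["points_per_slice"])
    pcfg = planner_config(config)

    per_injection = evaluate_injections(stack, emap, pcfg, records)
    per_animal = per_animal_summary(per_injection)

    comparison = pd.DataFrame()
    groups = per_animal["group"].unique()
    if len(groups) == 2:
        rows = []
        for col, name in (("mean_distance_mm", "distance to IBZ (mm)"),
                          ("mean_depth_mm", "injection depth (mm)")):
            a = per_animal[per_animal["group"] == groups[0]][col].to_numpy()
            b = per_animal[per_animal["group"] == groups[1]][col].to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                res = ttest_from_summary(GroupStats.from_sample(groups[0], a),
                                         GroupStats.from_sample(groups[1], b))
                rows.append({"endpoint": name,
                             f"{groups[0]}_mean": np.mean(a), f"{groups[0]}_sd": np.std(a, ddof=1),
                             f"{groups[1]}_mean": np.mean(b), f"{groups[1]}_sd": np.std(b, ddof=1),
                             "t": res.statistic, "df": res.df, "p": res.p})
        comparison = pd.DataFrame(rows)

    per_injection.to_csv(out_dir / "injections_scored.csv", index=False)
    per_animal.to_csv(out_dir / "per_animal.csv", index=False)
    comparison.to_csv(out_dir / "group_comparison.csv", index=False)
    return {"per_injection": per_injection, "per_animal": per_animal,
            "comparison": comparison}
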