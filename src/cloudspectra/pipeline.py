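"""End-to-end orchestration: simulate → calibrate → register → map → segment.

Each stage reads the artifacts of its predecessors from the run directory,
writes its own artifacts plus a JSON run report (resolved parameters, seed,
counts, warnings), and is individually re-runnable.  The registration stage
is optional: the synthetic generator emits poses already in the reference
frame, and registration exists to fix multispectral pose error when the two
clouds come from separate reconstructions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import radiometry as rad
from .cloud import PointCloud, read_cloud, write_cloud
from .geometry import read_camera_sidecar, write_camera_sidecar
from .mapping import MappingParams, enrich_cloud
from .radiometry import BANDS, ReflectanceImage, compute_reflectance, panel_calibration
from .registration import IcpParams, RigidTransform, icp
from .segmentation import (SegmentationParams, divisive_cluster, label_cloud,
                           standardize)
from .synthetic import (PanelShot, default_reference_scene, generate_scene,
                        panel_shots, render_views)

__all__ = ["PipelineConfig", "run", "STAGES"]

log = logging.getLogger("cloudspectra")

STAGES = ("simulate", "calibrate", "register", "map", "segment")

# spatial coordinates support the clustering but are not material properties;
# they are down-weighted so geometry cannot dominate the spectral signature
DEFAULT_FEATURE_WEIGHTS = {"x": 0.35, "y": 0.35, "z": 0.35}

_KNOWN_KEYS = {
    "output_dir", "seed", "scene", "mapping", "registration", "segmentation",
    "log_level",
}
_SCENE_KEYS = {"total_points", "image_noise_rel_sd", "n_cameras"}
_MAPPING_KEYS = {"neighbor_radius", "normal_angle_max"}
_REG_KEYS = {"max_iter", "tol", "max_normal_angle", "max_dist",
             "reference_cloud", "source_cloud"}
_SEG_KEYS = {"min_size", "n_init", "max_depth", "exact_threshold",
             "features", "weights"}


@dataclass
class PipelineConfig:
    output_dir: str = "cloudspectra_run"
    seed: int = 0
    scene: dict = field(default_factory=dict)
    mapping: dict = field(default_factory=dict)
    registration: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for sub, keys in (("scene", _SCENE_KEYS), ("mapping", _MAPPING_KEYS),
                          ("registration", _REG_KEYS), ("segmentation", _SEG_KEYS)):
            unknown = set(getattr(self, sub)) - keys
            if unknown:
                raise ValueError(f"unknown {sub} config keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _report(out: Path, stage: str, payload: dict) -> None:
    payload = {"stage": stage, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
               **payload}
    with open(out / f"report_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sc = cfg.scene
    config = default_reference_scene(
        seed=cfg.seed,
        total_points=int(sc.get("total_points", 10000)),
        image_noise_rel_sd=float(sc.get("image_noise_rel_sd", 0.01)))
    if "n_cameras" in sc:
        config.n_cameras = int(sc["n_cameras"])
    scene = generate_scene(config)
    captures = render_views(scene)
    write_cloud(scene.cloud, out / "scene.ply")
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for ci, cap in enumerate(captures):
        write_camera_sidecar(img_dir / f"cam{ci:02d}.yaml", cap.pose, cap.model)
        for b in BANDS:
            tifffile.imwrite(img_dir / f"cam{ci:02d}_{b}.tif",
                             cap.raw[b].astype(np.float32))
            rad.write_radiometry_sidecar(img_dir / f"cam{ci:02d}_{b}.yaml",
                                         cap.calibrations[b], cap.readings[b])
    shots = panel_shots(config)
    shots_doc = {
        b: [{"known_reflectance": s.known_reflectance, "mean_pixel": s.mean_pixel,
             "nu": s.reading.nu, "gain": s.reading.gain, "tau": s.reading.tau,
             "sun_angle": s.reading.sun_angle,
             "f_number": s.calibration.f_number, "iso": s.calibration.iso,
             "exposure": s.calibration.exposure, "A": s.calibration.A,
             "B": s.calibration.B, "C": s.calibration.C}
            for s in shots[b]]
        for b in BANDS}
    with open(out / "panel_shots.yaml", "w") as fh:
        yaml.safe_dump(shots_doc, fh, sort_keys=True)
    _report(out, "simulate", {
        "seed": cfg.seed, "n_points": len(scene.cloud),
        "n_cameras": config.n_cameras,
        "materials": {m.name: m.n_points for m in config.materials},
        "image_noise_rel_sd": config.image_noise_rel_sd})
    log.info("simulate: %d points, %d cameras", len(scene.cloud), config.n_cameras)


def _load_panel_shots(out: Path) -> dict[str, list[PanelShot]]:
    with open(out / "panel_shots.yaml") as fh:
        doc = yaml.safe_load(fh)
    shots: dict[str, list[PanelShot]] = {}
    for b, entries in doc.items():
        shots[b] = [
            PanelShot(
                band=b, known_reflectance=e["known_reflectance"],
                mean_pixel=e["mean_pixel"],
                reading=rad.SunshineReading(nu=e["nu"], gain=e["gain"],
                                            tau=e["tau"], sun_angle=e["sun_angle"]),
                calibration=rad.BandCalibration(
                    band=b, f_number=e["f_number"], iso=e["iso"],
                    exposure=e["exposure"], A=e["A"], B=e["B"], C=e["C"]))
            for e in entries]
    return shots


def _stage_calibrate(cfg: PipelineConfig, out: Path) -> None:
    img_dir = out / "images"
    if not (out / "panel_shots.yaml").exists():
        raise FileNotFoundError(
            "panel_shots.yaml not found: run the 'simulate' stage (or supply "
            "panel shots) first")
    shots = _load_panel_shots(out)
    ks = {}
    clip_total = 0
    for b in BANDS:
        cal_k = panel_calibration(shots[b])
        ks[b] = cal_k.K
    with open(out / "band_k.json", "w") as fh:
        json.dump(ks, fh, indent=1, sort_keys=True)
    for raw_path in sorted(img_dir.glob("cam*_*.tif")):
        stem = raw_path.stem
        band = stem.rsplit("_", 1)[1]
        cal, reading = rad.read_radiometry_sidecar(img_dir / f"{stem}.yaml")
        from dataclasses import replace
        cal = replace(cal, K=ks[band])
        raw = tifffile.imread(raw_path).astype(np.float64)
        refl = compute_reflectance(raw, cal, reading)
        clip_total += compute_reflectance.last_clip_count
        tifffile.imwrite(img_dir / f"{stem}_refl.tif", refl.astype(np.float32))
    _report(out, "calibrate", {"K": ks, "clipped_pixels": clip_total})
    log.info("calibrate: K=%s", ks)


def _stage_register(cfg: PipelineConfig, out: Path) -> None:
    rc = cfg.registration
    ref_path = rc.get("reference_cloud", str(out / "scene.ply"))
    src_path = rc.get("source_cloud")
    if src_path is None:
        # synthetic captures are already in the reference frame
        RigidTransform.identity().save(out / "transform.json")
        _report(out, "register", {"skipped": True,
                                  "reason": "no source cloud; poses already aligned"})
        log.info("register: skipped (aligned poses)")
        return
    reference = read_cloud(ref_path)
    source = read_cloud(src_path)
    params = IcpParams(max_iter=int(rc.get("max_iter", 50)),
                       tol=float(rc.get("tol", 1e-12)),
                       max_dist=rc.get("max_dist", np.inf),
                       max_normal_angle=float(rc.get("max_normal_angle", 60.0)))
    T, report = icp(source, reference, params)
    T.save(out / "transform.json")
    _report(out, "register", {
        "skipped": False, "iterations": report.iterations,
        "rmse": report.rmse, "converged": report.converged,
        "params": asdict(params)})
    log.info("register: rmse=%.3g after %d iterations", report.rmse, report.iterations)


def _stage_map(cfg: PipelineConfig, out: Path) -> None:
    img_dir = out / "images"
    if not (out / "scene.ply").exists():
        raise FileNotFoundError("scene.ply not found: run the 'simulate' stage first")
    cloud = read_cloud(out / "scene.ply")
    cam_files = sorted(img_dir.glob("cam??.yaml"))
    if not cam_files:
        raise FileNotFoundError("no camera sidecars: run the 'simulate' stage first")
    poses, models, images = [], [], []
    for cam_file in cam_files:
        pose, model = read_camera_sidecar(cam_file)
        bands = {}
        for b in BANDS:
            refl_path = img_dir / f"{cam_file.stem}_{b}_refl.tif"
            if not refl_path.exists():
                raise FileNotFoundError(
                    f"{refl_path.name} not found: run the 'calibrate' stage first")
            bands[b] = ReflectanceImage(b, tifffile.imread(refl_path).astype(np.float64))
        poses.append(pose)
        models.append(model)
        images.append(bands)
    params = MappingParams(
        neighbor_radius=cfg.mapping.get("neighbor_radius"),
        normal_angle_max=float(cfg.mapping.get("normal_angle_max", 60.0)))
    enriched, report = enrich_cloud(cloud, images, poses, models, params)
    write_cloud(enriched, out / "enriched.ply")
    _report(out, "map", {
        "n_points": report.n_points, "n_enriched": report.n_enriched,
        "per_band_coverage": report.per_band_coverage,
        "per_camera_visible": report.per_camera_visible})
    log.info("map: %d/%d points enriched", report.n_enriched, report.n_points)


def _stage_segment(cfg: PipelineConfig, out: Path) -> None:
    if not (out / "enriched.ply").exists():
        raise FileNotFoundError("enriched.ply not found: run the 'map' stage first")
    cloud = read_cloud(out / "enriched.ply")
    sc = cfg.segmentation
    admitted = np.nonzero(cloud.attributes["enriched"] == 1)[0]
    sub = cloud.select(admitted)
    weights = dict(DEFAULT_FEATURE_WEIGHTS)
    weights.update(sc.get("weights", {}))
    features = standardize(sub, sc.get("features"), weights)
    params = SegmentationParams(
        seed=cfg.seed, n_init=int(sc.get("n_init", 10)),
        min_size=int(sc.get("min_size", 10)),
        max_depth=int(sc.get("max_depth", 32)),
        exact_threshold=int(sc.get("exact_threshold", 2000)))
    result = divisive_cluster(features, params)
    labeled = label_cloud(result, cloud, admitted)
    write_cloud(labeled, out / "labeled.ply")
    result.save_tree(out / "cluster_tree.json")
    _report(out, "segment", {
        "n_admitted": len(admitted), "n_leaves": result.n_leaves,
        "leaf_sizes": [result.nodes[i].size for i in result.leaf_ids],
        "params": asdict(params), "feature_weights": weights})
    log.info("segment: %d material clusters", result.n_leaves)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "calibrate": _stage_calibrate,
    "register": _stage_register,
    "map": _stage_map,
    "segment": _stage_segment,
}


def run(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Execute the requested stages in pipeline order; returns the run dir."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(name)s %(levelname)s %(message)s")
    for stage in ordered:
        log.info("--- stage %s ---", stage)
        _STAGE_FN[stage](cfg, out)
    return out
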