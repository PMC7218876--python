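"""Reproducible evaluation studies for the full pipeline.

Each function sets up its own synthetic inputs from a seed, runs the
relevant part of the pipeline, and returns summary metrics.  They back both
the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

from .cloud import build_index
from .geometry import fisheye_project, fisheye_unproject
from .mapping import MappingParams, enrich_cloud, visible_points
from .radiometry import (BANDS, BandCalibration, ReflectanceImage,
                         SunshineReading, compute_reflectance, panel_calibration,
                         simulate_pixel)
from .registration import IcpParams, RigidTransform, icp
from .segmentation import (FeatureMatrix, SegmentationParams, divisive_cluster,
                           standardize)
from .synthetic import (MaterialSpec, SceneConfig, _fisheye_from_config,
                        default_reference_scene, gaussian_mixture,
                        generate_scene, look_at_pose, panel_shots,
                        perturb_cloud, ray_cast_visible, render_views)

__all__ = [
    "radiometric_roundtrip_study",
    "projection_study",
    "occlusion_agreement_study",
    "icp_recovery_study",
    "cluster_recovery_study",
    "end_to_end_study",
]


def radiometric_roundtrip_study(seed: int = 0, n: int = 1000,
                                noise_rel_sd: float = 0.01) -> dict:
    """Synthesize raw pixels from known reflectances, recover them.

    Draws (R_true, radiometry) at random with R_true in [0.05, 0.9] and sun
    angle in [0°, 80°]; reports the max relative error of the noise-free
    chain and the median relative error with multiplicative pixel noise.
    """
    rng = np.random.default_rng(seed)
    errs_clean = np.empty(n)
    errs_noisy = np.empty(n)
    for i in range(n):
        r_true = rng.uniform(0.05, 0.9)
        reading = SunshineReading(nu=rng.uniform(500, 5000),
                                  gain=rng.uniform(0.5, 4.0),
                                  tau=rng.uniform(1e-4, 1e-2),
                                  sun_angle=rng.uniform(0.0, 80.0))
        cal = BandCalibration(band=BANDS[i % 4],
                              f_number=rng.uniform(1.8, 4.0),
                              iso=rng.uniform(50, 800),
                              exposure=rng.uniform(1e-4, 1e-2),
                              A=rng.uniform(0.5, 20.0),
                              B=rng.uniform(0, 500.0),
                              C=rng.uniform(0.0, 0.1),
                              K=rng.uniform(0.5, 2.5))
        pixel = simulate_pixel(r_true, cal, reading)
        r_back = compute_reflectance(pixel, cal, reading)
        errs_clean[i] = abs(r_back - r_true) / r_true
        noisy = pixel * (1.0 + rng.normal(scale=noise_rel_sd))
        r_noisy = compute_reflectance(noisy, cal, reading)
        errs_noisy[i] = abs(r_noisy - r_true) / r_true
    return {"n": n,
            "max_rel_error_noise_free": float(errs_clean.max()),
            "median_rel_error_noisy": float(np.median(errs_noisy))}


def projection_study(seed: int = 0, n: int = 1000) -> dict:
    """Fisheye projection vs symbolic substitution + unproject∘project identity."""
    rng = np.random.default_rng(seed)
    # symbolic-substitution cases: zero-distortion model, pixel position known
    # in closed form: rho = theta = (2/pi) arctan(r/Z)
    sub_err = 0.0
    for _ in range(20):
        s = rng.uniform(50, 400)
        cx, cy = rng.uniform(100, 500, 2)
        from .geometry import FisheyeModel
        model = FisheyeModel(p2=0, p3=0, p4=0,
                             affine=np.array([[s, 0.0], [0.0, s]]),
                             principal_point=(cx, cy), image_size=(4000, 4000))
        X, Y = rng.uniform(-1, 1, 2)
        Z = rng.uniform(0.5, 3.0)
        r = math.hypot(X, Y)
        theta = (2 / math.pi) * math.atan2(r, Z)
        expect = (s * theta * X / r + cx, s * theta * Y / r + cy)
        pix, ok = fisheye_project(model, np.array([X, Y, Z]))
        assert ok
        sub_err = max(sub_err, float(np.hypot(pix[0] - expect[0],
                                              pix[1] - expect[1])))
    # the fixed worked case: (1, 0, 1) -> (0.5 s + cx, cy)
    from .geometry import FisheyeModel
    model = FisheyeModel(p2=0, p3=0, p4=0,
                         affine=np.array([[100.0, 0.0], [0.0, 100.0]]),
                         principal_point=(320.0, 240.0), image_size=(640, 480))
    pix, _ = fisheye_project(model, np.array([1.0, 0.0, 1.0]))
    sub_err = max(sub_err, float(np.hypot(pix[0] - 370.0, pix[1] - 240.0)))

    model = FisheyeModel(p2=0.05, p3=-0.03, p4=0.01,
                         affine=np.array([[150.0, 2.0], [-1.0, 148.0]]),
                         principal_point=(320.0, 240.0), image_size=(10000, 10000))
    theta = rng.uniform(0.01, 0.95, n)
    psi = rng.uniform(0, 2 * math.pi, n)
    alpha = theta * math.pi / 2
    pts = np.column_stack([np.sin(alpha) * np.cos(psi),
                           np.sin(alpha) * np.sin(psi), np.cos(alpha)])
    pix, ok = fisheye_project(model, pts)
    rays = fisheye_unproject(model, pix)
    pix2, _ = fisheye_project(model, rays)
    ident_err = float(np.abs(pix2 - pix).max())
    return {"n": n, "substitution_max_px_error": sub_err,
            "unproject_project_max_px_error": ident_err}


def _occlusion_case(materials, cam_center, look_at, seed) -> float:
    cfg = SceneConfig(materials=materials, seed=seed, n_cameras=1)
    scene = generate_scene(cfg)
    model = _fisheye_from_config(cfg.fisheye)
    pose = look_at_pose(cam_center, look_at)
    oracle = ray_cast_visible(scene, pose.center)
    mask = visible_points(scene.cloud, pose, model, MappingParams(),
                          build_index(scene.cloud))
    infr = mask.states != 0
    return float((mask.visible[infr] == oracle[infr]).mean())


def occlusion_agreement_study(seed: int = 0) -> dict:
    """Surfel-disk visibility vs exact ray casting on the two benchmark scenes."""
    sig = dict(color=(0.5, 0.5, 0.5),
               reflectance={b: 0.2 for b in BANDS})
    two_plane = [
        MaterialSpec("front", "plane", {"center": (0, 0, 1.0), "size": (2.0, 2.0)},
                     **sig, n_points=800),
        MaterialSpec("back", "plane", {"center": (0, 0, 0.0), "size": (8.0, 8.0)},
                     **sig, n_points=1200),
    ]
    sphere_plane = [
        MaterialSpec("sphere", "sphere", {"center": (0, 0, 1.0), "radius": 1.0},
                     **sig, n_points=1000),
        MaterialSpec("plane", "plane", {"center": (0, 0, 0.0), "size": (8.0, 8.0)},
                     **sig, n_points=1000),
    ]
    a = _occlusion_case(two_plane, (0.1, 0.07, 8.0), (0, 0, 0.5), seed)
    b = _occlusion_case(sphere_plane, (8.0, 0.0, 2.0), (0, 0, 0.5), seed + 1)
    return {"n": 4000, "two_plane_agreement_pct": 100.0 * a,
            "sphere_plane_agreement_pct": 100.0 * b}


def icp_recovery_study(seed: int = 0, n_trials: int = 200,
                       n_points: int = 5000) -> dict:
    """Noise-free rigid-perturbation recovery rate and residual RMSE."""
    cfg = default_reference_scene(seed=seed, total_points=n_points)
    cloud = generate_scene(cfg).cloud
    bbox = float(np.ptp(cloud.positions, axis=0).max())
    rng = np.random.default_rng(seed + 1)
    success = 0
    rmses = []
    for _ in range(n_trials):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0, 10.0)
        R = Rotation.from_rotvec(np.radians(ang) * axis).as_matrix()
        t = rng.uniform(-0.2, 0.2, 3) * bbox
        T_true = RigidTransform(R, t)
        source = perturb_cloud(cloud, T_true.inverse())
        T, rep = icp(source, cloud, IcpParams(max_iter=60))
        rot_err = RigidTransform(T.rotation @ T_true.rotation.T,
                                 np.zeros(3)).rotation_angle_deg()
        tr_err = float(np.linalg.norm(T.translation - T_true.translation)) / bbox
        if rot_err < 0.5 and tr_err < 0.01:
            success += 1
        rmses.append(rep.rmse)
    return {"n": n_trials,
            "success_rate_pct": 100.0 * success / n_trials,
            "median_rmse": float(np.median(rmses))}


def cluster_recovery_study(seed: int = 0, n_datasets: int = 50,
                           n_points: int = 5000) -> dict:
    """Leaf-count recovery and ARI on well-separated Gaussian mixtures."""
    rng = np.random.default_rng(seed)
    correct = 0
    aris = []
    for i in range(n_datasets):
        k = int(rng.integers(2, 9))
        X, truth = gaussian_mixture(k, n=n_points,
                                    seed=int(rng.integers(0, 2**31 - 1)))
        d = X.shape[1]
        fm = FeatureMatrix(X, [f"f{j}" for j in range(d)], np.zeros(d),
                           np.ones(d), np.ones(d))
        res = divisive_cluster(fm, SegmentationParams(seed=seed + 31 * i))
        if res.n_leaves == k:
            correct += 1
            aris.append(adjusted_rand_score(truth, res.labels))
    return {"n": n_datasets,
            "count_recovery_pct": 100.0 * correct / n_datasets,
            "min_ari_when_correct": float(np.min(aris)) if aris else 0.0,
            "mean_ari_when_correct": float(np.mean(aris)) if aris else 0.0}


def end_to_end_study(seed: int = 0, n_points: int = 10000,
                     noise_rel_sd: float = 0.01) -> dict:
    """Full chain on the reference scene: render → calibrate → map → segment."""
    cfg = default_reference_scene(seed=seed, total_points=n_points,
                                  image_noise_rel_sd=noise_rel_sd)
    scene = generate_scene(cfg)
    captures = render_views(scene)
    shots = panel_shots(cfg)
    ks = {b: panel_calibration(shots[b]).K for b in BANDS}
    images = []
    for cap in captures:
        bands = {}
        for b in BANDS:
            cal = replace(cap.calibrations[b], K=ks[b])
            bands[b] = ReflectanceImage(
                b, compute_reflectance(cap.raw[b], cal, cap.readings[b]))
        images.append(bands)
    enriched, report = enrich_cloud(scene.cloud, images,
                                    [c.pose for c in captures],
                                    [c.model for c in captures])
    ok = enriched.attributes["enriched"] == 1
    band_err = 0.0
    for b in BANDS:
        err = np.abs(enriched.attributes[f"{b}_refl"][ok]
                     - scene.true_reflectance[b][ok]) / scene.true_reflectance[b][ok]
        band_err = max(band_err, float(np.median(err)))
    sub = enriched.select(np.nonzero(ok)[0])
    fm = standardize(sub, None, {"x": 0.35, "y": 0.35, "z": 0.35})
    res = divisive_cluster(fm, SegmentationParams(seed=seed))
    truth = scene.cloud.attributes["gt_label"][ok]
    ari = float(adjusted_rand_score(truth, res.labels))
    return {"n": n_points,
            "enriched_fraction": float(ok.mean()),
            "median_band_rel_error_pct": 100.0 * band_err,
            "n_leaves": res.n_leaves,
            "n_materials": len(scene.material_names),
            "ari": ari}
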