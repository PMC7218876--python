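"""Scene generator, forward renderer, and their radiometric consistency."""

import numpy as np
import pytest

from cloudspectra.radiometry import (BANDS, compute_reflectance, ndvi,
                                     panel_calibration, simulate_pixel)
from cloudspectra.registration import RigidTransform
from cloudspectra.synthetic import (MaterialSpec, SceneConfig, _SIGNATURES,
                                    default_reference_scene, gaussian_mixture,
                                    generate_scene, panel_shots, perturb_cloud,
                                    ray_cast_visible, render_views,
                                    scene_cameras)


class TestGenerateScene:
    def test_plane_with_zero_spread_exact_signature(self):
        mat = MaterialSpec("m", "plane", {"center": (0, 0, 0), "size": (2, 2)},
                           color=(0.3, 0.4, 0.5),
                           reflectance={"green": 0.1, "red": 0.2,
                                        "reg": 0.3, "nir": 0.4},
                           color_sd=0.0, reflectance_rel_sd=0.0, n_points=50)
        scene = generate_scene(SceneConfig(materials=[mat], seed=0))
        np.testing.assert_allclose(scene.cloud.normals, [[0, 0, 1]] * 50)
        np.testing.assert_allclose(scene.cloud.colors, [[0.3, 0.4, 0.5]] * 50)
        np.testing.assert_allclose(scene.true_reflectance["nir"], 0.4)

    def test_same_seed_identical(self):
        a = generate_scene(default_reference_scene(seed=5, total_points=2000))
        b = generate_scene(default_reference_scene(seed=5, total_points=2000))
        np.testing.assert_array_equal(a.cloud.positions, b.cloud.positions)
        np.testing.assert_array_equal(a.true_reflectance["reg"],
                                      b.true_reflectance["reg"])

    def test_label_histogram_matches_material_sizes(self):
        cfg = default_reference_scene(seed=0, total_points=3000)
        scene = generate_scene(cfg)
        hist = np.bincount(scene.cloud.attributes["gt_label"])
        sizes = {}
        for m in cfg.materials:
            sizes[m.name] = sizes.get(m.name, 0) + m.n_points
        assert hist.tolist() == [sizes[n] for n in scene.material_names]

    def test_primitive_normals_unit(self):
        cfg = default_reference_scene(seed=1, total_points=2000)
        scene = generate_scene(cfg)
        np.testing.assert_allclose(
            np.linalg.norm(scene.cloud.normals, axis=1), 1.0, atol=1e-9)


class TestReferenceSignatures:
    def test_leaf_ndvi_high_rock_ndvi_low(self):
        _, (g, r, rg, nr) = _SIGNATURES["leaves"]
        assert ndvi(nr, r) > 0.6
        _, (g, r, rg, nr) = _SIGNATURES["rocks"]
        assert ndvi(nr, r) < 0.2

    def test_vegetation_reflects_infrared_more_than_visible(self):
        for name in ("leaves", "plants"):
            _, (g, r, rg, nr) = _SIGNATURES[name]
            assert nr >= rg > max(g, r)

    def test_signature_separation_in_standardized_space(self):
        """Between-material separation >= 6 within-material sd."""
        cfg = default_reference_scene(seed=3, total_points=6000,
                                      image_noise_rel_sd=0.0)
        scene = generate_scene(cfg)
        feats = np.column_stack(
            [scene.cloud.colors] +
            [scene.true_reflectance[b][:, None] for b in BANDS] +
            [ndvi(scene.true_reflectance["nir"],
                  scene.true_reflectance["red"])[:, None]])
        z = (feats - feats.mean(0)) / feats.std(0)
        lab = scene.cloud.attributes["gt_label"]
        cents = np.stack([z[lab == l].mean(0) for l in range(lab.max() + 1)])
        within = max(np.linalg.norm(z[lab == l].std(0))
                     for l in range(lab.max() + 1))
        for i in range(len(cents)):
            for j in range(i + 1, len(cents)):
                sep = np.linalg.norm(cents[i] - cents[j])
                assert sep >= 6.0 * within, (i, j, sep, within)


class TestRenderViews:
    def test_raw_pixel_matches_closed_form_inversion(self):
        cfg = default_reference_scene(seed=2, total_points=2000,
                                      image_noise_rel_sd=0.0)
        scene = generate_scene(cfg)
        caps = render_views(scene)
        cap = caps[0]
        r = cfg.radiometry
        for b in BANDS:
            img = cap.raw[b]
            filled = np.isfinite(img)
            assert filled.sum() > 500
            # independent hand inversion of the radiometric chain
            phi_ei = r["nu"] / (r["gain"] * r["tau"])
            some = img[filled][:100]
            refl = (r["f_number"] ** 2 * (some - r["B"]) /
                    (r["A"] * r["iso"] * r["exposure"]) + r["C"])
            recovered = r["K_true"][b] * refl / (
                phi_ei * np.cos(np.radians(r["sun_angle"])))
            lo = min(m.reflectance[b] for m in cfg.materials) * 0.9
            hi = max(m.reflectance[b] for m in cfg.materials) * 1.1
            assert np.all((recovered > lo) & (recovered < hi))

    def test_noise_free_roundtrip_through_calibration(self):
        cfg = default_reference_scene(seed=2, total_points=2000,
                                      image_noise_rel_sd=0.0)
        scene = generate_scene(cfg)
        cap = render_views(scene)[0]
        from dataclasses import replace
        shots = panel_shots(cfg)
        for b in BANDS:
            k_est = panel_calibration(shots[b]).K
            assert k_est == pytest.approx(cfg.radiometry["K_true"][b], abs=1e-9)
            img = cap.raw[b]
            filled = np.isfinite(img)
            # K attaches to each image's own metadata (panel exposure differs)
            cal = replace(cap.calibrations[b], K=k_est)
            refl = compute_reflectance(img[filled], cal, cap.readings[b])
            lo = min(m.reflectance[b] for m in cfg.materials)
            hi = max(m.reflectance[b] for m in cfg.materials)
            assert np.all(refl >= lo * 0.8 - 1e-9)
            assert np.all(refl <= hi * 1.2 + 1e-9)

    def test_exposure_cancellation(self):
        """Doubling the sunshine exposure halves incident flux; re-synthesized
        pixels then yield the same reflectance."""
        from cloudspectra.radiometry import BandCalibration, SunshineReading
        cal = BandCalibration("nir", A=5.0, B=100.0, C=0.0, K=1.3)
        r1 = SunshineReading(2000, 1.0, 1e-3, 10.0)
        r2 = SunshineReading(2000, 1.0, 2e-3, 10.0)
        p1 = simulate_pixel(0.44, cal, r1)
        p2 = simulate_pixel(0.44, cal, r2)
        assert compute_reflectance(p1, cal, r1) == pytest.approx(0.44)
        assert compute_reflectance(p2, cal, r2) == pytest.approx(0.44)
        assert p1 != p2

    def test_same_seed_identical_renders(self):
        cfg = default_reference_scene(seed=9, total_points=1500,
                                      image_noise_rel_sd=0.01)
        a = render_views(generate_scene(cfg))
        b = render_views(generate_scene(cfg))
        for ca, cb in zip(a, b):
            for band in BANDS:
                np.testing.assert_array_equal(ca.raw[band], cb.raw[band])


class TestRayCastOracle:
    def test_unobstructed_points_visible(self):
        mat = MaterialSpec("m", "plane", {"center": (0, 0, 0), "size": (4, 4)},
                           color=(0.5, 0.5, 0.5),
                           reflectance={b: 0.2 for b in BANDS}, n_points=200)
        scene = generate_scene(SceneConfig(materials=[mat], seed=0))
        vis = ray_cast_visible(scene, np.array([0.0, 0.0, 5.0]))
        assert vis.all()

    def test_sphere_blocks_points_behind_it(self):
        mats = [MaterialSpec("s", "sphere", {"center": (0, 0, 1), "radius": 0.8},
                             color=(0.5, 0.5, 0.5),
                             reflectance={b: 0.2 for b in BANDS}, n_points=100),
                MaterialSpec("p", "plane", {"center": (0, 0, 0), "size": (6, 6)},
                             color=(0.5, 0.5, 0.5),
                             reflectance={b: 0.2 for b in BANDS}, n_points=500)]
        scene = generate_scene(SceneConfig(materials=mats, seed=0))
        cam = np.array([0.0, 0.0, 8.0])
        vis = ray_cast_visible(scene, cam)
        lab = scene.cloud.attributes["gt_label"]
        plane = scene.cloud.positions[lab == 1]
        behind = np.linalg.norm(plane[:, :2], axis=1) < 0.5   # under the sphere
        assert not vis[lab == 1][behind].any()
        far = np.linalg.norm(plane[:, :2], axis=1) > 1.5
        assert vis[lab == 1][far].all()


class TestPerturbCloud:
    def test_identity_noise_free_is_identity(self, random_cloud):
        out = perturb_cloud(random_cloud, RigidTransform.identity(), 0.0)
        np.testing.assert_array_equal(out.positions, random_cloud.positions)

    def test_normals_stay_unit_after_rotation(self, random_cloud, rng):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        T = RigidTransform(q, rng.normal(size=3))
        out = perturb_cloud(random_cloud, T, 0.0)
        np.testing.assert_allclose(np.linalg.norm(out.normals, axis=1), 1.0,
                                   atol=1e-9)


class TestGaussianMixture:
    def test_sizes_and_determinism(self):
        X, lab = gaussian_mixture(4, n=1001, seed=3)
        assert len(X) == 1001
        assert np.bincount(lab).tolist() == [251, 250, 250, 250]
        X2, lab2 = gaussian_mixture(4, n=1001, seed=3)
        np.testing.assert_array_equal(X, X2)

    def test_separation_respected(self):
        X, lab = gaussian_mixture(6, n=600, seed=1)
        cents = np.stack([X[lab == i].mean(0) for i in range(6)])
        d = np.linalg.norm(cents[:, None] - cents[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 12.0    # placement guarantees >= 13.5 minus sample wobble
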