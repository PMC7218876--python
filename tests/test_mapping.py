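"""Visibility/occlusion, pixel sampling, multi-view fusion, enrichment."""

import numpy as np
import pytest

from cloudspectra.cloud import PointCloud, build_index
from cloudspectra.geometry import ViewClass
from cloudspectra.mapping import (OCCLUDED, OUT_OF_FRUSTUM, VISIBLE,
                                  MappingParams, aggregate_samples,
                                  enrich_cloud, projection_coverage_image,
                                  sample_band, visible_points)
from cloudspectra.radiometry import BANDS, ReflectanceImage
from cloudspectra.synthetic import (MaterialSpec, SceneConfig,
                                    _fisheye_from_config, generate_scene,
                                    look_at_pose, ray_cast_visible)

SIG = dict(color=(0.5, 0.5, 0.5),
           reflectance={"green": 0.2, "red": 0.2, "reg": 0.2, "nir": 0.2})


def scene_of(materials, seed=0):
    cfg = SceneConfig(materials=materials, seed=seed, n_cameras=1)
    return generate_scene(cfg), _fisheye_from_config(cfg.fisheye)


class TestVisibility:
    def test_single_point_in_frustum_visible(self):
        cloud = PointCloud(np.array([[0.0, 0.0, 0.0]]),
                           np.array([[0.0, 0.0, 1.0]]))
        pose = look_at_pose((0, 0, 5.0), (0, 0, 0))
        scene, model = scene_of([MaterialSpec("m", "plane",
                                              {"center": (0, 0, 0), "size": (1, 1)},
                                              **SIG, n_points=10)])
        mask = visible_points(cloud, pose, model,
                              MappingParams(neighbor_radius=0.1))
        assert mask.states[0] == VISIBLE

    def test_points_behind_camera_out_of_frustum(self, rng):
        pts = rng.uniform(-1, 1, (50, 3)) + [0, 0, 20.0]
        normals = np.tile([0.0, 0, 1], (50, 1))
        cloud = PointCloud(pts, normals)
        pose = look_at_pose((0, 0, 5.0), (0, 0, 0))   # looks down, points above
        scene, model = scene_of([MaterialSpec("m", "plane",
                                              {"center": (0, 0, 0), "size": (1, 1)},
                                              **SIG, n_points=10)])
        mask = visible_points(cloud, pose, model,
                              MappingParams(neighbor_radius=0.5))
        assert np.all(mask.states == OUT_OF_FRUSTUM)

    def test_two_plane_occlusion_vs_ray_oracle(self):
        mats = [MaterialSpec("front", "plane",
                             {"center": (0, 0, 1.0), "size": (2.0, 2.0)},
                             **SIG, n_points=800),
                MaterialSpec("back", "plane",
                             {"center": (0, 0, 0.0), "size": (8.0, 8.0)},
                             **SIG, n_points=1200)]
        scene, model = scene_of(mats)
        pose = look_at_pose((0.1, 0.07, 8.0), (0, 0, 0.5))
        oracle = ray_cast_visible(scene, pose.center)
        mask = visible_points(scene.cloud, pose, model, None,
                              build_index(scene.cloud))
        infr = mask.states != OUT_OF_FRUSTUM
        lab = scene.cloud.attributes["gt_label"]
        # front plane fully visible
        assert mask.visible[(lab == 0) & infr].all()
        # back points inside the front silhouette occluded
        shadowed = (~oracle) & infr & (lab == 1)
        assert shadowed.sum() > 100
        assert (mask.states[shadowed] == OCCLUDED).mean() >= 0.99
        assert (mask.visible[infr] == oracle[infr]).mean() >= 0.99

    def test_sphere_before_plane_vs_ray_oracle(self):
        mats = [MaterialSpec("sph", "sphere",
                             {"center": (0, 0, 1.0), "radius": 1.0},
                             **SIG, n_points=1000),
                MaterialSpec("pl", "plane",
                             {"center": (0, 0, 0.0), "size": (8.0, 8.0)},
                             **SIG, n_points=1000)]
        scene, model = scene_of(mats)
        pose = look_at_pose((8.0, 0, 2.0), (0, 0, 0.5))
        oracle = ray_cast_visible(scene, pose.center)
        mask = visible_points(scene.cloud, pose, model, None,
                              build_index(scene.cloud))
        infr = mask.states != OUT_OF_FRUSTUM
        assert (mask.visible[infr] == oracle[infr]).mean() >= 0.99


class TestSampleBand:
    def test_constant_image(self):
        img = ReflectanceImage("nir", np.full((10, 12), 0.37))
        pix = np.array([[3.2, 4.7], [0.0, 0.0], [11.0, 9.0]])
        np.testing.assert_allclose(sample_band(img, pix), 0.37)

    def test_pixel_center_exact(self):
        g = np.arange(20.0).reshape(4, 5)
        img = ReflectanceImage("red", g)
        assert sample_band(img, np.array([2.0, 3.0])) == g[3, 2]

    def test_linear_ramp_interpolates_exactly(self, rng):
        y, x = np.mgrid[0:20, 0:30]
        img = ReflectanceImage("green", 0.1 + 0.02 * x + 0.05 * y)
        pix = np.column_stack([rng.uniform(0, 29, 200), rng.uniform(0, 19, 200)])
        expect = 0.1 + 0.02 * pix[:, 0] + 0.05 * pix[:, 1]
        np.testing.assert_allclose(sample_band(img, pix), expect, atol=1e-9)

    def test_missing_support_pixel_gives_missing(self):
        g = np.full((5, 5), 1.0)
        g[2, 2] = np.nan
        img = ReflectanceImage("reg", g)
        assert np.isnan(sample_band(img, np.array([1.5, 1.5])))
        assert sample_band(img, np.array([0.5, 0.5])) == 1.0

    def test_outside_bounds_missing(self):
        img = ReflectanceImage("nir", np.ones((5, 5)))
        assert np.isnan(sample_band(img, np.array([-0.1, 2.0])))
        assert np.isnan(sample_band(img, np.array([2.0, 4.6])))

    def test_mixed_pixel_gate_rejects_edges(self):
        g = np.full((6, 6), 0.1)
        g[:, 3:] = 0.9
        img = ReflectanceImage("nir", g)
        assert np.isnan(sample_band(img, np.array([2.5, 2.5]),
                                    max_support_spread=0.2))
        assert sample_band(img, np.array([1.4, 2.5]),
                           max_support_spread=0.2) == pytest.approx(0.1)


class TestAggregation:
    def test_single_perpendicular_sample(self):
        assert aggregate_samples([0.6], [ViewClass.PERPENDICULAR]) == 0.6

    def test_mixed_classes_weighted_mean(self):
        got = aggregate_samples([0.6, 0.2],
                                [ViewClass.PERPENDICULAR, ViewClass.OBLIQUE])
        assert got == pytest.approx((1.0 * 0.6 + 0.5 * 0.2) / 1.5)

    def test_only_indirect_missing(self):
        assert np.isnan(aggregate_samples([0.4, 0.5],
                                          [ViewClass.INDIRECT, ViewClass.INDIRECT]))

    def test_order_invariance(self, rng):
        vals = rng.uniform(0, 1, 6)
        classes = [ViewClass.PERPENDICULAR, ViewClass.OBLIQUE] * 3
        a = aggregate_samples(vals, classes)
        perm = rng.permutation(6)
        b = aggregate_samples(vals[perm], [classes[i] for i in perm])
        assert a == pytest.approx(b)

    def test_weight_scaling_invariance(self, rng):
        vals = rng.uniform(0, 1, 4)
        classes = [ViewClass.PERPENDICULAR, ViewClass.OBLIQUE,
                   ViewClass.PERPENDICULAR, ViewClass.OBLIQUE]
        base = aggregate_samples(vals, classes)
        scaled = MappingParams(class_weights={ViewClass.PERPENDICULAR: 2.0,
                                              ViewClass.OBLIQUE: 1.0,
                                              ViewClass.INDIRECT: 0.0})
        assert aggregate_samples(vals, classes, scaled) == pytest.approx(base)

    def test_mad_gate_drops_inconsistent_view(self):
        vals = [0.30, 0.31, 0.29, 0.90]
        classes = [ViewClass.PERPENDICULAR] * 4
        got = aggregate_samples(vals, classes)
        assert got == pytest.approx(np.mean([0.30, 0.31, 0.29]))


class TestEnrichment:
    def one_camera_setup(self):
        mats = [MaterialSpec("pl", "plane",
                             {"center": (0, 0, 0.0), "size": (4.0, 4.0)},
                             **SIG, n_points=600)]
        cfg = SceneConfig(materials=mats, seed=0, n_cameras=1)
        scene = generate_scene(cfg)
        model = _fisheye_from_config(cfg.fisheye)
        pose = look_at_pose((0.2, 0.1, 6.0), (0, 0, 0))
        return scene, pose, model

    def test_constant_images_propagate_and_ndvi(self):
        scene, pose, model = self.one_camera_setup()
        w, h = model.image_size
        images = [{b: ReflectanceImage(b, np.full((h, w), v))
                   for b, v in zip(BANDS, (0.2, 0.1, 0.5, 0.8))}]
        enriched, report = enrich_cloud(scene.cloud, images, [pose], [model])
        ok = enriched.attributes["enriched"] == 1
        assert ok.mean() > 0.95
        np.testing.assert_allclose(enriched.attributes["nir_refl"][ok], 0.8)
        np.testing.assert_allclose(enriched.attributes["ndvi"][ok],
                                   (0.8 - 0.1) / 0.9, atol=1e-12)
        assert report.n_enriched == ok.sum()

    def test_camera_looking_away_errors(self):
        scene, pose, model = self.one_camera_setup()
        w, h = model.image_size
        away = look_at_pose((0, 0, 6.0), (0, 0, 12.0))
        images = [{b: ReflectanceImage(b, np.full((h, w), 0.5)) for b in BANDS}]
        with pytest.raises(ValueError):
            enrich_cloud(scene.cloud, images, [away], [model])


class TestCoverageImage:
    def test_empty_mask_untouched(self):
        from cloudspectra.mapping import VisibilityMask
        scene, model = scene_of([MaterialSpec("pl", "plane",
                                              {"center": (0, 0, 0), "size": (4, 4)},
                                              **SIG, n_points=100)])
        pose = look_at_pose((0, 0, 6.0), (0, 0, 0))
        w, h = model.image_size
        img = ReflectanceImage("nir", np.full((h, w), 0.5))
        mask = VisibilityMask(0, np.zeros(100, dtype=np.int8))
        out = projection_coverage_image(img, mask, model, pose, scene.cloud,
                                        mark_value=0.0)
        np.testing.assert_array_equal(out, img.grid)

    def test_marked_count_equals_distinct_projections(self):
        from cloudspectra.geometry import fisheye_project, world_to_camera
        scene, model = scene_of([MaterialSpec("pl", "plane",
                                              {"center": (0, 0, 0), "size": (4, 4)},
                                              **SIG, n_points=400)])
        pose = look_at_pose((0.1, 0.2, 6.0), (0, 0, 0))
        mask = visible_points(scene.cloud, pose, model)
        w, h = model.image_size
        img = ReflectanceImage("nir", np.full((h, w), 0.5))
        out = projection_coverage_image(img, mask, model, pose, scene.cloud,
                                        mark_value=-1.0)
        vis = np.nonzero(mask.visible)[0]
        pix, _ = fisheye_project(model, world_to_camera(pose,
                                                        scene.cloud.positions[vis]))
        distinct = {(int(round(x)), int(round(y))) for x, y in pix}
        assert (out == -1.0).sum() == len(distinct)
        # dense cloud over the frustum footprint: a sizable marked region
        assert (out == -1.0).sum() > 100
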