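"""Feature standardization and divisive bisecting-k-means clustering."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from cloudspectra.cloud import PointCloud, read_cloud, write_cloud
from cloudspectra.segmentation import (FeatureMatrix, SegmentationParams,
                                       bisect, cluster_diameter, distance,
                                       divisive_cluster, label_cloud,
                                       should_split, standardize)
from cloudspectra.synthetic import gaussian_mixture


def matrix_of(X):
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    return FeatureMatrix(np.asarray(X, float), [f"f{i}" for i in range(d)],
                         np.zeros(d), np.ones(d), np.ones(d))


def blob_cloud(rng, centers, n_each=100, sd=0.05):
    pts = np.concatenate([c + rng.normal(scale=sd, size=(n_each, 3))
                          for c in centers])
    cloud = PointCloud(pts, colors=rng.uniform(0, 1, (len(pts), 3)))
    cloud.attributes["nir_refl"] = rng.uniform(0, 1, len(pts))
    return cloud


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        cloud = blob_cloud(rng, [np.zeros(3), np.ones(3) * 4])
        fm = standardize(cloud, ["x", "y", "z", "nir_refl"])
        np.testing.assert_allclose(fm.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(fm.values.std(axis=0), 1, atol=1e-9)

    def test_constant_column_zeroed_with_warning(self, rng):
        cloud = blob_cloud(rng, [np.zeros(3)])
        cloud.attributes["flat"] = np.full(len(cloud), 7.0)
        with pytest.warns(UserWarning):
            fm = standardize(cloud, ["x", "flat"])
        assert np.all(fm.values[:, 1] == 0)

    def test_weight_scales_column_sd(self, rng):
        cloud = blob_cloud(rng, [np.zeros(3)])
        fm = standardize(cloud, ["x", "y"], weights={"y": 2.0})
        assert fm.values[:, 1].std() == pytest.approx(2.0, abs=1e-9)

    def test_raw_recoverable(self, rng):
        cloud = blob_cloud(rng, [np.ones(3)])
        fm = standardize(cloud, ["x", "y", "z"], weights={"x": 0.5})
        back = fm.to_raw(fm.values)
        np.testing.assert_allclose(back, cloud.positions, atol=1e-9)

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError):
            standardize(blob_cloud(rng, [np.zeros(3)]), [])


class TestDistance:
    def test_identical_zero(self):
        assert distance(np.ones(5), np.ones(5)) == 0.0

    def test_three_four_five(self):
        assert distance(np.zeros(4), np.array([3.0, 4.0, 0, 0])) == 5.0

    def test_symmetric(self, rng):
        p, q = rng.normal(size=(2, 7))
        assert distance(p, q) == pytest.approx(distance(q, p))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            distance(np.ones(3), np.ones(4))


class TestBisect:
    def test_two_points_two_singletons(self):
        fm = matrix_of([[0.0, 0], [1.0, 0]])
        A, B, cents = bisect(fm, np.array([0, 1]), seed=0)
        assert {len(A), len(B)} == {1, 1}

    def test_two_blobs_recovered(self, rng):
        X = np.concatenate([rng.normal(size=(100, 3)),
                            rng.normal(size=(100, 3)) + 10.0])
        fm = matrix_of(X)
        A, B, _ = bisect(fm, np.arange(200), seed=1)
        sides = [set(A.tolist()), set(B.tolist())]
        assert set(range(100)) in sides and set(range(100, 200)) in sides

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(50, 4))
        fm = matrix_of(X)
        r1 = bisect(fm, np.arange(50), seed=9)
        r2 = bisect(fm, np.arange(50), seed=9)
        np.testing.assert_array_equal(r1[0], r2[0])

    def test_identical_points_unsplittable(self):
        fm = matrix_of(np.ones((20, 3)))
        assert bisect(fm, np.arange(20), seed=0) is None


class TestClusterDiameter:
    def test_singleton_zero(self):
        fm = matrix_of(np.zeros((1, 2)))
        assert cluster_diameter(fm, np.array([0])) == 0.0

    def test_segment_length(self):
        X = np.column_stack([np.linspace(0, 3.5, 8), np.zeros(8)])
        fm = matrix_of(X)
        assert cluster_diameter(fm, np.arange(8)) == pytest.approx(3.5)

    def test_equals_bruteforce(self, rng):
        X = rng.normal(size=(500, 5))
        fm = matrix_of(X)
        assert cluster_diameter(fm, np.arange(500)) == pytest.approx(
            pdist(X).max())

    def test_subsampled_bounds(self, rng):
        X = rng.normal(size=(3000, 4))
        fm = matrix_of(X)
        exact = pdist(X).max()
        approx = cluster_diameter(fm, np.arange(3000), exact_threshold=500)
        assert exact / 2 <= approx <= exact + 1e-12


class TestShouldSplit:
    def test_singleton_never_splits(self):
        assert not should_split(0.0, 1, 2.0)

    def test_diameter_exceeding_centroid_distance_splits(self):
        assert should_split(5.0, 100, 2.0)

    def test_compact_cluster_stops(self):
        assert not should_split(1.0, 100, 3.0)

    def test_min_size_guard(self):
        assert not should_split(5.0, 5, 2.0, min_size=10)


class TestDivisiveCluster:
    def test_identical_points_one_leaf(self):
        fm = matrix_of(np.ones((40, 3)))
        res = divisive_cluster(fm)
        assert res.n_leaves == 1
        assert np.all(res.labels == 0)

    def test_two_separated_blobs(self, rng):
        X = np.concatenate([rng.normal(size=(200, 3)),
                            rng.normal(size=(200, 3)) + 15.0])
        truth = np.repeat([0, 1], 200)
        res = divisive_cluster(matrix_of(X), SegmentationParams(seed=0))
        assert res.n_leaves == 2
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_mixture_count_and_ari(self):
        X, truth = gaussian_mixture(5, n=2000, seed=11)
        res = divisive_cluster(matrix_of(X), SegmentationParams(seed=3))
        assert res.n_leaves == 5
        assert adjusted_rand_score(truth, res.labels) >= 0.95

    def test_partition_and_tree_invariants(self):
        X, _ = gaussian_mixture(4, n=1000, seed=5)
        res = divisive_cluster(matrix_of(X), SegmentationParams(seed=1))
        # leaves partition the points
        all_members = np.concatenate([res.nodes[i].members for i in res.leaf_ids])
        assert sorted(all_members.tolist()) == list(range(1000))
        # strict binary tree: children partition the parent
        for nd in res.nodes:
            if nd.children:
                a, b = (res.nodes[c] for c in nd.children)
                union = np.concatenate([a.members, b.members])
                assert sorted(union.tolist()) == sorted(nd.members.tolist())
        # labels contiguous from zero
        assert set(res.labels.tolist()) == set(range(res.n_leaves))

    def test_deterministic_given_seed(self):
        X, _ = gaussian_mixture(3, n=600, seed=2)
        r1 = divisive_cluster(matrix_of(X), SegmentationParams(seed=4))
        r2 = divisive_cluster(matrix_of(X), SegmentationParams(seed=4))
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_rigid_motion_invariance_without_spatial_dims(self, rng):
        cloud = blob_cloud(rng, [np.zeros(3), np.ones(3) * 5], n_each=150)
        cloud.attributes["nir_refl"] = np.concatenate(
            [np.full(150, 0.2), np.full(150, 0.8)]) + rng.normal(0, 0.01, 300)
        fm = standardize(cloud, ["r", "g", "b", "nir_refl"])
        res = divisive_cluster(fm, SegmentationParams(seed=0))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = cloud.copy()
        moved.positions = cloud.positions @ q.T + 100.0
        fm2 = standardize(moved, ["r", "g", "b", "nir_refl"])
        res2 = divisive_cluster(fm2, SegmentationParams(seed=0))
        assert adjusted_rand_score(res.labels, res2.labels) == 1.0

    def test_leaves_satisfy_stop_conditions(self):
        X, _ = gaussian_mixture(4, n=1200, seed=8)
        params = SegmentationParams(seed=2)
        res = divisive_cluster(matrix_of(X), params)
        for lid in res.leaf_ids:
            leaf = res.nodes[lid]
            if leaf.parent is None:
                continue
            parent = res.nodes[leaf.parent]
            sib = [c for c in parent.children if c != lid][0]
            d_cent = distance(leaf.centroid, res.nodes[sib].centroid)
            assert (leaf.diameter < d_cent or leaf.size < params.min_size
                    or np.allclose(res.features.values[leaf.members],
                                   res.features.values[leaf.members][0]))


class TestLabelCloud:
    def test_single_leaf_all_zero(self, rng):
        cloud = blob_cloud(rng, [np.zeros(3)], n_each=30)
        fm = matrix_of(np.ones((30, 2)))
        res = divisive_cluster(fm)
        out = label_cloud(res, cloud)
        assert np.all(out.attributes["label"] == 0)

    def test_excluded_points_minus_one_and_ply_roundtrip(self, rng, tmp_path):
        cloud = blob_cloud(rng, [np.zeros(3), np.ones(3) * 8], n_each=50)
        admitted = np.arange(0, 100, 2)
        fm = standardize(cloud.select(admitted), ["x", "y", "z"])
        res = divisive_cluster(fm, SegmentationParams(seed=0))
        out = label_cloud(res, cloud, admitted)
        labels = out.attributes["label"]
        assert np.all(labels[1::2] == -1)
        assert np.all(labels[admitted] >= 0)
        path = tmp_path / "labeled.ply"
        write_cloud(out, path)
        back = read_cloud(path)
        np.testing.assert_array_equal(back.attributes["label"], labels)

    def test_size_mismatch_rejected(self, rng):
        cloud = blob_cloud(rng, [np.zeros(3)], n_each=30)
        fm = matrix_of(np.ones((10, 2)))
        res = divisive_cluster(fm)
        with pytest.raises(ValueError):
            label_cloud(res, cloud)

    def test_tree_report_serializable(self, rng, tmp_path):
        import json
        X, _ = gaussian_mixture(3, n=300, seed=1)
        res = divisive_cluster(matrix_of(X), SegmentationParams(seed=0))
        path = tmp_path / "tree.json"
        res.save_tree(path)
        doc = json.loads(path.read_text())
        assert doc["n_leaves"] == res.n_leaves
        assert len(doc["nodes"]) == len(res.nodes)
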