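"""Divisive hierarchical clustering of the enriched cloud into materials.

The number of natural materials in a scene is unknown, so the hierarchy is
built top-down: all points start in one cluster, each cluster is bisected
with 2-means (k-means++, multiple restarts), and a child is recursed into
only while its diameter — the maximum pairwise Euclidean distance among its
members — is at least the distance between the two sibling centroids the
split produced.  A compact, homogeneous child (diameter shorter than the
centroid separation) is a final material cluster.

Features are the 11 per-point attributes (X, Y, Z, R, G, B, four band
reflectances, NDVI), z-scored per dimension so meters and reflectances share
one Euclidean metric; per-dimension weights can rebalance them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .cloud import PointCloud

__all__ = [
    "DEFAULT_FEATURES",
    "FeatureMatrix",
    "ClusterNode",
    "SegmentationResult",
    "SegmentationParams",
    "standardize",
    "distance",
    "bisect",
    "cluster_diameter",
    "should_split",
    "divisive_cluster",
    "label_cloud",
]

# the 11 clustering attributes, in canonical order
DEFAULT_FEATURES = ("x", "y", "z", "r", "g", "b",
                    "red_refl", "green_refl", "reg_refl", "nir_refl", "ndvi")


@dataclass
class FeatureMatrix:
    """Standardized n×d feature array with invertible per-dimension scaling."""

    values: np.ndarray
    names: list[str]
    offsets: np.ndarray          # per-dimension mean of the raw data
    divisors: np.ndarray         # per-dimension sd (1 for constant dims)
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_raw(self, standardized: np.ndarray) -> np.ndarray:
        """Map standardized vectors back to raw attribute units."""
        return np.asarray(standardized) / self.weights * self.divisors + self.offsets


def _extract_raw_features(cloud: PointCloud, names: list[str]) -> np.ndarray:
    cols = []
    for nm in names:
        if nm in ("x", "y", "z"):
            cols.append(cloud.positions[:, "xyz".index(nm)])
        elif nm in ("r", "g", "b"):
            if cloud.colors is None:
                raise ValueError("cloud has no colors")
            cols.append(cloud.colors[:, "rgb".index(nm)])
        elif nm in cloud.attributes:
            cols.append(np.asarray(cloud.attributes[nm], dtype=np.float64))
        else:
            raise ValueError(f"unknown feature {nm!r}")
    return np.stack(cols, axis=1)


def standardize(cloud: PointCloud, features: list[str] | None = None,
                weights: dict[str, float] | None = None) -> FeatureMatrix:
    """z-score the selected attributes into a :class:`FeatureMatrix`.

    Constant dimensions become all-zero columns (with a warning); an
    optional per-dimension weight multiplies the standardized column.
    """
    names = list(features) if features is not None else list(DEFAULT_FEATURES)
    if not names:
        raise ValueError("empty feature selection")
    raw = _extract_raw_features(cloud, names)
    if not np.all(np.isfinite(raw)):
        raise ValueError("features contain non-finite values; filter the cloud first")
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    constant = sd < 1e-15
    if np.any(constant):
        warnings.warn(f"constant feature dimensions passed through as 0: "
                      f"{[names[i] for i in np.nonzero(constant)[0]]}")
    div = np.where(constant, 1.0, sd)
    w = np.array([(weights or {}).get(nm, 1.0) for nm in names], dtype=np.float64)
    vals = (raw - mu) / div * w
    vals[:, constant] = 0.0
    return FeatureMatrix(vals, names, mu, div, w)


def distance(pi: np.ndarray, pj: np.ndarray) -> float:
    """Euclidean distance between two feature vectors."""
    pi = np.asarray(pi, dtype=np.float64)
    pj = np.asarray(pj, dtype=np.float64)
    if pi.shape != pj.shape:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(pi - pj))


def bisect(features: FeatureMatrix, members: np.ndarray, seed: int = 0,
           n_init: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """2-means split of ``members``; returns (A, B, centroids) or None if unsplittable."""
    members = np.asarray(members, dtype=np.intp)
    if len(members) < 2:
        raise ValueError("need at least 2 points to bisect")
    X = features.values[members]
    if np.allclose(X, X[0], atol=1e-12):
        return None
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed & 0x7FFFFFFF)
    lab = km.fit_predict(X)
    if len(np.unique(lab)) < 2:
        return None
    return members[lab == 0], members[lab == 1], km.cluster_centers_


def cluster_diameter(features: FeatureMatrix, members: np.ndarray,
                     exact_threshold: int = 2000) -> float:
    """Max pairwise distance; exact up to ``exact_threshold`` members.

    Above the threshold, the diameter of a farthest-point subsample of
    ``exact_threshold`` members is returned — never above the true value and
    at least half of it.
    """
    members = np.asarray(members, dtype=np.intp)
    X = features.values[members]
    if len(X) <= 1:
        return 0.0
    if len(X) > exact_threshold:
        X = X[_farthest_point_sample(X, exact_threshold)]
    return float(pdist(X).max())


def _farthest_point_sample(X: np.ndarray, m: int) -> np.ndarray:
    """Deterministic farthest-point subsample of m rows (seeded at row 0)."""
    n = len(X)
    chosen = np.empty(m, dtype=np.intp)
    chosen[0] = 0
    dmin = np.linalg.norm(X - X[0], axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(dmin))
        chosen[i] = nxt
        dmin = np.minimum(dmin, np.linalg.norm(X - X[nxt], axis=1))
    return chosen


def should_split(diameter: float, size: int, sibling_centroid_distance: float,
                 min_size: int = 10) -> bool:
    """Recurse into a child iff its diameter reaches the sibling-centroid
    distance and it is large enough to split."""
    return diameter >= sibling_centroid_distance and size >= min_size


@dataclass
class ClusterNode:
    """One node of the binary divisive hierarchy."""

    node_id: int
    members: np.ndarray
    centroid: np.ndarray                 # standardized units
    diameter: float
    parent: int | None = None
    children: tuple[int, int] | None = None
    split_features: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SegmentationParams:
    seed: int = 0
    n_init: int = 10
    min_size: int = 10
    max_depth: int = 32
    exact_threshold: int = 2000


@dataclass
class SegmentationResult:
    nodes: list[ClusterNode]
    labels: np.ndarray                   # per-point leaf label, contiguous from 0
    leaf_ids: list[int]
    features: FeatureMatrix

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaf_centroids_raw(self) -> np.ndarray:
        return np.stack([self.features.to_raw(self.nodes[i].centroid)
                         for i in self.leaf_ids])

    def tree_report(self) -> dict:
        """JSON-serializable cluster-tree report (centroids in raw units)."""
        return {
            "n_points": int(self.features.n),
            "n_leaves": self.n_leaves,
            "feature_names": list(self.features.names),
            "nodes": [
                {
                    "id": nd.node_id,
                    "parent": nd.parent,
                    "children": list(nd.children) if nd.children else None,
                    "size": nd.size,
                    "diameter": round(nd.diameter, 12),
                    "centroid_raw": [round(float(v), 12)
                                     for v in self.features.to_raw(nd.centroid)],
                    "split_features": nd.split_features,
                }
                for nd in self.nodes
            ],
        }

    def save_tree(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.tree_report(), fh, indent=1, sort_keys=True)


def divisive_cluster(features: FeatureMatrix,
                     params: SegmentationParams | None = None) -> SegmentationResult:
    """Recursive 2-means bisection with the diameter / centroid-distance stop rule.

    The root is always bisected (if splittable); each child is recursed into
    while ``should_split`` holds against the distance between the two sibling
    centroids.  ``max_depth`` guards pathological data.
    """
    params = params or SegmentationParams()
    n = features.n
    if n < 1:
        raise ValueError("empty feature matrix")
    all_members = np.arange(n, dtype=np.intp)
    root = ClusterNode(0, all_members, features.values.mean(axis=0),
                       cluster_diameter(features, all_members, params.exact_threshold))
    nodes = [root]
    # stack of (node_id, depth); a node on the stack is to be bisected
    stack: list[tuple[int, int]] = []
    if root.size >= 2 and root.size >= params.min_size:
        stack.append((0, 0))
    while stack:
        nid, depth = stack.pop()
        node = nodes[nid]
        res = bisect(features, node.members, seed=params.seed + 1000003 * nid,
                     n_init=params.n_init)
        if res is None:
            continue
        A, B, cents = res
        d_cent = distance(cents[0], cents[1])
        child_ids = []
        for members, cent in ((A, cents[0]), (B, cents[1])):
            cid = len(nodes)
            child = ClusterNode(cid, members, cent,
                                cluster_diameter(features, members,
                                                 params.exact_threshold),
                                parent=nid)
            nodes.append(child)
            child_ids.append(cid)
            if depth + 1 < params.max_depth and should_split(
                    child.diameter, child.size, d_cent, params.min_size):
                stack.append((cid, depth + 1))
        node.children = (child_ids[0], child_ids[1])
        rank = np.argsort(-np.abs(cents[0] - cents[1]))
        node.split_features = [features.names[i] for i in rank]
    leaf_ids = [nd.node_id for nd in nodes if nd.is_leaf]
    labels = np.empty(n, dtype=np.int32)
    for lab, lid in enumerate(leaf_ids):
        labels[nodes[lid].members] = lab
    return SegmentationResult(nodes, labels, leaf_ids, features)


def label_cloud(result: SegmentationResult, cloud: PointCloud,
                admitted: np.ndarray | None = None) -> PointCloud:
    """Attach the leaf label as an integer attribute; excluded points get −1.

    ``admitted`` holds the cloud indices the feature matrix was built from
    (default: all points, sizes must then match).
    """
    out = cloud.copy()
    labels = np.full(len(cloud), -1, dtype=np.int32)
    if admitted is None:
        if result.features.n != len(cloud):
            raise ValueError("result size does not match the cloud; pass `admitted`")
        labels[:] = result.labels
    else:
        admitted = np.asarray(admitted, dtype=np.intp)
        if len(admitted) != result.features.n:
            raise ValueError("`admitted` length does not match the clustered set")
        labels[admitted] = result.labels
    out.attributes["label"] = labels
    return out
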