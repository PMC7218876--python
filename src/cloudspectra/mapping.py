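"""Mapping calibrated multispectral images onto the RGB point cloud.

Per camera the stages are: frustum filtering, occlusion testing, pixel
sampling and view-angle weighting; per point the per-camera samples are then
fused into a single reflectance per band, and NDVI is derived from the fused
NIR and red values.  The result is the enriched cloud whose 11 per-point
attributes (X, Y, Z, R, G, B, green, red, reg, nir, NDVI) feed the material
clustering.

Occlusion model
---------------
Back-facing points are culled, then the rest are processed nearest-to-
farthest from the camera.  Each accepted point registers a small oriented
surface patch — a disk centered on the point, oriented by the average
normal of its radius-neighbors (neighbors whose normals disagree by more
than ``normal_angle_max`` are excluded).  A candidate is occluded when the
ray from the camera toward it intersects an already-registered disk
strictly closer than the candidate by at least a depth bias; the bias keeps
coplanar and gently curved neighbors from shadowing each other.  A
screen-space hash grid limits each candidate's test to nearby disks.

Sampling reliability
--------------------
Three gates protect the fused reflectances from boundary artifacts: a
depth-edge erosion (views whose pixel neighborhood contains strictly nearer
geometry are dropped), a mixed-pixel test on the bilinear support, and a
cross-view median/MAD consistency check.  All are configurable on
:class:`MappingParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud, SpatialIndex, build_index
from .geometry import (CameraPose, FisheyeModel, ViewClass, classify_view,
                       fisheye_project, view_angle, world_to_camera)
from .radiometry import BANDS, ReflectanceImage, ndvi

__all__ = [
    "OUT_OF_FRUSTUM", "VISIBLE", "OCCLUDED",
    "VisibilityMask", "MappingParams", "EnrichmentReport",
    "visible_points", "sample_band", "aggregate_samples",
    "enrich_cloud", "projection_coverage_image",
    "mean_nn_spacing",
]

# 3-state visibility flags
OUT_OF_FRUSTUM = 0
VISIBLE = 1
OCCLUDED = 2


@dataclass
class VisibilityMask:
    """Per-point visibility state for one camera."""

    camera_id: int
    states: np.ndarray          # int8 per point: OUT_OF_FRUSTUM / VISIBLE / OCCLUDED

    @property
    def visible(self) -> np.ndarray:
        return self.states == VISIBLE


@dataclass
class MappingParams:
    """Tunables of the visibility test and multi-view fusion.

    ``neighbor_radius`` ``None`` → 3× the mean nearest-neighbor spacing.
    Class weights follow the view-reliability ranges; indirect views carry
    no weight.
    """

    neighbor_radius: float | None = None
    normal_angle_max: float = 60.0
    # disks narrower than the neighbor radius: full-radius splats overhang
    # object silhouettes and shadow truly visible background points
    disk_radius_factor: float = 0.5
    # occluders must be nearer by a full disk radius: tangent-plane splats on
    # curved surfaces otherwise shadow grazing regions that are truly visible
    depth_bias_factor: float = 1.0
    class_weights: dict[ViewClass, float] = field(default_factory=lambda: {
        ViewClass.PERPENDICULAR: 1.0,
        ViewClass.OBLIQUE: 0.5,
        ViewClass.INDIRECT: 0.0,
    })
    # cross-view consistency gate: with >= outlier_min_views samples, a view
    # deviating from the per-point median by more than outlier_mad_factor
    # scaled MADs (and more than 5% of the median) is rejected — it usually
    # sampled across an occlusion or material boundary.  None disables.
    outlier_mad_factor: float | None = 3.0
    outlier_min_views: int = 4
    # depth-edge erosion: a view of a point is discarded when a strictly
    # nearer point projects within ``edge_px`` pixels and is closer by more
    # than ``edge_depth_factor`` × neighbor_radius — the pixel then straddles
    # an occlusion silhouette and its value is unreliable.  None disables.
    edge_depth_factor: float | None = 1.0
    edge_px: int = 2
    # mixed-pixel gate: reject a bilinear sample when its 4 support pixels
    # spread by more than this fraction of their mean.  None disables.
    max_support_spread: float | None = 0.15
    # neighborhood consistency: after fusion, a point whose band value
    # deviates from the median of its spatial neighbors by more than this
    # fraction is excluded from the enriched set — an isolated spectral
    # outlier on a surface is a residual mixed-pixel artifact, not a
    # material.  None disables.
    neighborhood_consistency_rel: float | None = 0.15
    neighborhood_radius_factor: float = 2.0


def mean_nn_spacing(cloud: PointCloud, sample: int = 1000, seed: int = 0) -> float:
    """Mean nearest-neighbor distance, estimated from a point subsample."""
    rng = np.random.default_rng(seed)
    n = len(cloud)
    idx = rng.choice(n, size=min(sample, n), replace=False) if n > 1 else np.array([0])
    tree = build_index(cloud).tree
    d, _ = tree.query(cloud.positions[idx], k=2)
    return float(np.mean(d[:, 1])) if n > 1 else 1.0


def _resolve_radius(cloud: PointCloud, params: MappingParams) -> float:
    if params.neighbor_radius is not None:
        return params.neighbor_radius
    return 3.0 * mean_nn_spacing(cloud)


def visible_points(cloud: PointCloud, pose: CameraPose, model: FisheyeModel,
                   params: MappingParams | None = None,
                   index: SpatialIndex | None = None,
                   camera_id: int = 0) -> VisibilityMask:
    """Occlusion-aware visibility of every cloud point from one camera."""
    if cloud.normals is None:
        raise ValueError("visibility test needs per-point normals")
    params = params or MappingParams()
    radius = _resolve_radius(cloud, params)
    disk_r = params.disk_radius_factor * radius
    bias = params.depth_bias_factor * disk_r
    index = index or build_index(cloud)

    n = len(cloud)
    states = np.zeros(n, dtype=np.int8)
    cam_pts = world_to_camera(pose, cloud.positions)
    pix, ok = fisheye_project(model, cam_pts)
    w, h = model.image_size
    infr = ok & (pix[:, 0] >= 0) & (pix[:, 0] < w) & (pix[:, 1] >= 0) & (pix[:, 1] < h)
    cand = np.nonzero(infr)[0]
    if len(cand) == 0:
        return VisibilityMask(camera_id, states)

    # back-face cull: a surface element facing away from the camera is
    # self-hidden regardless of any other geometry
    to_cam = pose.center - cloud.positions[cand]
    backface = np.einsum("ij,ij->i", cloud.normals[cand], to_cam) <= 0
    states[cand[backface]] = OCCLUDED
    cand = cand[~backface]
    if len(cand) == 0:
        return VisibilityMask(camera_id, states)

    dists = np.linalg.norm(cloud.positions[cand] - pose.center, axis=1)
    order = cand[np.argsort(dists, kind="stable")]
    patch_normals = _patch_normals(cloud, index, order, radius,
                                   params.normal_angle_max)

    # vectorized precomputation for the sequential near-to-far sweep
    cam = pose.center
    P = cloud.positions[order]
    seg_len = np.linalg.norm(P - cam, axis=1)
    rays = (P - cam) / seg_len[:, None]
    foot = _pixel_footprints(model, pose, P, disk_r)
    cell = max(2.0, float(np.median(foot)))
    cells = np.floor(pix[order] / cell).astype(np.int64)
    reach = np.minimum(np.ceil(foot / cell).astype(np.int64) + 1, 16)

    # screen-space hash grid over registered disks
    grid: dict[tuple[int, int], list[int]] = {}
    disk_c = np.empty((len(order), 3))
    disk_n = np.empty((len(order), 3))
    n_disks = 0
    for row in range(len(order)):
        i = order[row]
        cx, cy = cells[row]
        cand_disks: list[int] = []
        for dx in (-1, 0, 1):
            ext = cand_disks.extend
            for dy in (-1, 0, 1):
                got = grid.get((cx + dx, cy + dy))
                if got:
                    ext(got)
        if cand_disks:
            q = disk_c[cand_disks]
            m = disk_n[cand_disks]
            ray = rays[row]
            denom = m @ ray
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.einsum("ij,ij->i", q - cam, m) / denom
            hit = np.isfinite(t) & (t > 1e-9) & (t < seg_len[row] - bias)
            if np.any(hit):
                pt = cam + t[hit, None] * ray
                if np.any(np.einsum("ij,ij->i", pt - q[hit], pt - q[hit])
                          <= disk_r * disk_r):
                    states[i] = OCCLUDED
                    continue
        states[i] = VISIBLE
        disk_c[n_disks] = P[row]
        disk_n[n_disks] = patch_normals[row]
        r = int(reach[row])
        for dx in range(-r, r + 1):
            for dy in range(-r, r + 1):
                key = (cx + dx, cy + dy)
                got = grid.get(key)
                if got is None:
                    grid[key] = [n_disks]
                else:
                    got.append(n_disks)
        n_disks += 1
    return VisibilityMask(camera_id, states)


def _patch_normals(cloud: PointCloud, index: SpatialIndex, order: np.ndarray,
                   radius: float, normal_angle_max: float) -> np.ndarray:
    """Patch orientation per point: mean of radius-neighbor normals whose
    direction agrees with the point's own normal within the angle gate."""
    cos_gate = np.cos(np.radians(normal_angle_max))
    lists = index.tree.query_ball_point(cloud.positions[order], radius)
    counts = np.fromiter((len(l) for l in lists), dtype=np.intp, count=len(lists))
    flat = np.fromiter((j for l in lists for j in l), dtype=np.intp,
                       count=int(counts.sum()))
    owner = np.repeat(np.arange(len(order)), counts)
    agree = np.einsum("ij,ij->i", cloud.normals[flat],
                      cloud.normals[order][owner]) >= cos_gate
    sums = np.zeros((len(order), 3))
    np.add.at(sums, owner[agree], cloud.normals[flat[agree]])
    sums += cloud.normals[order]          # the point itself always contributes
    nrm = np.linalg.norm(sums, axis=1, keepdims=True)
    return np.where(nrm > 1e-12, sums / np.maximum(nrm, 1e-12),
                    cloud.normals[order])


def _pixel_footprints(model: FisheyeModel, pose: CameraPose,
                      points: np.ndarray, radius: float) -> np.ndarray:
    """Per-point conservative pixel radius of a world-space disk of ``radius``."""
    cam_pts = world_to_camera(pose, np.atleast_2d(points))
    pix0, ok0 = fisheye_project(model, cam_pts)
    out = np.full(len(cam_pts), 2.0)
    # displace along the two camera-frame tangent axes and take the max shift
    for axis in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        pix1, ok1 = fisheye_project(model, cam_pts + radius * axis)
        okb = np.atleast_1d(ok0 & ok1)
        d = np.linalg.norm(np.atleast_2d(pix1) - np.atleast_2d(pix0), axis=1)
        out[okb] = np.maximum(out[okb], d[okb])
    return out


def sample_band(image: ReflectanceImage, pixels: np.ndarray,
                max_support_spread: float | None = None) -> np.ndarray:
    """Bilinear samples of a reflectance raster at (x, y) pixel coordinates.

    Pixel centers sit at integer coordinates.  A sample is NaN (missing) when
    it falls outside the raster or any of its 4 support pixels is missing.
    With ``max_support_spread`` set, a sample is also rejected when the
    relative spread (max − min over the mean) of its 4 support pixels exceeds
    it — the interpolation cell then straddles a material or occlusion edge
    (a mixed pixel).
    """
    px = np.atleast_2d(np.asarray(pixels, dtype=np.float64))
    g = image.grid
    h_img, w_img = g.shape
    if h_img < 2 or w_img < 2:
        raise ValueError("raster must be at least 2x2 for bilinear sampling")
    x, y = px[:, 0], px[:, 1]
    valid = (x >= 0) & (x <= w_img - 1) & (y >= 0) & (y <= h_img - 1)
    out = np.full(len(px), np.nan)
    # support cell: clamp so points on the last row/column use the final cell
    xc = np.clip(np.floor(x).astype(int), 0, w_img - 2)
    yc = np.clip(np.floor(y).astype(int), 0, h_img - 2)
    if np.any(valid):
        xv, yv = xc[valid], yc[valid]
        fx = x[valid] - xv
        fy = y[valid] - yv
        v00 = g[yv, xv]
        v01 = g[yv, xv + 1]
        v10 = g[yv + 1, xv]
        v11 = g[yv + 1, xv + 1]
        val = (v00 * (1 - fx) * (1 - fy) + v01 * fx * (1 - fy)
               + v10 * (1 - fx) * fy + v11 * fx * fy)
        if max_support_spread is not None:
            sup = np.stack([v00, v01, v10, v11])
            mean = sup.mean(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                spread = (sup.max(axis=0) - sup.min(axis=0)) / np.abs(mean)
            val = np.where(spread > max_support_spread, np.nan, val)
        out[np.nonzero(valid)[0]] = val
    if np.asarray(pixels).ndim == 1:
        return out[0]
    return out


def _mad_keep(values: np.ndarray, weights: np.ndarray,
              params: MappingParams) -> np.ndarray:
    """Per-view keep mask for one point's band samples (rows = views)."""
    good = np.isfinite(values) & (weights > 0)
    if params.outlier_mad_factor is None or good.sum() < params.outlier_min_views:
        return good
    v = values[good]
    med = np.median(v)
    dev = np.abs(v - med)
    mad = 1.4826 * np.median(dev)
    limit = np.maximum(params.outlier_mad_factor * mad, 0.05 * abs(med) + 1e-12)
    keep = good.copy()
    keep[np.nonzero(good)[0][dev > limit]] = False
    return keep


def aggregate_samples(values: np.ndarray, classes: list[ViewClass],
                      params: MappingParams | None = None) -> float:
    """Fuse one point's per-view samples of one band into a single value.

    Weighted mean with flat per-class weights (perpendicular 1.0, oblique
    0.5, indirect 0.0 by default), after the cross-view consistency gate;
    NaN where no view carries weight.
    """
    params = params or MappingParams()
    v = np.asarray(values, dtype=np.float64)
    w = np.array([params.class_weights[c] for c in classes], dtype=np.float64)
    keep = _mad_keep(v, w, params)
    if not np.any(keep):
        return float("nan")
    return float(np.sum(v[keep] * w[keep]) / np.sum(w[keep]))


def _away_from_depth_edges(points: np.ndarray, pix: np.ndarray,
                           pose: CameraPose, model: FisheyeModel,
                           depth_threshold: float, edge_px: int) -> np.ndarray:
    """True where no strictly nearer point projects within ``edge_px`` pixels.

    Builds a min-depth raster from the (visible) points, dilated by the pixel
    radius, and keeps a point when its own depth is within ``depth_threshold``
    of the local minimum — i.e. its pixel does not straddle a silhouette.
    """
    w, h = model.image_size
    depth = np.linalg.norm(points - pose.center, axis=1)
    xi = np.clip(np.round(pix[:, 0]).astype(np.int64), 0, w - 1)
    yi = np.clip(np.round(pix[:, 1]).astype(np.int64), 0, h - 1)
    dmin = np.full((h, w), np.inf)
    np.minimum.at(dmin, (yi, xi), depth)
    if edge_px > 0:
        # grayscale erosion (min filter) with a (2k+1)² window, separably
        from scipy.ndimage import minimum_filter
        dmin = minimum_filter(dmin, size=2 * edge_px + 1, mode="nearest")
    return depth <= dmin[yi, xi] + depth_threshold


def _neighborhood_consistent(positions: np.ndarray, band_vals: dict,
                             complete: np.ndarray, radius: float,
                             rel_tol: float, min_neighbors: int = 5
                             ) -> np.ndarray:
    """False where a fused band value is an isolated outlier among the
    point's spatial neighbors (median deviation above ``rel_tol``)."""
    from scipy.spatial import cKDTree
    idx = np.nonzero(complete)[0]
    tree = cKDTree(positions[idx])
    neigh = tree.query_ball_point(positions[idx], radius)
    keep = np.ones(len(positions), dtype=bool)
    vals = np.stack([band_vals[b][idx] for b in BANDS])       # (4, m)
    for row, nb in enumerate(neigh):
        nb = [j for j in nb if j != row]
        if len(nb) < min_neighbors:
            continue
        med = np.median(vals[:, nb], axis=1)
        dev = np.abs(vals[:, row] - med) / np.maximum(np.abs(med), 1e-9)
        if np.any(dev > rel_tol):
            keep[idx[row]] = False
    return keep


def _aggregate_columns(values: np.ndarray, weights: np.ndarray,
                       params: MappingParams) -> np.ndarray:
    """Vectorized per-point fusion of one band's (n_views, n) sample table."""
    good = np.isfinite(values) & (weights > 0)
    v = np.where(good, values, np.nan)
    if params.outlier_mad_factor is not None:
        n_good = good.sum(axis=0)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN columns
            med = np.nanmedian(v, axis=0)
            dev = np.abs(v - med)
            mad = 1.4826 * np.nanmedian(dev, axis=0)
        limit = np.maximum(params.outlier_mad_factor * mad,
                           0.05 * np.abs(med) + 1e-12)
        reject = (dev > limit) & (n_good >= params.outlier_min_views)
        good &= ~reject
    w = np.where(good, weights, 0.0)
    wsum = w.sum(axis=0)
    vsum = np.where(good, values * w, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0), np.nan)


@dataclass
class EnrichmentReport:
    n_points: int
    n_enriched: int
    per_band_coverage: dict[str, int]
    per_camera_visible: list[int]


def enrich_cloud(cloud: PointCloud,
                 images: list[dict[str, ReflectanceImage]],
                 poses: list[CameraPose],
                 models: list[FisheyeModel],
                 params: MappingParams | None = None
                 ) -> tuple[PointCloud, EnrichmentReport]:
    """Fuse per-camera 4-band reflectance images into per-point attributes.

    ``images[c][band]`` is camera ``c``'s calibrated raster for ``band``.
    Returns the enriched cloud — attributes ``green_refl``, ``red_refl``,
    ``reg_refl``, ``nir_refl``, ``ndvi``, ``n_views`` plus ``enriched``
    (1 where all four bands were recovered) — and coverage statistics.
    Points lacking any band keep NaN attributes and ``enriched`` = 0.
    """
    if not images:
        raise ValueError("need at least one capture")
    if cloud.colors is None or cloud.normals is None:
        raise ValueError("enrichment needs a cloud with colors and normals")
    params = params or MappingParams()
    n = len(cloud)
    n_cams = len(images)
    index = build_index(cloud)

    # per-view sample tables: (n_cams, n) value arrays per band + weights
    vals = {b: np.full((n_cams, n), np.nan) for b in BANDS}
    wts = np.zeros((n_cams, n))
    per_camera_visible: list[int] = []

    for cam_id, (bands, pose, model) in enumerate(zip(images, poses, models)):
        mask = visible_points(cloud, pose, model, params, index, camera_id=cam_id)
        vis = np.nonzero(mask.visible)[0]
        per_camera_visible.append(len(vis))
        if len(vis) == 0:
            continue
        cam_pts = world_to_camera(pose, cloud.positions[vis])
        pix, _ = fisheye_project(model, cam_pts)
        if params.edge_depth_factor is not None:
            radius = _resolve_radius(cloud, params)
            keep = _away_from_depth_edges(
                cloud.positions[vis], pix, pose, model,
                params.edge_depth_factor * radius, params.edge_px)
            vis, pix = vis[keep], pix[keep]
            if len(vis) == 0:
                continue
        ang = view_angle(pose, cloud.positions[vis], cloud.normals[vis])
        cls = classify_view(ang)
        wts[cam_id, vis] = [params.class_weights[c] for c in np.atleast_1d(cls)]
        for b in BANDS:
            if b in bands:
                vals[b][cam_id, vis] = sample_band(bands[b], pix,
                                                   params.max_support_spread)

    out = cloud.copy()
    band_vals = {}
    for b in BANDS:
        band_vals[b] = _aggregate_columns(vals[b], wts, params)
        out.attributes[f"{b}_refl"] = band_vals[b]
    n_views = ((np.isfinite(np.stack([vals[b] for b in BANDS])).any(axis=0))
               & (wts > 0)).sum(axis=0).astype(np.int32)
    complete = np.all([np.isfinite(band_vals[b]) for b in BANDS], axis=0)
    if params.neighborhood_consistency_rel is not None and complete.sum() > 20:
        radius = params.neighborhood_radius_factor * _resolve_radius(cloud, params)
        complete &= _neighborhood_consistent(
            cloud.positions, band_vals, complete, radius,
            params.neighborhood_consistency_rel)
    if not np.any(complete):
        raise ValueError("no point received a complete set of band samples; "
                         "check camera poses against the cloud")
    nd = np.full(n, np.nan)
    nd[complete] = ndvi(band_vals["nir"][complete], band_vals["red"][complete])
    out.attributes["ndvi"] = nd
    out.attributes["n_views"] = n_views
    out.attributes["enriched"] = complete.astype(np.int32)
    report = EnrichmentReport(
        n_points=n,
        n_enriched=int(complete.sum()),
        per_band_coverage={b: int(np.isfinite(band_vals[b]).sum()) for b in BANDS},
        per_camera_visible=per_camera_visible,
    )
    return out, report


def projection_coverage_image(image: ReflectanceImage, mask: VisibilityMask,
                              model: FisheyeModel, pose: CameraPose,
                              cloud: PointCloud, mark_value: float = 0.0
                              ) -> np.ndarray:
    """Copy of the raster with every pixel hit by a visible point marked.

    Mirrors the image-space check of the mapping: project all visible points
    and stamp their (rounded) pixels with ``mark_value``.
    """
    out = image.grid.copy()
    vis = np.nonzero(mask.visible)[0]
    if len(vis) == 0:
        return out
    pix, ok = fisheye_project(model, world_to_camera(pose, cloud.positions[vis]))
    pix = pix[np.atleast_1d(ok)]
    xi = np.round(pix[:, 0]).astype(int)
    yi = np.round(pix[:, 1]).astype(int)
    keep = (xi >= 0) & (xi < image.width) & (yi >= 0) & (yi < image.height)
    out[yi[keep], xi[keep]] = mark_value
    return out
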