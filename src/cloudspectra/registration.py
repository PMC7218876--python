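"""Rigid registration of the multispectral cloud onto the RGB reference cloud.

Alignment is iterative closest point (ICP) with correspondences weighted by
both proximity and normal compatibility: a source point matched to its
nearest reference point at distance d with normal angle φ gets weight
exp(−d²/d_max²)·max(0, cos φ).  Each iteration solves the weighted
orthogonal-Procrustes problem in closed form, minimizing the mean squared
residual (1/Np)·Σ ||xᵢ − R·pᵢ − t||².

Alignment quality is reported as the RMSE of nearest-neighbor 3D distances
from the aligned cloud into the reference cloud.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud, SpatialIndex, build_index

__all__ = [
    "RigidTransform",
    "CorrespondenceSet",
    "AlignmentReport",
    "IcpParams",
    "match_points",
    "fit_transform",
    "icp",
    "alignment_rmse",
]


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ R·x + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def apply_to_cloud(self, cloud: PointCloud) -> PointCloud:
        out = cloud.copy()
        out.positions = self.apply(cloud.positions)
        if out.normals is not None:
            out.normals = out.normals @ self.rotation.T
        return out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.matrix().tolist()}, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "RigidTransform":
        with open(path) as fh:
            M = np.array(json.load(fh)["matrix"], dtype=np.float64).reshape(4, 4)
        return cls(M[:3, :3], M[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))


@dataclass
class CorrespondenceSet:
    """Weighted source→target nearest-neighbor pairs."""

    source_idx: np.ndarray
    target_idx: np.ndarray
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.source_idx)


@dataclass
class AlignmentReport:
    iterations: int
    final_error: float
    rmse: float
    converged: bool
    objective_history: list[float] = field(default_factory=list)


def match_points(source: PointCloud, target: PointCloud,
                 target_index: SpatialIndex | None = None,
                 max_dist: float = np.inf,
                 max_normal_angle: float = 180.0) -> CorrespondenceSet:
    """Nearest-neighbor pairing with distance and normal-compatibility gating.

    weight = exp(−d²/max_dist²) · max(0, cos φ); pairs beyond ``max_dist`` or
    with normal angle above ``max_normal_angle`` are dropped.
    """
    if source.normals is None or target.normals is None:
        raise ValueError("both clouds need normals for weighted matching")
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    if target_index is None:
        target_index = build_index(target)
    d, j = target_index.tree.query(source.positions, k=1)
    cosang = np.einsum("ij,ij->i", source.normals, target.normals[j])
    cosang = np.clip(cosang, -1.0, 1.0)
    cos_limit = math.cos(math.radians(max_normal_angle))
    keep = (d <= max_dist) & (cosang >= cos_limit) & (cosang > 0)
    if not np.any(keep):
        raise ValueError("no correspondences: clouds do not overlap under the gates")
    i = np.nonzero(keep)[0]
    if np.isfinite(max_dist):
        w_dist = np.exp(-(d[keep] ** 2) / max_dist ** 2)
    else:
        w_dist = np.ones(keep.sum())
    w = w_dist * np.maximum(0.0, cosang[keep])
    return CorrespondenceSet(i, j[keep], w)


def fit_transform(corr: CorrespondenceSet, source: PointCloud,
                  target: PointCloud) -> RigidTransform:
    """Weighted closed-form rigid fit (Kabsch / orthogonal Procrustes).

    Minimizes Σ wᵢ‖xᵢ − R·pᵢ − t‖² over proper rotations; reflections are
    rejected by flipping the sign of the smallest singular direction.
    """
    if len(corr) < 3:
        raise ValueError("need at least 3 correspondences")
    p = source.positions[corr.source_idx]
    x = target.positions[corr.target_idx]
    w = corr.weights / corr.weights.sum()
    p_bar = w @ p
    x_bar = w @ x
    P = p - p_bar
    X = x - x_bar
    H = (P * w[:, None]).T @ X
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-15 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear or coincident) correspondence geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = x_bar - R @ p_bar
    return RigidTransform(R, t)


def _objective(corr: CorrespondenceSet, src_pos: np.ndarray, target: PointCloud) -> float:
    """Mean squared residual over correspondences (unweighted, per the objective)."""
    diff = target.positions[corr.target_idx] - src_pos[corr.source_idx]
    return float(np.mean(np.einsum("ij,ij->i", diff, diff)))


@dataclass
class IcpParams:
    max_iter: int = 50
    tol: float = 1e-12
    max_dist: float | list[float] = np.inf   # scalar or per-iteration schedule
    max_normal_angle: float = 60.0

    def dist_at(self, it: int) -> float:
        if isinstance(self.max_dist, (list, tuple)):
            return self.max_dist[min(it, len(self.max_dist) - 1)]
        return self.max_dist


def icp(source: PointCloud, target: PointCloud,
        params: IcpParams | None = None,
        initial: RigidTransform | None = None
        ) -> tuple[RigidTransform, AlignmentReport]:
    """Iterative closest point: alternate matching and closed-form fitting.

    Iterations that would increase the objective are rejected; the best
    transform seen is returned.  Convergence means the objective decrease
    fell below ``tol`` (relative to the current objective plus 1e-300).
    """
    params = params or IcpParams()
    T = initial or RigidTransform.identity()
    tgt_index = build_index(target)
    best_T = T
    best_obj = np.inf
    history: list[float] = []
    converged = False
    n_iter = 0
    for it in range(params.max_iter):
        n_iter = it + 1
        moved = T.apply_to_cloud(source)
        try:
            corr = match_points(moved, target, tgt_index,
                                max_dist=params.dist_at(it),
                                max_normal_angle=params.max_normal_angle)
        except ValueError:
            break                      # correspondence collapse: keep best so far
        obj = _objective(corr, moved.positions, target)
        if obj > best_obj * (1.0 + 1e-12):
            break                      # rejected step
        improve = best_obj - obj
        best_obj, best_T = obj, T
        history.append(obj)
        if it > 0 and improve < params.tol * (obj + 1e-300):
            converged = True
            break
        try:
            delta = fit_transform(corr, moved, target)
        except ValueError:
            break
        T = delta.compose(T)
    rmse = alignment_rmse(target, best_T.apply_to_cloud(source), tgt_index)
    return best_T, AlignmentReport(iterations=n_iter,
                                   final_error=float(best_obj),
                                   rmse=rmse, converged=converged,
                                   objective_history=history)


def alignment_rmse(reference: PointCloud, aligned: PointCloud,
                   reference_index: SpatialIndex | None = None) -> float:
    """Root-mean-square nearest-neighbor 3D distance from ``aligned`` into ``reference``."""
    if len(reference) == 0 or len(aligned) == 0:
        raise ValueError("clouds must be non-empty")
    if reference_index is None:
        reference_index = build_index(reference)
    d, _ = reference_index.tree.query(aligned.positions, k=1)
    return float(np.sqrt(np.mean(d ** 2)))
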