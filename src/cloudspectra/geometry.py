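"""Camera poses, fisheye projection and view-angle classification.

The multispectral imager is a wide-angle (fisheye) camera.  A camera-frame
point (X, Y, Z), Z along the optical axis into the scene, projects through
a polynomial radial model: the off-axis angle is normalized to

    θ = (2/π) · arctan(√(X²+Y²) / Z),   θ ∈ [0, 1],

the image radius is the quartic ρ = θ + p2·θ² + p3·θ³ + p4·θ⁴, and pixel
coordinates follow from an affine 2×2 map (entries C, D, E, F, in pixels)
plus the principal point (cx, cy).  Note θ is *normalized*: θ = 1 is a ray
90° off axis, so the model covers the full hemisphere.

View reliability is classified from the angle between a point's surface
normal and the direction from the point to the camera: perpendicular
(< 25°), oblique (25°–60°) or indirect (> 60°).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "CameraPose",
    "FisheyeModel",
    "ViewClass",
    "world_to_camera",
    "camera_to_world",
    "fisheye_project",
    "fisheye_unproject",
    "in_frustum",
    "view_angle",
    "classify_view",
    "read_camera_sidecar",
    "write_camera_sidecar",
]


@dataclass(frozen=True)
class CameraPose:
    """Rigid camera pose: world→camera is ``rotation @ (p − center)``.

    Camera frame: +Z along the optical axis into the scene, +X right, +Y down.
    """

    center: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=np.float64).reshape(3))
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        object.__setattr__(self, "rotation", R)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must have det +1 (no reflection)")

    @property
    def optical_axis(self) -> np.ndarray:
        """Unit viewing direction (camera +Z) in world coordinates."""
        return self.rotation.T @ np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class FisheyeModel:
    """Polynomial fisheye intrinsics: ρ(θ) quartic, affine pixel map, principal point."""

    p2: float
    p3: float
    p4: float
    affine: np.ndarray          # 2×2, entries C, D / E, F in pixels
    principal_point: tuple[float, float]
    image_size: tuple[int, int]  # (width, height)
    theta_max: float = 1.0

    def __post_init__(self) -> None:
        A = np.asarray(self.affine, dtype=np.float64).reshape(2, 2)
        object.__setattr__(self, "affine", A)
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("affine matrix must be invertible")
        if not (0.0 < self.theta_max <= 1.0):
            raise ValueError("theta_max must be in (0, 1]")

    def rho(self, theta):
        t = np.asarray(theta, dtype=np.float64)
        return t + self.p2 * t**2 + self.p3 * t**3 + self.p4 * t**4


def world_to_camera(pose: CameraPose, points: np.ndarray) -> np.ndarray:
    """World → camera frame; accepts (3,) or (n, 3)."""
    p = np.asarray(points, dtype=np.float64)
    return (p - pose.center) @ pose.rotation.T


def camera_to_world(pose: CameraPose, cam_points: np.ndarray) -> np.ndarray:
    p = np.asarray(cam_points, dtype=np.float64)
    return p @ pose.rotation + pose.center


def fisheye_project(model: FisheyeModel, cam_points: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Project camera-frame points to pixel coordinates.

    Returns ``(pixels, ok)`` where ``pixels`` is (n, 2) and ``ok`` is a
    boolean mask; points with Z ≤ 0 or θ > theta_max are not projectable
    (their pixel rows are NaN).  A scalar (3,) input returns shapes
    (2,) and ().
    """
    p = np.asarray(cam_points, dtype=np.float64)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    X, Y, Z = p[:, 0], p[:, 1], p[:, 2]
    r = np.hypot(X, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = (2.0 / math.pi) * np.arctan2(r, Z)
    ok = (Z > 0) & (theta <= model.theta_max + 1e-15)
    rho = model.rho(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(r > 0, rho / np.where(r > 0, r, 1.0), 0.0)
    h = np.stack([scale * X, scale * Y], axis=1)          # (xhbt, yhbt)
    pix = h @ model.affine.T + np.asarray(model.principal_point, dtype=np.float64)
    pix[~ok] = np.nan
    if single:
        return pix[0], ok[0]
    return pix, ok


def in_frustum(model: FisheyeModel, pose: CameraPose, points: np.ndarray) -> np.ndarray:
    """True where the point projects inside the image bounds."""
    pix, ok = fisheye_project(model, world_to_camera(pose, points))
    pix = np.atleast_2d(pix)
    ok = np.atleast_1d(ok)
    w, h = model.image_size
    inside = ok & (pix[:, 0] >= 0) & (pix[:, 0] < w) & (pix[:, 1] >= 0) & (pix[:, 1] < h)
    return inside[0] if np.asarray(points).ndim == 1 else inside


def fisheye_unproject(model: FisheyeModel, pixels: np.ndarray) -> np.ndarray:
    """Pixel → unit ray in the camera frame (numeric inverse of the quartic).

    For each pixel, invert the affine map to (xhbt, yhbt), take ρ = |(xhbt,
    yhbt)| and solve ρ(θ) = ρ for θ ∈ [0, 1] by bracketed root finding; the
    ray's off-axis angle is θ·π/2.
    """
    px = np.atleast_2d(np.asarray(pixels, dtype=np.float64))
    inv = np.linalg.inv(model.affine)
    h = (px - np.asarray(model.principal_point)) @ inv.T
    rho = np.hypot(h[:, 0], h[:, 1])
    rho_max = float(model.rho(1.0))
    rays = np.empty((len(px), 3))
    for i, (hx, hy, rh) in enumerate(zip(h[:, 0], h[:, 1], rho)):
        if rh < 1e-15:
            rays[i] = (0.0, 0.0, 1.0)
            continue
        if rh > rho_max:
            raise ValueError(f"pixel {px[i]} maps outside the fisheye domain")
        theta = brentq(lambda t: model.rho(t) - rh, 0.0, 1.0, xtol=1e-14)
        alpha = theta * math.pi / 2.0
        rays[i] = (math.sin(alpha) * hx / rh, math.sin(alpha) * hy / rh, math.cos(alpha))
    return rays[0] if np.asarray(pixels).ndim == 1 else rays


class ViewClass(enum.Enum):
    """Reliability class of one observation, from the surface-to-camera angle."""

    PERPENDICULAR = "perpendicular"   # [0°, 25°)
    OBLIQUE = "oblique"               # [25°, 60°]
    INDIRECT = "indirect"             # (60°, 180°]


def view_angle(pose: CameraPose, points: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Angle in degrees between each point's normal and its point→camera direction."""
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n = np.atleast_2d(np.asarray(normals, dtype=np.float64))
    to_cam = pose.center - p
    d = np.linalg.norm(to_cam, axis=1)
    if np.any(d == 0):
        raise ValueError("point coincides with the camera center")
    cosang = np.einsum("ij,ij->i", n, to_cam) / d
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang[0] if np.asarray(points).ndim == 1 else ang


_VIEW_BOUNDS = (25.0, 60.0)


def classify_view(angle):
    """Map view angles (deg) to classes: [0,25) perpendicular, [25,60] oblique, (60,180] indirect."""
    a = np.asarray(angle, dtype=np.float64)
    if np.any(a < 0) or np.any(a > 180):
        raise ValueError("view angle must be in [0, 180] degrees")
    if a.ndim == 0:
        if a < _VIEW_BOUNDS[0]:
            return ViewClass.PERPENDICULAR
        if a <= _VIEW_BOUNDS[1]:
            return ViewClass.OBLIQUE
        return ViewClass.INDIRECT
    return np.array([classify_view(float(x)) for x in a], dtype=object)


# ---------------------------------------------------------------------------
# Sidecar I/O — one YAML record per image
# ---------------------------------------------------------------------------

def write_camera_sidecar(path: str, pose: CameraPose, model: FisheyeModel) -> None:
    doc = {
        "center": [float(v) for v in pose.center],
        "rotation": [float(v) for v in pose.rotation.ravel()],
        "p2": float(model.p2), "p3": float(model.p3), "p4": float(model.p4),
        "C": float(model.affine[0, 0]), "D": float(model.affine[0, 1]),
        "E": float(model.affine[1, 0]), "F": float(model.affine[1, 1]),
        "cx": float(model.principal_point[0]), "cy": float(model.principal_point[1]),
        "width": int(model.image_size[0]), "height": int(model.image_size[1]),
        "theta_max": float(model.theta_max),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_camera_sidecar(path: str) -> tuple[CameraPose, FisheyeModel]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    required = ["center", "rotation", "p2", "p3", "p4",
                "C", "D", "E", "F", "cx", "cy", "width", "height"]
    missing = [f for f in required if f not in doc]
    if missing:
        raise ValueError(f"camera sidecar {path} missing fields: {missing}")
    pose = CameraPose(np.array(doc["center"]), np.array(doc["rotation"]).reshape(3, 3))
    model = FisheyeModel(
        p2=doc["p2"], p3=doc["p3"], p4=doc["p4"],
        affine=np.array([[doc["C"], doc["D"]], [doc["E"], doc["F"]]]),
        principal_point=(doc["cx"], doc["cy"]),
        image_size=(int(doc["width"]), int(doc["height"])),
        theta_max=float(doc.get("theta_max", 1.0)),
    )
    return pose, model
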