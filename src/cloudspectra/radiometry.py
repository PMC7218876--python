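"""Radiometric calibration: raw multispectral counts → surface reflectance.

The sensor records two irradiance streams: the sunshine sensor on top of the
rig measures the incident flux Φei, and each band's imager measures the flux
Φer reflected by the scene.  Reflectance is their calibrated ratio

    R = K · Φer / (Φei · cos θ),

with θ the angle between the sun-ray direction and the sunshine-sensor axis
and K a per-band coefficient estimated from shots of a panel of known
reflectance.  The two fluxes are recovered from device metadata:

    Φei = ν / (g · τ)                      (sunshine counts ν, gain g, exposure τ)
    Φer = f²·(ρ − B) / (A · γ · ε) + C     (pixel ρ, f-number f, ISO γ, exposure ε,
                                            per-camera coefficients A, B, C)

NDVI = (NIR − Red)/(NIR + Red) is computed from calibrated reflectances.

Bands are named ``green``, ``red``, ``reg`` (red-edge) and ``nir``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

__all__ = [
    "BANDS",
    "SunshineReading",
    "BandCalibration",
    "PanelShot",
    "ReflectanceImage",
    "incident_irradiance",
    "reflected_irradiance",
    "panel_calibration",
    "compute_reflectance",
    "reflectance_image",
    "ndvi",
    "simulate_pixel",
    "read_radiometry_sidecar",
    "write_radiometry_sidecar",
]

BANDS = ("green", "red", "reg", "nir")


@dataclass(frozen=True)
class SunshineReading:
    """One sunshine-sensor sample: counts ν, gain g, exposure τ (s), sun angle θ (deg)."""

    nu: float
    gain: float
    tau: float
    sun_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.tau <= 0:
            raise ValueError("exposure time tau must be > 0")
        if not (0.0 <= self.sun_angle < 90.0):
            raise ValueError("sun_angle must be in [0, 90) degrees")


@dataclass(frozen=True)
class BandCalibration:
    """Per-band imager metadata and calibration coefficients.

    ``A``, ``B``, ``C`` are factory per-camera coefficients; ``K`` is the
    panel-derived band coefficient (``None`` until calibrated).
    """

    band: str
    f_number: float = 2.2
    iso: float = 100.0
    exposure: float = 1e-3
    A: float = 1.0
    B: float = 0.0
    C: float = 0.0
    K: float | None = None

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}, expected one of {BANDS}")
        if self.f_number <= 0 or self.iso <= 0 or self.exposure <= 0:
            raise ValueError("f_number, iso and exposure must be > 0")
        if self.A == 0:
            raise ValueError("calibration coefficient A must be nonzero")


@dataclass(frozen=True)
class PanelShot:
    """One capture of the calibration panel for one band."""

    band: str
    known_reflectance: float
    mean_pixel: float
    reading: SunshineReading
    calibration: BandCalibration

    def __post_init__(self) -> None:
        if not (0.0 < self.known_reflectance < 1.0):
            raise ValueError("panel reflectance must be in (0, 1)")


@dataclass
class ReflectanceImage:
    """Single-band reflectance raster; NaN marks missing pixels."""

    band: str
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2D")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]


def incident_irradiance(reading: SunshineReading) -> float:
    """Incident flux Φei = ν / (g·τ) from a sunshine-sensor sample."""
    return reading.nu / (reading.gain * reading.tau)


def reflected_irradiance(pixel, cal: BandCalibration):
    """Reflected flux Φer = f²·(ρ − B)/(A·γ·ε) + C; accepts scalar or array ρ."""
    denom = cal.A * cal.iso * cal.exposure
    if denom == 0:
        raise ValueError("A·iso·exposure must be nonzero")
    return cal.f_number ** 2 * (np.asarray(pixel, dtype=np.float64) - cal.B) / denom + cal.C


def panel_calibration(shots: list[PanelShot], saturation_fraction: float = 0.98,
                      dynamic_range: float = 65535.0) -> BandCalibration:
    """Estimate the band coefficient K from calibration-panel shots.

    Per shot, Ki = Ri·Φei/Φer.  K is the arithmetic mean over valid shots;
    a shot is excluded when its panel flux Φer ≤ 0 or its mean pixel is
    saturated (≥ ``saturation_fraction`` of ``dynamic_range``).
    """
    if not shots:
        raise ValueError("need at least one panel shot")
    band = shots[0].band
    if any(s.band != band for s in shots):
        raise ValueError("all panel shots must be of the same band")
    ks = []
    for s in shots:
        if s.mean_pixel >= saturation_fraction * dynamic_range:
            continue
        phi_ei = incident_irradiance(s.reading)
        phi_er = float(reflected_irradiance(s.mean_pixel, s.calibration))
        if phi_er <= 0 or phi_ei <= 0:
            continue
        ks.append(s.known_reflectance * phi_ei / phi_er)
    if not ks:
        raise ValueError(f"no valid panel shots for band {band!r}")
    return replace(shots[0].calibration, K=float(np.mean(ks)))


def compute_reflectance(pixel, cal: BandCalibration, reading: SunshineReading,
                        r_max: float = 2.0):
    """Calibrated reflectance R = K·Φer/(Φei·cos θ), clipped to [0, r_max].

    Scalar or array ``pixel``.  NaN pixels propagate as NaN.  The number of
    clipped finite values is stored in ``compute_reflectance.last_clip_count``.
    """
    if cal.K is None:
        raise ValueError("calibration has no K; run panel_calibration first")
    cos_t = math.cos(math.radians(reading.sun_angle))
    phi_ei = incident_irradiance(reading)
    if phi_ei * cos_t <= 0:
        raise ValueError("incident flux times cos(sun angle) must be positive")
    r = cal.K * reflected_irradiance(pixel, cal) / (phi_ei * cos_t)
    r = np.asarray(r, dtype=np.float64)
    finite = np.isfinite(r)
    clipped = finite & ((r < 0.0) | (r > r_max))
    compute_reflectance.last_clip_count = int(np.count_nonzero(clipped))
    out = np.where(finite, np.clip(r, 0.0, r_max), r)
    return float(out) if out.ndim == 0 else out


compute_reflectance.last_clip_count = 0


def reflectance_image(raw: np.ndarray, band: str, cal: BandCalibration,
                      reading: SunshineReading, r_max: float = 2.0) -> ReflectanceImage:
    """Convert a raw single-band raster to a :class:`ReflectanceImage`."""
    return ReflectanceImage(band, compute_reflectance(raw, cal, reading, r_max=r_max))


def simulate_pixel(reflectance, cal: BandCalibration, reading: SunshineReading):
    """Inverse radiometric chain: the raw pixel ρ that yields ``reflectance``.

    Φer = R·Φei·cos θ / K, then ρ = (Φer − C)·A·γ·ε / f² + B.  This is the
    forward image-synthesis model used by the synthetic renderer and the
    round-trip tests.
    """
    if cal.K is None:
        raise ValueError("calibration has no K")
    cos_t = math.cos(math.radians(reading.sun_angle))
    phi_ei = incident_irradiance(reading)
    phi_er = np.asarray(reflectance, dtype=np.float64) * phi_ei * cos_t / cal.K
    rho = (phi_er - cal.C) * cal.A * cal.iso * cal.exposure / cal.f_number ** 2 + cal.B
    return float(rho) if rho.ndim == 0 else rho


def ndvi(nir, red):
    """(NIR − Red)/(NIR + Red), defined as 0 where both are 0; scalar or array."""
    nir = np.asarray(nir, dtype=np.float64)
    red = np.asarray(red, dtype=np.float64)
    if np.any(nir[np.isfinite(nir)] < 0) or np.any(red[np.isfinite(red)] < 0):
        raise ValueError("reflectances must be non-negative")
    s = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, (nir - red) / np.where(s > 0, s, 1.0), 0.0)
    out = np.where(np.isnan(s), np.nan, out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Sidecar I/O — YAML with exactly the field names of the device metadata
# ---------------------------------------------------------------------------

_SIDE_FIELDS = ("nu", "gain", "tau", "sun_angle", "f_number", "iso",
                "exposure", "A", "B", "C")


def write_radiometry_sidecar(path: str, cal: BandCalibration,
                             reading: SunshineReading) -> None:
    doc = {
        "band": cal.band,
        "nu": float(reading.nu), "gain": float(reading.gain),
        "tau": float(reading.tau), "sun_angle": float(reading.sun_angle),
        "f_number": float(cal.f_number), "iso": float(cal.iso),
        "exposure": float(cal.exposure),
        "A": float(cal.A), "B": float(cal.B), "C": float(cal.C),
    }
    if cal.K is not None:
        doc["K"] = float(cal.K)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_radiometry_sidecar(path: str) -> tuple[BandCalibration, SunshineReading]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    missing = [f for f in _SIDE_FIELDS if f not in doc]
    if missing:
        raise ValueError(f"radiometry sidecar {path} missing fields: {missing}")
    reading = SunshineReading(nu=doc["nu"], gain=doc["gain"], tau=doc["tau"],
                              sun_angle=doc["sun_angle"])
    cal = BandCalibration(band=doc.get("band", "green"), f_number=doc["f_number"],
                          iso=doc["iso"], exposure=doc["exposure"],
                          A=doc["A"], B=doc["B"], C=doc["C"], K=doc.get("K"))
    return cal, reading
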