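"""Rotational and additive sensor-disturbance models.

Two disturbance families are modeled, mirroring the anomalies body-worn
inertial sensors suffer at runtime:

* **Rotational noise (RN)** — the sensor's local frame is rotated by an
  Euler-angle rotation (roll φ about X, pitch θ about Y, yaw ψ about Z,
  composed as ``Rz(ψ) @ Ry(θ) @ Rx(φ)``).  For a biaxial sensor the raw
  vector is ``(x_raw, y_raw, 0)``; only the first two components of the
  rotated vector are observed, so energy can leak into the unobserved
  third axis but never be gained.

* **Additive noise (AN)** — zero-mean white Gaussian noise of standard
  deviation ``σ_AN`` (quoted in mG) added independently per sample and
  per axis.  A coarse surrogate for displacement, uncalibration and
  battery/transmission faults.

Disturbances are meant to be applied to *test* data only: a system
trained at design time never saw them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .signals import LabeledSignalSet

__all__ = [
    "RotationAngles",
    "DisturbanceSpec",
    "rotation_matrix",
    "apply_rotation_biaxial",
    "apply_additive_noise",
    "sample_rotation",
    "disturb",
]

ROTATIONAL = "rotational"
ADDITIVE = "additive"
GRANULARITIES = ("window", "run")


def _canonical_degrees(angle: float) -> float:
    """Map a finite angle in degrees into (-180, 180]."""
    if not math.isfinite(angle):
        raise ValueError("rotation angles must be finite")
    a = math.fmod(angle, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class RotationAngles:
    """Euler angles in degrees: phi about X, theta about Y, psi about Z."""

    phi: float
    theta: float
    psi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", _canonical_degrees(self.phi))
        object.__setattr__(self, "theta", _canonical_degrees(self.theta))
        object.__setattr__(self, "psi", _canonical_degrees(self.psi))

    @property
    def radians(self) -> tuple[float, float, float]:
        return (
            math.radians(self.phi),
            math.radians(self.theta),
            math.radians(self.psi),
        )


@dataclass(frozen=True)
class DisturbanceSpec:
    """Which sensors get which disturbance at which level.

    ``level`` is the maximum rotation angle in degrees for ``kind ==
    "rotational"`` (per-axis angles are drawn uniformly from [0, level]),
    or the noise standard deviation σ_AN in mG for ``kind == "additive"``.
    ``granularity`` controls rotational angle sampling: ``"window"``
    redraws angles per window (arbitrary per-instance variation),
    ``"run"`` draws one rotation per sensor (a fixed misplacement).
    """

    kind: str
    level: float
    sensors: tuple[int, ...] = ()
    granularity: str = "window"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (ROTATIONAL, ADDITIVE):
            raise ValueError(f"unknown disturbance kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("disturbance level must be non-negative")
        if self.granularity not in GRANULARITIES:
            raise ValueError(f"granularity must be one of {GRANULARITIES}")
        object.__setattr__(self, "sensors", tuple(sorted(set(self.sensors))))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "level": self.level,
            "sensors": list(self.sensors),
            "granularity": self.granularity,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisturbanceSpec":
        return cls(
            kind=d["kind"],
            level=float(d["level"]),
            sensors=tuple(d.get("sensors", ())),
            granularity=d.get("granularity", "window"),
            seed=int(d.get("seed", 0)),
        )


def rotation_matrix(angles: RotationAngles) -> np.ndarray:
    """The 3x3 Euler rotation matrix ``Rz(psi) @ Ry(theta) @ Rx(phi)``.

    Orthonormal with determinant +1 (an element of SO(3)).
    """
    phi, theta, psi = angles.radians
    cf, sf = math.cos(phi), math.sin(phi)
    ct, st = math.cos(theta), math.sin(theta)
    cp, sp = math.cos(psi), math.sin(psi)
    return np.array(
        [
            [ct * cp, -cf * sp + sf * st * cp, sf * sp + cf * st * cp],
            [ct * sp, cf * cp + sf * st * sp, -sf * cp + cf * st * sp],
            [-st, sf * ct, cf * ct],
        ]
    )


def _biaxial_coefficients(angles: RotationAngles) -> tuple[float, float, float, float]:
    """Coefficients (axx, axy, ayx, ayy) of the biaxial shortcut.

    With ``z_raw = 0`` the rotated in-plane signals depend only on the
    upper-left 3x2 block of the rotation matrix:
    ``x_rot = axx*x_raw + axy*y_raw``; ``y_rot = ayx*x_raw + ayy*y_raw``.
    """
    phi, theta, psi = angles.radians
    cf, sf = math.cos(phi), math.sin(phi)
    ct, st = math.cos(theta), math.sin(theta)
    cp, sp = math.cos(psi), math.sin(psi)
    axx = ct * cp
    axy = -cf * sp + sf * st * cp
    ayx = ct * sp
    ayy = cf * cp + sf * st * sp
    return axx, axy, ayx, ayy


def apply_rotation_biaxial(
    x_raw: np.ndarray, y_raw: np.ndarray, angles: RotationAngles
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate biaxial signals: the observed projection of the full 3D rotation.

    Equivalent (to machine precision) to applying :func:`rotation_matrix`
    to ``(x_raw, y_raw, 0)`` samplewise and keeping the first two
    components.
    """
    x_raw = np.asarray(x_raw, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float)
    if x_raw.shape != y_raw.shape:
        raise ValueError("x_raw and y_raw must have equal shapes")
    axx, axy, ayx, ayy = _biaxial_coefficients(angles)
    return axx * x_raw + axy * y_raw, ayx * x_raw + ayy * y_raw


def apply_additive_noise(
    signal: np.ndarray, sigma_mG: float, rng: np.random.Generator
) -> np.ndarray:
    """Add zero-mean white Gaussian noise of standard deviation ``sigma_mG`` (mG)."""
    if sigma_mG < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma_mG == 0:
        return signal.copy()
    return signal + (sigma_mG / 1000.0) * rng.standard_normal(signal.shape)


def sample_rotation(max_angle_deg: float, rng: np.random.Generator) -> RotationAngles:
    """Draw each Euler angle independently and uniformly from [0, max]."""
    if max_angle_deg < 0:
        raise ValueError("maximum rotation angle must be non-negative")
    if max_angle_deg == 0:
        return RotationAngles(0.0, 0.0, 0.0)
    draws = rng.uniform(0.0, max_angle_deg, size=3)
    return RotationAngles(*draws)


def _disturb_sensor_arrays(
    x: np.ndarray,
    y: np.ndarray,
    kind: str,
    level: float,
    rng: np.random.Generator,
    granularity: str = "window",
) -> tuple[np.ndarray, np.ndarray]:
    """Disturb one sensor's window stack ``x, y`` of shape (W, T).

    Rotational: fresh angles per window (or one triple for the whole
    stack in "run" mode).  Additive: fresh noise per sample per axis.
    """
    if level == 0:
        return x.copy(), y.copy()
    if kind == ADDITIVE:
        return (
            apply_additive_noise(x, level, rng),
            apply_additive_noise(y, level, rng),
        )
    # rotational
    if granularity == "run":
        angles = sample_rotation(level, rng)
        return apply_rotation_biaxial(x, y, angles)
    w = x.shape[0]
    xr = np.empty_like(x)
    yr = np.empty_like(y)
    coeffs = np.empty((w, 4))
    for i in range(w):
        coeffs[i] = _biaxial_coefficients(sample_rotation(level, rng))
    xr = coeffs[:, 0:1] * x + coeffs[:, 1:2] * y
    yr = coeffs[:, 2:3] * x + coeffs[:, 3:4] * y
    return xr, yr


def disturb(dataset: LabeledSignalSet, spec: DisturbanceSpec) -> LabeledSignalSet:
    """Apply ``spec`` to the selected sensors of ``dataset``.

    Returns a new set: disturbed sensors transformed, everything else
    (including all labels) bit-identical; the input is never modified.
    Windows actually altered get their provenance flag raised.
    """
    columns = {s: dataset.sensor_index(s) for s in spec.sensors}  # raises for unknown ids
    out = dataset.copy()
    if not spec.sensors or spec.level == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    for sensor_id in spec.sensors:
        j = columns[sensor_id]
        xr, yr = _disturb_sensor_arrays(
            dataset.x[:, j], dataset.y[:, j], spec.kind, spec.level, rng,
            spec.granularity,
        )
        out.x[:, j] = xr
        out.y[:, j] = yr
        out.disturbed[:, j] = True
    return out
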