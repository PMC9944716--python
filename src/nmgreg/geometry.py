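"""The 6-DOF rigid transform optimized by the registration.

Parameters are three rotation angles (rx, ry, rz, degrees) and three
translations (tx, ty, tz, mm).  Rotations are intrinsic, applied in the
order Z, then Y, then X (matrix R = Rz @ Ry @ Rx), about a configurable
world-space center (by default the floating volume's physical center);
the translation is applied afterwards:

    p' = R (p - c) + c + t

Decomposition back to Euler angles is supported away from gimbal lock
(|ry| -> 90 deg is documented as unsupported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PARAM_NAMES = ("rx", "ry", "rz", "tx", "ty", "tz")


@dataclass
class RigidTransform6:
    """Rigid pose: rotations in degrees, translations in mm."""

    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vals = [self.rx, self.ry, self.rz, self.tx, self.ty, self.tz, *self.center]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite transform parameters: {vals}")
        for name in ("rx", "ry", "rz"):
            a = getattr(self, name)
            if not (-180.0 < a <= 180.0):
                raise ValueError(f"{name}={a} outside (-180, 180]")

    def params(self) -> np.ndarray:
        """Parameter vector in (rx, ry, rz, tx, ty, tz) order."""
        return np.array([self.rx, self.ry, self.rz, self.tx, self.ty, self.tz], dtype=float)

    @classmethod
    def from_params(cls, theta, center=(0.0, 0.0, 0.0)) -> "RigidTransform6":
        rx, ry, rz, tx, ty, tz = (float(v) for v in theta)
        return cls(rx=rx, ry=ry, rz=rz, tx=tx, ty=ty, tz=tz, center=tuple(center))

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotation_matrix(t: RigidTransform6) -> np.ndarray:
    """3x3 rotation for intrinsic Z-Y-X Euler angles in degrees."""
    rx, ry, rz = np.deg2rad([t.rx, t.ry, t.rz])
    return _rot_z(rz) @ _rot_y(ry) @ _rot_x(rx)


def to_matrix(t: RigidTransform6) -> np.ndarray:
    """4x4 homogeneous pose matrix (world mm), rotation about t.center."""
    R = rotation_matrix(t)
    c = np.asarray(t.center, dtype=float)
    tvec = np.array([t.tx, t.ty, t.tz], dtype=float)
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = c - R @ c + tvec
    return m


def apply_matrix(m: np.ndarray, points) -> np.ndarray:
    """Apply a 4x4 pose matrix to an (n, 3) array of world points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite points")
    return pts @ m[:3, :3].T + m[:3, 3]


def invert_matrix(m: np.ndarray) -> np.ndarray:
    """Closed-form inverse of a rigid pose matrix (R^T, -R^T t)."""
    out = np.eye(4)
    R = m[:3, :3]
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ m[:3, 3]
    return out


def decompose_matrix(m: np.ndarray, center=(0.0, 0.0, 0.0)) -> RigidTransform6:
    """Recover (rx, ry, rz, tx, ty, tz) from a pose matrix.

    Valid away from gimbal lock (|ry| near 90 deg raises).
    """
    R = m[:3, :3]
    sy = -R[2, 0]
    if abs(sy) > 1 - 1e-9:
        raise ValueError("gimbal lock: |ry| ~ 90 deg, Euler decomposition unsupported")
    ry = np.arcsin(sy)
    rx = np.arctan2(R[2, 1], R[2, 2])
    rz = np.arctan2(R[1, 0], R[0, 0])
    c = np.asarray(center, dtype=float)
    tvec = m[:3, 3] - (c - R @ c)
    return RigidTransform6(
        rx=float(np.rad2deg(rx)),
        ry=float(np.rad2deg(ry)),
        rz=float(np.rad2deg(rz)),
        tx=float(tvec[0]),
        ty=float(tvec[1]),
        tz=float(tvec[2]),
        center=tuple(c),
    )
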