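"""Rigid 3D transforms in world (millimetre) coordinates.

A :class:`RigidTransform` maps a world point ``x`` to ``R (x - c) + c + t``
where ``R`` is a proper rotation built from three intrinsic x-y-z Euler
angles (degrees), ``c`` is the rotation center and ``t`` a translation, both
in millimetres.  The parameterisation is the one used throughout the
registration and evaluation machinery: 3 translations (mm) + 3 rotations
(degrees) about a stated center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError

__all__ = ["RigidTransform"]


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise ValidationError(f"{name} must have 3 components, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} must be finite, got {v}")
    v.flags.writeable = False
    return v


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid transform about a stated center.

    Parameters
    ----------
    translation : (3,) array-like
        Translation in mm.
    rotation_deg : (3,) array-like
        Intrinsic x-y-z Euler angles in degrees.
    center : (3,) array-like
        Rotation center in world mm.
    """

    translation: np.ndarray = field(default=(0.0, 0.0, 0.0))
    rotation_deg: np.ndarray = field(default=(0.0, 0.0, 0.0))
    center: np.ndarray = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self):
        object.__setattr__(self, "translation", _as_vec3(self.translation, "translation"))
        object.__setattr__(self, "rotation_deg", _as_vec3(self.rotation_deg, "rotation_deg"))
        object.__setattr__(self, "center", _as_vec3(self.center, "center"))

    # ------------------------------------------------------------------ #
    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center=center)

    @property
    def rotation_matrix(self) -> np.ndarray:
        """3x3 proper rotation matrix (intrinsic x-y-z Euler order)."""
        return Rotation.from_euler("XYZ", self.rotation_deg, degrees=True).as_matrix()

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix equivalent to this transform."""
        R = self.rotation_matrix
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.center + self.translation - R @ self.center
        return m

    @classmethod
    def from_matrix(cls, matrix, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Recover the 6 parameters from a 4x4 rigid matrix about ``center``.

        Exact round-trip for Euler angles away from the gimbal-lock
        configuration (middle angle ±90°).
        """
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"matrix must be 4x4, got {m.shape}")
        R = m[:3, :3]
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValidationError("matrix rotation block is not a proper rotation")
        c = np.asarray(center, dtype=float)
        angles = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
        t = m[:3, 3] - c + R @ c
        return cls(translation=t, rotation_deg=angles, center=c)

    # ------------------------------------------------------------------ #
    def apply(self, points) -> np.ndarray:
        """Map world points through the transform.

        Accepts a (3,) point or an (N, 3) array; returns the same shape.
        """
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        R = self.rotation_matrix
        out = (p - self.center) @ R.T + self.center + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        """Transform undoing this one (same rotation center)."""
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix), center=self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first), about self.center."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix, center=self.center)

    def with_center(self, center) -> "RigidTransform":
        """Same mapping re-expressed about a different rotation center."""
        return RigidTransform.from_matrix(self.matrix, center=center)

    # ------------------------------------------------------------------ #
    @property
    def params(self) -> np.ndarray:
        """Flat parameter vector (tx, ty, tz, rx, ry, rz) in mm / degrees."""
        return np.concatenate([self.translation, self.rotation_deg])

    @classmethod
    def from_params(cls, params, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        p = np.asarray(params, dtype=float).reshape(-1)
        if p.shape != (6,):
            raise ValidationError(f"expected 6 parameters, got shape {p.shape}")
        return cls(translation=p[:3], rotation_deg=p[3:], center=center)

    def to_dict(self) -> dict:
        return {
            "translation_mm": [float(x) for x in self.translation],
            "rotation_deg": [float(x) for x in self.rotation_deg],
            "center_mm": [float(x) for x in self.center],
            "matrix": [[float(x) for x in row] for row in self.matrix],
            "conventions": {
                "rotation_order": "intrinsic x-y-z",
                "mapping": "x -> R (x - c) + c + t",
                "units": "mm / degrees",
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            translation=d["translation_mm"],
            rotation_deg=d["rotation_deg"],
            center=d["center_mm"],
        )
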