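"""Rigid-body (6 degree-of-freedom) world-coordinate transforms.

A rigid transform models inter-scan subject motion: three rotation angles
about fixed (extrinsic) x, y, z axes and a translation, applied about a
rotation center expressed in world millimetres:

    T(p) = R (p - c) + c + t

Rotation matrices come from :class:`scipy.spatial.transform.Rotation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid motion: rotation (radians), translation and center (mm)."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix (extrinsic x-y-z convention)."""
        return Rotation.from_euler("xyz", self.rotation).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform points of shape (..., 3) in world mm."""
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return (p - c) @ self.matrix.T + c + t

    def apply_grid(self, pts: np.ndarray) -> np.ndarray:
        """Transform a stacked coordinate array of shape (3, ...)."""
        c = np.asarray(self.center, dtype=float).reshape(3, 1)
        t = np.asarray(self.translation, dtype=float).reshape(3, 1)
        flat = pts.reshape(3, -1)
        out = self.matrix @ (flat - c) + c + t
        return out.reshape(pts.shape)

    def inverse(self) -> "RigidTransform":
        """T^{-1}(p) = R^T (p - c) + c - R^T t  (same center)."""
        r = Rotation.from_euler("xyz", self.rotation).inv()
        t_inv = -(self.matrix.T @ np.asarray(self.translation, dtype=float))
        return RigidTransform(
            rotation=tuple(r.as_euler("xyz")),
            translation=tuple(t_inv),
            center=self.center,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform p -> self(other(p)), centered at self.center."""
        r_net = Rotation.from_matrix(self.matrix @ other.matrix)
        c = np.asarray(self.center, dtype=float)
        t_net = self.apply(other.apply(c)) - c
        return RigidTransform(
            rotation=tuple(r_net.as_euler("xyz")),
            translation=tuple(t_net),
            center=self.center,
        )

    def recenter(self, new_center: tuple[float, float, float]) -> "RigidTransform":
        """Equivalent transform expressed about a different rotation center."""
        c1 = np.asarray(self.center, dtype=float)
        c2 = np.asarray(new_center, dtype=float)
        t2 = self.matrix @ (c2 - c1) - (c2 - c1) + np.asarray(self.translation)
        return RigidTransform(self.rotation, tuple(t2), tuple(c2))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            max(abs(a) for a in self.rotation) <= tol
            and max(abs(t) for t in self.translation) <= tol
        )

    def magnitude(self) -> tuple[float, float]:
        """(translation norm in mm, total rotation angle in degrees)."""
        t = float(np.linalg.norm(self.translation))
        ang = float(np.linalg.norm(Rotation.from_euler("xyz", self.rotation).as_rotvec()))
        return t, math.degrees(ang)

    def to_dict(self) -> dict:
        return {
            "rotation_deg": [math.degrees(a) for a in self.rotation],
            "translation_mm": list(self.translation),
            "center_mm": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation=tuple(math.radians(a) for a in d["rotation_deg"]),
            translation=tuple(d["translation_mm"]),
            center=tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
        )
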