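"""Small-angle rigid transforms between the tissue frame and the optical working space.

All coordinates are micrometres. Rotations are parameterised by intrinsic
x-y-z Euler angles in radians; the intended regime is the sub-5-degree
relative motion between a patient and table-mounted scanning optics, so the
angles compose and invert without gimbal concerns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

MAX_ROTATION_RAD = np.deg2rad(5.0)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion ``p -> R p + t`` with small rotation angles.

    Parameters
    ----------
    translation : array-like of 3 floats
        Offset in micrometres.
    angles : array-like of 3 floats
        Euler angles (radians, intrinsic ``xyz``). Each must stay below
        5 degrees in magnitude; larger motions are outside the tracking
        regime this model supports.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    angles: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=float).reshape(3)
        a = np.asarray(self.angles, dtype=float).reshape(3)
        if np.any(np.abs(a) >= MAX_ROTATION_RAD):
            raise ValueError(
                f"rotation angles {np.rad2deg(a)} deg exceed the 5 deg small-angle bound"
            )
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "angles", a)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        angles = Rotation.from_matrix(R).as_euler("xyz")
        return cls(translation=np.asarray(t, dtype=float), angles=angles)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.angles).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(..., 3)`` points through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation_matrix.T + self.translation

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix
        return RigidTransform.from_matrix(R.T, -R.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        R1, R2 = self.rotation_matrix, other.rotation_matrix
        return RigidTransform.from_matrix(
            R1 @ R2, R1 @ other.translation + self.translation
        )

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.translation, 0.0, atol=atol)
            and np.allclose(self.angles, 0.0, atol=atol)
        )

    def magnitude(self) -> float:
        """Translation norm in micrometres (rotation ignored)."""
        return float(np.linalg.norm(self.translation))
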