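"""Rigid-body transforms: the currency of superposition, symmetry and docking.

A :class:`RigidTransform` is a proper rotation plus a translation acting on
column 3-vectors as ``r -> R @ r + t``.  Rotations are validated to be
orthonormal with determinant +1 so that reflections can never sneak into a
symmetry expansion or a docking transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

#: tolerance for the orthonormality / determinant check of rotations
ROTATION_ATOL = 1e-9


def _as_matrix(value) -> np.ndarray:
    m = np.asarray(value, dtype=float)
    if m.shape != (3, 3):
        raise GeometryError(f"rotation must be 3x3, got shape {m.shape}")
    return m


def _as_vector(value) -> np.ndarray:
    v = np.asarray(value, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise GeometryError(f"translation must be a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, ``r -> rotation @ r + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    #: loosen only for transforms assembled from noisy numerics
    atol: float = field(default=ROTATION_ATOL, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "rotation", _as_matrix(self.rotation))
        object.__setattr__(self, "translation", _as_vector(self.translation))
        R = self.rotation
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(self.translation)):
            raise GeometryError("transform contains non-finite values")
        err = np.abs(R @ R.T - np.eye(3)).max()
        det = np.linalg.det(R)
        if err > self.atol or abs(det - 1.0) > max(self.atol, 1e-9):
            raise GeometryError(
                f"rotation is not a proper rotation (orthonormality error {err:.2e}, det {det:.12f})"
            )

    # -- constructors ----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, point=None) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``point`` (default origin)."""
        u = np.asarray(axis, dtype=float)
        n = np.linalg.norm(u)
        if n == 0:
            raise GeometryError("rotation axis must be non-zero")
        u = u / n
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        t = np.zeros(3)
        if point is not None:
            p = _as_vector(point)
            t = p - R @ p
        return cls(R, t)

    # -- algebra ---------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        """Map an (N,3) array or a single 3-vector."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first: (self∘other)(r)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    # -- inspection ------------------------------------------------------
    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= tol
            and np.abs(self.translation).max() <= tol
        )

    @property
    def matrix4(self) -> np.ndarray:
        """Homogeneous 4x4 representation (for reports)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle(self) -> float:
        """Rotation angle in degrees, in [0, 180]."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def rotation_axis(self) -> np.ndarray:
        """Unit rotation axis (undefined direction for the identity)."""
        R = self.rotation
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        n = np.linalg.norm(w)
        if n > 1e-12:
            return w / n
        # angle 0 or 180 deg: take eigenvector of eigenvalue +1
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        axis = vecs[:, np.argmax(vals)]
        return axis / np.linalg.norm(axis)


def rotation_difference_rad(a: np.ndarray, b: np.ndarray) -> float:
    """Geodesic distance on SO(3) between two rotation matrices, in radians."""
    c = (np.trace(a.T @ b) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))
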