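"""Anatomical frame construction and rigid registration.

The local frame is built from the three plantar landmarks: the heel is the
origin, the Y axis points from the heel to the midpoint of MT1 and MT5
(projected into the plantar plane), the Z axis is the plantar-plane normal
oriented towards the dorsum (disambiguated by the arch point, falling back to
the malleoli midpoint), and X = Y x Z completes a right-handed frame.
Registration maps this frame onto the canonical world frame so the plantar
plane becomes z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import DegenerateGeometryError, MissingLandmarkError
from .mesh_io import LandmarkSet, TriangleMesh

__all__ = [
    "RigidTransform",
    "FootFrame",
    "build_foot_frame",
    "compute_registration",
    "register",
    "register_scene",
]

#: Plantar-landmark triangle area below which the frame is refused (mm^2).
COLLINEARITY_AREA_TOL = 1.0


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise DegenerateGeometryError("rotation determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class FootFrame:
    """Orthonormal anatomical frame anchored at the heel landmark."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.float64).reshape(3)
            )
        axes = np.vstack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("frame axes are not orthonormal")


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"degenerate {what} (zero length)")
    return v / n


def build_foot_frame(landmarks: LandmarkSet) -> FootFrame:
    """Construct the anatomical frame from HEEL, MT1 and MT5.

    Raises :class:`DegenerateGeometryError` when the plantar landmarks are
    collinear (triangle area below 1 mm^2) and :class:`MissingLandmarkError`
    when no dorsal point is available to orient the normal.
    """
    landmarks.require("HEEL", "MT1", "MT5")
    heel = landmarks["HEEL"]
    mt1 = landmarks["MT1"]
    mt5 = landmarks["MT5"]

    n = np.cross(mt1 - heel, mt5 - heel)
    area = 0.5 * np.linalg.norm(n)
    if area <= COLLINEARITY_AREA_TOL:
        raise DegenerateGeometryError(
            f"plantar landmarks nearly collinear (area {area:.3g} mm^2)"
        )
    z = _unit(n, "plantar normal")

    if "ARCH" in landmarks:
        dorsal = landmarks["ARCH"]
    elif "MED_MAL" in landmarks and "LAT_MAL" in landmarks:
        dorsal = 0.5 * (landmarks["MED_MAL"] + landmarks["LAT_MAL"])
    else:
        raise MissingLandmarkError(
            "need ARCH (or both malleoli) to orient the plantar normal"
        )
    if np.dot(z, dorsal - heel) < 0:
        z = -z

    y = 0.5 * (mt1 + mt5) - heel
    y = y - np.dot(y, z) * z  # in-plane component
    y = _unit(y, "longitudinal axis")
    x = np.cross(y, z)
    return FootFrame(origin=heel, x_axis=x, y_axis=y, z_axis=z)


def compute_registration(frame: FootFrame) -> RigidTransform:
    """Rigid transform mapping the frame onto the canonical world frame.

    The frame origin maps to (0,0,0) and the frame axes to the world axes, so
    the plantar plane lands on z = 0.
    """
    R = np.vstack([frame.x_axis, frame.y_axis, frame.z_axis])
    return RigidTransform(R, -R @ frame.origin)


def register(
    mesh: TriangleMesh, landmarks: LandmarkSet, t: RigidTransform
) -> Tuple[TriangleMesh, LandmarkSet]:
    """Apply a rigid transform to a mesh and its landmarks."""
    out = TriangleMesh(t.apply(mesh.vertices), mesh.faces, mesh.name, dict(mesh.meta))
    return out, landmarks.transform(t)


def register_scene(
    mesh: TriangleMesh, landmarks: LandmarkSet
) -> Tuple[TriangleMesh, LandmarkSet, RigidTransform]:
    """Build the frame, compute the registration and apply it in one step."""
    frame = build_foot_frame(landmarks)
    t = compute_registration(frame)
    mesh_r, lm_r = register(mesh, landmarks, t)
    return mesh_r, lm_r, t
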