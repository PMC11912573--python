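"""Planar and 3D geometric primitives shared by the whole package.

The model length unit is the pentagon circumradius: a capsomer (pentameric
building block) is reduced to a regular pentagon whose five vertices lie on
the unit circle.  All lattice and tube dimensions downstream are expressed
in this unit; conversion to physical units (angstrom, nm) happens only when
structures are exported.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PENTAGON_EDGE_LENGTH",
    "PENTAGON_INRADIUS",
    "Pentagon2D",
    "CapsomerFrame",
    "Assembly",
    "AnglePair",
    "regular_pentagon",
    "fit_polygon_frame",
    "rotate_about_axis",
    "rotation_matrix",
    "DegenerateGeometryError",
]

#: Edge length of a regular pentagon with unit circumradius, 2*sin(36 deg).
PENTAGON_EDGE_LENGTH: float = 2.0 * np.sin(np.deg2rad(36.0))
#: Inradius of a regular pentagon with unit circumradius, cos(36 deg).
PENTAGON_INRADIUS: float = float(np.cos(np.deg2rad(36.0)))

_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when input geometry is too degenerate to process."""


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Pentagon2D:
    """A regular pentagon in the plane.

    ``orientation`` is +1 for a counterclockwise vertex ring (positive
    signed area) and -1 for clockwise.
    """

    vertices: np.ndarray  # (5, 2)
    center: np.ndarray  # (2,)
    orientation: int

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (5, 2):
            raise ValueError("Pentagon2D requires exactly 5 planar vertices")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        radii = np.linalg.norm(v - self.center, axis=1)
        if np.ptp(radii) > 1e-5 * max(1.0, radii.mean()):
            raise ValueError("vertices are not equidistant from the center")
        area = _signed_area(v)
        if abs(area) < 1e-12:
            raise ValueError("degenerate pentagon with zero signed area")
        if int(np.sign(area)) != self.orientation:
            raise ValueError("orientation does not match the signed area")

    @property
    def circumradius(self) -> float:
        return float(np.linalg.norm(self.vertices[0] - self.center))

    @property
    def edge_length(self) -> float:
        return float(np.linalg.norm(self.vertices[1] - self.vertices[0]))


@dataclass
class CapsomerFrame:
    """A polygonal multimer reduced to center, unit normal and vertex ring.

    This is the unit between which bending and torsion angles are measured:
    the pentamer's subunits are collapsed to a planar regular pentagon with
    a well-defined plane normal.
    """

    center: np.ndarray  # (3,)
    normal: np.ndarray  # (3,) unit
    vertices: np.ndarray  # (5, 3), on the plane through center
    label: str = ""

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            if n < 1e-12:
                raise DegenerateGeometryError("zero-length frame normal")
            self.normal = self.normal / n

    def validate(self, tol: float = _TOL) -> None:
        """Check planarity and regularity of the vertex ring."""
        if self.vertices.shape[0] != 5:
            raise ValueError("capsomer frame requires 5 vertices")
        offs = (self.vertices - self.center) @ self.normal
        if np.max(np.abs(offs)) > tol:
            raise ValueError("vertices do not lie on the frame plane")
        radii = np.linalg.norm(self.vertices - self.center, axis=1)
        if np.ptp(radii) > tol * max(1.0, radii.mean()):
            raise ValueError("vertex ring is not a regular pentagon")

    @property
    def circumradius(self) -> float:
        return float(np.mean(np.linalg.norm(self.vertices - self.center, axis=1)))

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "CapsomerFrame":
        """Return a copy mapped by the rigid transform x -> R x + t."""
        return CapsomerFrame(
            center=R @ self.center + t,
            normal=R @ self.normal,
            vertices=self.vertices @ R.T + t,
            label=self.label,
        )


@dataclass
class Assembly:
    """A collection of capsomer frames, optionally with subunit centroids.

    ``scale`` is the physical length represented by one model unit
    (dimensionless 1.0 by default); it is applied on structure export only.
    """

    frames: list = field(default_factory=list)
    subunit_coords: list | None = None  # per frame: (5, 3) array
    scale: float = 1.0

    def __post_init__(self) -> None:
        labels = [f.label for f in self.frames]
        if len(set(labels)) != len(labels):
            raise ValueError("frame labels must be unique")
        if self.subunit_coords is not None:
            if len(self.subunit_coords) != len(self.frames):
                raise ValueError("subunit_coords must have one entry per frame")
            self.subunit_coords = [
                np.asarray(c, dtype=float).reshape(-1, 3) for c in self.subunit_coords
            ]
            for c in self.subunit_coords:
                if c.shape[0] != 5:
                    raise ValueError("each frame requires 5 subunit centroids")

    def __len__(self) -> int:
        return len(self.frames)

    def centroid(self) -> np.ndarray:
        return np.mean([f.center for f in self.frames], axis=0)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Assembly":
        subs = None
        if self.subunit_coords is not None:
            subs = [c @ R.T + t for c in self.subunit_coords]
        return Assembly(
            frames=[f.transformed(R, t) for f in self.frames],
            subunit_coords=subs,
            scale=self.scale,
        )


@dataclass(frozen=True)
class AnglePair:
    """Bending and torsion angle between two contacting capsomers, degrees.

    Bending is 180 deg for a coplanar (flat) contact and decreases as the
    interface closes; torsion is the rotation about the center-to-center
    axis, zero for untwisted contacts.
    """

    bending: float
    torsion: float

    def __post_init__(self) -> None:
        if not (0.0 < self.bending <= 180.0 + 1e-9):
            raise ValueError(f"bending angle {self.bending} outside (0, 180]")
        if not (-180.0 < self.torsion <= 180.0 + 1e-9):
            raise ValueError(f"torsion angle {self.torsion} outside (-180, 180]")


def regular_pentagon(
    circumradius: float, phase_deg: float = 90.0, orientation: int = 1
) -> Pentagon2D:
    """Regular pentagon on the circle of given radius about the origin.

    Vertices sit at angles ``phase + k*72 deg``; with unit radius and zero
    phase they are the fifth roots of unity.  ``orientation`` +1 places the
    vertices counterclockwise, -1 clockwise.
    """
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    if orientation not in (+1, -1):
        raise ValueError("orientation must be +1 or -1")
    ang = np.deg2rad(phase_deg) + orientation * np.deg2rad(72.0) * np.arange(5)
    verts = circumradius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return Pentagon2D(vertices=verts, center=np.zeros(2), orientation=orientation)


def fit_polygon_frame(points: Iterable[Sequence[float]], label: str = "") -> CapsomerFrame:
    """Least-squares plane fit of >= 3 points, returned as a capsomer frame.

    The center is the centroid, the normal the minor principal axis of the
    point scatter, and the vertices are the input points projected onto the
    plane and ordered counterclockwise about the normal.  The normal sign is
    chosen so the projected ring is counterclockwise; callers that need an
    assembly-level convention (e.g. outward normals) re-orient afterwards.
    """
    pts = np.asarray(list(points), dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fitting requires at least 3 points")
    center = pts.mean(axis=0)
    centered = pts - center
    # SVD of the scatter: the right-singular vector of the smallest singular
    # value is the plane normal; rank < 2 means collinear input.
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1e-30) or svals[0] < 1e-12:
        raise DegenerateGeometryError("points are collinear; no unique plane")
    normal = vt[2]
    proj = centered - np.outer(centered @ normal, normal)
    # order counterclockwise about the normal
    e1 = proj[0] / np.linalg.norm(proj[0])
    e2 = np.cross(normal, e1)
    ang = np.arctan2(proj @ e2, proj @ e1)
    order = np.argsort(ang)
    verts = proj[order] + center
    return CapsomerFrame(center=center, normal=normal, vertices=verts, label=label)


def rotation_matrix(axis_dir: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a unit axis (Rodrigues)."""
    axis = np.asarray(axis_dir, dtype=float).reshape(3)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length rotation axis")
    axis = axis / n
    th = np.deg2rad(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)


def rotate_about_axis(
    point: np.ndarray,
    axis_origin: np.ndarray,
    axis_dir: np.ndarray,
    angle_deg: float,
) -> np.ndarray:
    """Rotate a point about an arbitrary axis (right-handed, counterclockwise
    when viewed from the axis tip)."""
    p = np.asarray(point, dtype=float)
    o = np.asarray(axis_origin, dtype=float)
    R = rotation_matrix(axis_dir, angle_deg)
    return (p - o) @ R.T + o
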