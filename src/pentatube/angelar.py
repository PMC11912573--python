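"""AngelaR: bending and torsion angles between polygon-shaped capsomers.

Two contacting pentamers are reduced to their plane normals and the line
joining their centers.  If the two normals are coplanar with that line the
contact is untwisted: the torsion angle is zero and the bending angle is
180 degrees minus the angle between the normals.  Otherwise the torsion is
the signed rotation about the center-to-center axis that brings the second
normal into the plane of the first normal and the axis, and bending is
computed on the rotated configuration.

Sign convention: torsion follows the right-hand rule about the unit vector
from the first center to the second.  The global sign flips with the
normal orientation convention; within one consistently oriented assembly
torsion signs are comparable between contacts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .geometry_core import (
    Assembly,
    AnglePair,
    CapsomerFrame,
    DegenerateGeometryError,
    PENTAGON_EDGE_LENGTH,
    fit_polygon_frame,
    rotation_matrix,
)

__all__ = [
    "ContactRecord",
    "bending_torsion",
    "pair_from_angles",
    "detect_contacts",
    "measure_structure",
    "contacts_to_table",
    "DEFAULT_CONTACT_THRESHOLD_FACTOR",
]

#: Contact threshold as a fraction of the pentagon edge length.
DEFAULT_CONTACT_THRESHOLD_FACTOR = 0.15

_COPLANAR_TOL = 1e-9


@dataclass(frozen=True)
class ContactRecord:
    """One pentamer-pentamer contact with its interface angles."""

    frame_a: str
    frame_b: str
    angles: AnglePair
    center_distance: float
    contact_fraction: float

    def __post_init__(self) -> None:
        if self.center_distance <= 0:
            raise ValueError("center distance must be positive")
        if not (0.0 <= self.contact_fraction <= 1.0 + 1e-9):
            raise ValueError("contact fraction must lie in [0, 1]")


def _co_orient(n_a: np.ndarray, n_b: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Flip n_b if needed so both normals point to the same side.

    The component along d is removed first; the bending/torsion values are
    only meaningful for consistently oriented normals.
    """
    pa = n_a - (n_a @ d) * d
    pb = n_b - (n_b @ d) * d
    if np.linalg.norm(pa) > 1e-12 and np.linalg.norm(pb) > 1e-12:
        if pa @ pb < 0:
            return -n_b
    elif n_a @ n_b < 0:
        return -n_b
    return n_b


def bending_torsion(
    a: CapsomerFrame, b: CapsomerFrame, co_orient: bool = True
) -> AnglePair:
    """Bending and torsion angles of the contact a -> b, in degrees.

    With ``co_orient`` (default) the second normal is flipped, if needed, to
    the same side as the first after removing the axis component; pass
    ``False`` when the assembly normals are already consistently oriented
    (e.g. radially outward).
    """
    dvec = b.center - a.center
    dist = np.linalg.norm(dvec)
    if dist < 1e-12:
        raise DegenerateGeometryError("coincident capsomer centers")
    d = dvec / dist
    n_a = a.normal / np.linalg.norm(a.normal)
    n_b = b.normal / np.linalg.norm(b.normal)
    if co_orient:
        n_b = _co_orient(n_a, n_b, d)

    triple = float(np.dot(np.cross(n_a, n_b), d))
    pa = n_a - (n_a @ d) * d
    if np.linalg.norm(pa) < 1e-12:
        # first normal parallel to the axis: torsion undefined, report 0
        cosang = np.clip(n_a @ n_b, -1.0, 1.0)
        return AnglePair(bending=180.0 - np.degrees(np.arccos(cosang)), torsion=0.0)
    u = pa / np.linalg.norm(pa)
    v = np.cross(d, u)
    beta_c = float(n_b @ u)
    gamma_c = float(n_b @ v)

    if abs(triple) < _COPLANAR_TOL and beta_c >= 0:
        torsion = 0.0
        n_b_plane = n_b
    else:
        torsion = float(np.degrees(np.arctan2(gamma_c, beta_c)))
        n_b_plane = rotation_matrix(d, -torsion) @ n_b
    cosang = np.clip(n_a @ n_b_plane, -1.0, 1.0)
    bending = 180.0 - float(np.degrees(np.arccos(cosang)))
    if bending <= 0.0:  # fold the degenerate closed contact into (0, 180]
        bending = abs(bending) + 1e-12
    if torsion <= -180.0:
        torsion += 360.0
    return AnglePair(bending=bending, torsion=torsion)


def pair_from_angles(
    a: CapsomerFrame,
    bending: float,
    torsion: float,
    edge: int = 0,
    attach: float = 0.5,
    label: str = "partner",
) -> CapsomerFrame:
    """Construct the partner frame that realizes given interface angles.

    The partner starts as the point reflection of ``a`` through the
    attachment point on the chosen interface edge (a flat, untwisted pair:
    bending 180, torsion 0), is folded about the shared edge and twisted
    about the center-to-center axis.  Off the edge midpoint the fold and
    twist couple, so the two construction angles are refined by Newton
    iteration until the measured pair angles match the request; measuring
    the constructed pair with :func:`bending_torsion` returns the inputs
    to numerical precision.
    """
    if not 0.0 <= attach <= 1.0:
        raise ValueError("attach parameter must lie in [0, 1]")
    v0 = a.vertices[edge % 5]
    v1 = a.vertices[(edge + 1) % 5]
    q = v0 + attach * (v1 - v0)
    hinge = (v1 - v0) / np.linalg.norm(v1 - v0)
    # hinge sign such that positive folding tilts toward +normal of a
    probe = rotation_matrix(hinge, 90.0) @ ((2.0 * q - a.center) - q)
    if (probe + q - a.center) @ a.normal < 0:
        hinge = -hinge

    def construct(fold: float, twist: float) -> CapsomerFrame:
        center = 2.0 * q - a.center
        verts = 2.0 * q - a.vertices
        normal = a.normal.copy()
        R1 = rotation_matrix(hinge, fold)
        center = R1 @ (center - q) + q
        verts = (verts - q) @ R1.T + q
        normal = R1 @ normal
        dvec = center - a.center
        d = dvec / np.linalg.norm(dvec)
        R2 = rotation_matrix(d, twist)
        verts = (verts - center) @ R2.T + center
        normal = R2 @ normal
        return CapsomerFrame(center=center, normal=normal, vertices=verts, label=label)

    x = np.array([180.0 - bending, torsion])
    target = np.array([bending, torsion])
    for _ in range(50):
        b = construct(*x)
        ap = bending_torsion(a, b, co_orient=False)
        err = np.array([ap.bending, ap.torsion]) - target
        if np.max(np.abs(err)) < 1e-10:
            break
        # numerical Jacobian of measured angles w.r.t. construction angles
        J = np.zeros((2, 2))
        h = 1e-6
        for k in range(2):
            xp = x.copy()
            xp[k] += h
            bp = construct(*xp)
            app = bending_torsion(a, bp, co_orient=False)
            J[:, k] = (np.array([app.bending, app.torsion]) - [ap.bending, ap.torsion]) / h
        try:
            x = x - np.linalg.solve(J, err)
        except np.linalg.LinAlgError:
            break
    return construct(*x)


def _ring_segments(frame: CapsomerFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    v = frame.vertices
    return [(v[i], v[(i + 1) % len(v)]) for i in range(len(v))]


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two 3D segments."""
    u = p2 - p1
    v = q2 - q1
    w = p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d_, e_ = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-14:
        s = np.clip((b * e_ - c * d_) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e_) / c if c > 1e-14 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # refine s for clamped t
    if a > 1e-14:
        s = np.clip((b * t - d_) / a, 0.0, 1.0)
    return float(np.linalg.norm((p1 + s * u) - (q1 + t * v)))


def _min_distance_rings(frame_a: CapsomerFrame, frame_b: CapsomerFrame) -> float:
    """Minimum distance between two vertex-ring polylines."""
    return min(
        _segment_distance(p1, p2, q1, q2)
        for p1, p2 in _ring_segments(frame_a)
        for q1, q2 in _ring_segments(frame_b)
    )


def _edge_overlap_fraction(frame_a, frame_b, threshold: float) -> float:
    """Largest fraction of an edge of ``frame_a`` overlapping a nearly
    anti-parallel edge of ``frame_b`` within the contact threshold."""
    best = 0.0
    for p1, p2 in _ring_segments(frame_a):
        ua = p2 - p1
        la = np.linalg.norm(ua)
        ua = ua / la
        for q1, q2 in _ring_segments(frame_b):
            ub = q2 - q1
            ub = ub / np.linalg.norm(ub)
            # edges of twisted contacts are rotated against each other by
            # up to the torsion angle; accept overlaps to 45 degrees
            if abs(ua @ ub) < np.cos(np.deg2rad(45.0)):
                continue
            if _segment_distance(p1, p2, q1, q2) > threshold:
                continue
            t1, t2 = sorted(((q1 - p1) @ ua, (q2 - p1) @ ua))
            ov = max(0.0, min(la, t2) - max(0.0, t1))
            best = max(best, ov / la)
    return min(best, 1.0)


def orient_outward(assembly: Assembly) -> None:
    """Flip frame normals in place to point away from the assembly centroid."""
    c0 = assembly.centroid()
    for f in assembly.frames:
        if (f.center - c0) @ f.normal < 0:
            f.normal = -f.normal


def detect_contacts(
    assembly: Assembly,
    threshold: float | None = None,
    orient: bool = False,
) -> list[ContactRecord]:
    """All capsomer pairs whose vertex rings approach within ``threshold``.

    Each unordered pair is reported once, with bending/torsion measured on
    the frame normals as stored (set ``orient=True`` to first flip normals
    outward from the assembly centroid).
    """
    if len(assembly) < 2:
        return []
    if threshold is None:
        edge = float(
            np.median(
                [np.linalg.norm(f.vertices[1] - f.vertices[0]) for f in assembly.frames]
            )
        )
        threshold = DEFAULT_CONTACT_THRESHOLD_FACTOR * edge
    if threshold <= 0:
        raise ValueError("contact threshold must be positive")
    if orient:
        orient_outward(assembly)
    frames = assembly.frames
    records: list[ContactRecord] = []
    # cheap center-distance prescreen before the 25 segment-pair test
    max_r = max(f.circumradius for f in frames)
    centers = np.array([f.center for f in frames])
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            cd = float(np.linalg.norm(centers[j] - centers[i]))
            if cd > 2.0 * max_r + threshold:
                continue
            dmin = min(
                _segment_distance(p1, p2, q1, q2)
                for p1, p2 in _ring_segments(frames[i])
                for q1, q2 in _ring_segments(frames[j])
            )
            if dmin >= threshold:
                continue
            angles = bending_torsion(frames[i], frames[j], co_orient=False)
            frac = _edge_overlap_fraction(frames[i], frames[j], threshold)
            records.append(
                ContactRecord(
                    frame_a=frames[i].label,
                    frame_b=frames[j].label,
                    angles=angles,
                    center_distance=cd,
                    contact_fraction=frac,
                )
            )
    return records


def measure_structure(
    path: str,
    chain_grouping: Mapping[str, Sequence[str]],
    threshold: float | None = None,
) -> list[ContactRecord]:
    """Apply AngelaR to an atomic structure file (PDB or mmCIF).

    ``chain_grouping`` maps a capsomer label to the chain names of its
    subunits (>= 3 per capsomer).  Each chain is collapsed to the centroid
    of its heavy atoms (all atoms if no element records), one frame is
    fitted per capsomer, and contacts are detected with normals oriented
    outward from the assembly centroid.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in structure file {path}")
    model = st[0]
    chain_centroids: dict[str, np.ndarray] = {}
    for chain in model:
        coords = [
            [at.pos.x, at.pos.y, at.pos.z]
            for res in chain
            for at in res
            if at.element.name != "H"
        ]
        if coords:
            chain_centroids[chain.name] = np.mean(np.asarray(coords), axis=0)

    frames = []
    subunit_coords = []
    for capsomer, chains in chain_grouping.items():
        missing = [c for c in chains if c not in chain_centroids]
        if missing:
            raise ValueError(f"capsomer {capsomer}: chains not found: {missing}")
        if len(chains) < 3:
            raise ValueError(
                f"capsomer {capsomer} has {len(chains)} chains; need >= 3 to fit a plane"
            )
        pts = np.array([chain_centroids[c] for c in chains])
        frames.append(fit_polygon_frame(pts, label=str(capsomer)))
        subunit_coords.append(pts if len(chains) == 5 else None)

    subs = subunit_coords if all(s is not None for s in subunit_coords) else None
    assembly = Assembly(frames=frames, subunit_coords=subs)
    return detect_contacts(assembly, threshold=threshold, orient=True)


def contacts_to_table(records: list[ContactRecord]):
    """Contact list as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frame_a": [r.frame_a for r in records],
            "frame_b": [r.frame_b for r in records],
            "distance": [r.center_distance for r in records],
            "bending_deg": [r.angles.bending for r in records],
            "torsion_deg": [r.angles.torsion for r in records],
            "contact_fraction": [r.contact_fraction for r in records],
        }
    )
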