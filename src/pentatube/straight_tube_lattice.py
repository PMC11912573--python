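"""Planar lattice model of straight pentamer tubes.

The model tiles the plane with regular pentagons of unit circumradius in
two orientations: "up" pentagons with vertices at the fifth roots of unity
and "down" pentagons obtained from them by an in-plane point reflection
(a 180-degree rotation, realizable by protein pentamers).  Pentagons are
organized in staircase strips: within a strip, consecutive pentagons bond
across edges e1 (P1P2) and e3 (P3P4); adjacent strips, offset by the
vector H = (a, b), contact through edges e2 (strip above) and e5 (strip
below).  For a given inter-strip offset b, the free parameter a is fixed
by the closure condition that makes the rolled-up tube consistent: the
identification vector C = n_p*P - n_h*H must be perpendicular to the tube
axis, i.e. the second components of H and P satisfy

    n_p * P_y = n_h * b

where P is the strip repeat vector, n_h the helicity number (number of
distinct helical strips) and n_p the periodicity number (steps along P
separating lattice-identified pentagons).

Solutions carry per-edge contact percentages (fraction of a pentagon edge
overlapping a neighbor's edge), feasibility flags (interior overlap,
contact loss) and the flip diagnosis: for n_p = n_h the closure forces a
degenerate tiling in which edge e3 must host two distinct contacts, which
a single asymmetric protein interface cannot form - realizing that tiling
would require mirrored (flipped) pentamers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .geometry_core import Assembly, CapsomerFrame

__all__ = [
    "PENT_VERTICES",
    "EDGE_NORMALS",
    "LatticeParams",
    "LatticeSolution",
    "EdgeContactConstruction",
    "InfeasibleTilingError",
    "construction_contacts",
    "solve_lattice",
    "contact_percentage",
    "flip_required",
    "enumerate_tilings",
    "wrap_to_cylinder",
    "roll_point",
]

_D2R = np.pi / 180.0
#: Up-pentagon vertices: the fifth roots of unity.
PENT_VERTICES = np.array(
    [[np.cos(72 * k * _D2R), np.sin(72 * k * _D2R)] for k in range(5)]
)
#: Outward edge normals of the up pentagon, edge k joining vertices k, k+1.
EDGE_NORMALS = np.array(
    [[np.cos((36 + 72 * k) * _D2R), np.sin((36 + 72 * k) * _D2R)] for k in range(5)]
)
_EDGE_TANGENTS = np.array(
    [
        (PENT_VERTICES[(k + 1) % 5] - PENT_VERTICES[k])
        / np.linalg.norm(PENT_VERTICES[(k + 1) % 5] - PENT_VERTICES[k])
        for k in range(5)
    ]
)
_INRADIUS = float(np.cos(36 * _D2R))
_EDGE_LEN = float(2 * np.sin(36 * _D2R))
_ROT144 = np.array(
    [
        [np.cos(144 * _D2R), -np.sin(144 * _D2R)],
        [np.sin(144 * _D2R), np.cos(144 * _D2R)],
    ]
)
#: Rotation (degrees) mapping the e1 edge line onto the e3 edge line about
#: the pentagon center; the edge-contact construction's origin rotation.
EDGE_MAPPING_ROTATION_DEG = 144.0

_SHRINK = 1e-7  # polygon shrink for robust interior-overlap tests
_CONTACT_TOL = 1e-6  # minimum edge-overlap length counted as a contact


class InfeasibleTilingError(ValueError):
    """A (n_h, n_p, b) combination admits no realizable tiling.

    ``reason`` is one of ``"overlap"``, ``"contact-loss"`` or
    ``"flip-forbidden"``; the first two are geometric, the last marks a
    tiling that exists geometrically but needs mirrored pentamers.
    """

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class LatticeParams:
    """Lattice offset b (circumradius units), helicity n_h, periodicity n_p."""

    b: float
    n_h: int
    n_p: int

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("lattice offset b must be positive")
        if int(self.n_h) != self.n_h or self.n_h < 1:
            raise ValueError("helicity number n_h must be a positive integer")
        if int(self.n_p) != self.n_p or self.n_p < 1:
            raise ValueError("periodicity number n_p must be a positive integer")


@dataclass(frozen=True)
class EdgeContactConstruction:
    """Contact points of the strip-boundary construction.

    R1 is the intersection of the e1 edge line of the base pentagon with
    the e3 edge line of the pentagon translated by H (the adjacent strip);
    T is the anticlockwise 144-degree rotation of R1 about the origin,
    landing on the e3 edge line; R3 = R1 + (P1 - P3) is the translated
    contact point, exactly one pentagon-diagonal along the strip.
    """

    R1: np.ndarray
    T: np.ndarray
    R3: np.ndarray

    @staticmethod
    def from_lattice(H: np.ndarray) -> "EdgeContactConstruction":
        n1, n3 = EDGE_NORMALS[0], EDGE_NORMALS[2]
        M = np.array([n1, n3])
        rhs = np.array([_INRADIUS, _INRADIUS + float(H @ n3)])
        R1 = np.linalg.solve(M, rhs)
        T = _ROT144 @ R1
        R3 = R1 + (PENT_VERTICES[0] - PENT_VERTICES[2])
        return EdgeContactConstruction(R1=R1, T=T, R3=R3)


@dataclass
class LatticeSolution:
    """A solved straight-tube tiling for given (b, n_h, n_p)."""

    params: LatticeParams
    a: float
    H: np.ndarray  # (a, b): translation between adjacent strips
    P: np.ndarray  # strip repeat vector
    w: np.ndarray  # offset of the down-pentagon sublattice
    theta: float  # angle between P and H, degrees
    contact_lengths: dict = field(default_factory=dict)  # edge class -> length
    contact_percent_per_edge: dict = field(default_factory=dict)
    mean_contact_percent: float = 0.0
    feasible: bool = False
    overlap: bool = False
    flip_required: bool = False
    construction: EdgeContactConstruction | None = None

    @property
    def circumference_vector(self) -> np.ndarray:
        return self.params.n_p * self.P - self.params.n_h * self.H

    @property
    def closure_residual(self) -> float:
        return float(self.params.n_p * self.P[1] - self.params.n_h * self.params.b)


def construction_contacts() -> list[tuple[int, int, int]]:
    """Designated contact classes of the construction.

    Each entry is ``(edge_index, m, j)``: the up pentagon's edge hosts a
    contact with the down pentagon at lattice offset ``m*P + j*H``.  This
    single function isolates the edge-pair choice of the strip-boundary
    construction; correcting it does not touch the solver.
    """
    return [
        (0, 0, 0),  # e1: pair partner within the strip
        (2, -1, 0),  # e3: previous pair's partner within the strip
        (1, -1, 1),  # e2: partner in the strip above
        (4, 0, -1),  # e5: partner in the strip below
    ]


def _degenerate_contacts() -> list[tuple[int, int, int]]:
    """Contact classes of the n_p = n_h degenerate tiling: the strip-above
    partner slips from edge e2 to a second contact on edge e3."""
    return [(0, 0, 0), (2, -1, 0), (2, -1, 1), (4, 0, -1)]


def _solve_degenerate(params: LatticeParams):
    """Solve the doubled-e3 tiling.

    Collinearity of edge e3 with both the previous pair's partner and the
    strip-above partner forces H . n3 = 0, i.e. a = 0; the remaining three
    contact constraints plus the closure (P_y = n_h b / n_p) determine
    (P, w) linearly.
    """
    b = params.b
    H = np.array([0.0, b])
    contacts = [(0, 0, 0), (2, -1, 0), (4, 0, -1)]
    A = np.zeros((4, 4))
    rhs = np.zeros(4)
    for i, (k, m, j) in enumerate(contacts):
        n = EDGE_NORMALS[k]
        A[i, 0:2] = m * n
        A[i, 2:4] = n
        rhs[i] = 2.0 * _INRADIUS - j * float(H @ n)
    A[3, 1] = 1.0  # closure: P_y = n_h b / n_p
    rhs[3] = params.n_h * b / params.n_p
    x = np.linalg.solve(A, rhs)
    return x[0:2], x[2:4], H


def _solve_geometry(a: float, b: float, contacts: list[tuple[int, int, int]]):
    """Solve the 4 collinearity constraints for (P, w) at given a.

    Contact (k, m, j): the down pentagon at w + m*P + j*H has its edge of
    class k collinear with the up pentagon's edge line, i.e.
    (w + m*P + j*H) . n_k = 2 * inradius.
    """
    H = np.array([a, b])
    A = np.zeros((4, 4))
    rhs = np.zeros(4)
    for i, (k, m, j) in enumerate(contacts):
        n = EDGE_NORMALS[k]
        A[i, 0:2] = m * n  # P coefficients
        A[i, 2:4] = n  # w coefficients
        rhs[i] = 2.0 * _INRADIUS - j * float(H @ n)
    x = np.linalg.solve(A, rhs)
    return x[0:2], x[2:4], H


def _contact_overlaps(P, H, w, contacts) -> dict[tuple[int, int, int], float]:
    """Exact 1D overlap length of each designated contact."""
    out = {}
    for (k, m, j) in contacts:
        v = m * P + j * H
        a0 = PENT_VERTICES[k]
        u = _EDGE_TANGENTS[k]
        d0 = v + w - PENT_VERTICES[(k + 1) % 5]
        d1 = v + w - PENT_VERTICES[k]
        lo, hi = sorted((float((d0 - a0) @ u), float((d1 - a0) @ u)))
        out[(k, m, j)] = max(0.0, min(_EDGE_LEN, hi) - max(0.0, lo))
    return out


def _has_interior_overlap(P, H, w, m_range: int = 3, j_range: int = 2) -> bool:
    """Any pairwise interior intersection in a patch of the tiling.

    Polygons are shrunk by a tiny factor so exactly-touching edges do not
    trip the robustness limits of the boolean predicates.
    """
    from shapely.geometry import Polygon
    from shapely.affinity import translate

    if not np.all(np.isfinite(P)) or np.linalg.norm(P) > 50 or np.linalg.norm(H) > 50:
        return True
    cell = abs(P[0] * H[1] - P[1] * H[0])
    pent_area = 2.0 * 2.377641290737884  # two pentagons per cell
    if cell < pent_area - 1e-9:
        return True
    up = Polygon(PENT_VERTICES * (1.0 - _SHRINK))
    down = Polygon(w - PENT_VERTICES * (1.0 - _SHRINK))
    items = []
    for m in range(-m_range, m_range + 1):
        for j in range(-j_range, j_range + 1):
            off = m * P + j * H
            items.append((off, translate(up, *off)))
            items.append((off + w, translate(down, *off)))
    for i in range(len(items)):
        ci, pi = items[i]
        for jx in range(i + 1, len(items)):
            cj, pj = items[jx]
            if np.linalg.norm(ci - cj) > 2.05:
                continue
            if pi.intersection(pj).area > 1e-9:
                return True
    return False


def _closure_root(params: LatticeParams, contacts, bracket=(-20.0, 30.0)) -> float:
    """Root of the closure residual n_p * P_y(a) - n_h * b over a bracket.

    The residual is solved numerically (brentq after a sign-change scan);
    failure to bracket a root signals a geometrically forbidden
    combination, distinct from numerical failure inside the solver.
    """

    def residual(a: float) -> float:
        P, _, _ = _solve_geometry(a, params.b, contacts)
        return params.n_p * P[1] - params.n_h * params.b

    grid = np.linspace(bracket[0], bracket[1], 64)
    vals = [residual(x) for x in grid]
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            return float(grid[i])
        if vals[i] * vals[i + 1] < 0:
            root = brentq(residual, grid[i], grid[i + 1], xtol=1e-12)
            if abs(residual(root)) > 1e-9:
                raise RuntimeError("closure root did not converge")
            return float(root)
    raise InfeasibleTilingError(
        f"no closure root for (n_h={params.n_h}, n_p={params.n_p}, b={params.b})",
        reason="overlap",
    )


def _build_solution(params: LatticeParams, contacts, flip: bool) -> LatticeSolution:
    a = _closure_root(params, contacts)
    P, w, H = _solve_geometry(a, params.b, contacts)
    overlaps = _contact_overlaps(P, H, w, contacts)
    has_overlap = _has_interior_overlap(P, H, w)
    ok = (min(overlaps.values()) > _CONTACT_TOL) and not has_overlap

    per_edge = {f"e{k + 1}": 0.0 for k in range(5)}
    for (k, _, _), ln in overlaps.items():
        per_edge[f"e{k + 1}"] += 100.0 * ln / _EDGE_LEN
    mean_pct = sum(per_edge.values()) / 5.0

    cosang = np.clip(P @ H / (np.linalg.norm(P) * np.linalg.norm(H)), -1, 1)
    return LatticeSolution(
        params=params,
        a=a,
        H=H,
        P=P,
        w=w,
        theta=float(np.degrees(np.arccos(cosang))),
        contact_lengths={f"e{k + 1}_{m}_{j}": ln for (k, m, j), ln in overlaps.items()},
        contact_percent_per_edge=per_edge,
        mean_contact_percent=mean_pct,
        feasible=ok and not flip,
        overlap=has_overlap,
        flip_required=flip and ok,
        construction=EdgeContactConstruction.from_lattice(H),
    )


def solve_lattice(params: LatticeParams, validate: bool = True) -> LatticeSolution:
    """Solve the straight-tube closure for (b, n_h, n_p).

    Returns a :class:`LatticeSolution`.  With ``validate`` (default) an
    :class:`InfeasibleTilingError` is raised for geometrically forbidden
    combinations (interior overlap or contact loss) and for tilings that
    would require mirrored pentamers (``reason="flip-forbidden"``).
    """
    sol = _build_solution(params, construction_contacts(), flip=False)
    if sol.feasible:
        return sol
    # closure with n_p = n_h degenerates: the strip-above contact slips onto
    # edge e3, doubling that interface; check whether that tiling exists.
    try:
        P, w, H = _solve_degenerate(params)
        overlaps = _contact_overlaps(P, H, w, _degenerate_contacts())
        ok = (min(overlaps.values()) > _CONTACT_TOL) and not _has_interior_overlap(
            P, H, w
        )
        per_edge = {f"e{k + 1}": 0.0 for k in range(5)}
        for (k, _, _), ln in overlaps.items():
            per_edge[f"e{k + 1}"] += 100.0 * ln / _EDGE_LEN
        cosang = np.clip(P @ H / (np.linalg.norm(P) * np.linalg.norm(H)), -1, 1)
        degen = LatticeSolution(
            params=params,
            a=0.0,
            H=H,
            P=P,
            w=w,
            theta=float(np.degrees(np.arccos(cosang))),
            contact_lengths={
                f"e{k + 1}_{m}_{j}": ln for (k, m, j), ln in overlaps.items()
            },
            contact_percent_per_edge=per_edge,
            mean_contact_percent=sum(per_edge.values()) / 5.0,
            feasible=False,
            overlap=not ok,
            flip_required=ok,
            construction=EdgeContactConstruction.from_lattice(H),
        )
    except (InfeasibleTilingError, np.linalg.LinAlgError):
        degen = None
    if degen is not None and degen.flip_required:
        if validate:
            raise InfeasibleTilingError(
                f"(n_h={params.n_h}, n_p={params.n_p}) requires flipped pentagons: "
                "edge e3 would host two distinct contacts",
                reason="flip-forbidden",
            )
        return degen
    if validate:
        reason = "overlap" if sol.overlap else "contact-loss"
        raise InfeasibleTilingError(
            f"(n_h={params.n_h}, n_p={params.n_p}, b={params.b}) is geometrically "
            f"forbidden ({reason})",
            reason=reason,
        )
    return sol


def contact_percentage(solution: LatticeSolution) -> dict:
    """Per-edge-class contact percentages of a feasible solution."""
    if not solution.feasible:
        raise InfeasibleTilingError(
            "contact percentages are defined for feasible tilings only",
            reason="overlap" if solution.overlap else "contact-loss",
        )
    return dict(solution.contact_percent_per_edge)


def flip_required(solution: LatticeSolution) -> bool:
    """True iff the tiling forces mirrored pentagons (see module docs)."""
    return bool(solution.flip_required)


def enumerate_tilings(
    b: float,
    n_h_range: Iterable[int] = range(1, 9),
    n_p_range: Iterable[int] = range(1, 13),
):
    """Feasibility/contact table over a grid of (n_h, n_p) combinations.

    Returns a pandas DataFrame with one row per combination; ``status`` is
    ``"ok"``, ``"flip-forbidden"`` or ``"geometrically-forbidden"``.
    """
    import pandas as pd

    rows = []
    for n_h in n_h_range:
        for n_p in n_p_range:
            params = LatticeParams(b=b, n_h=n_h, n_p=n_p)
            try:
                sol = solve_lattice(params, validate=False)
            except (InfeasibleTilingError, np.linalg.LinAlgError):
                rows.append(
                    dict(
                        n_h=n_h, n_p=n_p, feasible=False, flip_required=False,
                        a=np.nan, theta_deg=np.nan, mean_contact_percent=np.nan,
                        status="geometrically-forbidden",
                    )
                )
                continue
            if sol.feasible:
                status = "ok"
            elif sol.flip_required:
                status = "flip-forbidden"
            else:
                status = "geometrically-forbidden"
            rows.append(
                dict(
                    n_h=n_h,
                    n_p=n_p,
                    feasible=sol.feasible,
                    flip_required=sol.flip_required,
                    a=sol.a if sol.feasible else np.nan,
                    theta_deg=sol.theta if sol.feasible else np.nan,
                    mean_contact_percent=(
                        sol.mean_contact_percent if sol.feasible else np.nan
                    ),
                    status=status,
                )
            )
    return pd.DataFrame(rows)


def roll_point(solution: LatticeSolution, xy: np.ndarray, radius: float | None = None):
    """Map a planar lattice point onto the cylinder surface.

    The identification vector C (horizontal by closure) becomes the
    circumference; the y axis becomes the tube axis.
    """
    C = solution.circumference_vector
    Cx = float(C[0])
    if radius is None:
        radius = abs(Cx) / (2 * np.pi)
    theta = 2 * np.pi * float(xy[0]) / Cx
    return np.array([radius * np.cos(theta), radius * np.sin(theta), float(xy[1])])


def _site_frame(solution: LatticeSolution, center2d, verts2d, label: str):
    """Rigid pentagon placed tangent to the cylinder at its center."""
    C = solution.circumference_vector
    Cx = float(C[0])
    radius = abs(Cx) / (2 * np.pi)
    theta = 2 * np.pi * float(center2d[0]) / Cx
    sgn = np.sign(Cx)
    center3d = np.array(
        [radius * np.cos(theta), radius * np.sin(theta), float(center2d[1])]
    )
    tangent = sgn * np.array([-np.sin(theta), np.cos(theta), 0.0])
    axial = np.array([0.0, 0.0, 1.0])
    normal = np.array([np.cos(theta), np.sin(theta), 0.0])
    verts3d = np.array(
        [
            center3d + (v[0] - center2d[0]) * tangent + (v[1] - center2d[1]) * axial
            for v in verts2d
        ]
    )
    return CapsomerFrame(center=center3d, normal=normal, vertices=verts3d, label=label)


def wrap_to_cylinder(solution: LatticeSolution, n_turns: float = 1.0) -> Assembly:
    """Roll the planar lattice onto a cylinder.

    The circumferential identification maps lattice-equivalent pentagons
    onto the same 3D pentamer, so the tube has exactly n_h distinct
    helical threads.  Pentagons are placed rigid, tangent to the cylinder
    at their centers, with radial (outward) normals.  ``n_turns`` sets the
    number of strip-repeat steps per thread via the circumference length.
    """
    if not solution.feasible:
        raise InfeasibleTilingError(
            "cannot wrap an infeasible or flip-forbidden solution",
            reason="flip-forbidden" if solution.flip_required else "overlap",
        )
    P, H, w = solution.P, solution.H, solution.w
    n_h = solution.params.n_h
    L = abs(float(solution.circumference_vector[0]))
    m_count = max(2, int(round(n_turns * L / abs(P[0]))))
    frames = []
    subunit_coords = []
    for j in range(n_h):
        for m in range(m_count):
            site = m * P + j * H
            for kind, c2d in (("U", site), ("D", site + w)):
                verts2d = (
                    PENT_VERTICES + c2d if kind == "U" else c2d - PENT_VERTICES
                )
                label = f"{kind}_t{j}_m{m}"
                fr = _site_frame(solution, c2d, verts2d, label)
                frames.append(fr)
                subunit_coords.append(fr.vertices.copy())
    return Assembly(frames=frames, subunit_coords=subunit_coords)
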