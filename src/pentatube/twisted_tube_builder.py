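"""Single-stranded helix model for twisted pentamer tubes.

A chain of pentamers is grown by applying the same bending and torsion
angles at every step: the incoming pentamer is placed on the interface
edge of the previous one (its position along that edge set by a free
attachment parameter), folded out of plane by the bending angle and
twisted about the center-to-center axis by the torsion angle.  The chain
alternates between the two interface classes of a pentamer ribbon (edges
e1 and e3): a regular pentagon has no anti-parallel edge pair, so a
single repeating interface cannot propagate a strip, exactly as in the
straight-tube lattice whose threads bond across e1 and e3.  The chain is
therefore a discrete screw orbit at the pair level: one rigid motion
maps pentamer i to pentamer i+2 for all i, and the construction is fully
determined by (bending, torsion, attach).

Zero torsion yields a planar ring (no helical rise); bending of 180 with
zero torsion yields a straight planar strip (infinite radius); generic
angles yield a helix whose rise, radius and inter-turn gap are measured
by :func:`thread_metrics`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angelar import pair_from_angles, _segment_distance, _ring_segments
from .geometry_core import Assembly, CapsomerFrame, DegenerateGeometryError

__all__ = [
    "HelixSpec",
    "TubeMetrics",
    "build_helix",
    "thread_metrics",
    "gap_angle_scan",
]

_RING_RISE_TOL = 1e-6
_STRIP_ANGLE_TOL = 1e-9


@dataclass(frozen=True)
class HelixSpec:
    """Parameters of the iterative helix construction.

    bending, torsion in degrees; ``attach`` in [0, 1] locates the incoming
    pentamer along the interface edge (0.5 = edge midpoint).
    """

    bending: float
    torsion: float
    attach: float = 0.5
    n_steps: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.bending <= 180.0):
            raise ValueError("bending must lie in (0, 180]")
        if not (-180.0 < self.torsion <= 180.0):
            raise ValueError("torsion must lie in (-180, 180]")
        if not (0.0 <= self.attach <= 1.0):
            raise ValueError("attach must lie in [0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class TubeMetrics:
    """Helical descriptors of a tubular assembly (model units)."""

    n_threads: int
    rise_per_step: float
    rise_per_turn: float
    radius: float
    thread_gap: float
    angle_per_step_deg: float
    is_ring: bool = False


def _base_frame() -> CapsomerFrame:
    ang = np.deg2rad(72.0) * np.arange(5)
    verts = np.stack([np.cos(ang), np.sin(ang), np.zeros(5)], axis=1)
    return CapsomerFrame(
        center=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]), vertices=verts,
        label="h0",
    )


def build_helix(spec: HelixSpec) -> Assembly:
    """Grow the deterministic pentamer chain defined by ``spec``.

    Every consecutive pair, measured by AngelaR, returns exactly the
    specified bending and torsion.  Odd steps attach on edge e1, even
    steps on edge e3, so the chain is the folded ribbon of the planar
    strip model; zero torsion closes it into a planar ring (zero rise)
    and bending 180 with zero torsion gives a straight planar strip.
    """
    frames = [_base_frame()]
    for i in range(1, spec.n_steps):
        prev = frames[-1]
        nxt = pair_from_angles(
            prev,
            bending=spec.bending,
            torsion=spec.torsion,
            edge=0 if (i - 1) % 2 == 0 else 2,
            attach=spec.attach,
            label=f"h{i}",
        )
        frames.append(nxt)
    return Assembly(
        frames=frames, subunit_coords=[f.vertices.copy() for f in frames]
    )


def _frame_basis(f: CapsomerFrame) -> np.ndarray:
    u1 = f.vertices[0] - f.center
    u1 = u1 / np.linalg.norm(u1)
    u2 = np.cross(f.normal, u1)
    return np.stack([u1, u2, f.normal], axis=1)


def _step_transform(f0: CapsomerFrame, f1: CapsomerFrame):
    """Rigid transform (R, t) with x -> R x + t mapping frame f0 to f1."""
    B0, B1 = _frame_basis(f0), _frame_basis(f1)
    R = B1 @ B0.T
    t = f1.center - R @ f0.center
    return R, t


def _screw_parameters(R: np.ndarray, t: np.ndarray, point: np.ndarray):
    """Screw axis decomposition of a rigid motion.

    Returns (angle_deg, rise, radius, axis_dir) where radius is the
    distance of ``point`` from the screw axis.  A pure translation has
    angle 0 and undefined axis/radius (returned as inf).
    """
    cos_th = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.arccos(cos_th))
    if theta < _STRIP_ANGLE_TOL:
        return 0.0, float(np.linalg.norm(t)), np.inf, None
    W = (R - R.T) / (2.0 * np.sin(theta))
    axis = np.array([W[2, 1], W[0, 2], W[1, 0]])
    axis = axis / np.linalg.norm(axis)
    rise = float(t @ axis)
    # point on the axis: solve (I - R) x = t_perp in the plane normal to axis
    t_perp = t - rise * axis
    A = np.eye(3) - R
    x0, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    # remove axis component ambiguity
    x0 = x0 - (x0 @ axis) * axis
    lever = (point - x0) - ((point - x0) @ axis) * axis
    return float(np.degrees(theta)), rise, float(np.linalg.norm(lever)), axis


def _threads_from_labels(assembly: Assembly) -> dict[str, list[int]]:
    threads: dict[str, list[int]] = {}
    for idx, f in enumerate(assembly.frames):
        tag = "0"
        if "_t" in f.label:
            tag = f.label.split("_t")[1].split("_")[0]
        threads.setdefault(tag, []).append(idx)
    return threads


def _min_ring_distance(fa: CapsomerFrame, fb: CapsomerFrame) -> float:
    return min(
        _segment_distance(p1, p2, q1, q2)
        for p1, p2 in _ring_segments(fa)
        for q1, q2 in _ring_segments(fb)
    )


def thread_metrics(assembly: Assembly) -> TubeMetrics:
    """Fit the common screw of a tubular assembly and measure it.

    Uses consecutive same-kind frames within each thread (threads are
    tagged in frame labels by the builders).  Raises for straight strips
    (no rotation, infinite radius); planar rings are returned with the
    ``is_ring`` flag and zero rise.
    """
    if len(assembly) < 3:
        raise ValueError("thread metrics require at least 3 frames")
    threads = _threads_from_labels(assembly)
    thread0 = list(threads.values())[0]
    frames = assembly.frames
    # same-kind consecutive pairs: labels "U_.."/"D_.." alternate in wrapped
    # tubes; in helices all frames are the same kind
    up_down = all(frames[i].label[:2] in ("U_", "D_") for i in thread0)
    if up_down:
        # wrapped lattice tube: up-pentagons along a thread repeat by one
        # strip step, which is the thread's screw
        seq = [i for i in thread0 if frames[i].label.startswith("U_")]
        stride = 1
        pent_per_screw_step = 2  # one up + one down per strip step
    else:
        # helix chain: the screw repeat is the pentamer pair (two steps)
        seq = thread0
        stride = 2
        pent_per_screw_step = 2
    if len(seq) < stride + 1:
        raise ValueError("not enough frames along a thread to fit a screw")
    R, t = _step_transform(frames[seq[0]], frames[seq[stride]])
    angle, rise, radius, axis = _screw_parameters(R, t, frames[seq[0]].center)
    if axis is None or not np.isfinite(radius) or radius > 1e6:
        raise DegenerateGeometryError(
            "degenerate straight strip: no helical axis (infinite radius)"
        )
    steps_per_turn = 360.0 / abs(angle)  # screw steps per full turn
    rise_per_turn = rise * steps_per_turn
    is_ring = abs(rise_per_turn) < _RING_RISE_TOL

    n_threads = len(threads)
    gap = np.nan
    if is_ring:
        rise = 0.0
        rise_per_turn = 0.0
    elif n_threads > 1:
        # closest approach between pentamers of different threads
        gap = min(
            _min_ring_distance(frames[i], frames[j])
            for ta in threads
            for tb in threads
            if ta < tb
            for i in threads[ta]
            for j in threads[tb]
        )
    else:
        # single strand: axial clearance between consecutive helical turns,
        # rise per turn minus the axial width of the pentamer band
        mid = seq[len(seq) // 2]
        z = frames[mid].vertices @ axis
        band = float(z.max() - z.min())
        gap = max(0.0, abs(rise_per_turn) - band)
    return TubeMetrics(
        n_threads=n_threads,
        rise_per_step=rise / pent_per_screw_step if not is_ring else 0.0,
        rise_per_turn=rise_per_turn,
        radius=radius,
        thread_gap=float(gap),
        angle_per_step_deg=angle,
        is_ring=is_ring,
    )


#: Default scan path: from the compacted twisted tube (gap ~ 0) toward
#: open spring-like helices; bending decreases while torsion increases.
DEFAULT_SCAN_BENDING = np.linspace(150.0, 140.0, 8)
DEFAULT_SCAN_TORSION = np.linspace(2.0, 16.0, 8)


def gap_angle_scan(
    bending_range=None,
    torsion_range=None,
    attach: float = 0.5,
    n_steps: int | None = None,
):
    """Build one helix per (bending, torsion) pair and tabulate its metrics.

    The two ranges are traversed in parallel (a path through angle space);
    scalar inputs are broadcast.  The default path starts at the compacted
    dual-thread geometry (inter-turn gap 0) and opens the helix as bending
    decreases and torsion increases.  Returns a pandas DataFrame with
    columns bending_deg, torsion_deg, thread_gap, rise_per_turn, radius.
    """
    import pandas as pd

    if bending_range is None:
        bending_range = DEFAULT_SCAN_BENDING
    if torsion_range is None:
        torsion_range = DEFAULT_SCAN_TORSION
    bends = np.atleast_1d(np.asarray(bending_range, dtype=float))
    tors = np.atleast_1d(np.asarray(torsion_range, dtype=float))
    if bends.size == 1:
        bends = np.full(tors.size, bends[0])
    if tors.size == 1:
        tors = np.full(bends.size, tors[0])
    if bends.size != tors.size:
        raise ValueError("bending and torsion ranges must have equal length")
    rows = []
    for b, t in zip(bends, tors):
        probe = build_helix(HelixSpec(bending=b, torsion=t, attach=attach, n_steps=3))
        R, tv = _step_transform(probe.frames[0], probe.frames[2])
        ang, _, _, _ = _screw_parameters(R, tv, probe.frames[0].center)
        if ang < 1e-6:
            rows.append(
                dict(bending_deg=b, torsion_deg=t, thread_gap=np.nan,
                     rise_per_turn=np.nan, radius=np.inf)
            )
            continue
        need = int(np.ceil(2.2 * 2.0 * 360.0 / ang))
        n = n_steps or min(max(need, 8), 200)
        asm = build_helix(HelixSpec(bending=b, torsion=t, attach=attach, n_steps=n))
        m = thread_metrics(asm)
        rows.append(
            dict(
                bending_deg=b,
                torsion_deg=t,
                thread_gap=m.thread_gap,
                rise_per_turn=m.rise_per_turn,
                radius=m.radius,
            )
        )
    return pd.DataFrame(rows)
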