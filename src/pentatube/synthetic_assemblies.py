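"""Parameterized synthetic pentamer assemblies and structure-file export.

These generators provide every fixture the angle and network analyses
need without touching a structural database: the dodecahedral cage (12
pentamers, 60 subunits), generic spherical cages for size-trend tests,
straight tubes wrapped from the planar lattice model, double-stranded
twisted tubes from the helix builder, optionally with Gaussian
positional noise.  All fixtures are deterministic under a fixed seed.
Subunits are reduced to one centroid each, placed at the pentagon
vertices; structure files carry one pseudo-atom per subunit so a
write/read round trip reproduces the capsomer frames.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry_core import Assembly, CapsomerFrame, fit_polygon_frame
from .straight_tube_lattice import LatticeParams, solve_lattice, wrap_to_cylinder
from .twisted_tube_builder import (
    HelixSpec,
    build_helix,
    _step_transform,
    _screw_parameters,
)
from .geometry_core import rotation_matrix

__all__ = [
    "FixtureSpec",
    "make_dodecahedron",
    "make_sphere_cage",
    "make_straight_tube",
    "make_twisted_tube",
    "add_noise",
    "write_structure",
    "chain_grouping_for",
    "make_fixture",
    "DODECAHEDRON_BENDING_DEG",
]

_PHI = (1.0 + np.sqrt(5.0)) / 2.0
#: Analytic bending angle between adjacent dodecahedron faces,
#: arccos(-1/sqrt(5)) ~ 116.565 degrees (the dodecahedral dihedral angle).
DODECAHEDRON_BENDING_DEG = float(np.degrees(np.arccos(-1.0 / np.sqrt(5.0))))


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic assembly."""

    kind: str  # dodecahedron | sphere_cage | straight_tube | twisted_tube
    params: dict = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (
            "dodecahedron",
            "sphere_cage",
            "straight_tube",
            "twisted_tube",
        ):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _dodecahedron_template() -> list[np.ndarray]:
    """Vertex sets of the 12 faces of a regular dodecahedron, scaled so
    each face is a pentagon of unit circumradius."""
    phi = _PHI
    verts = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                verts.append((sx, sy, sz))
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            verts.append((0, s1 / phi, s2 * phi))
            verts.append((s1 / phi, s2 * phi, 0))
            verts.append((s1 * phi, 0, s2 / phi))
    V = np.array(verts, dtype=float)
    # face-center directions for this vertex convention: (0, +-phi, +-1) cyclic
    normals = []
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            normals.append((0, s1 * phi, s2))
            normals.append((s1 * phi, s2, 0))
            normals.append((s1, 0, s2 * phi))
    faces = []
    for n in np.array(normals, dtype=float):
        n = n / np.linalg.norm(n)
        dots = V @ n
        idx = np.argsort(dots)[-5:]
        faces.append(V[idx])
    # face circumradius of this template
    f0 = faces[0]
    c0 = f0.mean(axis=0)
    rad = float(np.mean(np.linalg.norm(f0 - c0, axis=1)))
    return [f / rad for f in faces]


def make_dodecahedron(circumradius: float | None = None) -> Assembly:
    """The dodecahedral cage: 12 pentamer frames, 60 subunit centroids.

    Faces are unit-circumradius pentagons sharing full edges; normals
    point outward.  ``circumradius`` (distance from the cage center to
    the subunit centroids) uniformly rescales the whole cage; bending
    angles are scale-invariant.
    """
    faces = _dodecahedron_template()
    if circumradius is not None:
        if circumradius <= 0:
            raise ValueError("circumradius must be positive")
        r0 = float(np.linalg.norm(faces[0][0]))
        faces = [f * (circumradius / r0) for f in faces]
    frames = []
    subunit_coords = []
    for i, pts in enumerate(faces):
        fr = fit_polygon_frame(pts, label=f"C_t0_m{i}")
        if (fr.center @ fr.normal) < 0:  # outward normals
            fr.normal = -fr.normal
        frames.append(fr)
        subunit_coords.append(fr.vertices.copy())
    return Assembly(frames=frames, subunit_coords=subunit_coords)


def make_sphere_cage(n_pentamers: int, radius: float, seed: int = 0) -> Assembly:
    """Pentamers tangent to a sphere at near-equidistributed points.

    Placement uses the deterministic Fibonacci spiral; the in-plane
    orientation of each pentamer is drawn from the seeded generator.
    ``n_pentamers = 12`` special-cases to the exact dodecahedron scaled
    to the requested radius.
    """
    if n_pentamers < 4:
        raise ValueError("a cage requires at least 4 pentamers")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_pentamers == 12:
        # exact dodecahedron, rescaled so pentamer centers sit at `radius`
        asm = make_dodecahedron()
        r0 = float(np.linalg.norm(asm.frames[0].center))
        scale = radius / r0
        frames = []
        for f in asm.frames:
            frames.append(
                CapsomerFrame(
                    center=f.center * scale,
                    normal=f.normal,
                    vertices=f.center * scale
                    + (f.vertices - f.center),  # pentagon stays unit-sized
                    label=f.label,
                )
            )
        return Assembly(
            frames=frames, subunit_coords=[f.vertices.copy() for f in frames]
        )
    rng = np.random.default_rng(seed)
    ga = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    frames = []
    for i in range(n_pentamers):
        z = 1.0 - 2.0 * (i + 0.5) / n_pentamers
        rho = np.sqrt(max(0.0, 1.0 - z * z))
        theta = ga * i
        n = np.array([rho * np.cos(theta), rho * np.sin(theta), z])
        center = radius * n
        # tangent-plane basis with a seeded in-plane phase
        ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(n, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        phase = rng.uniform(0, 2 * np.pi)
        ang = phase + np.deg2rad(72.0) * np.arange(5)
        verts = center + np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)
        frames.append(
            CapsomerFrame(center=center, normal=n, vertices=verts, label=f"S_t0_m{i}")
        )
    return Assembly(frames=frames, subunit_coords=[f.vertices.copy() for f in frames])


def make_straight_tube(
    n_h: int = 3, n_p: int = 4, b: float = 2.18, n_turns: float = 1.5
) -> Assembly:
    """Straight tube wrapped from the solved planar lattice."""
    sol = solve_lattice(LatticeParams(b=b, n_h=n_h, n_p=n_p))
    return wrap_to_cylinder(sol, n_turns=n_turns)


def make_twisted_tube(
    bending: float = 146.0,
    torsion: float = 10.0,
    attach: float = 0.5,
    n_steps: int = 30,
    n_threads: int = 2,
) -> Assembly:
    """Twisted tube: parallel helical strands of the single-strand model.

    Strand 0 is the iterative helix; further strands are copies rotated
    about the common screw axis by equal fractions of a turn, giving the
    double-stranded twisted-tube architecture with an inter-thread gap
    controlled by (bending, torsion).
    """
    if n_threads < 1:
        raise ValueError("n_threads must be >= 1")
    helix = build_helix(
        HelixSpec(bending=bending, torsion=torsion, attach=attach, n_steps=n_steps)
    )
    R, t = _step_transform(helix.frames[0], helix.frames[2])
    _, _, _, axis = _screw_parameters(R, t, helix.frames[0].center)
    if axis is None:
        raise ValueError("helix parameters give a degenerate (straight) chain")
    # a point on the screw axis
    A = np.eye(3) - R
    rise = float(t @ axis)
    x0, *_ = np.linalg.lstsq(A, t - rise * axis, rcond=None)
    x0 = x0 - (x0 @ axis) * axis
    frames = []
    subunit_coords = []
    for k in range(n_threads):
        Rk = rotation_matrix(axis, 360.0 * k / n_threads)
        for f in helix.frames:
            g = CapsomerFrame(
                center=Rk @ (f.center - x0) + x0,
                normal=Rk @ f.normal,
                vertices=(f.vertices - x0) @ Rk.T + x0,
                label=f"h_t{k}_m{f.label[1:]}",
            )
            frames.append(g)
            subunit_coords.append(g.vertices.copy())
    return Assembly(frames=frames, subunit_coords=subunit_coords)


def add_noise(assembly: Assembly, sigma: float, seed: int = 0) -> Assembly:
    """Isotropic Gaussian displacement of subunit centroids, frames refit.

    ``sigma = 0`` returns an identical copy.  Refit normals keep the sign
    of the originals so orientation conventions survive the noise.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    coords = (
        assembly.subunit_coords
        if assembly.subunit_coords is not None
        else [f.vertices for f in assembly.frames]
    )
    rng = np.random.default_rng(seed)
    frames = []
    new_coords = []
    for f, pts in zip(assembly.frames, coords):
        noisy = pts + (sigma * rng.standard_normal(pts.shape) if sigma > 0 else 0.0)
        nf = fit_polygon_frame(noisy, label=f.label)
        if nf.normal @ f.normal < 0:
            nf.normal = -nf.normal
        frames.append(nf)
        new_coords.append(np.asarray(noisy))
    return Assembly(frames=frames, subunit_coords=new_coords, scale=assembly.scale)


_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def _chain_names(n: int) -> list[str]:
    if n <= len(_CHAIN_ALPHABET):
        return list(_CHAIN_ALPHABET[:n])
    names = []
    for i in range(n):
        a, b = divmod(i, len(_CHAIN_ALPHABET))
        names.append(_CHAIN_ALPHABET[a] + _CHAIN_ALPHABET[b])
    return names


def chain_grouping_for(assembly: Assembly) -> dict[str, list[str]]:
    """Chain grouping (capsomer label -> subunit chain names) matching
    :func:`write_structure`'s chain naming."""
    names = _chain_names(5 * len(assembly))
    return {
        f.label: names[5 * i : 5 * i + 5] for i, f in enumerate(assembly.frames)
    }


def write_structure(assembly: Assembly, path: str, format: str = "pdb") -> None:
    """Write the assembly as PDB or mmCIF pseudo-atom coordinates.

    One chain per subunit, a single carbon pseudo-atom at each subunit
    centroid; coordinates are multiplied by ``assembly.scale``.  PDB
    output is limited by its single-character chain names to 62 subunits;
    larger assemblies use mmCIF.
    """
    import gemmi

    if len(assembly) == 0:
        raise ValueError("cannot write an empty assembly")
    fmt = format.lower()
    if fmt not in ("pdb", "cif", "mmcif"):
        raise ValueError(f"unsupported format {format!r}")
    coords = (
        assembly.subunit_coords
        if assembly.subunit_coords is not None
        else [f.vertices for f in assembly.frames]
    )
    n_sub = sum(len(c) for c in coords)
    if fmt == "pdb" and n_sub > len(_CHAIN_ALPHABET):
        raise ValueError(
            f"{n_sub} subunits exceed PDB chain naming; write mmCIF instead"
        )
    names = _chain_names(n_sub)
    st = gemmi.Structure()
    st.name = "pentatube synthetic assembly"
    model = gemmi.Model("1")
    ci = 0
    for pts in coords:
        for p in np.asarray(pts, dtype=float):
            chain = gemmi.Chain(names[ci])
            res = gemmi.Residue()
            res.name = "SUB"
            res.seqid = gemmi.SeqId(1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.pos = gemmi.Position(*(p * assembly.scale))
            res.add_atom(atom)
            chain.add_residue(res)
            model.add_chain(chain)
            ci += 1
    st.add_model(model)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def make_fixture(spec: FixtureSpec) -> Assembly:
    """Build the assembly described by a :class:`FixtureSpec`."""
    builders = {
        "dodecahedron": make_dodecahedron,
        "sphere_cage": make_sphere_cage,
        "straight_tube": make_straight_tube,
        "twisted_tube": make_twisted_tube,
    }
    params = dict(spec.params)
    if spec.kind == "sphere_cage":
        params.setdefault("seed", spec.seed)
    asm = builders[spec.kind](**params)
    if spec.noise_sigma > 0:
        asm = add_noise(asm, spec.noise_sigma, seed=spec.seed)
    return asm
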