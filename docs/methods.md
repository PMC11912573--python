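# Methods

This note records the models implemented in `pentatube`, the assumptions
behind them, and the numerical and design choices a maintainer would want
to know. All lengths are in pentagon-circumradius units unless stated.

## Capsomer reduction and the angle calculator

A pentameric capsomer is reduced to a `CapsomerFrame`: the centroid of its
subunits, the least-squares plane normal (minor principal axis of the
subunit scatter, via SVD), and the subunit positions projected onto that
plane and ordered counterclockwise about the normal. When reading atomic
coordinates, a subunit is collapsed to the centroid of its heavy atoms;
groups with fewer than three chains are rejected because no unique plane
exists. Planarity and regularity tolerances default to 1e-6 model units
for exact constructions and are configurable for noisy input.

**Bending and torsion.** For frames a and b with unit normals n_a, n_b and
center-to-center unit vector d: if n_a, n_b, d are coplanar (scalar triple
product below 1e-9 after normalization), the torsion is zero and the
bending angle is 180° minus the angle between the normals. Otherwise the
torsion is the signed angle (right-hand rule about d) by which n_b must be
rotated about d to bring it into the plane spanned by n_a and d, and
bending is evaluated after that rotation. Bending lies in (0, 180°] with
180° meaning a flat, coplanar contact; torsion lies in (−180°, 180°].

Two conventions matter:

- *Normal co-orientation.* Angles are only meaningful for consistently
  oriented normals. Assembly builders orient normals outward (radially for
  tubes, from the centroid for cages); the pairwise fallback flips n_b when
  its component perpendicular to d opposes n_a's. A global flip of all
  normals flips the sign of every torsion, so only torsion signs *within*
  one consistently oriented assembly are comparable.
- *Swap symmetry.* The torsion of an unordered pair is order-independent:
  swapping the arguments also reverses d, and the handedness measure
  (n_a × n_b) · d is invariant under that joint change. Both bending and
  torsion are therefore symmetric under argument swap. No intrinsic
  definition of this kind can be antisymmetric.

**Pair construction.** `pair_from_angles` realizes a prescribed (bending,
torsion) pair: the partner starts as the point reflection of the frame
through an attachment point on the chosen interface edge (flat pair), is
folded about the shared edge and twisted about the center-to-center axis.
Off the edge midpoint the fold and twist couple, so the two construction
angles are refined by a 2-by-2 Newton iteration on the measured angles
(numerical Jacobian, convergence to 1e-10 degrees, typically 2-3 steps).
Build-then-measure is exact to numerical precision by construction.

**Contact detection.** Two capsomers are in contact when their vertex
rings approach within a threshold, default 0.15 of the pentagon edge
length. The contact fraction is the largest projected 1D overlap between
an edge of one ring and a nearly anti-parallel edge of the other, divided
by the edge length; "nearly anti-parallel" allows up to 45° because the
edges of twisted contacts are rotated against each other by roughly the
torsion angle.

## Straight-tube lattice model

**The tiling.** The plane is tiled by unit-circumradius regular pentagons
in two orientations: "up" pentagons with vertices at the fifth roots of
unity, and "down" pentagons that are in-plane point reflections of them.
A point reflection is a 180° rotation — on the tube surface, a two-fold
rotation about the radial axis — so both orientations are realizable by
one chiral protein; a mirror reflection is not. Edge k of the up pentagon
(joining vertices k and k+1, outward normal at 36° + 72°k) can only form
edge-edge contact with the matching anti-parallel edge of a down pentagon,
which makes every contact a pseudo-two-fold interface between equivalent
edges, consistent with the conserved dimer-like interfaces of cage-forming
pentamers.

**Strips.** Pentagons form staircase strips: an up pentagon bonds a down
partner across its e1 edge, and the previous pair's partner across e3.
The strip repeats with vector P⃗; adjacent strips are offset by
H⃗ = (a, b) and contact through e2 (strip above, partner at −P⃗ + H⃗) and
e5 (strip below, partner at −H⃗). Edge e4 stays uncontacted. Given a, the
four collinearity constraints (each contacting pair shares an edge line)
determine P⃗ and the down-pentagon offset w linearly. The register of the
interstrip contacts — which down pentagon of the adjacent strip touches
which edge — is part of the construction and is isolated in a single
function (`construction_contacts`) so it can be corrected without touching
the solver.

**Closure.** Rolling the lattice onto a cylinder identifies pentagons
separated by the circumference vector C⃗ = n_p·P⃗ − n_h·H⃗, where n_h is
the helicity number (number of distinct strips after rolling) and n_p the
periodicity number (strip steps between identified pentagons). With the
tube axis along y, C⃗ must be horizontal: **n_p·P_y = n_h·b** — the
equality of the (scaled) second components of P⃗ and H⃗. For fixed b this
is one equation in the single unknown a; the solver scans a bracket for a
sign change and refines with Brent's method to |residual| < 1e-9. (For
this construction the residual happens to be linear in a, so the root is
unique; the bracketed-root interface is kept because it is robust to
changes in the underlying construction.)

**Feasibility.** A solved combination is accepted when all four contact
overlaps are positive (1D projections onto the shared edge lines) and no
two pentagons in a patch of the tiling interpenetrate (pairwise
intersection area below 1e-9, computed on polygons shrunk by 1e-7 to
avoid boolean-predicate failures on exactly-touching edges). At
b = 2.18 — the offset matching the biological tube — the feasible set is
the band n_h < n_p ≲ 2.4·n_h: below it strips overlap, above it the
interstrip contact vanishes. Contact percentage per edge class is the
overlap length over the edge length; the mean is taken over all five
edges (the uncontacted e4 contributes zero). Both per-edge and mean values
are reported since either average convention may be wanted.

**Flip-forbidden tilings.** When n_p = n_h the closure forces P_y = b and
the doubled constraint on edge e3 (the strip-above partner's contact
slips from e2 onto a second interval of e3) forces a = 0. The resulting
tiling exists geometrically, but one pentagon edge then hosts two
distinct contacts with two different partners — impossible for a single
asymmetric protein interface unless mirrored pentamers are admitted.
These combinations are reported as flip-forbidden, distinct from
geometrically forbidden ones. The (n_h, n_p) = (4, 4) case is the
canonical example.

**Wrapping.** `wrap_to_cylinder` places pentagons rigid and tangent to
the cylinder at their centers (normals radial); the planar x coordinate
becomes the azimuth via the circumference |C⃗|, the y coordinate the
axial position. Whether pentamers deform when a lattice wraps is not
modeled; rigid tangent placement slightly opens planar contacts (ring
distances of ~0.07 at contacts, ~0.4 at next-nearest neighbors for the
three-strip tube), which the contact threshold comfortably absorbs.

**Edge-contact construction points.** The solution exposes R1, the
intersection of the base pentagon's e1 edge line with the adjacent
strip's e3 edge line — the corner of the zigzag strip boundary. The
anticlockwise 144° rotation about the origin (the pentagon's edge-to-edge
map, carrying the e1 line onto the e3 line and vertex P2 to P4) sends R1
to the boundary point T with |P4 T| = |R1 P2| exactly; R3 = R1 + (P1 − P3)
is the corresponding point one pentagon diagonal along the strip.

## Twisted-tube helix model

The single-stranded helix grows a pentamer chain by applying the same
(bending, torsion) at every step, the incoming pentamer placed on the
interface edge at a position set by the attachment parameter (default
0.5, the edge midpoint; the value is a free model parameter). Steps
alternate between the e1 and e3 interfaces: a regular pentagon has no
anti-parallel edge pair, so no single repeating interface can propagate a
strip — the chain is the folded version of the lattice model's strip.
Consequently the chain's exact screw symmetry lives at the pentamer-pair
level: one rigid motion maps pentamer i to pentamer i+2 for all i,
verified to machine precision. Two limits are exact: zero torsion gives
zero screw rise — a planar ring, whatever the bending — and bending 180°
with zero torsion gives a straight planar strip (no helical axis,
reported as degenerate).

`thread_metrics` extracts the screw from consecutive same-kind frames
(pair repeat for helices, strip step for wrapped tubes): rotation angle,
rise, axis, and the radius of the pentamer orbit. Rise per turn below
1e-6 flags a ring; a fitted radius above 1e6 flags a strip. The
inter-turn gap of a single strand is the rise per turn minus the axial
width of the pentamer band — a smooth measure of the clearance that the
second strand of a dual-thread tube would occupy; for multi-thread
assemblies the gap is the closest ring-to-ring approach between threads.

The default `gap_angle_scan` path runs bending 150° → 140° against
torsion 2° → 16°, starting at the compacted geometry (gap 0) and opening
the helix; along it the gap increases monotonically while bending falls
and torsion rises. The path is this package's choice of a representative
section through angle space; the monotone tendency is asserted on it, not
on all of angle space (at much larger torsions the gap saturates).

## Network rewiring

`network_from_assembly` puts nodes at pentamer centers, weight-1 edges at
detected contacts and weight-0 candidate edges between next-nearest
neighbors, then groups edges into symmetry classes by node kinds and
rounded interface geometry (distance, bending, |torsion|) — for the tube
builders this reproduces the orbits of the helical symmetry. The
candidate radius is 3 times the contact threshold: in the wrapped
three-strip tube the next-nearest band sits at ring distance ~0.4 and the
following band at ~1.8, so any factor between roughly 2.4 and 10 selects
the same candidates (the two "diagonal" classes connecting like pentamers
across strips).

A rewiring assigns one weight per class. Admissible alternatives must
keep the weight-1 graph connected; respect local realizability (at most
five contacts per pentamer, no pentagon edge slot hosting two classes);
conserve each interior pentamer's contact count (assembly conditions
saturate the available interfaces — a blueprint with different
coordination is a different morphology class, not a rewiring); and
preserve the principal two-fold class, the maximal-overlap pair bond,
which is structurally conserved across every observed assembly of these
proteins. Under these rules the three-strip straight-tube network has
exactly one alternative: the two interthread classes are deleted, the two
diagonal classes are gained, and the squashed-hexagon faces (two
triangles and one square, the diagonals being the candidate edges) turn
into the triangle blueprint of the twisted tube. The transformation is
reversible at the network level. Boundary pentamers of the finite patch
have truncated neighborhoods, so degree rules are enforced on interior
nodes only. This constraint set is a formalization choice; it reproduces
the known straight/twisted relationship but is not claimed to be the
unique possible formalization.

## Synthetic assemblies

The generators emulate idealized pentameric assemblies: mathematically
exact dodecahedra (12 pentamers, 60 subunits at the pentagon vertices,
all 30 contacts at the analytic dihedral arccos(−1/√5) ≈ 116.565° with
zero torsion), Fibonacci-spiral spherical cages for the size-vs-bending
trend (deterministic placement; the seeded generator sets only in-plane
phases), lattice-wrapped straight tubes, and dual-strand twisted tubes
(the helix plus its copy rotated half a turn about the screw axis).
Gaussian noise displaces subunit centroids isotropically and refits the
frames, keeping normal signs.

What these fixtures do *not* emulate: atomic detail, interface chemistry,
occupancy of partially formed assemblies, or the deformation of real
pentamers on curved surfaces. Tests passing on them validate the
geometric machinery, not any claim about a particular protein's
energetics. Structure files carry one carbon pseudo-atom per subunit
centroid, one chain per subunit (single-character chain names limit PDB
output to 62 subunits; larger assemblies are written as mmCIF); PDB's
three-decimal coordinates limit round-trip angle agreement to about
0.01°, mmCIF round trips agree to ~1e-5°.

## Problem sizes

The default test and analysis sizes are: tiling grids up to 8 × 12
combinations, wrapped tubes of about two turns (24-48 pentamers), helices
of 10-40 steps, noise trends aggregated over 20 seeds, and a 200k-point
Monte-Carlo check of the contact percentage. The full test suite runs in
well under a minute on one CPU.

## Known limitations

- The interstrip register of the lattice construction is fixed to the
  documented one; other registers can tile for large periodicities but
  are not part of this model family.
- Flip detection covers the degenerate n_p = n_h family; a general
  mirrored-tiling search is not implemented.
- The rewiring admissibility rules are network-level; no 3D realization
  of arbitrary rewired architectures is attempted.
- Helical axis extraction assumes label-tagged threads from the builders;
  untagged assemblies are treated as a single chain in insertion order.
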