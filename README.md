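# pentatube

Geometric analysis and model building for pentamer-based protein cages and
nanotubes.

Cage-forming proteins whose building block is a pentamer — lumazine-synthase
style capsomers — can assemble not only into closed shells but into straight
and twisted tubes. This package implements the geometry needed to reason
about that polymorphism quantitatively:

- **AngelaR** — the bending/torsion angle calculator for two polygon-shaped
  capsomers. With unit normals n_a, n_b and the center-to-center unit vector
  d: if n_a, n_b, d are coplanar the contact is untwisted (torsion 0) and
  the bending angle is 180° − ∠(n_a, n_b); otherwise the torsion is the
  signed rotation about d that brings n_b into the plane of (n_a, d), and
  bending is computed on the rotated configuration. Works on synthetic
  assemblies and on PDB/mmCIF coordinates with user-supplied chain grouping.
- **Straight-tube lattice model** — plane tilings by regular pentagons of
  unit circumradius in two orientations (a pentagon and its in-plane
  180°-rotated partner), organized in staircase strips. A strip repeats with
  vector P⃗, adjacent strips are offset by H⃗ = (a, b). For a given b the
  free parameter a is fixed by the closure condition that the rolled-up tube
  is consistent: the identification vector C⃗ = n_p·P⃗ − n_h·H⃗ must be
  perpendicular to the tube axis, i.e. **n_p·P_y = n_h·b**, linking the
  helicity number n_h (distinct helical strips) and the periodicity number
  n_p (strip steps between identified pentamers). The model scores each
  (n_h, n_p) by the percentage of pentagon edge length in contact and flags
  combinations that are geometrically forbidden or that would require
  mirrored ("flipped") pentamers, which asymmetric protein interfaces cannot
  provide.
- **Twisted-tube helix builder** — grows a pentamer chain by applying fixed
  bending and torsion angles step by step (attachment point on the interface
  edge set by a free parameter). Zero torsion provably yields a planar ring
  with no helical rise; torsion opens the ring into a helix whose rise,
  radius and inter-turn gap are measured by a screw-axis fit.
- **Interaction-network rewiring** — builds the capsomer contact graph
  (nodes at pentamer centers, edges classed by helical symmetry), and
  enumerates the alternative architectures reachable by symmetry-respecting
  weight reassignment under local realizability constraints.
- **Synthetic assemblies** — dodecahedral cages, spherical cages, straight
  and twisted tubes, with optional Gaussian noise and PDB/mmCIF export, so
  everything above is testable without any structural database.

All lengths are in units of the pentagon circumradius; a scale factor
converts to Å/nm on structure export.

## Worked example

Solve the biological straight tube — helicity 3, periodicity 4, lattice
offset b = 2.18 — wrap it onto its cylinder and measure it:

```python
import numpy as np
from pentatube import (LatticeParams, solve_lattice, wrap_to_cylinder,
                       detect_contacts, thread_metrics)

sol = solve_lattice(LatticeParams(b=2.18, n_h=3, n_p=4))
print(f"a = {sol.a:.4f}")
print("per-edge contact %:",
      {k: round(v, 1) for k, v in sol.contact_percent_per_edge.items()})

tube = wrap_to_cylinder(sol, n_turns=2.0)
m = thread_metrics(tube)
records = detect_contacts(tube)
print(f"threads: {m.n_threads}, radius: {m.radius:.3f}")
print(f"mean bending: {np.mean([r.angles.bending for r in records]):.1f} deg")
```

Output:

```
a = 0.4535
per-edge contact %: {'e1': 81.8, 'e2': 40.6, 'e3': 27.1, 'e4': 0.0, 'e5': 52.6}
threads: 3, radius: 1.727
mean bending: 146.4 deg
```

Reading this: the closure fixes the strip-to-strip offset at a = 0.4535.
Four of the five pentamer interfaces carry contacts — e1 (the pseudo-two-fold
pair bond, 82% of the edge in contact), e3 (the other intra-strip bond), and
e2/e5 toward the neighboring strips — while e4 stays uncontacted, matching
the free interface seen in tubular assemblies. Rolled up, the lattice gives
exactly three helical threads on a cylinder of radius 1.73 circumradii.
Intrathread contacts come out with consistently positive torsion (+24.3°,
+27.4°) and interthread contacts with negative torsion (−27.0°, −29.7°); the
mean bending angle of 146° sits well above the dodecahedral cage value of
116.57°, the flat-to-curved trend expected of large tubes.

The same operations are exposed on the command line:

```
pentatube tile --b 2.18 --nh-max 8 --np-max 12 --out heatmap.csv
pentatube build-straight --nh 3 --np 4 --b 2.18 --turns 2 --out tube.cif
pentatube build-twisted --bending 146 --torsion 10 --steps 30 --out helix.cif
pentatube fixtures --kind dodecahedron --out dod.pdb --groups-out groups.json
pentatube angles dod.pdb --groups groups.json --out angles.tsv
pentatube rewire --nh 3 --np 4 --out alternatives/
```

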