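"""Capsomer interaction networks and symmetry-respecting rewiring.

The contact network of a tubular assembly has pentamer centers as nodes
and two kinds of edges: weight-1 edges are realized contacts, weight-0
edges are candidate contacts between next-nearest neighbors.  Edges are
partitioned into symmetry-equivalence classes (orbits of the helical
symmetry); a rewiring reassigns weights class-wise.  An admissible
alternative architecture must

* assign one weight per class (symmetry equivalence),
* keep the weight-1 subgraph connected (an assembly in one piece),
* respect local realizability: a pentamer has five interface edges, so a
  node's contacts may not exceed five and no pentagon edge slot may host
  two distinct contact classes,
* engage each pentamer in exactly as many contacts as the input
  architecture (assembly conditions saturate the available interfaces,
  and a blueprint with a different coordination number is a different
  morphology class, not a rewiring of this one),
* preserve the principal two-fold contact class (the maximal-overlap
  pair bond): that dimer-like interface is structurally conserved across
  every observed assembly of the protein, so rewiring operates on the
  remaining contacts.

For the three-stranded straight tube this leaves exactly one
alternative: two interthread contact classes are deleted and the two
diagonal (next-nearest) classes are gained, turning the squashed-hexagon
network into the triangle-based blueprint of the twisted tubes.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .angelar import bending_torsion, detect_contacts, _min_distance_rings
from .geometry_core import Assembly

__all__ = [
    "ContactNetwork",
    "network_from_assembly",
    "enumerate_rewirings",
]


@dataclass
class ContactNetwork:
    """Capsomer centers with classed, weighted contact edges."""

    positions: dict  # label -> (3,) position
    edges: dict  # (a, b) sorted tuple -> dict(weight=0|1, cls=str)
    slots: dict  # (node, (a, b)) -> int pentagon edge slot in 0..4
    meta: dict = field(default_factory=dict)

    def graph(self, weight: int | None = 1) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.positions)
        for (a, b), data in self.edges.items():
            if weight is None or data["weight"] == weight:
                g.add_edge(a, b, **data)
        return g

    @property
    def edge_classes(self) -> dict:
        classes: dict[str, list] = {}
        for e, data in self.edges.items():
            classes.setdefault(data["cls"], []).append(e)
        return classes

    def class_weights(self) -> dict:
        out = {}
        for e, data in self.edges.items():
            out.setdefault(data["cls"], data["weight"])
            if out[data["cls"]] != data["weight"]:
                raise ValueError(f"class {data['cls']} has mixed weights")
        return out

    def with_class_weights(self, weights: dict) -> "ContactNetwork":
        new_edges = {
            e: dict(d, weight=weights[d["cls"]]) for e, d in self.edges.items()
        }
        return ContactNetwork(
            positions=dict(self.positions),
            edges=new_edges,
            slots=dict(self.slots),
            meta=dict(self.meta),
        )

    def degrees(self, weight: int = 1) -> dict:
        g = self.graph(weight=weight)
        return dict(g.degree())

    def principal_class(self) -> str:
        """Weight-1 class with the largest mean edge-overlap fraction:
        the pseudo-two-fold pair bond of pentamer-pair architectures."""
        best, best_frac = None, -1.0
        sums: dict[str, list] = {}
        for e, d in self.edges.items():
            if d["weight"] == 1:
                sums.setdefault(d["cls"], []).append(d.get("frac", 0.0))
        for cls, fr in sums.items():
            m = float(np.mean(fr))
            if m > best_frac:
                best, best_frac = cls, m
        return best


def _edge_slot(frame, other_center: np.ndarray) -> int:
    """Pentagon edge slot of ``frame`` facing a neighbor center."""
    d = other_center - frame.center
    d = d - (d @ frame.normal) * frame.normal
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        return 0
    d = d / nd
    mids = 0.5 * (frame.vertices + np.roll(frame.vertices, -1, axis=0)) - frame.center
    return int(np.argmax(mids @ d))


def _kind(label: str) -> str:
    return label.split("_")[0]


def network_from_assembly(
    assembly: Assembly, threshold: float | None = None
) -> ContactNetwork:
    """Build the classed contact network of an assembly.

    Weight-1 edges come from contact detection; weight-0 candidate edges
    connect next-nearest neighbors within twice the contact threshold.
    Classes group edges by node kinds and rounded interface geometry
    (distance, bending, |torsion|), which captures the helical symmetry
    orbits of the tube builders.
    """
    if len(assembly) < 2:
        raise ValueError("network requires at least 2 frames")
    if threshold is None:
        edge = float(
            np.median(
                [np.linalg.norm(f.vertices[1] - f.vertices[0]) for f in assembly.frames]
            )
        )
        threshold = 0.15 * edge
    contacts = detect_contacts(assembly, threshold=threshold)
    if not contacts:
        raise ValueError("assembly has no contacts at this threshold")
    frames = {f.label: f for f in assembly.frames}
    positions = {f.label: f.center for f in assembly.frames}

    edges: dict = {}
    slots: dict = {}

    def add_edge(a: str, b: str, weight: int, frac: float = 0.0) -> None:
        key = tuple(sorted((a, b)))
        fa, fb = frames[key[0]], frames[key[1]]
        ap = bending_torsion(fa, fb, co_orient=False)
        dist = float(np.linalg.norm(fb.center - fa.center))
        kinds = "-".join(sorted((_kind(a), _kind(b))))
        cls = (
            f"{'c' if weight == 0 else 'w'}|{kinds}|d{dist:.2f}"
            f"|b{ap.bending:.0f}|t{abs(ap.torsion):.0f}"
        )
        edges[key] = dict(weight=weight, cls=cls, frac=frac)
        slots[(key[0], key)] = _edge_slot(fa, fb.center)
        slots[(key[1], key)] = _edge_slot(fb, fa.center)

    for rec in contacts:
        add_edge(rec.frame_a, rec.frame_b, 1, frac=rec.contact_fraction)

    labels = list(frames)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            key = tuple(sorted((a, b)))
            if key in edges:
                continue
            fa, fb = frames[a], frames[b]
            if np.linalg.norm(fa.center - fb.center) > 4.0 * fa.circumradius:
                continue
            # candidate radius 3x the contact threshold: the next-nearest
            # neighbor band of the tube lattice (ring distance ~0.4) is far
            # below the following band (~1.8), so the factor is not critical
            if _min_distance_rings(fa, fb) < 3.0 * threshold:
                add_edge(a, b, 0)

    net = ContactNetwork(positions=positions, edges=edges, slots=slots)
    if not nx.is_connected(net.graph(weight=1)):
        # keep only the largest connected piece's perspective: reject
        raise ValueError("weight-1 contact graph is not connected")
    return net


def _admissible(
    net: ContactNetwork, weights: dict, interior: set, principal: str | None
) -> bool:
    """Check a class-weight assignment against the admissibility rules.

    Degree rules are enforced on interior nodes only (boundary pentamers
    of a finite tube patch have truncated neighborhoods).
    """
    if principal is not None and weights.get(principal, 1) != 1:
        return False
    cand = net.with_class_weights(weights)
    g = cand.graph(weight=1)
    if g.number_of_edges() == 0 or not nx.is_connected(g):
        return False
    ref_deg = net.degrees(weight=1)
    deg = dict(g.degree())
    for node in interior:
        if deg.get(node, 0) > 5:
            return False
        # coordination number conserved for interior pentamers
        if deg.get(node, 0) != ref_deg.get(node, 0):
            return False
        used = [
            net.slots[(node, e)]
            for e in g.edges(node)
            for e in [tuple(sorted(e))]
        ]
        if len(used) != len(set(used)):
            return False
    return True


def _interior_nodes(net: ContactNetwork) -> set:
    """Nodes whose full neighborhood is inside the finite patch: maximum
    weighted degree among nodes of the same kind."""
    g = net.graph(weight=None)
    deg = dict(g.degree())
    by_kind: dict[str, int] = {}
    for node, d in deg.items():
        k = _kind(node)
        by_kind[k] = max(by_kind.get(k, 0), d)
    return {n for n, d in deg.items() if d == by_kind[_kind(n)]}


def enumerate_rewirings(net: ContactNetwork) -> list[ContactNetwork]:
    """All admissible class-weight reassignments other than the input.

    Exhaustive over classes; class counts are small by symmetry.  The
    input architecture never appears in its own output.
    """
    current = net.class_weights()
    classes = sorted(current)
    if len(classes) > 16:
        raise ValueError("too many edge classes for exhaustive rewiring")
    interior = _interior_nodes(net)
    principal = net.principal_class()
    out = []
    for bits in itertools.product((0, 1), repeat=len(classes)):
        weights = dict(zip(classes, bits))
        if weights == current:
            continue
        if _admissible(net, weights, interior, principal):
            out.append(net.with_class_weights(weights))
    return out
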