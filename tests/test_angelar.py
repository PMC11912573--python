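import numpy as np
import pytest

from pentatube.angelar import (
    bending_torsion,
    detect_contacts,
    measure_structure,
    pair_from_angles,
)
from pentatube.geometry_core import (
    Assembly,
    CapsomerFrame,
    DegenerateGeometryError,
    rotation_matrix,
)
from pentatube.synthetic_assemblies import (
    chain_grouping_for,
    make_sphere_cage,
    make_straight_tube,
    write_structure,
)

from conftest import DODECA_BENDING, thread_of


def flat_frame(label="a"):
    ang = np.radians(72.0) * np.arange(5)
    verts = np.stack([np.cos(ang), np.sin(ang), np.zeros(5)], axis=1)
    return CapsomerFrame(
        center=np.zeros(3), normal=[0, 0, 1.0], vertices=verts, label=label
    )


class TestBendingTorsion:
    def test_dodecahedron_faces(self, dodecahedron):
        records = detect_contacts(dodecahedron)
        assert len(records) == 30
        for rec in records:
            assert rec.angles.bending == pytest.approx(DODECA_BENDING, abs=1e-9)
            assert rec.angles.torsion == pytest.approx(0.0, abs=1e-9)

    def test_flat_pair_is_180_0(self):
        a = flat_frame("a")
        b = pair_from_angles(a, bending=180.0, torsion=0.0)
        ap = bending_torsion(a, b)
        assert ap.bending == pytest.approx(180.0, abs=1e-9)
        assert ap.torsion == pytest.approx(0.0, abs=1e-9)

    def test_axis_twist_reads_as_torsion(self):
        # rotate the flat partner by +10 deg about the center-to-center axis
        a = flat_frame("a")
        b = pair_from_angles(a, bending=180.0, torsion=0.0)
        d = b.center - a.center
        R = rotation_matrix(d / np.linalg.norm(d), 10.0)
        b.normal = R @ b.normal
        b.vertices = (b.vertices - b.center) @ R.T + b.center
        ap = bending_torsion(a, b)
        assert ap.torsion == pytest.approx(10.0, abs=1e-9)
        assert ap.bending == pytest.approx(180.0, abs=1e-6)

    def test_swap_preserves_both_angles(self):
        # the twist handedness of an unordered pair is order-independent,
        # so both bending and torsion are symmetric under argument swap
        a = flat_frame("a")
        b = pair_from_angles(a, bending=141.0, torsion=17.0)
        ab = bending_torsion(a, b)
        ba = bending_torsion(b, a)
        assert ab.bending == pytest.approx(ba.bending, abs=1e-9)
        assert ab.torsion == pytest.approx(ba.torsion, abs=1e-9)

    def test_rigid_motion_invariance(self):
        a = flat_frame("a")
        b = pair_from_angles(a, bending=150.0, torsion=-25.0)
        ref = bending_torsion(a, b)
        R = rotation_matrix([1, 2, 0.5], 73.0)
        t = np.array([3.0, -1.0, 2.0])
        ap = bending_torsion(a.transformed(R, t), b.transformed(R, t))
        assert ap.bending == pytest.approx(ref.bending, abs=1e-9)
        assert ap.torsion == pytest.approx(ref.torsion, abs=1e-9)

    @pytest.mark.parametrize("bending", [95.0, 120.0, 145.0, 179.0])
    @pytest.mark.parametrize("torsion", [-39.0, -12.5, 0.0, 8.0, 39.0])
    def test_build_measure_round_trip(self, bending, torsion):
        a = flat_frame("a")
        b = pair_from_angles(a, bending=bending, torsion=torsion)
        ap = bending_torsion(a, b)
        assert ap.bending == pytest.approx(bending, abs=1e-6)
        assert ap.torsion == pytest.approx(torsion, abs=1e-6)

    def test_round_trip_off_midpoint_attachment(self):
        a = flat_frame("a")
        b = pair_from_angles(a, bending=130.0, torsion=22.0, attach=0.3, edge=2)
        ap = bending_torsion(a, b)
        assert ap.bending == pytest.approx(130.0, abs=1e-6)
        assert ap.torsion == pytest.approx(22.0, abs=1e-6)

    def test_coincident_centers_rejected(self):
        a = flat_frame("a")
        b = flat_frame("b")
        with pytest.raises(DegenerateGeometryError):
            bending_torsion(a, b)


class TestDetectContacts:
    def test_single_frame_no_contacts(self):
        asm = Assembly(frames=[flat_frame("a")])
        assert detect_contacts(asm) == []

    def test_negative_threshold_rejected(self, dodecahedron):
        with pytest.raises(ValueError):
            detect_contacts(dodecahedron, threshold=-1.0)

    def test_dodecahedron_five_contacts_each(self, dodecahedron):
        records = detect_contacts(dodecahedron)
        counts = {}
        for r in records:
            counts[r.frame_a] = counts.get(r.frame_a, 0) + 1
            counts[r.frame_b] = counts.get(r.frame_b, 0) + 1
        assert set(counts.values()) == {5}

    def test_straight_tube_interior_pentamer_four_contacts(self, tube_34):
        records = detect_contacts(tube_34)
        counts = {}
        for r in records:
            counts[r.frame_a] = counts.get(r.frame_a, 0) + 1
            counts[r.frame_b] = counts.get(r.frame_b, 0) + 1
        assert max(counts.values()) == 4  # interior pentamers: P1..P4

    def test_contact_fraction_in_unit_interval(self, tube_34):
        for r in detect_contacts(tube_34):
            assert 0.0 <= r.contact_fraction <= 1.0


class TestMeasureStructure:
    def test_dodecahedron_round_trip(self, dodecahedron, tmp_path):
        path = tmp_path / "dod.pdb"
        write_structure(dodecahedron, str(path), "pdb")
        records = measure_structure(str(path), chain_grouping_for(dodecahedron))
        assert len(records) == 30
        for rec in records:
            # PDB coordinates carry 3 decimals; angles follow to ~0.01 deg
            assert rec.angles.bending == pytest.approx(DODECA_BENDING, abs=0.01)
            assert rec.angles.torsion == pytest.approx(0.0, abs=0.01)

    def test_tube_torsion_signs_survive_round_trip(self, tube_34, tmp_path):
        path = tmp_path / "tube.cif"
        write_structure(tube_34, str(path), "cif")
        records = measure_structure(str(path), chain_grouping_for(tube_34))
        intra = [r for r in records if thread_of(r.frame_a) == thread_of(r.frame_b)]
        inter = [r for r in records if thread_of(r.frame_a) != thread_of(r.frame_b)]
        assert intra and inter
        assert all(r.angles.torsion > 0 for r in intra)
        assert all(r.angles.torsion < 0 for r in inter)

    def test_group_with_two_chains_rejected(self, dodecahedron, tmp_path):
        path = tmp_path / "dod.pdb"
        write_structure(dodecahedron, str(path), "pdb")
        groups = chain_grouping_for(dodecahedron)
        first = next(iter(groups))
        groups[first] = groups[first][:2]
        with pytest.raises(ValueError):
            measure_structure(str(path), groups)


class TestCageSizeTrend:
    def test_bending_increases_with_cage_radius(self):
        # larger cages have flatter (larger) inter-pentamer bending angles
        means = []
        for radius in (1.2, 1.6, 2.4):
            cage = make_sphere_cage(20, radius, seed=3)
            recs = detect_contacts(cage, threshold=1.0)
            means.append(np.mean([r.angles.bending for r in recs]))
        assert means[0] < means[1] < means[2]

    def test_tube_bending_exceeds_dodecahedron(self, tube_34):
        records = detect_contacts(tube_34)
        assert np.mean([r.angles.bending for r in records]) > DODECA_BENDING
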