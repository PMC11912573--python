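import numpy as np
import pytest

from pentatube.straight_tube_lattice import (
    EDGE_MAPPING_ROTATION_DEG,
    EDGE_NORMALS,
    InfeasibleTilingError,
    LatticeParams,
    PENT_VERTICES,
    construction_contacts,
    contact_percentage,
    enumerate_tilings,
    flip_required,
    roll_point,
    solve_lattice,
    wrap_to_cylinder,
)
from pentatube.angelar import detect_contacts

from conftest import DODECA_BENDING, thread_of

B = 2.18
_R = float(np.cos(np.radians(36)))
_S = float(2 * np.sin(np.radians(36)))


def oracle_residual(a, b, n_h, n_p):
    """Closure residual computed independently of the package solver.

    The strip vector P and pair offset w are obtained by explicitly
    writing out the four collinearity constraints of the construction and
    solving with a least-squares route (different code path from the
    package's direct solve)."""
    H = np.array([a, b])
    rows, rhs = [], []
    for (k, m, j) in construction_contacts():
        n = EDGE_NORMALS[k]
        rows.append(np.concatenate([m * n, n]))
        rhs.append(2 * _R - j * (H @ n))
    x, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    P = x[:2]
    return n_p * P[1] - n_h * b


class TestSolveLattice:
    def test_34_feasible_no_flip_no_overlap(self, lattice_34):
        assert lattice_34.feasible
        assert not lattice_34.flip_required
        assert not lattice_34.overlap
        assert abs(lattice_34.closure_residual) < 1e-9

    def test_solved_a_matches_bracketed_root_scan_oracle(self):
        # brute-force sign-change scan over a in (0, 5) at 1e5 grid points
        sol = solve_lattice(LatticeParams(B, 3, 4))
        grid = np.linspace(0.0, 5.0, 100_001)
        vals = np.array([oracle_residual(a, B, 3, 4) for a in grid[:: 1000]])
        # residual is monotone; bracket the root on the coarse scan, then
        # refine on the fine grid between the bracketing nodes
        sign_change = np.nonzero(np.diff(np.sign(vals)))[0]
        assert len(sign_change) == 1
        lo, hi = grid[sign_change[0] * 1000], grid[(sign_change[0] + 1) * 1000]
        fine = np.linspace(lo, hi, 100_001)
        fvals = np.array([oracle_residual(a, B, 3, 4) for a in fine[::100]])
        k = np.nonzero(np.diff(np.sign(fvals)))[0][0]
        assert fine[k * 100] <= sol.a <= fine[(k + 1) * 100]

    @pytest.mark.parametrize("n_h,n_p", [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6)])
    def test_solver_agrees_with_oracle_on_small_grid(self, n_h, n_p):
        sol = solve_lattice(LatticeParams(B, n_h, n_p))
        assert abs(oracle_residual(sol.a, B, n_h, n_p)) < 1e-8

    def test_31_infeasible(self):
        with pytest.raises(InfeasibleTilingError) as exc:
            solve_lattice(LatticeParams(B, 3, 1))
        assert exc.value.reason in ("overlap", "contact-loss")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LatticeParams(B, 0, 4)
        with pytest.raises(ValueError):
            LatticeParams(-1.0, 3, 4)


class TestFlipRequired:
    def test_44_flip_forbidden(self):
        sol = solve_lattice(LatticeParams(B, 4, 4), validate=False)
        assert flip_required(sol)
        with pytest.raises(InfeasibleTilingError) as exc:
            solve_lattice(LatticeParams(B, 4, 4))
        assert exc.value.reason == "flip-forbidden"

    def test_34_not_flip_forbidden(self, lattice_34):
        assert not flip_required(lattice_34)

    def test_feasible_tilings_never_flagged(self):
        for n_h, n_p in [(1, 2), (2, 3), (4, 6)]:
            assert not flip_required(solve_lattice(LatticeParams(B, n_h, n_p)))


class TestContactPercentage:
    def test_percentages_within_range(self, lattice_34):
        pct = contact_percentage(lattice_34)
        assert set(pct) == {"e1", "e2", "e3", "e4", "e5"}
        for v in pct.values():
            assert 0.0 <= v <= 100.0
        assert pct["e4"] == 0.0  # the uncontacted interface

    def test_mean_contact_matches_monte_carlo_oracle(self, lattice_34):
        # sample points on the up pentagon's edges; a point is in contact
        # when it lies on the boundary of a neighboring down pentagon
        rng = np.random.default_rng(0)
        P, H, w = lattice_34.P, lattice_34.H, lattice_34.w
        down_centers = [
            m * P + j * H + w for m in range(-2, 3) for j in range(-2, 3)
        ]
        n_pts = 200_000
        edges = rng.integers(0, 5, n_pts)
        ts = rng.random(n_pts)
        pts = (
            PENT_VERTICES[edges]
            + ts[:, None] * (PENT_VERTICES[(edges + 1) % 5] - PENT_VERTICES[edges])
        )
        hit = np.zeros(n_pts, dtype=bool)
        for c in down_centers:
            local = c[None, :] - pts  # down pentagon: c - (unit pentagon)
            # on the boundary: support distance equals inradius on the
            # nearest edge normal, within tolerance
            proj = local @ EDGE_NORMALS.T
            inside = np.all(proj <= _R + 1e-9, axis=1)
            on_edge = np.any(np.abs(proj - _R) < 1e-9, axis=1)
            hit |= inside & on_edge
        mc = 100.0 * hit.mean()
        assert lattice_34.mean_contact_percent == pytest.approx(mc, abs=0.1)

    def test_infeasible_solution_rejected(self):
        sol = solve_lattice(LatticeParams(B, 3, 1), validate=False)
        with pytest.raises(InfeasibleTilingError):
            contact_percentage(sol)


@pytest.fixture(scope="module")
def table():
    return enumerate_tilings(B, range(1, 7), range(1, 11))


class TestEnumerateTilings:

    def test_max_contact_at_smallest_feasible_np(self, table):
        feas = table[table.feasible]
        for n_h, grp in feas.groupby("n_h"):
            best = grp.loc[grp.mean_contact_percent.idxmax(), "n_p"]
            assert best == grp.n_p.min()

    def test_44_flagged_flip_forbidden(self, table):
        row = table[(table.n_h == 4) & (table.n_p == 4)].iloc[0]
        assert row.status == "flip-forbidden"
        assert not row.feasible

    def test_34_and_45_feasible(self, table):
        for n_h, n_p in [(3, 4), (4, 5)]:
            row = table[(table.n_h == n_h) & (table.n_p == n_p)].iloc[0]
            assert row.feasible

    def test_empty_range_empty_table(self):
        assert len(enumerate_tilings(B, [], [])) == 0


class TestEdgeContactConstruction:
    def test_r3_minus_r1_is_p1_minus_p3(self, lattice_34):
        con = lattice_34.construction
        diff = con.R3 - con.R1
        assert np.allclose(diff, PENT_VERTICES[0] - PENT_VERTICES[2], atol=1e-12)

    def test_rotation_maps_r1_onto_target_edge_line(self, lattice_34):
        con = lattice_34.construction
        # T is the 144-degree anticlockwise rotation of R1 about the origin
        th = np.radians(EDGE_MAPPING_ROTATION_DEG)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert np.allclose(R @ con.R1, con.T, atol=1e-12)
        # and it lands on the e3 edge line of the base pentagon
        assert abs(con.T @ EDGE_NORMALS[2] - _R) < 1e-9

    def test_rotation_magnitude_is_144(self):
        assert EDGE_MAPPING_ROTATION_DEG == 144.0

    def test_contact_length_identity(self, lattice_34):
        # |R1 P2| = |P4 T|: the rotation carries P2 to P4
        con = lattice_34.construction
        d1 = np.linalg.norm(con.R1 - PENT_VERTICES[1])
        d2 = np.linalg.norm(con.T - PENT_VERTICES[3])
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestWrapToCylinder:
    def test_three_threads(self, tube_34):
        threads = {thread_of(f.label) for f in tube_34.frames}
        assert len(threads) == 3

    def test_identified_lattice_points_coincide(self, lattice_34):
        # pentagons separated by the identification vector map to the
        # same 3D position
        xy = np.array([0.37, 1.2])
        C = lattice_34.circumference_vector
        p1 = roll_point(lattice_34, xy)
        p2 = roll_point(lattice_34, xy + C)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_torsion_signs_by_thread(self, tube_34):
        records = detect_contacts(tube_34)
        intra = [r for r in records if thread_of(r.frame_a) == thread_of(r.frame_b)]
        inter = [r for r in records if thread_of(r.frame_a) != thread_of(r.frame_b)]
        intra_torsions = {round(r.angles.torsion, 6) for r in intra}
        assert all(t > 0 for t in intra_torsions)
        assert any(r.angles.torsion < 0 for r in inter)

    def test_mean_bending_exceeds_dodecahedron(self, tube_34):
        records = detect_contacts(tube_34)
        assert np.mean([r.angles.bending for r in records]) > DODECA_BENDING

    def test_wrap_rejects_infeasible(self):
        sol = solve_lattice(LatticeParams(B, 3, 1), validate=False)
        with pytest.raises(InfeasibleTilingError):
            wrap_to_cylinder(sol)
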