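"""Unit and property tests for the coordinate mathematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares, minimize

from ibpenum import geometry as geo
from ibpenum.errors import (
    DegenerateGeometryError,
    InfeasibleGeometryError,
    InvalidGeometryError,
)
from ibpenum.geometry import AngleDomain, BranchGeometry, Interval


def random_chain(rng, n=4):
    """A generic non-degenerate point chain."""
    pts = [np.zeros(3), np.array([1.5, 0, 0]), np.array([2.1, 1.2, 0.0])]
    while len(pts) < n:
        pts.append(
            geo.place_from_internal(
                pts[-3], pts[-2], pts[-1],
                rng.uniform(1.0, 1.8), rng.uniform(1.2, 2.2),
                rng.uniform(-math.pi, math.pi),
            )
        )
    return np.array(pts)


class TestInitialPlacement:
    def test_first_three_vertices(self):
        x1, x2, x3, q3 = geo.initial_placement(1.5, 1.2, math.pi / 3)
        assert np.allclose(x1, 0.0)
        assert np.allclose(x2, [-1.5, 0.0, 0.0])
        assert math.isclose(np.linalg.norm(x3 - x2), 1.2)
        assert math.isclose(geo.bond_angle(x1, x2, x3), math.pi / 3)
        assert abs(x3[2]) < 1e-12  # in the z = 0 plane

    def test_right_angle_case(self):
        x1, x2, x3, _ = geo.initial_placement(1.0, 1.0, math.pi / 2)
        assert math.isclose(np.linalg.norm(x3 - x2), 1.0)
        assert math.isclose(geo.bond_angle(x1, x2, x3), math.pi / 2)

    @pytest.mark.parametrize("bad", [(0.0, 1, 1.0), (1, -2, 1.0), (1, 1, 0.0), (1, 1, math.pi)])
    def test_degenerate_inputs_raise(self, bad):
        d21, d32, theta = bad
        with pytest.raises(InvalidGeometryError):
            geo.initial_placement(d21, d32, theta)


class TestBranchMatrix:
    def test_fourth_column_as_printed(self):
        g = BranchGeometry(theta2=math.pi / 2, omega3=0.0, sigma=+1, d_set=(1.0, 1.5, 2.0))
        b = geo.branch_matrix(g)
        assert np.allclose(b[:, 3], [0.0, 1.0, 0.0, 1.0], atol=1e-12)

    def test_rotation_block_orthonormal(self, rng):
        for _ in range(50):
            g = BranchGeometry(
                theta2=rng.uniform(0.2, 2.9),
                omega3=rng.uniform(-math.pi, math.pi),
                sigma=int(rng.choice([1, -1])),
                d_set=(rng.uniform(1, 2), rng.uniform(1, 3), rng.uniform(1, 4)),
            )
            r = geo.branch_matrix(g)[:3, :3]
            assert np.allclose(r @ r.T, np.eye(3), atol=1e-8)

    def test_both_torsion_signs_hit_first_predecessor_distance(self, rng):
        pts = random_chain(rng)
        q = geo.frame_from_positions(pts[2], pts[1], pts[0])
        d = 1.4
        for om in (0.7, -0.7):
            g = BranchGeometry(theta2=1.8, omega3=om, sigma=+1, d_set=(d, 0, 0))
            pos, _ = geo.place_vertex(q, geo.branch_matrix(g))
            assert math.isclose(np.linalg.norm(pos - pts[2]), d, abs_tol=1e-9)


class TestPlaceVertex:
    def test_identity_frame_gives_fourth_column(self):
        g = BranchGeometry(theta2=1.2, omega3=0.5, sigma=+1, d_set=(1.3, 1, 1))
        b = geo.branch_matrix(g)
        pos, q = geo.place_vertex(np.eye(4), b)
        assert np.allclose(pos, b[:3, 3])
        assert np.allclose(q, b)

    def test_matrix_product_associativity(self):
        x1, x2, x3, q3 = geo.initial_placement(1.45, 1.53, 1.9)
        g = BranchGeometry(theta2=1.9, omega3=1.0, sigma=+1, d_set=(1.33, 1, 1))
        b4 = geo.branch_matrix(g)
        pos, _ = geo.place_vertex(q3, b4)
        e4 = np.array([0, 0, 0, 1.0])
        assert np.allclose(pos, (q3 @ (b4 @ e4))[:3], atol=1e-12)

    def test_chain_placement_matches_trilateration_roots(self, rng):
        """The two torsion-sign branches coincide with the two
        sphere-intersection roots, over many random geometries."""
        for _ in range(1000):
            pts = random_chain(rng)
            p1, p2, p3, p4 = pts
            d1, d2, d3 = (np.linalg.norm(p4 - p) for p in (p3, p2, p1))
            roots = geo.trilaterate(p3, p2, p1, d1, d2, d3)
            q = geo.frame_from_positions(p3, p2, p1)
            d12 = np.linalg.norm(p3 - p2)
            theta2 = geo.bond_angle(p4, p3, p2)
            om = abs(geo.dihedral_angle(p1, p2, p3, p4))
            branch = []
            for s in (+1, -1):
                g = BranchGeometry(theta2=theta2, omega3=-s * om, sigma=+1, d_set=(d1, d2, d3))
                pos, _ = geo.place_vertex(q, geo.branch_matrix(g))
                branch.append(pos)
            for b in branch:
                assert min(np.linalg.norm(b - r) for r in roots) < 1e-6


class TestTrilaterate:
    def test_symmetric_example(self):
        roots = geo.trilaterate(
            [0, 0, 0], [1, 0, 0], [0, 1, 0], 1.0, math.sqrt(2), math.sqrt(2)
        )
        got = sorted(tuple(np.round(r, 9)) for r in roots)
        assert got == [(0.0, 0.0, -1.0), (0.0, 0.0, 1.0)]

    def test_zero_radius_gives_center(self):
        roots = geo.trilaterate([0, 0, 0], [1, 0, 0], [0, 1, 0], 0.0, 1.0, 1.0)
        assert len(roots) == 1
        assert np.allclose(roots[0], [0, 0, 0], atol=1e-9)

    def test_inconsistent_radii_empty(self):
        assert geo.trilaterate([0, 0, 0], [1, 0, 0], [0, 1, 0], 0.1, 0.1, 1.0) == []

    def test_collinear_centers_raise(self):
        with pytest.raises(DegenerateGeometryError):
            geo.trilaterate([0, 0, 0], [1, 0, 0], [2, 0, 0], 1, 1, 1)

    def test_roots_are_mirror_images_and_satisfy_radii(self, rng):
        for _ in range(100):
            pts = random_chain(rng)
            p1, p2, p3, p4 = pts
            d = [np.linalg.norm(p4 - p) for p in (p1, p2, p3)]
            roots = geo.trilaterate(p1, p2, p3, *d)
            assert roots
            for r in roots:
                for di, pi in zip(d, (p1, p2, p3)):
                    assert abs(np.linalg.norm(r - pi) - di) < 1e-9
            if len(roots) == 2:
                n = np.cross(p2 - p1, p3 - p1)
                proj = [float((r - p1) @ n) for r in roots]
                assert math.isclose(proj[0], -proj[1], rel_tol=1e-6)


class TestDiscretizeInterval:
    def test_printed_example(self):
        assert geo.discretize_interval(Interval(0, 5), 5) == [0, 1, 2, 3, 4]

    def test_degenerate_interval_collapses(self):
        assert geo.discretize_interval(Interval(2, 2), 7) == [2.0]

    def test_b_equal_one(self):
        assert geo.discretize_interval(Interval(1.5, 3.0), 1) == [1.5]

    def test_include_upper_redistributes(self):
        vals = geo.discretize_interval(Interval(0, 3), 4, include_upper=True)
        assert vals == [0, 1, 2, 3]

    @given(
        lo=st.floats(0, 10),
        width=st.one_of(st.just(0.0), st.floats(1e-6, 5)),
        b=st.integers(1, 12),
    )
    @settings(deadline=None, max_examples=200)
    def test_samples_ascending_inside_interval(self, lo, width, b):
        iv = Interval(lo, lo + width)
        vals = geo.discretize_interval(iv, b)
        assert all(iv.lower <= v <= iv.upper for v in vals)
        assert vals == sorted(vals)
        assert vals[0] == iv.lower
        if width > 0:
            assert len(vals) == b
            assert iv.upper not in vals[1:]


class TestTorsionDistance:
    def test_law_of_cosines_reduction(self):
        # right angles at both intermediate atoms: b = c = 0, e = f = 1
        d_ij = d_lj = 1.0
        d_jk = 1.0
        d_ik = d_kl = math.sqrt(2.0)
        for xi in (0.3, 1.2, 2.9):
            expect = math.sqrt(d_ij ** 2 + d_lj ** 2 - 2 * d_ij * d_lj * math.cos(xi))
            got = geo.torsion_distance(xi, d_ij, d_jk, d_kl, d_ik, d_lj)
            assert math.isclose(got, expect, abs_tol=1e-12)

    def test_matches_coordinates(self, rng):
        for _ in range(200):
            p = random_chain(rng)
            i, j, k, l = p
            xi = geo.dihedral_angle(i, j, k, l)
            got = geo.torsion_distance(
                xi,
                np.linalg.norm(i - j), np.linalg.norm(j - k), np.linalg.norm(k - l),
                np.linalg.norm(i - k), np.linalg.norm(l - j),
            )
            assert abs(got - np.linalg.norm(i - l)) < 1e-8

    def test_monotone_in_magnitude(self, rng):
        p = random_chain(rng)
        i, j, k, l = p
        dists = (
            np.linalg.norm(i - j), np.linalg.norm(j - k), np.linalg.norm(k - l),
            np.linalg.norm(i - k), np.linalg.norm(l - j),
        )
        grid = [geo.torsion_distance(x, *dists) for x in np.linspace(0, math.pi, 50)]
        assert all(a <= b + 1e-12 for a, b in zip(grid, grid[1:]))
        d0, dpi = grid[0], grid[-1]
        for x in np.linspace(-math.pi, math.pi, 41):
            d = geo.torsion_distance(x, *dists)
            assert d0 - 1e-12 <= d <= dpi + 1e-12

    def test_unrealizable_distances_raise(self):
        with pytest.raises(InfeasibleGeometryError):
            geo.torsion_distance(1.0, 1.0, 1.0, 1.0, 5.0, 1.0)


class TestTorsionDomainBounds:
    def _dists(self, rng):
        p = random_chain(rng)
        i, j, k, l = p
        return (
            np.linalg.norm(i - j), np.linalg.norm(j - k), np.linalg.norm(k - l),
            np.linalg.norm(i - k), np.linalg.norm(l - j),
        )

    def test_singleton_domain(self, rng):
        dists = self._dists(rng)
        dom = AngleDomain((Interval(0.8, 0.8),))
        iv, signs = geo.torsion_domain_to_bounds(dom, *dists)
        assert iv.is_exact
        assert math.isclose(iv.lower, geo.torsion_distance(0.8, *dists))
        assert signs == {+1}

    def test_full_half_domain(self, rng):
        dists = self._dists(rng)
        dom = AngleDomain((Interval(0.0, math.pi),))
        iv, _ = geo.torsion_domain_to_bounds(dom, *dists)
        assert math.isclose(iv.lower, geo.torsion_distance(0.0, *dists))
        assert math.isclose(iv.upper, geo.torsion_distance(math.pi, *dists))

    def test_union_envelope_matches_grid_oracle(self, rng):
        dists = self._dists(rng)
        dom = AngleDomain((Interval(-2.5, -1.0), Interval(0.3, 0.9)))
        iv, signs = geo.torsion_domain_to_bounds(dom, *dists)
        grid = []
        for sub in dom.intervals:
            grid += [
                geo.torsion_distance(x, *dists)
                for x in np.linspace(sub.lower, sub.upper, 2000)
            ]
        assert abs(iv.lower - min(grid)) < 1e-6
        assert abs(iv.upper - max(grid)) < 1e-6
        assert signs == {-1, +1}


class TestDihedral:
    def test_cis_is_zero(self):
        assert abs(geo.dihedral_angle([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0])) < 1e-12

    def test_trans_is_pi(self):
        val = geo.dihedral_angle([-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0])
        assert math.isclose(abs(val), math.pi)
        assert val > 0  # the convention maps trans to +pi, not -pi

    def test_mirror_flips_sign(self, rng):
        p = random_chain(rng)
        xi = geo.dihedral_angle(*p)
        m = p.copy()
        m[:, 2] *= -1
        assert math.isclose(geo.dihedral_angle(*m), -xi, rel_tol=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            geo.dihedral_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestOxygenPlacement:
    def _setup(self, rng):
        p = random_chain(rng)
        vC, vN, vH = p[0], p[1], p[2]
        true = geo.place_from_internal(p[3], vN, vC, 1.23, 2.1, 0.0)
        # target in the C/N/H plane: project
        n = np.cross(vN - vC, vH - vC)
        n /= np.linalg.norm(n)
        true = true - float((true - vC) @ n) * n
        d = [np.linalg.norm(true - v) for v in (vC, vN, vH)]
        return vC, vN, vH, d, true

    def test_residuals_and_coplanarity(self, rng):
        vC, vN, vH, d, _ = self._setup(rng)
        o = geo.place_peptide_oxygen(vC, vN, vH, *d)
        for di, v in zip(d, (vC, vN, vH)):
            assert abs(np.linalg.norm(o - v) - di) < 1e-6
        n = np.cross(vN - vC, vH - vC)
        assert abs(float((vC - o) @ n) / np.linalg.norm(n)) < 1e-8

    def test_matches_nonlinear_least_squares_oracle(self, rng):
        vC, vN, vH, d, true = self._setup(rng)
        o = geo.place_peptide_oxygen(vC, vN, vH, *d)
        n = np.cross(vN - vC, vH - vC)
        n = n / np.linalg.norm(n)

        def residuals(x):
            return [
                np.linalg.norm(x - vC) ** 2 - d[0] ** 2,
                np.linalg.norm(x - vN) ** 2 - d[1] ** 2,
                np.linalg.norm(x - vH) ** 2 - d[2] ** 2,
                float(n @ (vC - x)),
            ]

        sol = least_squares(residuals, x0=true + 0.05, xtol=1e-15, ftol=1e-15)
        assert np.linalg.norm(o - sol.x) < 1e-6

    def test_collinear_plane_atoms_raise(self):
        with pytest.raises(DegenerateGeometryError):
            geo.place_peptide_oxygen([0, 0, 0], [1, 0, 0], [2, 0, 0], 1, 1, 1)


class TestCbetaPlacement:
    def test_residuals_and_uniqueness(self, template):
        anchors = (template.ca, template.ha, template.n, template.c)
        d = [1.521, template.distance("HA", "CB"), template.distance("N", "CB"),
             template.distance("C", "CB")]
        cb = geo.place_cbeta(*anchors, *d)
        for di, v in zip(d, anchors):
            assert abs(np.linalg.norm(cb - v) - di) < 1e-6
        assert np.linalg.norm(cb - template.cb) < 1e-9
        # linear contract: O(delta) response to a perturbed right-hand side
        cb2 = geo.place_cbeta(*anchors, d[0] + 1e-4, *d[1:])
        assert np.linalg.norm(cb2 - cb) < 1e-2

    def test_coplanar_anchors_raise(self):
        with pytest.raises(DegenerateGeometryError):
            geo.place_cbeta(
                [0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], 1, 1, 1, 1
            )


class TestKabschRmsd:
    def test_identical_and_rigid_motion(self, rng):
        a = rng.normal(size=(8, 3))
        assert geo.kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        b = a @ rot.T + np.array([1.0, -2.0, 3.0])
        assert geo.kabsch_rmsd(a, b) < 1e-9

    def test_symmetry(self, rng):
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        assert math.isclose(geo.kabsch_rmsd(a, b), geo.kabsch_rmsd(b, a), rel_tol=1e-9)

    def test_against_brute_force_rotation_search(self, rng):
        """Three-atom case cross-checked against direct minimization
        over rotations (Euler angles)."""
        a = np.array([[0, 0, 0], [1.5, 0, 0], [0.7, 1.2, 0.0]])
        b = a.copy()
        b[2] += np.array([0.0, 0.0, 1.0])  # move one atom 1 A out of plane
        got = geo.kabsch_rmsd(a, b)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def cost(angles):
            from scipy.spatial.transform import Rotation

            r = Rotation.from_euler("xyz", angles).as_matrix()
            return np.sqrt(np.mean(np.sum((ac - bc @ r.T) ** 2, axis=1)))

        best = min(
            minimize(cost, x0, method="Nelder-Mead").fun
            for x0 in ([0, 0, 0], [1, 1, 1], [-1, 2, 0.5])
        )
        assert math.isclose(got, best, abs_tol=1e-5)

    def test_mismatched_shapes_raise(self):
        with pytest.raises(InvalidGeometryError):
            geo.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestAngleDomain:
    def test_signed_containment(self):
        dom = AngleDomain.from_degrees((-90, -30))
        assert dom.contains(math.radians(-57))
        assert not dom.contains(math.radians(57))

    def test_tolerance_is_inclusive(self):
        dom = AngleDomain.from_degrees((-90, -30))
        assert dom.contains(math.radians(-28), tol=math.radians(2))
        assert not dom.contains(math.radians(-27), tol=math.radians(2))

    def test_shift_wraps_across_cut(self):
        dom = AngleDomain.from_degrees((150, 180)).shifted(math.radians(60))
        # [150, 180] + 60 -> [-150, -120]
        assert dom.contains(math.radians(-135))
        assert not dom.contains(math.radians(170))

    @given(
        lo=st.floats(-179, 179), width=st.floats(0, 100), off=st.floats(-360, 360)
    )
    @settings(deadline=None, max_examples=200)
    def test_shift_preserves_membership(self, lo, width, off):
        hi = min(lo + width, 180.0)
        dom = AngleDomain.from_degrees((lo, hi))
        mid = math.radians((lo + hi) / 2)
        shifted = dom.shifted(math.radians(off))
        assert shifted.contains(geo.wrap_angle(mid + math.radians(off)), tol=1e-9)
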