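"""Tests for the instance builder: vertex order, constraint
generation, bound smoothing and assembly."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from ibpenum import geometry as geo
from ibpenum import instance as inst
from ibpenum.conformation import AtomRef
from ibpenum.errors import ConfigurationError, InvalidGeometryError
from ibpenum.geometry import AngleDomain, Interval
from ibpenum.instance import (
    ConstraintSet,
    CovalentGeometry,
    DistanceConstraint,
    HelixDefinition,
    ToleranceConfig,
    VdwTable,
    build_atom_order,
)


class TestVertexOrder:
    @pytest.mark.parametrize("n,expected", [(15, 107), (24, 170), (51, 359)])
    def test_reference_vertex_counts(self, n, expected):
        assert len(build_atom_order(n)) == expected

    @pytest.mark.parametrize("n", range(1, 61))
    def test_count_formula(self, n):
        assert len(build_atom_order(n)) == 7 * n + 2

    def test_duplicates_reference_earlier_ranks(self):
        order = build_atom_order(5)
        for v in order:
            if v.is_duplicate:
                assert v.original_rank is not None and v.original_rank < v.rank
                assert order[v.original_rank - 1].atom == v.atom
            else:
                assert v.original_rank is None

    def test_three_predecessor_property(self, geom):
        """Every vertex beyond the third has exact distances to its
        immediate two predecessors and an exact-or-interval distance to
        the third, once all constraint sources are built."""
        seq = "A" * 6
        order = build_atom_order(6)
        helix = HelixDefinition(ranges=((1, 6),))
        phi, psi = inst.default_torsion_domains(seq, helix)
        cs = inst.covalent_constraints(seq, geom)
        for c in inst.torsion_constraints(seq, phi, psi, geom):
            cs.add(c)
        atom_of = {v.rank: v.atom for v in order}
        for v in order:
            if v.rank <= 3:
                continue
            for back, need_exact in ((1, True), (2, True), (3, False)):
                a, b = v.atom, atom_of[v.rank - back]
                if a == b:
                    continue  # duplicate pair, distance zero
                c = cs.get(a, b)
                assert c is not None, f"missing {a}-{b} at rank {v.rank}"
                if need_exact:
                    assert c.is_exact, f"{a}-{b} must be exact"

    def test_invalid_count_rejected(self):
        with pytest.raises(ConfigurationError):
            build_atom_order(0)


class TestSequences:
    def test_proline_rejected(self):
        with pytest.raises(ConfigurationError, match="[Pp]roline"):
            inst.validate_sequence("AAPA")

    def test_glycine_has_no_cbeta(self):
        roster = inst.atom_roster("AGA")
        assert AtomRef(2, "CB") not in roster
        assert AtomRef(1, "CB") in roster
        assert AtomRef(2, "HA") in roster


class TestCovalentConstraints:
    def test_amide_bond_length(self, geom):
        cs = inst.covalent_constraints("AA", geom)
        c = cs.get(AtomRef(1, "N"), AtomRef(1, "H"))
        assert c.is_exact and c.lower == pytest.approx(1.01)

    def test_one_three_distance_law_of_cosines(self, geom):
        # N-CA 1.458, CA-C 1.525, angle N-CA-C 111.2 deg
        expect = math.sqrt(
            1.458 ** 2 + 1.525 ** 2 - 2 * 1.458 * 1.525 * math.cos(math.radians(111.2))
        )
        assert expect == pytest.approx(2.462, abs=5e-4)
        c = inst.covalent_constraints("AA", geom).get(AtomRef(1, "N"), AtomRef(1, "C"))
        assert c.lower == pytest.approx(expect, abs=1e-12)

    def test_all_near_order_edges_covered(self, geom):
        order = build_atom_order(4)
        cs = inst.covalent_constraints("AAAA", geom)
        atom_of = {v.rank: v.atom for v in order}
        for v in order:
            for back in (1, 2):
                if v.rank - back < 1:
                    continue
                a, b = v.atom, atom_of[v.rank - back]
                if a == b:
                    continue
                c = cs.get(a, b)
                assert c is not None and c.is_exact, f"{a}-{b}"

    def test_omega_derived_ca_ca_distance(self, geom, helix8):
        """The trans 1-4 CA..CA distance matches the built helix."""
        _, conf = helix8
        cs = inst.covalent_constraints("A" * 8, geom)
        c = cs.get(AtomRef(1, "CA"), AtomRef(2, "CA"))
        measured = np.linalg.norm(conf[AtomRef(1, "CA")] - conf[AtomRef(2, "CA")])
        assert c.is_exact and c.lower == pytest.approx(measured, abs=1e-9)
        assert 3.7 < c.lower < 3.9  # the canonical trans virtual bond

    def test_missing_table_entry_names_pair(self):
        bonds = dict(inst._DEFAULT_BONDS)
        del bonds[("N", "H")]
        geom = CovalentGeometry(bonds=bonds)
        with pytest.raises(ConfigurationError, match="N-H|H-N"):
            inst.covalent_constraints("AA", geom)


class TestVdwBounds:
    def test_carbon_nitrogen_bound(self):
        t = VdwTable(sigma=0.85)
        assert t.lower_bound(AtomRef(1, "CA"), AtomRef(2, "N")) == pytest.approx(2.72)

    def test_hydrogen_pair_bound(self):
        t = VdwTable(sigma=0.85)
        assert t.lower_bound(AtomRef(1, "H"), AtomRef(3, "HA")) == pytest.approx(1.70)

    def test_existing_restraint_untouched(self, geom):
        seq = "A" * 6
        cs = inst.covalent_constraints(seq, geom)
        nmr = DistanceConstraint(AtomRef(1, "CA"), AtomRef(6, "CA"), 3.0, 8.0, "nmr")
        cs.add(nmr)
        vdw = inst.vdw_bounds(seq, cs)
        assert vdw.get(AtomRef(1, "CA"), AtomRef(6, "CA")) is None

    def test_only_distant_pairs_get_bounds(self, geom):
        seq = "AAA"
        cs = inst.covalent_constraints(seq, geom)
        vdw = inst.vdw_bounds(seq, cs)
        # H-N are bonded; N-C are two bonds apart: no vdw bound
        assert vdw.get(AtomRef(1, "N"), AtomRef(1, "H")) is None
        for c in vdw:
            assert c.upper == math.inf
            assert c.lower > 0


class TestHelixConstraints:
    def test_helix_1_15_gives_eleven_pairs(self):
        helix = HelixDefinition(ranges=((1, 15),))
        cs = inst.helix_hbond_constraints(helix)
        assert len(cs) == 11
        pairs = {(c.a.residue_index, c.b.residue_index) for c in cs}
        assert pairs == {(i - 4, i) for i in range(5, 16)}

    def test_short_helix_gives_none(self):
        assert len(inst.helix_hbond_constraints(HelixDefinition(ranges=((3, 6),)))) == 0

    def test_bounds_equal_configured_interval(self):
        helix = HelixDefinition(ranges=((2, 8),), hbond=Interval(2.0, 2.9))
        for c in inst.helix_hbond_constraints(helix):
            assert (c.lower, c.upper) == (2.0, 2.9)
            assert c.a.atom_name == "O" and c.b.atom_name == "H"


class TestTorsionConstraints:
    def test_singleton_domain_gives_exact_distance(self, geom, helix8):
        spec, conf = helix8
        phi = {i: AngleDomain.from_degrees((-57.0, -57.0)) for i in range(1, 9)}
        psi = {i: AngleDomain.from_degrees((-47.0, -47.0)) for i in range(1, 9)}
        cs = inst.torsion_constraints("A" * 8, phi, psi, geom)
        c = cs.get(AtomRef(1, "C"), AtomRef(2, "C"))
        measured = np.linalg.norm(conf[AtomRef(1, "C")] - conf[AtomRef(2, "C")])
        assert c.upper - c.lower < 1e-9
        assert c.lower == pytest.approx(measured, abs=1e-6)

    def test_helix_window_contains_ideal_distance(self, geom, helix8):
        _, conf = helix8
        helix = HelixDefinition(ranges=((1, 8),))
        phi, psi = inst.default_torsion_domains("A" * 8, helix)
        cs = inst.torsion_constraints("A" * 8, phi, psi, geom)
        for a, b in [
            (AtomRef(3, "H"), AtomRef(3, "HA")),
            (AtomRef(3, "HA"), AtomRef(4, "N")),
            (AtomRef(2, "C"), AtomRef(3, "C")),
            (AtomRef(3, "N"), AtomRef(4, "N")),
        ]:
            c = cs.get(a, b)
            d = float(np.linalg.norm(conf[a] - conf[b]))
            assert c.lower - 1e-9 <= d <= c.upper + 1e-9, (a, b)

    def test_widening_domain_never_shrinks_interval(self, geom):
        narrow = {1: AngleDomain.from_degrees((-60.0, -50.0))}
        wide = {1: AngleDomain.from_degrees((-90.0, -20.0))}
        psi = {1: AngleDomain.from_degrees((-47.0, -47.0))}
        cs_n = inst.torsion_constraints("AA", {**narrow, 2: narrow[1]}, {**psi, 2: psi[1]}, geom)
        cs_w = inst.torsion_constraints("AA", {**wide, 2: wide[1]}, {**psi, 2: psi[1]}, geom)
        a, b = AtomRef(1, "H"), AtomRef(1, "HA")
        cn, cw = cs_n.get(a, b), cs_w.get(a, b)
        assert cw.lower <= cn.lower + 1e-12 and cw.upper >= cn.upper - 1e-12


class TestFloydWarshall:
    def test_triangle_example(self):
        atoms = [AtomRef(1, "N"), AtomRef(1, "CA"), AtomRef(1, "C")]
        cs = ConstraintSet()
        cs.add(DistanceConstraint(atoms[0], atoms[1], 0.0, 1.0, "nmr"))
        cs.add(DistanceConstraint(atoms[1], atoms[2], 0.0, 1.0, "nmr"))
        cs.add(DistanceConstraint(atoms[0], atoms[2], 0.0, 5.0, "nmr"))
        u, idx = inst.floyd_warshall_refine(cs, atoms)
        assert u[idx[atoms[0]], idx[atoms[2]]] == pytest.approx(2.0)

    def test_refined_bounds_never_exceed_inputs_and_idempotent(self, geom):
        seq = "A" * 5
        cs = inst.covalent_constraints(seq, geom)
        atoms = inst.atom_roster(seq)
        u, idx = inst.floyd_warshall_refine(cs, atoms)
        for c in cs:
            assert u[idx[c.a], idx[c.b]] <= c.upper + 1e-9
        # idempotence: running shortest paths on the refined matrix is a no-op
        from scipy.sparse.csgraph import floyd_warshall as fw

        again = fw(u, directed=False)
        assert np.allclose(np.where(np.isinf(u), -1, u), np.where(np.isinf(again), -1, again))

    def test_matches_brute_force_on_random_graphs(self, rng):
        for trial in range(5):
            g = nx.gnp_random_graph(12, 0.35, seed=int(rng.integers(1 << 30)))
            atoms = [AtomRef(i + 1, "CA") for i in range(12)]
            cs = ConstraintSet()
            weights = {}
            for u_, v_ in g.edges:
                w = float(rng.uniform(0.5, 4.0))
                weights[(u_, v_)] = w
                cs.add(DistanceConstraint(atoms[u_], atoms[v_], 0.0, w, "nmr"))
            refined, idx = inst.floyd_warshall_refine(cs, atoms)
            oracle = nx.Graph()
            oracle.add_nodes_from(range(12))
            oracle.add_edges_from(
                (a, b, {"weight": w}) for (a, b), w in weights.items()
            )
            for u_ in range(12):
                for v_ in range(u_ + 1, 12):
                    try:
                        expect = nx.dijkstra_path_length(oracle, u_, v_)
                    except nx.NetworkXNoPath:
                        expect = math.inf
                    got = refined[idx[atoms[u_]], idx[atoms[v_]]]
                    assert got == pytest.approx(expect) or (
                        math.isinf(got) and math.isinf(expect)
                    )


class TestAssembly:
    def test_exact_instance_has_singleton_samples(self, geom):
        phi = {i: AngleDomain.from_degrees((-57.0, -57.0)) for i in range(1, 5)}
        psi = {i: AngleDomain.from_degrees((-47.0, -47.0)) for i in range(1, 5)}
        instance = inst.build_instance(
            "AAAA", helix=HelixDefinition(ranges=((1, 4),)),
            phi_domains=phi, psi_domains=psi,
        )
        for k, v in instance.vertices.items():
            if v.duplicate_of is None:
                assert len(v.samples) >= 1
                assert v.interval is None or v.interval.width < 1e-9

    def test_interval_edges_get_b_samples(self):
        tol = ToleranceConfig(b=5)
        instance = inst.build_instance(
            "A" * 5, helix=HelixDefinition(ranges=((1, 5),)), tol=tol
        )
        widths = [
            len(v.samples)
            for v in instance.vertices.values()
            if v.interval is not None and v.interval.width > 1e-6
        ]
        assert widths and all(w <= 5 for w in widths)
        assert max(w for w in widths) == 5

    def test_long_range_restraint_lands_in_pruning_edges(self):
        from ibpenum.io import RestraintRecord

        rec = RestraintRecord(1, "HA", 8, "H", 2.0, 3.5)
        instance = inst.build_instance(
            "A" * 8, helix=HelixDefinition(ranges=((1, 8),)), restraints=[rec]
        )
        canon = instance.protein.canonical_rank
        lo_rank, hi_rank = sorted(
            (canon[AtomRef(1, "HA")], canon[AtomRef(8, "H")])
        )
        assert any(
            u == lo_rank and lo == pytest.approx(2.0) and hi == pytest.approx(3.5)
            for (u, lo, hi) in instance.prune_edges[hi_rank]
        )

    def test_contradictory_bounds_rejected(self):
        cs = ConstraintSet()
        cs.add(DistanceConstraint(AtomRef(1, "N"), AtomRef(2, "N"), 5.0, 6.0, "nmr"))
        with pytest.raises(InvalidGeometryError, match="contradictory"):
            cs.add(DistanceConstraint(AtomRef(1, "N"), AtomRef(2, "N"), 1.0, 2.0, "nmr"))

    def test_edge_partition_reports_levels(self):
        instance = inst.build_instance("A" * 5, helix=HelixDefinition(ranges=((1, 5),)))
        part = instance.edge_partition
        assert part["l"] > 0 and part["k"] > 0 and part["E_P"] > 0
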