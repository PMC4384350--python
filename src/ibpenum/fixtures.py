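"""Synthetic test systems: ideal helices, instances derived from known
structures, and the input-degradation protocol.

These generators are the download-free test surface of the package: an
ideal helix built from the covalent tables plays the role of a solved
reference structure, and :func:`derive_instance` turns it into a
discretizable instance whose solution set must contain the original
(up to the global mirror, which survives until the first chirality
check).  They emulate idealized alpha-helical systems — uniform
phi/psi, exact covalent geometry, noise-free intervals around true
distances — not the error statistics of real NOE data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conformation import AtomRef, Conformation
from .errors import ConfigurationError
from . import geometry as geo
from .geometry import AngleDomain, Interval
from . import instance as inst
from .instance import (
    ConstraintSet,
    CovalentGeometry,
    DGPInstance,
    DistanceConstraint,
    HelixDefinition,
    ToleranceConfig,
)

__all__ = [
    "FixtureSpec",
    "build_ideal_helix",
    "derive_instance",
    "degrade_inputs",
    "chain_instance_from_points",
    "random_exact_instance",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic helix and the instance derived from it.

    n_residues : length of the (all-alanine by default) chain
    phi, psi   : uniform backbone torsions in degrees (ideal helix
                 -57 / -47)
    width      : interval width (angstroms) given to the discretizable
                 {v, v-3} edges; 0 means exact distances
    n_pruning_pairs : number of seeded long-range CA-CA interval
                 constraints added as pruning edges
    pruning_width : width of those long-range intervals
    seed       : seed for the random pair selection (recorded so runs
                 can be reproduced)
    """

    n_residues: int
    phi: float = -57.0
    psi: float = -47.0
    width: float = 0.0
    n_pruning_pairs: int = 2
    pruning_width: float = 0.5
    seed: int = 0
    sequence: str | None = None
    helix_ranges: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.n_residues < 4:
            raise ConfigurationError("fixtures need at least 4 residues")
        if self.width < 0 or self.pruning_width < 0:
            raise ConfigurationError("interval widths must be non-negative")

    @property
    def seq(self) -> str:
        return inst.validate_sequence(self.sequence or "A" * self.n_residues)

    @property
    def helix(self) -> HelixDefinition:
        ranges = self.helix_ranges or ((1, self.n_residues),)
        return HelixDefinition(ranges=ranges)


def build_ideal_helix(spec: FixtureSpec, geom: CovalentGeometry | None = None) -> Conformation:
    """Build a full backbone (N, H, CA, HA, C, carbonyl O, C-beta) with
    uniform phi/psi and trans peptide bonds from the covalent tables.

    The heavy-atom chain is grown by internal coordinates; amide
    hydrogens follow from amide planarity, H-alpha and C-beta from the
    tetrahedral C-alpha template (C-beta through the same linear-system
    placement the search uses, O through the in-plane placement)."""
    geom = geom or CovalentGeometry()
    seq = spec.seq
    n = len(seq)
    phi = math.radians(spec.phi)
    psi = math.radians(spec.psi)
    tmpl = inst.CAlphaTemplate.from_geometry(geom)
    offs = inst.torsion_offsets(geom)

    b_nca = geom.bond("N", "CA")
    b_cac = geom.bond("CA", "C")
    b_cn = geom.bond("C", "N+")
    b_nh = geom.bond("N", "H")

    pos: dict[AtomRef, np.ndarray] = {}
    pos[AtomRef(1, "N")] = np.zeros(3)
    pos[AtomRef(1, "CA")] = np.array([b_nca, 0.0, 0.0])
    ang = geom.angle("N", "CA", "C")
    pos[AtomRef(1, "C")] = pos[AtomRef(1, "CA")] + np.array(
        [-b_cac * math.cos(ang), b_cac * math.sin(ang), 0.0]
    )
    for i in range(1, n):
        A = AtomRef
        pos[A(i + 1, "N")] = geo.place_from_internal(
            pos[A(i, "N")], pos[A(i, "CA")], pos[A(i, "C")],
            b_cn, geom.angle("CA", "C", "N+"), psi,
        )
        pos[A(i + 1, "CA")] = geo.place_from_internal(
            pos[A(i, "CA")], pos[A(i, "C")], pos[A(i + 1, "N")],
            b_nca, geom.angle("C-", "N", "CA"), geom.omega(i + 1),
        )
        pos[A(i + 1, "C")] = geo.place_from_internal(
            pos[A(i, "C")], pos[A(i + 1, "N")], pos[A(i + 1, "CA")],
            b_cac, geom.angle("N", "CA", "C"), phi,
        )
    # decorations
    for i in range(1, n + 1):
        A = AtomRef
        if i == 1:
            # no preceding carbonyl: orient the amide H consistently
            # with the uniform phi
            pos[A(1, "H")] = geo.place_from_internal(
                pos[A(1, "C")], pos[A(1, "CA")], pos[A(1, "N")],
                b_nh, geom.angle("H", "N", "CA"),
                geo.wrap_angle(phi + offs["off_h_c"]),
            )
        else:
            pos[A(i, "H")] = geo.place_from_internal(
                pos[A(i, "CA")], pos[A(i - 1, "C")], pos[A(i, "N")],
                b_nh, geom.angle("C-", "N", "H"), math.pi,
            )
        pos[A(i, "HA")] = geo.place_from_internal(
            pos[A(i, "N")], pos[A(i, "C")], pos[A(i, "CA")],
            geom.bond("CA", "HA"), geom.angle("C", "CA", "HA"), tmpl.improper_ha,
        )
        if seq[i - 1] != "G":
            pos[A(i, "CB")] = geo.place_cbeta(
                pos[A(i, "CA")], pos[A(i, "HA")], pos[A(i, "N")], pos[A(i, "C")],
                geom.bond("CA", "CB"), tmpl.distance("HA", "CB"),
                tmpl.distance("N", "CB"), tmpl.distance("C", "CB"),
            )
    for i in range(1, n):
        A = AtomRef
        d_oc = geom.bond("C", "O")
        d_on = geom.distance_13("O", "C", "N+")
        d_oh = geo.torsion_distance(
            geom.omega(i + 1),
            d_oc, geom.bond("C", "N+"), geom.bond("N", "H"),
            d_on, geom.distance_13("C-", "N", "H"),
        )
        pos[A(i, "O")] = geo.place_peptide_oxygen(
            pos[A(i, "C")], pos[A(i + 1, "N")], pos[A(i + 1, "H")],
            d_oc, d_on, d_oh,
        )
    atoms = inst.atom_roster(seq)
    return Conformation(atoms, np.array([pos[a] for a in atoms]))


def derive_instance(
    conf: Conformation,
    spec: FixtureSpec,
    geom: CovalentGeometry | None = None,
    tol: ToleranceConfig | None = None,
    degrade: bool = False,
) -> DGPInstance:
    """Derive a discretizable instance from a known structure.

    Covalent, angular and omega-derived distances come from the tables
    (the fixture is built from the same tables, so they match the
    measured values); each phi/psi-dependent order edge becomes an
    interval of the spec's width centered on the measured distance;
    seeded long-range CA-CA pairs become pruning-edge intervals.  Every
    interval contains the true distance, so the fixture itself is a
    solution of the derived instance.

    With ``degrade=True`` the robustness protocol of
    :func:`degrade_inputs` is applied first: each helix loses one
    residue per extremity and the long-range intervals widen by 0.5 A
    on each side.
    """
    geom = geom or CovalentGeometry()
    tol = tol or ToleranceConfig()
    seq = spec.seq
    n = len(seq)
    edges = ConstraintSet()
    long_range = ConstraintSet()

    def iv_around(cs: ConstraintSet, a: AtomRef, b: AtomRef, width: float, source: str):
        d = float(np.linalg.norm(conf[a] - conf[b]))
        lo = max(0.0, d - width / 2.0)
        cs.add(DistanceConstraint(a, b, lo, d + width / 2.0, source))

    for i in range(1, n + 1):
        iv_around(edges, AtomRef(i, "H"), AtomRef(i, "HA"), spec.width, "torsion")
        if i < n:
            iv_around(edges, AtomRef(i, "HA"), AtomRef(i + 1, "N"), spec.width, "torsion")

    rng = np.random.default_rng(spec.seed)
    eligible = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + 4, n + 1)
    ]
    if eligible and spec.n_pruning_pairs:
        take = min(spec.n_pruning_pairs, len(eligible))
        for idx in rng.choice(len(eligible), size=take, replace=False):
            i, j = eligible[int(idx)]
            iv_around(long_range, AtomRef(i, "CA"), AtomRef(j, "CA"), spec.pruning_width, "nmr")

    helix = spec.helix
    if degrade:
        helix, long_range, _warnings = degrade_inputs(helix, long_range)
    extra = ConstraintSet()
    for cs in (edges, long_range):
        for c in cs:
            extra.add(c)

    phi_dom = {
        i: AngleDomain.from_degrees((spec.phi - 30.0, spec.phi + 30.0))
        for i in range(1, n + 1)
    }
    psi_dom = {
        i: AngleDomain.from_degrees((spec.psi - 30.0, spec.psi + 30.0))
        for i in range(1, n + 1)
    }
    return inst.build_instance(
        seq,
        helix=helix,
        tol=tol,
        geom=geom,
        phi_domains=phi_dom,
        psi_domains=psi_dom,
        extra_constraints=extra,
    )


def degrade_inputs(
    helix: HelixDefinition,
    pruning_constraints: ConstraintSet,
) -> tuple[HelixDefinition, ConstraintSet, list[str]]:
    """The robustness protocol: shrink every helix by one residue per
    extremity and widen every long-range interval by 0.5 A on each
    side (floored at zero).  Helices shorter than three residues after
    shrinking are dropped; a warning string is returned for each.
    """
    new_ranges = []
    warnings = []
    for lo, hi in helix.ranges:
        lo2, hi2 = lo + 1, hi - 1
        if hi2 - lo2 + 1 < 3:
            warnings.append(f"helix {lo}-{hi} too short after shrinking; dropped")
            continue
        new_ranges.append((lo2, hi2))
    degraded_helix = HelixDefinition(
        ranges=tuple(new_ranges),
        hbond=helix.hbond,
        energy_threshold=helix.energy_threshold,
        q1=helix.q1, q2=helix.q2, f=helix.f,
        theta=helix.theta, theta_p=helix.theta_p, theta_pp=helix.theta_pp,
    )
    widened = ConstraintSet()
    for c in pruning_constraints:
        widened.add(
            DistanceConstraint(
                c.a, c.b, max(0.0, c.lower - 0.5), c.upper + 0.5, c.source
            )
        )
    return degraded_helix, widened, warnings


# ---------------------------------------------------------------------------
# Abstract (non-protein) instances for theory properties
# ---------------------------------------------------------------------------

def chain_instance_from_points(
    points: np.ndarray,
    pruning_pairs: list[tuple[int, int, float, float]] = (),
    b: int = 1,
    interval_width: float = 0.0,
) -> DGPInstance:
    """Build a bare discretizable instance from realized coordinates.

    ``points`` is an ``(n, 3)`` array; vertex v (1-based) gets exact
    distances to v-1 and v-2 and an exact (or ``interval_width``-wide,
    b-sampled) distance to v-3.  ``pruning_pairs`` are
    ``(u, v, lower, upper)`` with 1-based ranks and ``u < v``.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 4:
        raise ConfigurationError("need at least 4 points")

    def dist(i, j):
        return float(np.linalg.norm(pts[i - 1] - pts[j - 1]))

    vertices = {}
    for k in range(4, n + 1):
        d1, d2 = dist(k, k - 1), dist(k, k - 2)
        d12, d13, d23 = dist(k - 1, k - 2), dist(k - 1, k - 3), dist(k - 2, k - 3)
        theta2 = math.acos(
            min(1.0, max(-1.0, (d1 * d1 + d12 * d12 - d2 * d2) / (2 * d1 * d12)))
        )
        d3_true = dist(k, k - 3)
        if interval_width > 0 and b > 1:
            iv = Interval(max(0.0, d3_true - interval_width / 2), d3_true + interval_width / 2)
            dset = geo.discretize_interval(iv, b)
        else:
            iv = None
            dset = [d3_true]
        samples = []
        for d3 in dset:
            try:
                cosx = geo.torsion_cosine(d3, d23, d12, d1, d13, d2)
            except Exception:
                continue
            if abs(cosx) > 1 + 1e-9:
                continue
            samples.append((d3, math.acos(min(1.0, max(-1.0, cosx)))))
        vertices[k] = inst.VertexEmbeddingData(d1, d2, samples, theta2, interval=iv)

    prune_edges = {k: [] for k in range(1, n + 1)}
    for u, v, lo, hi in pruning_pairs:
        prune_edges[v].append((u, lo, hi))
    d21, d32, d31 = dist(2, 1), dist(3, 2), dist(3, 1)
    theta3 = math.acos(
        min(1.0, max(-1.0, (d21 ** 2 + d32 ** 2 - d31 ** 2) / (2 * d21 * d32)))
    )
    return DGPInstance(
        n_vertices=n,
        b=b,
        vertices=vertices,
        init=(d21, d32, theta3),
        prune_edges=prune_edges,
    )


def random_exact_instance(
    n: int,
    seed: int,
    n_pruning: int = 2,
    pruning_slack: float = 0.05,
):
    """A random exact chain plus random pruning-edge intervals around
    the true long-range distances.  Returns ``(instance, points)``.

    The chain is generated with generic bond lengths/angles/torsions so
    that no quadruple is accidentally planar.
    """
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3), np.array([1.5, 0.0, 0.0])]
    ang = rng.uniform(1.3, 2.2)
    pts.append(pts[1] + 1.4 * np.array([-math.cos(ang), math.sin(ang), 0.0]))
    for _ in range(n - 3):
        bond = rng.uniform(1.2, 1.6)
        angle = rng.uniform(1.4, 2.1)
        tors = rng.uniform(-math.pi, math.pi)
        pts.append(geo.place_from_internal(pts[-3], pts[-2], pts[-1], bond, angle, tors))
    pts = np.array(pts)
    pairs = [(u, v) for u in range(1, n + 1) for v in range(u + 4, n + 1)]
    pruning = []
    if pairs and n_pruning:
        for idx in rng.choice(len(pairs), size=min(n_pruning, len(pairs)), replace=False):
            u, v = pairs[int(idx)]
            d = float(np.linalg.norm(pts[u - 1] - pts[v - 1]))
            pruning.append((u, v, max(0.0, d - pruning_slack), d + pruning_slack))
    return chain_instance_from_points(pts, pruning), pts
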