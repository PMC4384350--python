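"""Construction of discretizable distance-geometry instances for
protein backbones.

The search embeds atoms along a *repetition order* in which every
vertex beyond the third is constrained to its three immediate
predecessors.  Each residue contributes the seven-vertex block::

    N, H, CA, N*, HA, CA*, C        (* = re-embedded duplicate)

and the order closes with a two-vertex terminal re-embedding
``CA_n**, C_n*``, for ``7 n + 2`` vertices in total.  With this block
the ``{v, v-1}`` and ``{v, v-2}`` edges are always covalent bond or
bond-angle distances (exact scalars), while the ``{v, v-3}`` edges are
either exact (fixed peptide torsion omega, or a bond angle) or
phi/psi-dependent intervals that the search discretizes into ``b``
sample values:

* ``H_i .. HA_i`` depends on phi(i) through the quadruple
  ``H-N-CA-HA`` (a constant offset from phi);
* ``HA_i .. N_{i+1}`` depends on psi(i) through ``HA-CA-C-N``.

Constraints are held per unordered *physical* atom pair; duplicated
vertices refer to one physical atom.  Carbonyl oxygens and C-beta
atoms are not part of the order and are placed separately during the
search, but their covalent geometry, hydrogen-bond windows, van der
Waals bounds and restraints are built here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall as _scipy_floyd_warshall

from .conformation import ALLOWED_ATOMS, AtomRef
from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    InfeasibleGeometryError,
    InfeasibleOrderError,
    InvalidGeometryError,
)
from . import geometry as geo
from .geometry import AngleDomain, Interval

__all__ = [
    "OrderedVertex",
    "VertexOrder",
    "CovalentGeometry",
    "VdwTable",
    "DistanceConstraint",
    "ConstraintSet",
    "HelixDefinition",
    "ToleranceConfig",
    "DGPInstance",
    "build_atom_order",
    "validate_sequence",
    "atom_roster",
    "covalent_constraints",
    "vdw_bounds",
    "helix_hbond_constraints",
    "torsion_constraints",
    "default_torsion_domains",
    "floyd_warshall_refine",
    "assemble_instance",
    "build_instance",
]

AMINO_ACIDS = set("ACDEFGHIKLMNQRSTVWY")  # proline intentionally absent


def validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ConfigurationError("empty sequence")
    for i, aa in enumerate(seq, start=1):
        if aa == "P":
            raise ConfigurationError(
                f"residue {i}: proline is not supported (its ring constrains phi; "
                "substitute e.g. alanine)"
            )
        if aa not in AMINO_ACIDS:
            raise ConfigurationError(f"residue {i}: unknown amino acid {aa!r}")
    return seq


# ---------------------------------------------------------------------------
# Vertex order
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderedVertex:
    rank: int  # 1-based
    atom: AtomRef
    is_duplicate: bool
    original_rank: int | None = None


class VertexOrder(list):
    """The repetition order: a list of :class:`OrderedVertex`."""

    @property
    def n_residues(self) -> int:
        return (len(self) - 2) // 7

    def first_rank(self, atom: AtomRef) -> int:
        for v in self:
            if v.atom == atom and not v.is_duplicate:
                return v.rank
        raise ConfigurationError(f"atom {atom} not in order")


_BLOCK = ("N", "H", "CA", "N", "HA", "CA", "C")
_BLOCK_DUP = (False, False, False, True, False, True, False)


def build_atom_order(n_residues: int) -> VertexOrder:
    """The repetition order over the backbone atoms of ``n_residues``
    residues: ``7 n + 2`` vertices, each (beyond the third) constrained
    to its three immediate predecessors."""
    if n_residues < 1:
        raise ConfigurationError(f"need at least one residue, got {n_residues}")
    order = VertexOrder()
    first_seen: dict[AtomRef, int] = {}
    rank = 0
    for res in range(1, n_residues + 1):
        for name, dup in zip(_BLOCK, _BLOCK_DUP):
            rank += 1
            atom = AtomRef(res, name)
            orig = first_seen.get(atom)
            order.append(OrderedVertex(rank, atom, dup, orig))
            if orig is None:
                first_seen[atom] = rank
    # terminal re-embedding of CA_n and C_n closes the count at 7n+2
    for name in ("CA", "C"):
        rank += 1
        atom = AtomRef(n_residues, name)
        order.append(OrderedVertex(rank, atom, True, first_seen[atom]))
    return order


# ---------------------------------------------------------------------------
# Covalent geometry and the C-alpha template
# ---------------------------------------------------------------------------

_DEFAULT_BONDS = {
    ("N", "H"): 1.01,
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N+"): 1.329,  # peptide bond to the next residue
    ("C", "O"): 1.231,
    ("CA", "HA"): 1.090,
    ("CA", "CB"): 1.521,
}

_DEFAULT_ANGLES = {  # degrees
    ("C-", "N", "CA"): 121.7,
    ("H", "N", "CA"): 118.2,
    ("C-", "N", "H"): 120.1,  # planar amide nitrogen closes 360
    ("N", "CA", "C"): 111.2,
    ("N", "CA", "HA"): 108.0,
    ("C", "CA", "HA"): 109.0,
    ("N", "CA", "CB"): 110.5,
    ("C", "CA", "CB"): 110.1,
    ("CA", "C", "N+"): 116.2,
    ("CA", "C", "O"): 120.8,
    ("O", "C", "N+"): 123.0,  # planar carbonyl carbon closes 360
}


@dataclass(frozen=True)
class CovalentGeometry:
    """Bond-length and bond-angle tables plus the peptide torsion
    setting per bond.

    Tables use atom names, with ``C-``/``N+`` marking the preceding or
    following residue.  ``cis_peptides`` lists residues *i* whose
    peptide bond (i-1, i) is cis (omega = 0) instead of trans.
    """

    bonds: dict = field(default_factory=lambda: dict(_DEFAULT_BONDS))
    angles: dict = field(default_factory=lambda: dict(_DEFAULT_ANGLES))
    cis_peptides: frozenset = frozenset()

    def __post_init__(self):
        for pair, length in self.bonds.items():
            if not (0.8 < length < 2.0):
                raise ConfigurationError(f"bond {pair}: length {length} outside (0.8, 2.0)")
        for triple, deg in self.angles.items():
            if not (90.0 < deg < 135.0):
                raise ConfigurationError(f"angle {triple}: {deg} outside (90, 135) degrees")

    def bond(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.bonds else (b, a)
        try:
            return self.bonds[key]
        except KeyError:
            raise ConfigurationError(f"no bond length for pair {a}-{b}") from None

    def angle(self, a: str, b: str, c: str) -> float:
        """Bond angle in radians for the triple ``a-b-c``."""
        key = (a, b, c) if (a, b, c) in self.angles else (c, b, a)
        try:
            return math.radians(self.angles[key])
        except KeyError:
            raise ConfigurationError(f"no bond angle for triple {a}-{b}-{c}") from None

    def omega(self, residue: int) -> float:
        """Peptide torsion (radians) of the bond between residues
        ``residue - 1`` and ``residue``."""
        return 0.0 if residue in self.cis_peptides else math.pi

    def distance_13(self, a: str, b: str, c: str) -> float:
        """1-3 distance across the angle ``a-b-c`` by the law of
        cosines."""
        ab = self._bond_flex(a, b)
        bc = self._bond_flex(b, c)
        alpha = self.angle(a, b, c)
        return math.sqrt(ab * ab + bc * bc - 2.0 * ab * bc * math.cos(alpha))

    def _bond_flex(self, a: str, b: str) -> float:
        """Bond lookup tolerating the C-/N+ markers."""
        names = {a, b}
        if "C-" in names:
            other = (names - {"C-"}).pop()
            return self.bond("C", "N+") if other == "N" else self.bond("C", other)
        if "N+" in names:
            other = (names - {"N+"}).pop()
            return self.bond("C", "N+") if other == "C" else self.bond("N", other)
        return self.bond(a, b)


@dataclass(frozen=True)
class CAlphaTemplate:
    """Consistent local geometry around a C-alpha: positions of N, C,
    HA and CB in a canonical frame with CA at the origin, realizing the
    table angles.  HA and CB sit on opposite sides of the N-CA-C plane
    with the L-configuration (positive CORN torsion C, N, CB, HA)."""

    ca: np.ndarray
    n: np.ndarray
    c: np.ndarray
    ha: np.ndarray
    cb: np.ndarray

    @classmethod
    def from_geometry(cls, geom: CovalentGeometry) -> "CAlphaTemplate":
        ca = np.zeros(3)
        n = np.array([geom.bond("N", "CA"), 0.0, 0.0])
        ang = geom.angle("N", "CA", "C")
        dcac = geom.bond("CA", "C")
        c = np.array([dcac * math.cos(ang), dcac * math.sin(ang), 0.0])
        ha_pts = geo.trilaterate(
            ca, n, c,
            geom.bond("CA", "HA"),
            geom.distance_13("N", "CA", "HA"),
            geom.distance_13("C", "CA", "HA"),
        )
        cb_pts = geo.trilaterate(
            ca, n, c,
            geom.bond("CA", "CB"),
            geom.distance_13("N", "CA", "CB"),
            geom.distance_13("C", "CA", "CB"),
        )
        if len(ha_pts) != 2 or len(cb_pts) != 2:
            raise InvalidGeometryError("C-alpha template angles are not realizable")
        # HA and CB on opposite sides; pick the L-form assignment
        for ha, cb in ((ha_pts[0], cb_pts[1]), (ha_pts[1], cb_pts[0])):
            if geo.dihedral_angle(c, n, cb, ha) > 0.0:
                return cls(ca, n, c, ha, cb)
        raise InvalidGeometryError("could not realize an L-form C-alpha template")

    def distance(self, a: str, b: str) -> float:
        pts = {"CA": self.ca, "N": self.n, "C": self.c, "HA": self.ha, "CB": self.cb}
        return float(np.linalg.norm(pts[a] - pts[b]))

    @property
    def improper_ha(self) -> float:
        """Torsion (N, C, CA, HA) used to decorate a backbone with HA."""
        return geo.dihedral_angle(self.n, self.c, self.ca, self.ha)

    @property
    def improper_cb(self) -> float:
        return geo.dihedral_angle(self.n, self.c, self.ca, self.cb)


def torsion_offsets(geom: CovalentGeometry) -> dict[str, float]:
    """Constant offsets between the classic phi/psi torsions and the
    hydrogen-bearing quadruples of the vertex order.

    Measured on a small ideal fragment built from the covalent table:
    ``H-N-CA-HA = phi + off_h_ha``, ``HA-CA-C-N+ = psi + off_ha_n``,
    ``H-N-CA-C = phi + off_h_c``.
    """
    tmpl = CAlphaTemplate.from_geometry(geom)
    phi = math.radians(-65.0)
    psi = math.radians(-40.0)
    c0 = np.zeros(3)
    n1 = np.array([geom.bond("C", "N+"), 0.0, 0.0])
    ang = geom.angle("C-", "N", "CA")
    dnca = geom.bond("N", "CA")
    ca1 = n1 + np.array([-dnca * math.cos(ang), dnca * math.sin(ang), 0.0])
    c1 = geo.place_from_internal(c0, n1, ca1, geom.bond("CA", "C"), geom.angle("N", "CA", "C"), phi)
    h1 = geo.place_from_internal(ca1, c0, n1, geom.bond("N", "H"), geom.angle("C-", "N", "H"), math.pi)
    ha1 = geo.place_from_internal(n1, c1, ca1, geom.bond("CA", "HA"), geom.angle("C", "CA", "HA"), tmpl.improper_ha)
    n2 = geo.place_from_internal(n1, ca1, c1, geom.bond("C", "N+"), geom.angle("CA", "C", "N+"), psi)
    return {
        "off_h_ha": geo.wrap_angle(geo.dihedral_angle(h1, n1, ca1, ha1) - phi),
        "off_h_c": geo.wrap_angle(geo.dihedral_angle(h1, n1, ca1, c1) - phi),
        "off_ha_n": geo.wrap_angle(geo.dihedral_angle(ha1, ca1, c1, n2) - psi),
    }


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceConstraint:
    a: AtomRef
    b: AtomRef
    lower: float
    upper: float
    source: str

    def __post_init__(self):
        if self.lower < 0 or self.lower > self.upper:
            raise InvalidGeometryError(
                f"invalid bounds [{self.lower}, {self.upper}] for {self.a}-{self.b}"
            )

    @property
    def is_exact(self) -> bool:
        return self.lower == self.upper


class ConstraintSet:
    """Constraints per unordered physical atom pair, with
    intersection-merge semantics (the lower bounds take the max, the
    upper bounds the min)."""

    def __init__(self):
        self._by_pair: dict[frozenset, DistanceConstraint] = {}

    def __len__(self):
        return len(self._by_pair)

    def __iter__(self):
        return iter(self._by_pair.values())

    def key(self, a: AtomRef, b: AtomRef) -> frozenset:
        return frozenset((AtomRef(*a), AtomRef(*b)))

    def add(self, c: DistanceConstraint) -> None:
        k = self.key(c.a, c.b)
        old = self._by_pair.get(k)
        if old is None:
            self._by_pair[k] = c
            return
        lower = max(old.lower, c.lower)
        upper = min(old.upper, c.upper)
        if lower > upper + 1e-9:
            raise InvalidGeometryError(
                f"contradictory bounds for {c.a}-{c.b}: "
                f"[{old.lower:.3f}, {old.upper:.3f}] vs [{c.lower:.3f}, {c.upper:.3f}]"
            )
        src = old.source if old.source == c.source else f"{old.source}+{c.source}"
        self._by_pair[k] = DistanceConstraint(old.a, old.b, lower, min(old.upper, c.upper), src)

    def get(self, a: AtomRef, b: AtomRef) -> DistanceConstraint | None:
        return self._by_pair.get(self.key(a, b))

    def involving(self, atom: AtomRef):
        atom = AtomRef(*atom)
        for k, c in self._by_pair.items():
            if atom in k:
                yield c

    def partner(self, c: DistanceConstraint, atom: AtomRef) -> AtomRef:
        return c.b if c.a == AtomRef(*atom) else c.a


@dataclass(frozen=True)
class VdwTable:
    """Van der Waals radii by element and the scale factor applied to
    the sum of radii when deriving steric lower bounds."""

    radii: dict = field(default_factory=lambda: {"O": 1.4, "H": 1.0, "C": 1.7, "N": 1.5})
    sigma: float = 0.85

    def __post_init__(self):
        if not (0.0 <= self.sigma <= 1.0):
            raise ConfigurationError(f"sigma_vdw={self.sigma} outside [0, 1]")
        if any(r <= 0 for r in self.radii.values()):
            raise ConfigurationError("van der Waals radii must be positive")

    def radius(self, atom_name: str) -> float:
        return self.radii[atom_name[0]]

    def lower_bound(self, a: AtomRef, b: AtomRef) -> float:
        return self.sigma * (self.radius(a.atom_name) + self.radius(b.atom_name))


@dataclass(frozen=True)
class HelixDefinition:
    """Alpha-helix ranges plus the hydrogen-bond acceptance windows.

    ``theta``/``theta_p``/``theta_pp`` are the hydrogen-bond
    directionality windows (degrees): the angle between the C->O and
    O->H directions, between N->H and H->O, and the angle at H in
    O..H-N, respectively.
    """

    ranges: tuple[tuple[int, int], ...] = ()
    hbond: Interval = Interval(1.9, 3.0)
    energy_threshold: float = -0.5
    q1: float = 0.42
    q2: float = 0.2
    f: float = 332.0
    theta: tuple[float, float] = (0.0, 70.0)
    theta_p: tuple[float, float] = (0.0, 90.0)
    theta_pp: tuple[float, float] = (110.0, 180.0)

    def __post_init__(self):
        for lo, hi in self.ranges:
            if lo > hi or lo < 1:
                raise ConfigurationError(f"invalid helix range {lo}-{hi}")

    def residues(self) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.ranges:
            out.update(range(lo, hi + 1))
        return out

    def hbond_pairs(self) -> list[tuple[int, int]]:
        """(i-4, i) residue pairs fully inside one helix range."""
        pairs = []
        for lo, hi in self.ranges:
            for i in range(lo + 4, hi + 1):
                pairs.append((i - 4, i))
        return pairs

    def clipped(self, n_residues: int) -> "HelixDefinition":
        for lo, hi in self.ranges:
            if hi > n_residues:
                raise ConfigurationError(f"helix range {lo}-{hi} exceeds {n_residues} residues")
        return self


@dataclass(frozen=True)
class ToleranceConfig:
    """Numerical tolerances and the discretization factor.

    eps_x : position tolerance (angstroms) widening distance windows
    eps_t : angle tolerance (degrees) widening angular windows
    b     : number of samples per discretized interval distance
    sigma_vdw : scale on the sum of van der Waals radii
    eps_dup : accepted drift when re-embedding duplicate vertices (angstroms)
    """

    eps_x: float = 0.2
    eps_t: float = 2.0
    b: int = 4
    sigma_vdw: float = 0.85
    eps_dup: float = 0.1
    include_upper: bool = False

    def __post_init__(self):
        if min(self.eps_x, self.eps_t, self.sigma_vdw, self.eps_dup) < 0 or self.b < 1:
            raise ConfigurationError("tolerances must be non-negative and b >= 1")


# ---------------------------------------------------------------------------
# Roster and builders
# ---------------------------------------------------------------------------

def atom_roster(sequence: str) -> list[AtomRef]:
    """All physical atoms of the model: backbone N, H, CA, HA, C per
    residue, carbonyl O for every peptide bond and CB for non-glycine
    residues."""
    seq = validate_sequence(sequence)
    n = len(seq)
    atoms: list[AtomRef] = []
    for i, aa in enumerate(seq, start=1):
        for name in ("N", "H", "CA", "HA", "C"):
            atoms.append(AtomRef(i, name))
        if i < n:
            atoms.append(AtomRef(i, "O"))
        if aa != "G":
            atoms.append(AtomRef(i, "CB"))
    return atoms


def _bond_list(sequence: str) -> list[tuple[AtomRef, AtomRef]]:
    seq = validate_sequence(sequence)
    n = len(seq)
    bonds = []
    for i, aa in enumerate(seq, start=1):
        bonds += [
            (AtomRef(i, "N"), AtomRef(i, "H")),
            (AtomRef(i, "N"), AtomRef(i, "CA")),
            (AtomRef(i, "CA"), AtomRef(i, "HA")),
            (AtomRef(i, "CA"), AtomRef(i, "C")),
        ]
        if aa != "G":
            bonds.append((AtomRef(i, "CA"), AtomRef(i, "CB")))
        if i < n:
            bonds += [
                (AtomRef(i, "C"), AtomRef(i, "O")),
                (AtomRef(i, "C"), AtomRef(i + 1, "N")),
            ]
    return bonds


def covalent_constraints(
    sequence: str,
    geom: CovalentGeometry | None = None,
) -> ConstraintSet:
    """Exact constraints from covalent structure: bond lengths, 1-3
    distances across bond angles, and 1-4 distances fixed by the
    peptide torsion omega (trans by default, cis where configured).

    Every ``{v, v-1}`` and ``{v, v-2}`` edge of the vertex order is
    covered by these constraints.
    """
    geom = geom or CovalentGeometry()
    seq = validate_sequence(sequence)
    n = len(seq)
    tmpl = CAlphaTemplate.from_geometry(geom)
    cs = ConstraintSet()

    def exact(a: AtomRef, b: AtomRef, d: float, source: str):
        cs.add(DistanceConstraint(a, b, d, d, source))

    for a, b in _bond_list(seq):
        names = {a.atom_name, b.atom_name}
        if a.residue_index != b.residue_index:
            exact(a, b, geom.bond("C", "N+"), "covalent")
        else:
            exact(a, b, geom.bond(*sorted(names, key=ALLOWED_ATOMS.index)), "covalent")

    for i, aa in enumerate(seq, start=1):
        A = lambda name, j=i: AtomRef(j, name)
        exact(A("H"), A("CA"), geom.distance_13("H", "N", "CA"), "angle")
        exact(A("N"), A("C"), geom.distance_13("N", "CA", "C"), "angle")
        exact(A("N"), A("HA"), tmpl.distance("N", "HA"), "angle")
        exact(A("C"), A("HA"), tmpl.distance("C", "HA"), "angle")
        if aa != "G":
            exact(A("N"), A("CB"), tmpl.distance("N", "CB"), "angle")
            exact(A("C"), A("CB"), tmpl.distance("C", "CB"), "angle")
            exact(A("HA"), A("CB"), tmpl.distance("HA", "CB"), "angle")
        if i < n:
            exact(A("CA"), A("O"), geom.distance_13("CA", "C", "O"), "angle")
            exact(A("O"), A("N", i + 1), geom.distance_13("O", "C", "N+"), "angle")
            exact(A("CA"), A("N", i + 1), geom.distance_13("CA", "C", "N+"), "angle")
            exact(A("C"), A("CA", i + 1), geom.distance_13("C-", "N", "CA"), "angle")
            exact(A("C"), A("H", i + 1), geom.distance_13("C-", "N", "H"), "angle")

    # 1-4 distances fixed by the peptide torsion omega
    for i in range(2, n + 1):
        omega = geom.omega(i)
        A = lambda name, j: AtomRef(j, name)
        d_cn = geom.bond("C", "N+")
        quads = [
            # (i, j, k, l), torsion about the C(i-1)-N(i) bond
            (("CA", i - 1), ("C", i - 1), ("N", i), ("CA", i), omega),
            (("CA", i - 1), ("C", i - 1), ("N", i), ("H", i), geo.wrap_angle(omega - math.pi)),
            (("O", i - 1), ("C", i - 1), ("N", i), ("CA", i), geo.wrap_angle(omega - math.pi)),
            (("O", i - 1), ("C", i - 1), ("N", i), ("H", i), omega),
        ]
        for (ni, ri), (nj, rj), (nk, rk), (nl, rl), xi in quads:
            ai, aj, ak, al = A(ni, ri), A(nj, rj), A(nk, rk), A(nl, rl)
            d_ij = cs.get(ai, aj).lower
            d_jk = d_cn
            d_kl = cs.get(ak, al).lower
            d_ik = cs.get(ai, ak).lower
            d_lj = cs.get(al, aj).lower
            d_il = geo.torsion_distance(xi, d_ij, d_jk, d_kl, d_ik, d_lj)
            exact(ai, al, d_il, "torsion")
    return cs


def default_torsion_domains(
    sequence: str,
    helix: HelixDefinition,
) -> tuple[dict[int, AngleDomain], dict[int, AngleDomain]]:
    """Per-residue phi and psi domains: a tight alpha-helical window
    inside helix ranges, broad Ramachandran-style windows elsewhere.
    The broad windows are a modeling default, not experimental data."""
    seq = validate_sequence(sequence)
    helical = helix.residues()
    phi: dict[int, AngleDomain] = {}
    psi: dict[int, AngleDomain] = {}
    for i in range(1, len(seq) + 1):
        if i in helical:
            phi[i] = AngleDomain.from_degrees((-90.0, -30.0))
            psi[i] = AngleDomain.from_degrees((-77.0, -17.0))
        else:
            phi[i] = AngleDomain.from_degrees((-179.999, -30.0))
            psi[i] = AngleDomain.from_degrees(
                (-179.999, -170.0), (-90.0, -10.0), (50.0, 180.0)
            )
    return phi, psi


def torsion_constraints(
    sequence: str,
    phi_domains: dict[int, AngleDomain],
    psi_domains: dict[int, AngleDomain],
    geom: CovalentGeometry | None = None,
) -> ConstraintSet:
    """Interval constraints on 1-4 atom pairs derived from phi/psi
    domains.

    For each residue this emits bounds on the classic quadruple pairs
    (``C(i-1)..C(i)`` for phi, ``N(i)..N(i+1)`` for psi) and on the
    hydrogen-bearing order edges (``H(i)..HA(i)``, ``HA(i)..N(i+1)``)
    whose torsions are the same angles up to a constant offset.
    """
    geom = geom or CovalentGeometry()
    seq = validate_sequence(sequence)
    n = len(seq)
    cov = covalent_constraints(seq, geom)
    offs = torsion_offsets(geom)
    cs = ConstraintSet()

    def bounds(dom, ai, aj, ak, al, source):
        d_ij = cov.get(ai, aj).lower
        d_jk = cov.get(aj, ak).lower
        d_kl = cov.get(ak, al).lower
        d_ik = cov.get(ai, ak).lower
        d_lj = cov.get(al, aj).lower
        iv, _signs = geo.torsion_domain_to_bounds(dom, d_ij, d_jk, d_kl, d_ik, d_lj)
        cs.add(DistanceConstraint(ai, al, iv.lower, iv.upper, source))

    for i in range(1, n + 1):
        A = lambda name, j=i: AtomRef(j, name)
        phi = phi_domains.get(i, AngleDomain.full())
        psi = psi_domains.get(i, AngleDomain.full())
        # phi: the H..HA order edge always exists; C(i-1)..C(i) needs i >= 2
        bounds(phi.shifted(offs["off_h_ha"]), A("H"), A("N"), A("CA"), A("HA"), "torsion")
        if i >= 2:
            bounds(phi, A("C", i - 1), A("N"), A("CA"), A("C"), "torsion")
        if i < n:
            bounds(psi.shifted(offs["off_ha_n"]), A("HA"), A("CA"), A("C"), A("N", i + 1), "torsion")
            bounds(psi, A("N"), A("CA"), A("C"), A("N", i + 1), "torsion")
    return cs


def helix_hbond_constraints(helix: HelixDefinition) -> ConstraintSet:
    """One ``O(i-4)..H(i)`` interval constraint per (i-4, i) residue
    pair fully inside a helix range."""
    cs = ConstraintSet()
    for j, i in helix.hbond_pairs():
        cs.add(
            DistanceConstraint(
                AtomRef(j, "O"), AtomRef(i, "H"),
                helix.hbond.lower, helix.hbond.upper, "hbond",
            )
        )
    return cs


def vdw_bounds(
    sequence: str,
    existing: ConstraintSet,
    table: VdwTable | None = None,
) -> ConstraintSet:
    """Steric lower bounds for otherwise-unconstrained non-bonded
    pairs: atoms three or more covalent bonds apart with no explicit
    constraint get a lower bound of ``sigma * (r_i + r_j)``.

    Pairs that already carry a constraint (covalent, torsion-derived,
    hydrogen bond, restraint) are left untouched: an explicitly stated
    window — notably the 1.9 A hydrogen-bond floor, which deliberately
    undercuts the van der Waals sum — wins over the generic steric
    floor.
    """
    table = table or VdwTable()
    roster = atom_roster(sequence)
    g = nx.Graph(_bond_list(sequence))
    sep = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
    cs = ConstraintSet()
    for a, b in itertools.combinations(roster, 2):
        if b in sep.get(a, {}):
            continue  # closer than three bonds
        if existing.get(a, b) is not None:
            continue
        cs.add(DistanceConstraint(a, b, table.lower_bound(a, b), math.inf, "vdw"))
    return cs


def restraint_constraints(records, sequence: str) -> ConstraintSet:
    """Turn parsed restraint records into nmr-sourced constraints,
    validating atoms against the roster."""
    roster = set(atom_roster(sequence))
    cs = ConstraintSet()
    for r in records:
        a = AtomRef(r.res1, r.atom1).validate()
        b = AtomRef(r.res2, r.atom2).validate()
        for atom in (a, b):
            if atom not in roster:
                raise ConfigurationError(f"restraint references absent atom {atom}")
        cs.add(DistanceConstraint(a, b, r.lower, r.upper, r.tag or "nmr"))
    return cs


# ---------------------------------------------------------------------------
# Bound smoothing
# ---------------------------------------------------------------------------

def floyd_warshall_refine(
    constraints: ConstraintSet,
    atoms: list[AtomRef],
) -> tuple[np.ndarray, dict[AtomRef, int]]:
    """Refine upper bounds by all-pairs shortest paths on the graph
    weighted with the available upper bounds (triangle-inequality bound
    smoothing).  Returns the refined matrix and the atom index map;
    entries with no connecting path stay infinite."""
    index = {AtomRef(*a): i for i, a in enumerate(atoms)}
    m = len(atoms)
    w = np.full((m, m), np.inf)
    np.fill_diagonal(w, 0.0)
    for c in constraints:
        if not math.isfinite(c.upper):
            continue
        i, j = index.get(c.a), index.get(c.b)
        if i is None or j is None:
            continue
        w[i, j] = min(w[i, j], c.upper)
        w[j, i] = w[i, j]
    refined = _scipy_floyd_warshall(w, directed=False)
    return refined, index


# ---------------------------------------------------------------------------
# Instance assembly
# ---------------------------------------------------------------------------

@dataclass
class VertexEmbeddingData:
    """Everything needed to branch at one vertex: the two exact
    predecessor distances, the (possibly discretized) third distances
    with the torsion magnitude each realizes, and the inter-predecessor
    distances fixing theta2 / omega3."""

    d1: float  # d(v, v-1)
    d2: float  # d(v, v-2)
    samples: list[tuple[float, float]]  # (d(v, v-3) sample, |omega3|)
    theta2: float
    duplicate_of: int | None = None
    interval: Interval | None = None  # original {v, v-3} interval, if any


@dataclass
class ProteinContext:
    """Protein-specific schedule attached to a DGP instance."""

    sequence: str
    order: VertexOrder
    geom: CovalentGeometry
    tmpl: CAlphaTemplate
    helix: HelixDefinition
    tol: ToleranceConfig
    constraints: ConstraintSet
    phi_domains: dict[int, AngleDomain]
    psi_domains: dict[int, AngleDomain]
    u_plus: np.ndarray
    atom_index: dict[AtomRef, int]
    canonical_rank: dict[AtomRef, int]
    exact_partners: dict[AtomRef, list[tuple[AtomRef, float]]]


@dataclass
class DGPInstance:
    """A discretizable instance: per-vertex embedding data plus pruning
    bounds.  ``prune_edges[v]`` lists ``(u, lower, upper)`` bounds
    checked when vertex ``v`` is embedded (``u < v``), excluding the
    three discretization edges."""

    n_vertices: int
    b: int
    vertices: dict[int, VertexEmbeddingData]  # ranks 4..n
    init: tuple[float, float, float]  # d21, d32, theta3
    prune_edges: dict[int, list[tuple[int, float, float]]]
    protein: ProteinContext | None = None

    @property
    def edge_partition(self) -> dict[str, int]:
        """Counts of exact (E_D'), discretized (E_D'') and pruning
        (E_P) edges, plus the 2-branching/b-branching level counts used
        in the tree-size bound."""
        two_b = sum(
            1 for v in self.vertices.values()
            if v.duplicate_of is None and len(v.samples) == 1
        )
        b_b = sum(
            1 for v in self.vertices.values()
            if v.duplicate_of is None and len(v.samples) > 1
        )
        n_ep = sum(len(edges) for edges in self.prune_edges.values())
        return {"l": two_b, "k": b_b, "E_P": n_ep}


def _exact_distance(cs: ConstraintSet, a: AtomRef, b: AtomRef, what: str) -> float:
    if a == b:
        return 0.0
    c = cs.get(a, b)
    if c is None or not c.is_exact:
        raise InfeasibleOrderError(
            f"{what}: no exact distance between {a} and {b}"
        )
    return c.lower


def assemble_instance(
    order: VertexOrder,
    constraints: ConstraintSet,
    tol: ToleranceConfig,
    protein: ProteinContext | None = None,
) -> DGPInstance:
    """Partition the constraints along the vertex order into exact
    discretization distances, b-sampled interval distances and pruning
    bounds, and precompute the per-vertex branching geometry."""
    n = len(order)
    atom_of = {v.rank: v.atom for v in order}
    canonical: dict[AtomRef, int] = {}
    for v in order:
        canonical.setdefault(v.atom, v.rank)

    d21 = _exact_distance(constraints, atom_of[2], atom_of[1], "initial triangle")
    d32 = _exact_distance(constraints, atom_of[3], atom_of[2], "initial triangle")
    d31 = _exact_distance(constraints, atom_of[3], atom_of[1], "initial triangle")
    theta3 = math.acos(
        min(1.0, max(-1.0, (d21 * d21 + d32 * d32 - d31 * d31) / (2.0 * d21 * d32)))
    )

    vertices: dict[int, VertexEmbeddingData] = {}
    for v in order:
        if v.rank <= 3:
            continue
        k = v.rank
        a_k = v.atom
        a_1, a_2, a_3 = atom_of[k - 1], atom_of[k - 2], atom_of[k - 3]
        where = f"vertex {k} ({a_k.residue_index} {a_k.atom_name})"
        d1 = _exact_distance(constraints, a_k, a_1, where)
        d2 = _exact_distance(constraints, a_k, a_2, where)
        d12 = _exact_distance(constraints, a_1, a_2, where)
        d13 = _exact_distance(constraints, a_1, a_3, where)
        d23 = _exact_distance(constraints, a_2, a_3, where)
        theta2 = math.acos(
            min(1.0, max(-1.0, (d1 * d1 + d12 * d12 - d2 * d2) / (2.0 * d1 * d12)))
        )
        interval = None
        if a_k == a_3:
            dset = [0.0]
        else:
            c3 = constraints.get(a_k, a_3)
            if c3 is None:
                raise InfeasibleOrderError(
                    f"{where}: no {{v, v-3}} distance to {a_3}; the order is not discretizable"
                )
            if c3.is_exact:
                dset = [c3.lower]
            else:
                interval = Interval(c3.lower, c3.upper)
                dset = geo.discretize_interval(interval, tol.b, tol.include_upper)
        samples: list[tuple[float, float]] = []
        if v.is_duplicate:
            dup = VertexEmbeddingData(d1, d2, [], theta2, duplicate_of=v.original_rank)
            vertices[k] = dup
            continue
        for d3 in dset:
            # |omega3| realizing this d(v, v-3); quadruple (v-3, v-2, v-1, v)
            try:
                cosx = geo.torsion_cosine(d3, d23, d12, d1, d13, d2)
            except (InfeasibleGeometryError, DegenerateGeometryError):
                continue
            if abs(cosx) > 1.0 + 1e-9:
                continue  # this sample is not realizable
            samples.append((d3, math.acos(min(1.0, max(-1.0, cosx)))))
        vertices[k] = VertexEmbeddingData(d1, d2, samples, theta2, interval=interval)

    # pruning bounds, mapped onto canonical (first-occurrence) ranks
    prune_edges: dict[int, list[tuple[int, float, float]]] = {v.rank: [] for v in order}
    order_pairs = set()
    for v in order:
        if v.rank > 3:
            for back in (1, 2, 3):
                order_pairs.add(frozenset((v.atom, atom_of[v.rank - back])))
        if v.rank == 2:
            order_pairs.add(frozenset((v.atom, atom_of[1])))
        if v.rank == 3:
            order_pairs.add(frozenset((v.atom, atom_of[1])))
            order_pairs.add(frozenset((v.atom, atom_of[2])))
    for c in constraints:
        ra, rb = canonical.get(c.a), canonical.get(c.b)
        if ra is None or rb is None:
            continue  # involves O/CB: checked when those atoms are placed
        if frozenset((c.a, c.b)) in order_pairs:
            continue  # discretization edge, satisfied by construction
        lo, hi = sorted((ra, rb))
        prune_edges[hi].append((lo, c.lower, c.upper))

    return DGPInstance(
        n_vertices=n,
        b=tol.b,
        vertices=vertices,
        init=(d21, d32, theta3),
        prune_edges=prune_edges,
        protein=protein,
    )


def build_instance(
    sequence: str,
    helix: HelixDefinition | None = None,
    restraints=(),
    tol: ToleranceConfig | None = None,
    geom: CovalentGeometry | None = None,
    phi_domains: dict[int, AngleDomain] | None = None,
    psi_domains: dict[int, AngleDomain] | None = None,
    extra_constraints: ConstraintSet | None = None,
) -> DGPInstance:
    """Full pipeline: sequence + helix + restraints -> DGP instance."""
    seq = validate_sequence(sequence)
    helix = (helix or HelixDefinition()).clipped(len(seq))
    tol = tol or ToleranceConfig()
    geom = geom or CovalentGeometry()
    order = build_atom_order(len(seq))
    dom_phi, dom_psi = default_torsion_domains(seq, helix)
    if phi_domains:
        dom_phi.update(phi_domains)
    if psi_domains:
        dom_psi.update(psi_domains)

    cs = ConstraintSet()
    for c in covalent_constraints(seq, geom):
        cs.add(c)
    for c in torsion_constraints(seq, dom_phi, dom_psi, geom):
        cs.add(c)
    for c in helix_hbond_constraints(helix):
        cs.add(c)
    for c in restraint_constraints(restraints, seq):
        cs.add(c)
    if extra_constraints is not None:
        for c in extra_constraints:
            cs.add(c)
    for c in vdw_bounds(seq, cs, VdwTable(sigma=tol.sigma_vdw)):
        cs.add(c)

    roster = atom_roster(seq)
    u_plus, atom_index = floyd_warshall_refine(cs, roster)
    exact_partners: dict[AtomRef, list[tuple[AtomRef, float]]] = {a: [] for a in roster}
    for c in cs:
        if c.is_exact:
            exact_partners[c.a].append((c.b, c.lower))
            exact_partners[c.b].append((c.a, c.lower))

    canonical: dict[AtomRef, int] = {}
    order_ = order
    for v in order_:
        canonical.setdefault(v.atom, v.rank)

    ctx = ProteinContext(
        sequence=seq,
        order=order_,
        geom=geom,
        tmpl=CAlphaTemplate.from_geometry(geom),
        helix=helix,
        tol=tol,
        constraints=cs,
        phi_domains=dom_phi,
        psi_domains=dom_psi,
        u_plus=u_plus,
        atom_index=atom_index,
        canonical_rank=canonical,
        exact_partners=exact_partners,
    )
    return assemble_instance(order_, cs, tol, protein=ctx)
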