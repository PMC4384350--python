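"""Coordinate mathematics for branch-and-prune embedding.

This module contains every geometric primitive the search needs:

* the homogeneous recursion matrices ``B_k`` used to embed vertex *k*
  in the frame accumulated from its three predecessors, and the
  equivalent sphere-intersection (trilateration) oracle;
* uniform discretization of interval distances;
* the torsion-angle / fourth-distance relation for a quadruple of
  points with known intermediate distances, and its envelope over a
  union of angular intervals;
* closed-form placement of the carbonyl oxygen (in-plane, three
  spheres + coplanarity) and of the C-beta (four spheres, unique
  because the anchors are non-coplanar);
* signed dihedral angles, internal-coordinate placement and optimal
  rigid-superposition RMSD.

All distances are in angstroms and all angles in radians unless a
function name says otherwise.  Points are plain ``(3,)`` float arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    InfeasibleGeometryError,
    InvalidGeometryError,
)

__all__ = [
    "Interval",
    "AngleDomain",
    "BranchGeometry",
    "wrap_angle",
    "initial_placement",
    "branch_matrix",
    "place_vertex",
    "frame_from_positions",
    "trilaterate",
    "discretize_interval",
    "torsion_distance",
    "torsion_cosine",
    "torsion_domain_to_bounds",
    "dihedral_angle",
    "bond_angle",
    "place_from_internal",
    "place_peptide_oxygen",
    "place_cbeta",
    "kabsch_rmsd",
]

_E4 = np.array([0.0, 0.0, 0.0, 1.0])


def wrap_angle(angle: float) -> float:
    """Wrap an angle into the canonical torsion range ``(-pi, pi]``."""
    a = math.fmod(angle, 2.0 * math.pi)
    if a <= -math.pi:
        a += 2.0 * math.pi
    elif a > math.pi:
        a -= 2.0 * math.pi
    return a


@dataclass(frozen=True)
class Interval:
    """A closed interval ``[lower, upper]`` (angstroms, or radians when
    used for angles)."""

    lower: float
    upper: float

    def __post_init__(self):
        if not (math.isfinite(self.lower)):
            raise InvalidGeometryError("interval lower bound must be finite")
        if self.lower > self.upper:
            raise InvalidGeometryError(
                f"interval lower bound {self.lower} exceeds upper {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def is_exact(self) -> bool:
        return self.lower == self.upper

    def contains(self, value: float, tol: float = 0.0) -> bool:
        return self.lower - tol <= value <= self.upper + tol


@dataclass(frozen=True)
class AngleDomain:
    """A union of disjoint closed angular intervals and singletons.

    Members live in ``(-pi, pi]``.  Singletons are represented as
    zero-width intervals.  Containment is *signed*: an angle belongs to
    the domain only if its signed value lies in some member; mirrored
    magnitudes do not count.
    """

    intervals: tuple[Interval, ...] = field(default_factory=tuple)

    def __post_init__(self):
        ivs = tuple(sorted(self.intervals, key=lambda iv: iv.lower))
        for iv in ivs:
            if iv.lower <= -math.pi or iv.upper > math.pi:
                raise InvalidGeometryError(
                    f"angle interval [{iv.lower}, {iv.upper}] outside (-pi, pi]"
                )
        for a, b in zip(ivs, ivs[1:]):
            if b.lower < a.upper:
                raise InvalidGeometryError("angle intervals must be disjoint")
        object.__setattr__(self, "intervals", ivs)

    @classmethod
    def from_degrees(cls, *bounds: tuple[float, float]) -> "AngleDomain":
        return cls(tuple(Interval(math.radians(lo), math.radians(hi)) for lo, hi in bounds))

    @classmethod
    def full(cls) -> "AngleDomain":
        return cls((Interval(-math.pi + 1e-12, math.pi),))

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    def contains(self, angle: float, tol: float = 0.0) -> bool:
        """Signed containment, each member widened by ``tol``.

        Widening is performed on the circle, so a member touching the
        branch cut at pi also accepts angles just above ``-pi``.
        """
        a = wrap_angle(angle)
        for iv in self.intervals:
            if iv.contains(a, tol):
                return True
            # wrap-around near the +/- pi cut
            if iv.contains(a + 2.0 * math.pi, tol) or iv.contains(a - 2.0 * math.pi, tol):
                return True
        return False

    def shifted(self, offset: float) -> "AngleDomain":
        """Shift every member by ``offset`` on the circle, splitting
        members that cross the ``+/-pi`` cut and merging overlaps."""
        pieces: list[tuple[float, float]] = []
        for iv in self.intervals:
            lo = wrap_angle(iv.lower + offset)
            hi = wrap_angle(iv.upper + offset)
            if iv.width >= 2.0 * math.pi - 1e-12:
                return AngleDomain.full()
            if lo <= hi:
                pieces.append((lo, hi))
            else:  # crossed the cut
                pieces.append((lo, math.pi))
                pieces.append((-math.pi + 1e-12, hi))
        pieces.sort()
        merged: list[list[float]] = []
        for lo, hi in pieces:
            if merged and lo <= merged[-1][1] + 1e-12:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        return AngleDomain(tuple(Interval(lo, hi) for lo, hi in merged))

    def signs(self) -> set[int]:
        """The set of signs (+1, -1, 0) that angles in the domain can take."""
        out: set[int] = set()
        for iv in self.intervals:
            if iv.lower < 0:
                out.add(-1)
            if iv.upper > 0:
                out.add(+1)
            if iv.lower <= 0 <= iv.upper:
                out.add(0)
        return out


@dataclass(frozen=True)
class BranchGeometry:
    """Parameters of a single recursion matrix ``B_k``.

    theta2
        Angle formed by atoms ``{k, k-1, k-2}`` (at ``k-1``), radians.
    omega3
        Torsion over ``{k, k-1, k-2, k-3}``, radians.  Note the realized
        signed dihedral of the embedded quadruple is ``-omega3`` (the
        matrix convention); branch enumeration therefore sweeps both
        signs of ``omega3``.
    sigma
        Branch sign in ``{+1, -1}`` as it appears in the matrix.
    d_set
        Distances ``(d_{k,k-1}, d_{k,k-2}, d_{k,k-3})``.
    """

    theta2: float
    omega3: float
    sigma: int
    d_set: tuple[float, float, float]

    def __post_init__(self):
        if not (0.0 < self.theta2 < math.pi):
            raise InvalidGeometryError(f"theta2={self.theta2} outside (0, pi)")
        if self.sigma not in (1, -1):
            raise InvalidGeometryError(f"sigma must be +1 or -1, got {self.sigma}")
        if min(self.d_set) < 0:
            raise InvalidGeometryError("distances must be non-negative")


# ---------------------------------------------------------------------------
# Recursion-matrix embedding
# ---------------------------------------------------------------------------

def initial_placement(d21: float, d32: float, theta3: float):
    """Place the first three vertices and return their accumulated frame.

    The first vertex sits at the origin, the second at ``(-d21, 0, 0)``
    and the third in the ``z = 0`` plane so that the angle at vertex 2
    equals ``theta3``.

    Returns ``(x1, x2, x3, Q3)`` where ``Q3`` is the 4x4 accumulated
    transform after the initial triangle.
    """
    if d21 <= 0 or d32 <= 0:
        raise InvalidGeometryError("initial distances must be positive")
    if not (0.0 < theta3 < math.pi):
        raise InvalidGeometryError(f"theta3={theta3} is degenerate")
    c, s = math.cos(theta3), math.sin(theta3)
    b2 = np.eye(4)
    b2[0, 0] = -1.0
    b2[2, 2] = -1.0
    b2[0, 3] = -d21
    # note the (2,4) entry: d32*sin(theta3), which is what the distance
    # contract ||x3 - x2|| = d32 requires
    b3 = np.eye(4)
    b3[0, 0] = -c
    b3[0, 1] = -s
    b3[0, 3] = -d32 * c
    b3[1, 0] = s
    b3[1, 1] = -c
    b3[1, 3] = d32 * s
    q3 = b2 @ b3
    x1 = np.zeros(3)
    x2 = (b2 @ _E4)[:3]
    x3 = (q3 @ _E4)[:3]
    return x1, x2, x3, q3


def branch_matrix(g: BranchGeometry) -> np.ndarray:
    """The recursion matrix ``B_k(d, sigma)``.

    The fourth column is
    ``(-d*cos(theta2), sigma*d*sin(theta2)*cos(omega3),
    sigma*d*sin(theta2)*sin(omega3), 1)`` with ``d = d_{k,k-1}``.
    """
    c2, s2 = math.cos(g.theta2), math.sin(g.theta2)
    c3, s3 = math.cos(g.omega3), math.sin(g.omega3)
    d = g.d_set[0]
    sg = float(g.sigma)
    return np.array(
        [
            [-c2, -sg * s2, 0.0, -d * c2],
            [sg * s2 * c3, -c2 * c3, -s3, sg * d * s2 * c3],
            [sg * s2 * s3, -c2 * s3, c3, sg * d * s2 * s3],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def place_vertex(q_prev: np.ndarray, b_k: np.ndarray):
    """Apply one recursion step: position is the fourth column of
    ``Q_prev @ B_k``; the full ``Q_k`` is also returned.

    Callers on the hot path may compute the position alone as
    ``q_prev @ b_k[:, 3]`` and defer the full product until the vertex
    survives pruning; this helper returns both for convenience.
    """
    q_k = q_prev @ b_k
    return q_k[:3, 3].copy(), q_k


def frame_from_positions(xk, xk1, xk2) -> np.ndarray:
    """Rebuild the accumulated transform ``Q_k`` from the positions of
    vertex ``k`` and its two predecessors.

    The rotation block of ``Q_k`` is exactly the orthonormal frame with
    first axis along ``x_k - x_{k-1}``, second axis the component of
    ``x_{k-2} - x_{k-1}`` orthogonal to it, third axis their cross
    product; the translation column is ``x_k``.  Used to re-anchor the
    recursion at duplicate vertices.
    """
    xk, xk1, xk2 = (np.asarray(p, dtype=float) for p in (xk, xk1, xk2))
    u = xk - xk1
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise DegenerateGeometryError("coincident vertices in frame reconstruction")
    u = u / nu
    w = xk2 - xk1
    w = w - (w @ u) * u
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise DegenerateGeometryError("collinear vertices in frame reconstruction")
    w = w / nw
    q = np.eye(4)
    q[:3, 0] = u
    q[:3, 1] = w
    q[:3, 2] = np.cross(u, w)
    q[:3, 3] = xk
    return q


# ---------------------------------------------------------------------------
# Sphere intersection
# ---------------------------------------------------------------------------

def trilaterate(p1, p2, p3, d1: float, d2: float, d3: float, eps: float = 1e-9):
    """Intersect three spheres; return 0, 1 or 2 points.

    Points are returned with the point on the positive side of the
    ``p1 p2 p3`` plane normal (``(p2-p1) x (p3-p1)``) first.  The two
    points (when present) are mirror images through that plane.

    Raises :class:`DegenerateGeometryError` for collinear centers; an
    empty intersection is a normal outcome, not an error.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    if min(d1, d2, d3) < 0:
        raise InvalidGeometryError("sphere radii must be non-negative")
    ex = p2 - p1
    d = np.linalg.norm(ex)
    if d < 1e-12:
        raise DegenerateGeometryError("coincident sphere centers")
    ex = ex / d
    v3 = p3 - p1
    i = ex @ v3
    ey = v3 - i * ex
    j = np.linalg.norm(ey)
    if j < 1e-12:
        raise DegenerateGeometryError("collinear sphere centers")
    ey = ey / j
    ez = np.cross(ex, ey)
    x = (d1 * d1 - d2 * d2 + d * d) / (2.0 * d)
    y = (d1 * d1 - d3 * d3 + i * i + j * j - 2.0 * i * x) / (2.0 * j)
    z2 = d1 * d1 - x * x - y * y
    if z2 < -eps * max(1.0, d1 * d1):
        return []
    z = math.sqrt(max(z2, 0.0))
    base = p1 + x * ex + y * ey
    if z < 1e-12:
        return [base]
    return [base + z * ez, base - z * ez]


# ---------------------------------------------------------------------------
# Interval discretization
# ---------------------------------------------------------------------------

def discretize_interval(iv: Interval, b: int, include_upper: bool = False) -> list[float]:
    """Uniformly sample ``b`` values from a distance interval.

    The sampling is ``l + (t-1)(u-l)/b`` for ``t = 1..b``: the lower
    endpoint is always included and the upper endpoint is not (unless
    ``include_upper`` redistributes the samples over the closed
    interval).  Degenerate intervals collapse to a single value.
    """
    if b < 1:
        raise InvalidGeometryError(f"discretization factor b={b} must be >= 1")
    l, u = iv.lower, iv.upper
    if u == l or b == 1:
        return [l]
    if include_upper:
        return [l + t * (u - l) / (b - 1) for t in range(b)]
    return [l + t * (u - l) / b for t in range(b)]


# ---------------------------------------------------------------------------
# Torsion <-> distance
# ---------------------------------------------------------------------------

def _torsion_coeffs(d_ij, d_jk, d_kl, d_ik, d_lj):
    b = 0.5 * (d_lj * d_lj + d_jk * d_jk - d_kl * d_kl) / (d_lj * d_jk)
    c = 0.5 * (d_ij * d_ij + d_jk * d_jk - d_ik * d_ik) / (d_ij * d_jk)
    if abs(b) > 1.0 + 1e-12 or abs(c) > 1.0 + 1e-12:
        raise InfeasibleGeometryError(
            f"distances not realizable: |b|={abs(b):.6f}, |c|={abs(c):.6f}"
        )
    b = min(1.0, max(-1.0, b))
    c = min(1.0, max(-1.0, c))
    e = 1.0 - b * b
    f = 1.0 - c * c
    return b, c, e, f


def torsion_distance(xi: float, d_ij, d_jk, d_kl, d_ik, d_lj) -> float:
    """Distance ``d_il`` across a quadruple ``(i, j, k, l)`` as a
    function of the torsion ``xi`` about the ``j-k`` axis, given the
    five intermediate distances.

    The function depends on ``xi`` only through ``cos(xi)`` and is
    non-decreasing in ``|xi|`` on ``[0, pi]``.
    """
    b, c, e, f = _torsion_coeffs(d_ij, d_jk, d_kl, d_ik, d_lj)
    val = (
        d_ij * d_ij
        + d_lj * d_lj
        - 2.0 * (math.cos(xi) * math.sqrt(e * f) + b * c) * d_ij * d_lj
    )
    return math.sqrt(max(val, 0.0))


def torsion_cosine(d_il: float, d_ij, d_jk, d_kl, d_ik, d_lj) -> float:
    """Invert :func:`torsion_distance`: the cosine of the torsion that
    realizes a given fourth distance ``d_il``.

    Returns a value that may fall slightly outside ``[-1, 1]`` for an
    unrealizable ``d_il``; callers decide whether to clamp or reject.
    """
    b, c, e, f = _torsion_coeffs(d_ij, d_jk, d_kl, d_ik, d_lj)
    ef = math.sqrt(e * f)
    if ef < 1e-12:
        raise DegenerateGeometryError("degenerate quadruple: collinear triple")
    return ((d_ij * d_ij + d_lj * d_lj - d_il * d_il) / (2.0 * d_ij * d_lj) - b * c) / ef


def torsion_domain_to_bounds(dom: AngleDomain, d_ij, d_jk, d_kl, d_ik, d_lj):
    """Envelope of the fourth distance over a torsion domain.

    Since the distance depends on the torsion only through its cosine,
    extrema occur at member endpoints or at 0 when a member straddles
    it.  Returns ``(Interval, sign set)`` where the sign set records
    which torsion signs occur in the domain (the additional pruning
    criterion used alongside the interval).
    """
    if dom.is_empty:
        raise InvalidGeometryError("empty torsion domain")
    lo = math.inf
    hi = -math.inf
    for iv in dom.intervals:
        candidates = [iv.lower, iv.upper]
        if iv.lower <= 0.0 <= iv.upper:
            candidates.append(0.0)
        for xi in candidates:
            d = torsion_distance(xi, d_ij, d_jk, d_kl, d_ik, d_lj)
            lo = min(lo, d)
            hi = max(hi, d)
    return Interval(lo, hi), dom.signs()


# ---------------------------------------------------------------------------
# Dihedrals and internal-coordinate placement
# ---------------------------------------------------------------------------

def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion over four points in ``(-pi, pi]`` (IUPAC
    convention: cis = 0, trans = pi; mirroring flips the sign)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb2 < 1e-12:
        raise DegenerateGeometryError("collinear triple in dihedral computation")
    m1 = np.cross(n1, b2 / nb2)
    angle = math.atan2(m1 @ n2, n1 @ n2)
    return math.pi if angle == -math.pi else angle


def bond_angle(p1, p2, p3) -> float:
    """Angle at ``p2`` formed by ``p1-p2-p3``, radians."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p1 - p2
    v = p3 - p2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("coincident points in angle computation")
    return math.acos(min(1.0, max(-1.0, (u @ v) / (nu * nv))))


def place_from_internal(p1, p2, p3, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a fourth point from internal coordinates: ``bond`` from
    ``p3``, ``angle`` at ``p3`` against ``p2`` and signed ``torsion``
    over ``(p1, p2, p3, new)``."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    bc = p3 - p2
    nbc = np.linalg.norm(bc)
    if nbc < 1e-12:
        raise DegenerateGeometryError("coincident points in internal placement")
    bc = bc / nbc
    n = np.cross(p2 - p1, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise DegenerateGeometryError("collinear reference points in internal placement")
    n = n / nn
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.cos(torsion) * math.sin(angle),
            -bond * math.sin(torsion) * math.sin(angle),
        ]
    )
    return p3 + d[0] * bc + d[1] * m + d[2] * n


# ---------------------------------------------------------------------------
# Separately placed atoms: carbonyl O and C-beta
# ---------------------------------------------------------------------------

_COND_LIMIT = 1e10


def place_peptide_oxygen(vC, vN, vH, dk1: float, dk2: float, dk3: float, plane_normal=None) -> np.ndarray:
    """Place a carbonyl oxygen inside its peptide plane.

    The oxygen is the point at distances ``dk1``, ``dk2``, ``dk3`` from
    the carbonyl carbon, the next amide nitrogen and the next amide
    hydrogen, constrained to the plane of those three atoms.  Two of
    the sphere equations are differenced into radical planes, giving a
    3x3 linear system together with the coplanarity row.

    The supplied distances encode the peptide torsion (trans places the
    oxygen anti to the amide hydrogen); the solve itself is
    orientation-free.
    """
    v1, v2, v3 = (np.asarray(p, dtype=float) for p in (vC, vN, vH))
    if plane_normal is None:
        plane_normal = np.cross(v2 - v1, v3 - v1)
    n = np.asarray(plane_normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise DegenerateGeometryError("collinear peptide-plane atoms")
    n = n / nn
    a = np.empty((3, 3))
    rhs = np.empty(3)
    a[0] = 2.0 * (v2 - v1)
    rhs[0] = dk1 * dk1 - dk2 * dk2 - v1 @ v1 + v2 @ v2
    a[1] = 2.0 * (v3 - v1)
    rhs[1] = dk1 * dk1 - dk3 * dk3 - v1 @ v1 + v3 @ v3
    a[2] = n
    rhs[2] = n @ v1
    if np.linalg.cond(a) > _COND_LIMIT:
        raise DegenerateGeometryError("singular peptide-plane system")
    return np.linalg.solve(a, rhs)


def place_cbeta(vCA, vHA, vN, vC, dk1: float, dk2: float, dk3: float, dk4: float) -> np.ndarray:
    """Place a C-beta from four exact distances to ``CA``, ``HA``,
    ``N`` and ``C``.

    Because the four anchors are not coplanar the three radical-plane
    equations have a unique solution; a near-coplanar anchor set raises
    :class:`DegenerateGeometryError`.
    """
    v1, v2, v3, v4 = (np.asarray(p, dtype=float) for p in (vCA, vHA, vN, vC))
    vol = abs(np.cross(v2 - v1, v3 - v1) @ (v4 - v1))
    if vol < 1e-6:
        raise DegenerateGeometryError("coplanar anchors in C-beta placement")
    a = np.empty((3, 3))
    rhs = np.empty(3)
    for row, (v, dk) in enumerate(((v2, dk2), (v3, dk3), (v4, dk4))):
        a[row] = 2.0 * (v - v1)
        rhs[row] = dk1 * dk1 - dk * dk - v1 @ v1 + v @ v
    if np.linalg.cond(a) > _COND_LIMIT:
        raise DegenerateGeometryError("singular C-beta system")
    return np.linalg.solve(a, rhs)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal least-squares RMSD between two equal-size coordinate
    sets under optimal rigid (proper-rotation) superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise InvalidGeometryError(
            f"coordinate sets must match and contain >= 3 atoms, got {a.shape} vs {b.shape}"
        )
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(ac, bc)
    diff = ac - rot.apply(bc)
    return math.sqrt(float(np.mean(np.sum(diff * diff, axis=1))))
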