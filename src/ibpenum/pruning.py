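"""Pruning devices: pure feasibility predicates over partial embeddings.

Each device inspects a proposed atom position (or a completed local
motif) and either accepts it or rejects it with a human-readable
reason.  The devices are:

DDF
    direct distance feasibility — every known bound between the new
    atom and the already-embedded atoms must hold within the position
    tolerance;
TAF
    torsion-angle feasibility — a completed phi/psi quadruple must fall
    inside its permitted (signed) angular domain;
DSP
    shortest-path feasibility — the triangle-inequality consequence of
    the smoothed upper bounds (an embedded pair far apart cannot both
    be close to the new atom);
CHI
    amino-acid chirality via the CORN rule, restated as a signed
    torsion test on C, N, C-beta, H-alpha;
helix
    the alpha-helix device — hydrogen-bond distance window, DSSP-style
    electrostatic energy threshold and three directionality angles for
    every (i-4, i) pair inside a declared helix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError
from .geometry import AngleDomain, bond_angle, dihedral_angle
from .errors import DegenerateGeometryError

__all__ = [
    "PruneResult",
    "ddf",
    "taf",
    "dsp",
    "chi",
    "hbond_energy",
    "helix_check",
]


@dataclass(frozen=True)
class PruneResult:
    accepted: bool
    device: str
    reason: str = ""

    def __post_init__(self):
        if not self.accepted and not self.reason:
            raise ValueError("a rejection must carry a reason")

    def __bool__(self) -> bool:
        return self.accepted


_ACCEPT_DDF = PruneResult(True, "ddf")
_ACCEPT_TAF = PruneResult(True, "taf")
_ACCEPT_DSP = PruneResult(True, "dsp")
_ACCEPT_CHI = PruneResult(True, "chi")
_ACCEPT_HLX = PruneResult(True, "helix")


def ddf(x_k, partners, eps_x: float) -> PruneResult:
    """Direct distance feasibility for a newly embedded atom.

    ``partners`` yields ``(label, position, lower, upper)`` for every
    embedded atom holding a bound to the new one.  Bounds are widened
    by ``eps_x`` on both sides, inclusively.
    """
    for label, pos, lo, hi in partners:
        d = math.dist(x_k, pos)
        if d < lo - eps_x - 1e-12:
            return PruneResult(
                False, "ddf", f"{label}: d={d:.3f} below lower bound {lo:.3f}"
            )
        if d > hi + eps_x + 1e-12:
            return PruneResult(
                False, "ddf", f"{label}: d={d:.3f} above upper bound {hi:.3f}"
            )
    return _ACCEPT_DDF


def taf(p1, p2, p3, p4, dom: AngleDomain, eps_t: float, label: str = "torsion") -> PruneResult:
    """Torsion-angle feasibility: the signed dihedral of the quadruple
    must lie in the domain widened by ``eps_t`` (radians).  The sign is
    respected — a mirrored magnitude in a mirrored window does not
    pass."""
    try:
        xi = dihedral_angle(p1, p2, p3, p4)
    except DegenerateGeometryError as exc:
        return PruneResult(False, "taf", f"{label}: degenerate quadruple ({exc})")
    if dom.contains(xi, eps_t):
        return _ACCEPT_TAF
    return PruneResult(
        False, "taf", f"{label}: {math.degrees(xi):.1f} deg outside permitted domain"
    )


def dsp(x_k, anchors, embedded_labels, embedded_coords, u_plus_row) -> PruneResult:
    """Shortest-path feasibility (smoothed-bound device).

    For each anchor ``i`` with exact distance ``d_ik`` to the new atom
    and each embedded atom ``j``, prune when
    ``||x_i - x_j|| - d_ik > u+_{jk}`` (strict), where ``u+`` are the
    Floyd-Warshall refined upper bounds.

    ``anchors`` yields ``(label, position, d_ik)``; ``embedded_coords``
    is an ``(m, 3)`` array aligned with ``embedded_labels`` and
    ``u_plus_row`` (refined bounds between each embedded atom and the
    new one).
    """
    if len(embedded_coords) == 0:
        return _ACCEPT_DSP
    coords = np.asarray(embedded_coords)
    for label, pos, d_ik in anchors:
        gap = np.linalg.norm(coords - np.asarray(pos), axis=1) - d_ik
        bad = gap > u_plus_row
        if bad.any():
            j = int(np.argmax(bad))
            return PruneResult(
                False,
                "dsp",
                f"pair ({label}, {embedded_labels[j]}): separation {gap[j] + d_ik:.3f} "
                f"exceeds d_ik + u+ = {d_ik + u_plus_row[j]:.3f}",
            )
    return _ACCEPT_DSP


def chi(vC, vN, vCB, vHA, form: str = "L", glycine: bool = False) -> PruneResult:
    """Chirality via the CORN rule: for the L-form the torsion
    (C, N, C-beta, H-alpha) must be positive; the D-form swaps N and
    C-beta.  Glycine has no chiral center and passes trivially."""
    if glycine:
        return _ACCEPT_CHI
    if form == "L":
        xi = dihedral_angle(vC, vN, vCB, vHA)
    elif form == "D":
        xi = dihedral_angle(vC, vCB, vN, vHA)
    else:
        raise InvalidGeometryError(f"unknown chiral form {form!r}")
    if xi > 0.0:
        return _ACCEPT_CHI
    return PruneResult(
        False, "chi", f"{form}-form CORN torsion {math.degrees(xi):.1f} deg not positive"
    )


def hbond_energy(
    d_on: float, d_ch: float, d_oh: float, d_cn: float,
    q1: float = 0.42, q2: float = 0.2, f: float = 332.0,
) -> float:
    """DSSP-style electrostatic hydrogen-bond energy
    ``q1*q2*(1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN)*f`` for a backbone
    C=O ... H-N pair (kcal/mol-scale units of the DSSP convention)."""
    if min(d_on, d_ch, d_oh, d_cn) <= 0.0:
        raise InvalidGeometryError("hydrogen-bond distances must be positive")
    return q1 * q2 * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn) * f


def helix_check(
    vO, vC, vN, vH,
    helix,
    eps_x: float = 0.0,
    eps_t: float = 0.0,
    pair: tuple[int, int] | None = None,
) -> PruneResult:
    """The alpha-helix device for one (i-4, i) residue pair.

    ``vO``/``vC`` belong to residue i-4, ``vN``/``vH`` to residue i.
    Accepts iff (i) the O..H distance falls in the hydrogen-bond
    window, (ii) the DSSP-style energy is below the threshold, and
    (iv) the three directionality angles fall in their windows (theta:
    C->O against O->H; theta': N->H against H->O; theta'': the angle at
    H in O..H-N).  Criterion (iii) — phi/psi feasibility — is the TAF
    device's job and is not re-checked here.

    ``helix`` is a :class:`~ibpenum.instance.HelixDefinition`;
    tolerances widen the windows additively and inclusively.
    """
    tag = f" {pair[0]}-{pair[1]}" if pair else ""
    d_oh = math.dist(vO, vH)
    if not (helix.hbond.lower - eps_x <= d_oh <= helix.hbond.upper + eps_x):
        return PruneResult(
            False, "helix",
            f"O..H{tag}: {d_oh:.3f} outside [{helix.hbond.lower}, {helix.hbond.upper}]",
        )
    energy = hbond_energy(
        math.dist(vO, vN), math.dist(vC, vH), d_oh, math.dist(vC, vN),
        helix.q1, helix.q2, helix.f,
    )
    if energy >= helix.energy_threshold:
        return PruneResult(
            False, "helix",
            f"H-bond energy{tag}: {energy:.3f} not below {helix.energy_threshold}",
        )
    vO = np.asarray(vO, float)
    vC = np.asarray(vC, float)
    vN = np.asarray(vN, float)
    vH = np.asarray(vH, float)
    theta = _vec_angle(vO - vC, vH - vO)
    theta_p = _vec_angle(vH - vN, vO - vH)
    theta_pp = bond_angle(vO, vH, vN)
    for name, value, (lo, hi) in (
        ("theta", theta, helix.theta),
        ("theta'", theta_p, helix.theta_p),
        ("theta''", theta_pp, helix.theta_pp),
    ):
        deg = math.degrees(value)
        if not (lo - eps_t <= deg <= hi + eps_t):
            return PruneResult(
                False, "helix", f"{name}{tag}: {deg:.1f} deg outside [{lo}, {hi}]"
            )
    return _ACCEPT_HLX


def _vec_angle(u, v) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise InvalidGeometryError("zero-length vector in angle computation")
    return math.acos(min(1.0, max(-1.0, float(u @ v) / (nu * nv))))
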