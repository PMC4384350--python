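"""Depth-first branch-and-prune search over a discretizable instance.

The engine embeds vertices one by one along the repetition order.  At
each new vertex it generates at most two candidate positions per
sampled third-predecessor distance (the two signs of the torsion over
the last four vertices), using the cached recursion matrices; every
candidate is screened by the pruning devices before the search
descends.  Duplicate vertices are re-embedded onto their original
coordinates (with a drift check) and the accumulated frame is
re-anchored from positions.

For protein instances the engine also places the carbonyl oxygen of
residue i-1 as soon as the amide hydrogen of residue i is embedded,
and the C-beta of residue i as soon as its carbonyl carbon is
embedded, so that the chirality and alpha-helix devices (and any
restraints touching O or CB) can prune as early as possible.

Solutions are filtered on storage: a finished conformation is kept
only if its backbone RMSD to the previously stored one exceeds the
configured threshold, and the search stops once the store is full.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import pruning
from .conformation import AtomRef, Conformation
from .errors import DegenerateGeometryError, IBPError
from . import geometry as geo
from .geometry import BranchGeometry
from .instance import DGPInstance, ProteinContext

__all__ = [
    "SearchConfig",
    "SolutionStore",
    "branch_candidates",
    "reembed_duplicate",
    "ibp_search",
    "finalize_conformation",
    "tree_size_bound",
]

_EMBED_TOL = 1e-6  # candidate must satisfy its three predecessor distances


def tree_size_bound(l: int, k: int, b: int) -> int:
    """Worst-case width bound of the search tree: ``3 + 2^l * b^k``
    where ``l`` counts 2-branching levels and ``k`` counts b-branching
    levels."""
    if l < 0 or k < 0 or b < 1:
        raise ValueError("need l, k >= 0 and b >= 1")
    return 3 + (2 ** l) * (b ** k)


@dataclass
class SearchConfig:
    """Run-time options of the tree search."""

    max_saved: int = 10000
    rmsd_threshold: float = 1.5  # angstroms, between successively stored solutions
    compare: str = "last"  # or "all": filter against every stored conformation
    use_dsp: bool = True


@dataclass
class SolutionStore:
    """Filtered solutions plus search statistics."""

    max_saved: int = 10000
    rmsd_threshold: float = 1.5
    compare: str = "last"
    conformations: list = field(default_factory=list)
    generated: int = 0
    saved: int = 0
    prune_counts: dict = field(default_factory=dict)
    nodes_per_level: dict = field(default_factory=dict)
    b_matrix_count: int = 0
    leaf_failures: int = 0

    @property
    def full(self) -> bool:
        return self.saved >= self.max_saved

    @staticmethod
    def _rmsd(a, b) -> float:
        if isinstance(a, Conformation):
            return a.backbone_rmsd(b)
        return geo.kabsch_rmsd(np.asarray(a), np.asarray(b))

    def accept(self, conf) -> bool:
        """Count a finished conformation and store it if it differs by
        more than the RMSD threshold from the reference set (the
        previously stored conformation, or all of them)."""
        self.generated += 1
        if self.full:
            return False
        thr = self.rmsd_threshold + 1e-9  # floor keeps exact repeats out at threshold 0
        if not self.conformations:
            keep = True
        elif self.compare == "all":
            keep = all(self._rmsd(conf, c) > thr for c in self.conformations)
        else:
            keep = self._rmsd(conf, self.conformations[-1]) > thr
        if keep:
            self.conformations.append(conf)
            self.saved += 1
        return keep

    def count_prune(self, device: str) -> None:
        self.prune_counts[device] = self.prune_counts.get(device, 0) + 1


# ---------------------------------------------------------------------------
# Branching
# ---------------------------------------------------------------------------

class _BMatrixCache:
    """Per-level cache of recursion matrices.

    ``B_k`` depends only on distances, never on positions, so every
    node at the same tree level shares the same candidate matrices;
    the total number of constructions is bounded by ``2 |order| b``.
    """

    def __init__(self):
        self._cache: dict[tuple, np.ndarray] = {}
        self.constructions = 0

    def get(self, rank: int, sample_idx: int, sign: int, vdata) -> np.ndarray:
        key = (rank, sample_idx, sign)
        b = self._cache.get(key)
        if b is None:
            d3, om_abs = vdata.samples[sample_idx]
            # the realized signed torsion of the quadruple is -omega3
            g = BranchGeometry(
                theta2=vdata.theta2,
                omega3=-sign * om_abs,
                sigma=+1,
                d_set=(vdata.d1, vdata.d2, d3),
            )
            b = geo.branch_matrix(g)
            self._cache[key] = b
            self.constructions += 1
        return b


def branch_candidates(k: int, q_prev: np.ndarray, vdata, cache: _BMatrixCache):
    """Ordered candidate positions for vertex ``k``: positive torsion
    branch before negative, sampled distances ascending within each
    branch.  Degenerate torsions (0 or pi) yield a single branch.

    Yields ``(position, b_matrix, sample_d3)``.
    """
    for sign in (+1, -1):
        for idx, (d3, om_abs) in enumerate(vdata.samples):
            if sign < 0 and abs(math.sin(om_abs)) < 1e-9:
                continue  # the two branches coincide
            b = cache.get(k, idx, sign, vdata)
            pos = (q_prev @ b[:, 3])[:3]
            yield pos, b, d3


def reembed_duplicate(original, p1, p2, p3, d1, d2, d3, eps_dup: float):
    """Re-embed a duplicate vertex.

    Candidate positions are the sphere-intersection roots for the
    distances to the three immediate predecessors (a zero distance
    collapses the intersection onto that predecessor); the candidate
    nearest the original coordinates is returned together with its
    drift.  A drift beyond ``eps_dup`` means the node must be pruned.

    Returns ``(position or None, drift)``.
    """
    zero = [(p, d) for p, d in ((p1, d1), (p2, d2), (p3, d3)) if d == 0.0]
    if zero:
        cands = [np.asarray(zero[0][0], float)]
    else:
        try:
            cands = geo.trilaterate(p1, p2, p3, d1, d2, d3, eps=1e-6)
        except DegenerateGeometryError:
            cands = []
    if not cands:
        return None, math.inf
    dists = [math.dist(c, original) for c in cands]
    i = int(np.argmin(dists))
    if dists[i] > eps_dup:
        return None, dists[i]
    return cands[i], dists[i]


# ---------------------------------------------------------------------------
# Protein step schedule
# ---------------------------------------------------------------------------

class _ProteinPlan:
    """Per-rank schedule of placements and device checks, precomputed
    from the instance's protein context."""

    def __init__(self, instance: DGPInstance, config: SearchConfig):
        ctx = instance.protein
        self.ctx = ctx
        self.config = config
        n_res = len(ctx.sequence)
        canon = ctx.canonical_rank
        atom_of = {v.rank: v.atom for v in ctx.order}

        # availability step of every physical atom
        step: dict[AtomRef, float] = {}
        for atom, rank in canon.items():
            step[atom] = float(rank)
        for i in range(2, n_res + 1):
            step[AtomRef(i - 1, "O")] = canon[AtomRef(i, "H")] + 0.3
        for i, aa in enumerate(ctx.sequence, start=1):
            if aa != "G":
                step[AtomRef(i, "CB")] = canon[AtomRef(i, "C")] + 0.3
        self.step = step

        # discretization-edge pairs are guaranteed by construction
        order_pairs: set[frozenset] = set()
        for v in ctx.order:
            for back in (1, 2, 3):
                if v.rank - back >= 1:
                    order_pairs.add(frozenset((v.atom, atom_of[v.rank - back])))

        # distance checks per trigger atom
        self.ddf_partners: dict[AtomRef, list] = {a: [] for a in step}
        for c in ctx.constraints:
            if frozenset((c.a, c.b)) in order_pairs:
                continue
            first, second = (
                (c.a, c.b) if step[c.a] < step[c.b] else (c.b, c.a)
            )
            self.ddf_partners[second].append((first, c.lower, c.upper))

        # per-rank actions
        self.place_o: dict[int, int] = {}  # rank -> residue whose O is placed
        self.helix_pairs: dict[int, list] = {}
        self.place_cb: dict[int, int] = {}
        self.taf_checks: dict[int, list] = {}
        for i in range(2, n_res + 1):
            self.place_o[canon[AtomRef(i, "H")]] = i - 1
        hb_by_i: dict[int, list] = {}
        for j, i in ctx.helix.hbond_pairs():
            hb_by_i.setdefault(i, []).append((j, i))
        for i, pairs in hb_by_i.items():
            self.helix_pairs[canon[AtomRef(i, "H")]] = pairs
        for i, aa in enumerate(ctx.sequence, start=1):
            if aa != "G":
                self.place_cb[canon[AtomRef(i, "C")]] = i
        from .instance import torsion_offsets

        offs = torsion_offsets(ctx.geom)
        for i in range(1, n_res + 1):
            phi = ctx.phi_domains[i]
            psi = ctx.psi_domains[i]
            # early check on the hydrogen-bearing phi quadruple at HA(i)
            self.taf_checks.setdefault(canon[AtomRef(i, "HA")], []).append(
                (
                    (AtomRef(i, "H"), AtomRef(i, "N"), AtomRef(i, "CA"), AtomRef(i, "HA")),
                    phi.shifted(offs["off_h_ha"]),
                    f"phi-proxy {i}",
                )
            )
            if i >= 2:
                self.taf_checks.setdefault(canon[AtomRef(i, "C")], []).append(
                    (
                        (AtomRef(i - 1, "C"), AtomRef(i, "N"), AtomRef(i, "CA"), AtomRef(i, "C")),
                        phi,
                        f"phi {i}",
                    )
                )
            if i < n_res:
                self.taf_checks.setdefault(canon[AtomRef(i + 1, "N")], []).append(
                    (
                        (AtomRef(i, "N"), AtomRef(i, "CA"), AtomRef(i, "C"), AtomRef(i + 1, "N")),
                        psi,
                        f"psi {i}",
                    )
                )

        # C-beta placement distances per residue (exact, from constraints)
        self.cb_distances: dict[int, tuple] = {}
        for i, aa in enumerate(ctx.sequence, start=1):
            if aa == "G":
                continue
            cb = AtomRef(i, "CB")
            self.cb_distances[i] = tuple(
                ctx.constraints.get(cb, AtomRef(i, name)).lower
                for name in ("CA", "HA", "N", "C")
            )
        # O placement distances per residue (to its C, next N, next H)
        self.o_distances: dict[int, tuple] = {}
        for i in range(1, n_res):
            o = AtomRef(i, "O")
            self.o_distances[i] = (
                ctx.constraints.get(o, AtomRef(i, "C")).lower,
                ctx.constraints.get(o, AtomRef(i + 1, "N")).lower,
                ctx.constraints.get(o, AtomRef(i + 1, "H")).lower,
            )


# ---------------------------------------------------------------------------
# Search state
# ---------------------------------------------------------------------------

class _State:
    def __init__(self, instance: DGPInstance):
        n = instance.n_vertices
        self.positions = np.zeros((n + 1, 3))
        self.q = [None] * (n + 1)
        ctx = instance.protein
        self.atom_pos: dict[AtomRef, np.ndarray] = {}
        self.added_at: dict[int, list[AtomRef]] = {}
        if ctx is not None:
            m = len(ctx.atom_index)
            self.emb_coords = np.zeros((m, 3))
            self.emb_atoms: list[AtomRef] = []
            self.emb_index: list[int] = []

    def add_atom(self, ctx, rank: int, atom: AtomRef, pos) -> None:
        self.atom_pos[atom] = pos
        self.added_at.setdefault(rank, []).append(atom)
        i = len(self.emb_atoms)
        self.emb_coords[i] = pos
        self.emb_atoms.append(atom)
        self.emb_index.append(ctx.atom_index[atom])

    def undo_rank(self, rank: int) -> None:
        for atom in self.added_at.pop(rank, ()):  # LIFO order not required
            del self.atom_pos[atom]
            self.emb_atoms.pop()
            self.emb_index.pop()


# ---------------------------------------------------------------------------
# Device application at one embedding step
# ---------------------------------------------------------------------------

def _check_new_atom(state: _State, plan: _ProteinPlan, store, atom, pos, rank) -> bool:
    """DDF then DSP for one newly available atom; records the atom on
    success, counts the prune on failure."""
    ctx = plan.ctx
    eps_x = ctx.tol.eps_x
    partners = []
    for other, lo, hi in plan.ddf_partners.get(atom, ()):
        p = state.atom_pos.get(other)
        if p is not None:
            partners.append((f"{other.residue_index}{other.atom_name}", p, lo, hi))
    res = pruning.ddf(pos, partners, eps_x)
    if not res:
        store.count_prune("ddf")
        return False
    if plan.config.use_dsp and state.emb_atoms:
        k_idx = ctx.atom_index[atom]
        anchors = []
        for other, d in ctx.exact_partners[atom]:
            p = state.atom_pos.get(other)
            if p is not None:
                anchors.append((f"{other.residue_index}{other.atom_name}", p, d))
        m = len(state.emb_atoms)
        u_row = ctx.u_plus[state.emb_index, k_idx] + eps_x
        res = pruning.dsp(
            pos,
            anchors,
            [f"{a.residue_index}{a.atom_name}" for a in state.emb_atoms],
            state.emb_coords[:m],
            u_row,
        )
        if not res:
            store.count_prune("dsp")
            return False
    state.add_atom(ctx, rank, atom, pos)
    return True


def _protein_step(state: _State, plan: _ProteinPlan, store, instance, rank: int, pos) -> bool:
    """Run every placement and device scheduled at this rank.  Returns
    False (after undoing partial additions) when any device rejects."""
    ctx = plan.ctx
    eps_t = math.radians(ctx.tol.eps_t)
    vertex = ctx.order[rank - 1]
    ok = True
    if not vertex.is_duplicate:
        ok = _check_new_atom(state, plan, store, vertex.atom, pos, rank)
    if ok and rank in plan.place_cb:
        i = plan.place_cb[rank]
        d = plan.cb_distances[i]
        try:
            cb = geo.place_cbeta(
                state.atom_pos[AtomRef(i, "CA")],
                state.atom_pos[AtomRef(i, "HA")],
                state.atom_pos[AtomRef(i, "N")],
                state.atom_pos[AtomRef(i, "C")],
                *d,
            )
        except DegenerateGeometryError:
            store.count_prune("degenerate")
            ok = False
        if ok:
            res = pruning.chi(
                state.atom_pos[AtomRef(i, "C")],
                state.atom_pos[AtomRef(i, "N")],
                cb,
                state.atom_pos[AtomRef(i, "HA")],
            )
            if not res:
                store.count_prune("chi")
                ok = False
        if ok:
            ok = _check_new_atom(state, plan, store, AtomRef(i, "CB"), cb, rank)
    if ok and rank in plan.taf_checks:
        for quad, dom, label in plan.taf_checks[rank]:
            pts = [state.atom_pos[a] for a in quad]
            res = pruning.taf(*pts, dom, eps_t, label=label)
            if not res:
                store.count_prune("taf")
                ok = False
                break
    if ok and rank in plan.place_o:
        i = plan.place_o[rank]
        d = plan.o_distances[i]
        try:
            o = geo.place_peptide_oxygen(
                state.atom_pos[AtomRef(i, "C")],
                state.atom_pos[AtomRef(i + 1, "N")],
                state.atom_pos[AtomRef(i + 1, "H")],
                *d,
            )
        except DegenerateGeometryError:
            store.count_prune("degenerate")
            ok = False
        if ok:
            ok = _check_new_atom(state, plan, store, AtomRef(i, "O"), o, rank)
    if ok and rank in plan.helix_pairs:
        for j, i in plan.helix_pairs[rank]:
            vo = state.atom_pos.get(AtomRef(j, "O"))
            if vo is None:
                continue
            res = pruning.helix_check(
                vo,
                state.atom_pos[AtomRef(j, "C")],
                state.atom_pos[AtomRef(i, "N")],
                state.atom_pos[AtomRef(i, "H")],
                ctx.helix,
                eps_x=ctx.tol.eps_x,
                eps_t=ctx.tol.eps_t,
                pair=(j, i),
            )
            if not res:
                store.count_prune("helix")
                ok = False
                break
    if not ok:
        state.undo_rank(rank)
    return ok


def _abstract_step(state: _State, store, instance, rank: int, pos) -> bool:
    eps_x = 0.0
    partners = []
    for u, lo, hi in instance.prune_edges.get(rank, ()):
        partners.append((f"v{u}", state.positions[u], lo, hi))
    res = pruning.ddf(pos, partners, eps_x)
    if not res:
        store.count_prune("ddf")
        return False
    return True


# ---------------------------------------------------------------------------
# The search
# ---------------------------------------------------------------------------

def ibp_search(instance: DGPInstance, config: SearchConfig | None = None) -> SolutionStore:
    """Enumerate all realizations of the instance depth-first.

    Returns the :class:`SolutionStore` with stored conformations,
    generated/saved counters and per-device prune statistics.  The
    search is deterministic: identical inputs yield identical stores.
    """
    config = config or SearchConfig()
    store = SolutionStore(
        max_saved=config.max_saved,
        rmsd_threshold=config.rmsd_threshold,
        compare=config.compare,
    )
    n = instance.n_vertices
    if n < 4:
        raise IBPError("instances must have at least four vertices")
    state = _State(instance)
    plan = _ProteinPlan(instance, config) if instance.protein else None

    d21, d32, theta3 = instance.init
    x1, x2, x3, q3 = geo.initial_placement(d21, d32, theta3)
    state.positions[1], state.positions[2], state.positions[3] = x1, x2, x3
    state.q[3] = q3
    if plan is not None:
        for rank in (1, 2, 3):
            v = instance.protein.order[rank - 1]
            if not v.is_duplicate:
                state.add_atom(instance.protein, rank, v.atom, state.positions[rank])

    cache = _BMatrixCache()

    def candidates_for(k: int):
        vdata = instance.vertices[k]
        if vdata.duplicate_of is not None:
            original = state.positions[vdata.duplicate_of]
            d3 = _dup_d3(instance, k)
            pos, drift = reembed_duplicate(
                original,
                state.positions[k - 1],
                state.positions[k - 2],
                state.positions[k - 3],
                vdata.d1,
                vdata.d2,
                d3,
                instance.protein.tol.eps_dup if instance.protein else 1e-3,
            )
            if pos is None:
                store.count_prune("duplicate-drift")
                return iter(())
            return iter([(pos, None, d3)])
        return branch_candidates(k, state.q[k - 1], vdata, cache)

    iters = {4: candidates_for(4)}
    k = 4
    active = {r: False for r in range(4, n + 1)}
    while k >= 4:
        if active[k]:
            state.undo_rank(k)
            active[k] = False
        nxt = next(iters[k], None)
        if nxt is None:
            k -= 1
            continue
        pos, bmat, d3 = nxt
        vdata = instance.vertices[k]
        # verify the three predecessor distances (embedding contract)
        if bmat is not None and not _embedding_ok(state, k, pos, vdata, d3):
            store.count_prune("embed")
            continue
        state.positions[k] = pos
        if plan is not None:
            ok = _protein_step(state, plan, store, instance, k, pos)
        else:
            ok = _abstract_step(state, store, instance, k, pos)
        if not ok:
            continue
        active[k] = True
        store.nodes_per_level[k] = store.nodes_per_level.get(k, 0) + 1
        if bmat is not None:
            state.q[k] = state.q[k - 1] @ bmat
        else:
            state.q[k] = _safe_frame(state, k)
        if k == n:
            try:
                conf = finalize_conformation(state, instance)
            except IBPError:
                store.leaf_failures += 1
                continue
            store.accept(conf)
            if store.full:
                break
            continue
        k += 1
        iters[k] = candidates_for(k)
    store.b_matrix_count = cache.constructions
    return store


def _dup_d3(instance: DGPInstance, k: int) -> float:
    """Distance from duplicate vertex k to its rank k-3 (0 when they
    are the same physical atom)."""
    ctx = instance.protein
    if ctx is None:
        return 0.0
    a_k = ctx.order[k - 1].atom
    a_3 = ctx.order[k - 4].atom
    if a_k == a_3:
        return 0.0
    return ctx.constraints.get(a_k, a_3).lower


def _embedding_ok(state: _State, k: int, pos, vdata, d3) -> bool:
    return (
        abs(math.dist(pos, state.positions[k - 1]) - vdata.d1) < _EMBED_TOL
        and abs(math.dist(pos, state.positions[k - 2]) - vdata.d2) < _EMBED_TOL
        and abs(math.dist(pos, state.positions[k - 3]) - d3) < _EMBED_TOL
    )


def _safe_frame(state: _State, k: int):
    """Re-anchored frame at a duplicate; ``None`` when the local triple
    is degenerate (only possible at the terminal re-embedding, whose
    frame is never used)."""
    try:
        return geo.frame_from_positions(
            state.positions[k], state.positions[k - 1], state.positions[k - 2]
        )
    except DegenerateGeometryError:
        return None


def finalize_conformation(state: _State, instance: DGPInstance) -> Conformation:
    """Assemble the finished conformation.

    Duplicate vertices collapse onto their first occurrence; the
    separately placed oxygens and C-betas placed during the search are
    included.  For abstract (non-protein) instances the vertex
    coordinate array is returned instead.
    """
    ctx = instance.protein
    if ctx is None:
        return state.positions[1 : instance.n_vertices + 1].copy()
    atoms = list(ctx.atom_index)
    coords = np.array([state.atom_pos[a] for a in atoms])
    return Conformation(atoms, coords)
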