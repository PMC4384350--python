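# Methods

## Model

The package solves the discretizable Distance Geometry Problem for
protein backbones. A conformation is a map from atoms to points in
R³; constraints are closed intervals (possibly degenerate) on
inter-atomic distances. Edges are partitioned the standard way:
*discretization edges* E_D connect each vertex of the search order to
its three immediate predecessors and make the instance rigid (E_D′:
exact scalars for the {v, v−1} and {v, v−2} pairs; E_D″: the {v, v−3}
pairs, exact or discretized into b samples), while *pruning edges* E_P
carry every other bound and only filter realizations. With exact
distances the search tree is binary: 2^(n−3) leaves when E_P is empty,
and with pruning edges the number of surviving solutions is (almost
always) zero or a power of two, a property the test suite checks on
random instances.

## The vertex order

Published transcriptions of the repetition order give its size
(7 vertices per residue plus 2) and its defining property (three
covalently constrained immediate predecessors, with some atoms entered
twice), which this package realizes as the per-residue block

    N, H, CA, N*, HA, CA*, C     (* = re-embedded duplicate)

closed by a terminal re-embedding `CA_n**, C_n*`. The block was
chosen so that every {v, v−1} and {v, v−2} edge is a bond or
bond-angle distance and the only torsion-dependent edges fall exactly
at {v, v−3}:

| vertex | {v,v−3} edge | nature |
|---|---|---|
| N_i | HA_{i−1}···N_i | ψ(i−1)-dependent interval |
| H_i | CA*_{i−1}···H_i | exact (ω fixed) |
| CA_i | C_{i−1}···CA_i | exact (bond angle) |
| N*_i, CA*_i | duplicate | distance 0 |
| HA_i | H_i···HA_i | φ(i)-dependent interval |
| C_i | N*_i···C_i | exact (bond angle) |

The hydrogen-bearing quadruples H–N–Cα–Hα and Hα–Cα–C′–N are the
classic φ/ψ torsions shifted by constant impropers; the offsets are
measured once, numerically, on an ideal fragment built from the
covalent tables (≈ −60.4° and −119.0° with the defaults), rather than
hard-coded.

## Geometry engine

Vertex k is embedded through the 4×4 recursion matrix B_k(θ₂, ω₃)
applied to the accumulated frame Q_{k−1}; θ₂ comes from the exact
predecessor distances by the law of cosines and |ω₃| from inverting
the torsion–distance relation for the sampled d_{k,k−3}. Numerical
verification during development showed that the sign slot printed in
the matrix form does not preserve the third predecessor distance; the
two mirror branches are therefore realized by negating ω₃ (the matrix
convention embeds a quadruple whose signed dihedral is −ω₃), and every
candidate is validated against its three predecessor distances at
1e−6 Å before use. Likewise the initial-triangle matrix uses
d₃₂·sin θ₃ in its (2,4) entry — the sine, not the cosine, is what the
distance contract ‖x₃ − x₂‖ = d₃₂ requires. The rotation block of Q_k
is exactly the frame built from the last three positions (first axis
along x_k − x_{k−1}, second the orthogonalized x_{k−2} − x_{k−1}),
which is how frames are re-anchored at duplicate vertices instead of
accumulating products through them.

Duplicates are re-embedded by sphere intersection on their three
predecessor distances (a zero distance collapses the intersection onto
the original atom) and the candidate nearest the original coordinates
is kept; drift beyond ε_dup prunes the node.

Carbonyl oxygens solve a 3×3 linear system (two radical planes from
differenced sphere equations plus the peptide-plane row); Cβ a 3×3
system from four sphere equations around non-coplanar anchors.
Condition numbers above 1e10 raise a degeneracy error, which the
search counts and treats as a prune.

## Parameters

| parameter | default | meaning |
|---|---|---|
| b | 4 | samples per discretized interval edge |
| ε_x | 0.2 Å | additive, inclusive widening of distance windows |
| ε_t | 2° | additive, inclusive widening of angular windows |
| σ_vdw | 0.85 | scale on the sum of van der Waals radii (O 1.4, H 1.0, C 1.7, N 1.5 Å) |
| ε_dup | 0.1 Å | accepted duplicate re-embedding drift |
| H-bond window | [1.9, 3.0] Å | O(i−4)···H(i) inside declared helices |
| energy threshold | −0.5 | DSSP-style electrostatic energy, q₁ = 0.42, q₂ = 0.2, f = 332 |
| θ, θ′, θ″ | [0,70]°, [0,90]°, [110,180]° | hydrogen-bond directionality windows |
| RMSD filter | 1.5 Å | between successively stored conformations |
| max stored | 10000 | stopping rule |

Covalent geometry defaults (overridable): bonds N–H 1.01, N–Cα 1.458,
Cα–C 1.525, C–N 1.329, C=O 1.231, Cα–Hα 1.090, Cα–Cβ 1.521 Å; angles
C–N–Cα 121.7°, H–N–Cα 118.2°, N–Cα–C 111.2°, N–Cα–Hα 108.0°,
C–Cα–Hα 109.0°, N–Cα–Cβ 110.5°, C–Cα–Cβ 110.1°, Cα–C–N 116.2°,
Cα–C–O 120.8°. Angles at planar centers close to 360° by
construction (C–N–H 120.1°, O–C–N 123.0°). The angles around Cα are
realized through an explicit tetrahedral template (Hα and Cβ on
opposite sides of the N–Cα–C plane, L-configuration), so the four Cβ
anchor distances are mutually consistent by construction.

Ramachandran domains are a modeling default, not data: helix residues
φ ∈ [−90°, −30°], ψ ∈ [−77°, −17°]; other residues a broad
β/extended-friendly union. Angles are radians internally, degrees at
user interfaces. All domains are exposed in the API.

## Design choices on open points

* **Hydrogen-bond angles.** θ is the angle between the C→O and O→H
  directions, θ′ between N→H and H→O, θ″ the angle at H in O···H–N.
  These are standard directionality angles consistent with the
  configured windows; they are assumptions, configurable per run.
* **van der Waals floors.** Steric lower bounds σ·(r_i + r_j) apply
  only to pairs three or more covalent bonds apart *with no explicit
  constraint*. An explicitly stated window wins: notably the 1.9 Å
  hydrogen-bond floor deliberately undercuts the O/H van der Waals sum
  (2.04 Å at σ = 0.85), so merging the two would silently tighten a
  stated input.
* **Discretization endpoint.** Interval sampling includes the lower
  endpoint and excludes the upper; an `include_upper` flag
  redistributes samples over the closed interval for experimentation.
* **Storage filter reference.** "Differs from the previous stored
  conformation" is read literally (compare to the last stored one);
  `compare="all"` switches to all-vs-new. A 1e−9 floor on the
  comparison keeps exact repeats out even at threshold 0.
* **Generated counter.** Counts completed backbones (leaves that
  survived every device and finalization), before the storage filter.
* **DSP slack.** The shortest-path predicate is strict as specified;
  the engine adds ε_x to the refined bounds so the device's tolerance
  is consistent with DDF's.
* **Global mirror.** The first torsion branching produces mirror
  trees; both are explored, and the chirality device breaks the
  symmetry at the first Cβ-bearing residue. Fixture round-trips
  therefore compare against the reference and its mirror.
* **Proline** is rejected with a clear error (its ring constrains φ in
  a way the covalent tables here do not model); glycine gets a single
  Hα, no Cβ and no chirality check.

## Synthetic data

`fixtures.build_ideal_helix` grows a backbone with uniform φ/ψ
(default −57°/−47°), trans peptide bonds and the covalent tables;
oxygens and Cβ are placed by the same closed-form operations the
search uses. `derive_instance` measures the φ/ψ-dependent order edges
from the structure (intervals of configurable width centered on truth,
exact at width 0), adds helix hydrogen-bond windows and seeded
long-range Cα–Cα intervals, and re-derives everything else from the
tables. Every interval contains the true distance, so the fixture is
a solution of its own instance — the round-trip property the tests
rely on. `degrade_inputs` implements the robustness protocol: one
residue off each helix end, long-range bounds widened by 0.5 Å.

These fixtures emulate idealized helical systems: uniform torsions,
exact covalent geometry, noise-free windows. They do not emulate NOE
calibration errors, ambiguous assignments, or inconsistent deposited
restraint lists, so passing round-trips demonstrates correctness of
the search, not robustness to real experimental noise.

## Numerical choices and problem sizes

Candidate validation at 1e−6 Å; sphere-intersection clamping at 1e−9;
linear-solve condition limit 1e10; torsion-cosine clamping with
unrealizable samples dropped per branch. The test suite runs
enumeration end-to-end on 5–10-residue systems (an exhaustive
10-residue exact fixture has 4096 solutions and enumerates in well
under a minute) and verifies theory properties on abstract 5–10-vertex
chains; these sizes were chosen so the full suite stays interactive
while still exercising every device and both branching regimes.

## Known limitations

Backbone and Cβ only — no side chains beyond Cβ, no proline ring, no
β-sheet or 3₁₀-helix devices, single chains, unambiguous restraints
only. The enumeration is exponential in the worst case; the
discretization factor b trades completeness of interval coverage
against tree width (the node bound 3 + 2^l·b^k is exposed as
`tree_size_bound`).
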