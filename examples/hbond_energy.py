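"""Hydrogen-bond energetics of an ideal alpha-helix.

Measures the four electrostatic distances of an (i-4, i) backbone pair
and evaluates the DSSP-style energy the alpha-helix pruning device
thresholds at -0.5.
"""

import numpy as np

from ibpenum.conformation import AtomRef
from ibpenum.fixtures import FixtureSpec, build_ideal_helix
from ibpenum.pruning import hbond_energy

conf = build_ideal_helix(FixtureSpec(n_residues=10))
j, i = 3, 7  # acceptor residue i-4 = 3, donor residue i = 7

d_on = np.linalg.norm(conf[AtomRef(j, "O")] - conf[AtomRef(i, "N")])
d_ch = np.linalg.norm(conf[AtomRef(j, "C")] - conf[AtomRef(i, "H")])
d_oh = np.linalg.norm(conf[AtomRef(j, "O")] - conf[AtomRef(i, "H")])
d_cn = np.linalg.norm(conf[AtomRef(j, "C")] - conf[AtomRef(i, "N")])
energy = hbond_energy(d_on, d_ch, d_oh, d_cn)

print(f"O..N  = {d_on:.3f} A   C..H = {d_ch:.3f} A")
print(f"O..H  = {d_oh:.3f} A   C..N = {d_cn:.3f} A")
print(f"DSSP-style energy = {energy:.3f}  (accept when < -0.5)")

# An ideal helix scores well below the -0.5 threshold: the carbonyl
# and amide dipoles are aligned, so candidate positions breaking this
# alignment are pruned during the search.
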