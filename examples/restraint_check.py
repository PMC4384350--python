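"""Check a conformation against distance restraints.

Parses the whitespace-delimited restraint format and reports per-pair
violations (a violation is how far the measured distance falls outside
the [lower, upper] window).
"""

from ibpenum.fixtures import FixtureSpec, build_ideal_helix
from ibpenum.io import parse_restraints, violation_report

conf = build_ideal_helix(FixtureSpec(n_residues=8))
restraints = parse_restraints(
    """
    # res1 atom1 res2 atom2 lower upper
    1 O 5 H 1.9 3.0    # helix hydrogen bond: satisfied
    2 CA 7 CA 2.0 4.0  # deliberately too tight: violated
    """
)
count, max_viol, table = violation_report(conf, restraints, threshold=1.0)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"violations above 1.0 A: {count}; largest violation: {max_viol:.2f} A")

# The helix hydrogen bond sits inside its window; the artificial CA-CA
# window is exceeded by several angstroms, so it is flagged.
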