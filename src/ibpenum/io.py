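"""File formats, run configuration and reports.

The restraint format is deliberately minimal: whitespace-delimited
lines ``res1 atom1 res2 atom2 lower upper [tag]`` with ``#`` comments,
residues 1-based and distances in angstroms.  Ensembles are written as
multi-model PDB (v3 atom naming, single chain A) through biotite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .conformation import ALLOWED_ATOMS, AtomRef, Conformation
from .errors import ConfigurationError
from .instance import ToleranceConfig, validate_sequence

logger = logging.getLogger("ibpenum")

__all__ = [
    "RestraintRecord",
    "RunConfig",
    "parse_restraints",
    "format_restraints",
    "write_pdb",
    "read_pdb_models",
    "violation_report",
]

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "Q": "GLN", "R": "ARG", "S": "SER",
    "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


class RestraintRecord(NamedTuple):
    res1: int
    atom1: str
    res2: int
    atom2: str
    lower: float
    upper: float
    tag: str = ""


def parse_restraints(text: str) -> list[RestraintRecord]:
    """Parse the whitespace-delimited restraint format; malformed
    lines raise with their line number."""
    records: list[RestraintRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (6, 7):
            raise ConfigurationError(
                f"restraint line {lineno}: expected 6 or 7 fields, got {len(fields)}"
            )
        try:
            res1, res2 = int(fields[0]), int(fields[2])
            lower, upper = float(fields[4]), float(fields[5])
        except ValueError as exc:
            raise ConfigurationError(f"restraint line {lineno}: {exc}") from None
        atom1, atom2 = fields[1].upper(), fields[3].upper()
        for name in (atom1, atom2):
            if name not in ALLOWED_ATOMS:
                raise ConfigurationError(
                    f"restraint line {lineno}: unknown atom name {name!r}"
                )
        if lower > upper:
            raise ConfigurationError(
                f"restraint line {lineno}: lower {lower} exceeds upper {upper}"
            )
        if min(res1, res2) < 1:
            raise ConfigurationError(f"restraint line {lineno}: residues are 1-based")
        tag = fields[6] if len(fields) == 7 else ""
        records.append(RestraintRecord(res1, atom1, res2, atom2, lower, upper, tag))
    return records


def format_restraints(records) -> str:
    lines = ["# res1 atom1 res2 atom2 lower upper [tag]"]
    for r in records:
        tail = f" {r.tag}" if r.tag else ""
        lines.append(
            f"{r.res1} {r.atom1} {r.res2} {r.atom2} {r.lower:.3f} {r.upper:.3f}{tail}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _atom_array(conf: Conformation, sequence: str) -> struc.AtomArray:
    n = len(conf)
    arr = struc.AtomArray(n)
    arr.coord = conf.coords.astype(np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.array([a.residue_index for a in conf.atoms])
    arr.res_name = np.array([_THREE[sequence[a.residue_index - 1]] for a in conf.atoms])
    arr.atom_name = np.array([a.atom_name for a in conf.atoms])
    arr.element = np.array([a.atom_name[0] for a in conf.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n, dtype=np.float32))
    arr.set_annotation("b_factor", np.zeros(n, dtype=np.float32))
    return arr


def write_pdb(conformations, sequence: str, path) -> bool:
    """Write an ensemble as a multi-model PDB file (one MODEL per
    conformation).  An empty ensemble writes nothing and logs a
    warning; returns whether a file was written."""
    conformations = list(conformations)
    sequence = validate_sequence(sequence)
    if not conformations:
        logger.warning("no conformations to write; %s not created", path)
        return False
    stack = struc.stack([_atom_array(c, sequence) for c in conformations])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    return True


def read_pdb_models(path) -> list[Conformation]:
    """Read a multi-model PDB back into conformations (only the atom
    names this package produces are kept)."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    out = []
    keep = np.isin(stack.atom_name, ALLOWED_ATOMS)
    for model in stack:
        sel = model[keep]
        atoms = [
            AtomRef(int(r), str(n)) for r, n in zip(sel.res_id, sel.atom_name)
        ]
        out.append(Conformation(atoms, sel.coord.astype(float)))
    return out


# ---------------------------------------------------------------------------
# Violation report
# ---------------------------------------------------------------------------

def violation_report(
    conf: Conformation,
    restraints,
    threshold: float = 1.0,
):
    """Check a conformation against restraints.

    The violation of a restraint is ``max(0, d - upper, lower - d)``.
    Returns ``(count_above_threshold, max_violation, table)`` where the
    table is a per-restraint DataFrame.
    """
    rows = []
    for r in restraints:
        a = AtomRef(r.res1, r.atom1)
        b = AtomRef(r.res2, r.atom2)
        d = float(np.linalg.norm(conf[a] - conf[b]))
        viol = max(0.0, d - r.upper, r.lower - d)
        rows.append(
            {
                "res1": r.res1, "atom1": r.atom1,
                "res2": r.res2, "atom2": r.atom2,
                "lower": r.lower, "upper": r.upper,
                "distance": d, "violation": viol,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return 0, 0.0, table
    count = int((table["violation"] > threshold).sum())
    return count, float(table["violation"].max()), table


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """A complete, serializable description of one enumeration run."""

    sequence: str
    helix_ranges: tuple[tuple[int, int], ...] = ()
    b: int = 4
    pos_tol: float = 0.2
    ang_tol: float = 2.0
    sigma_vdw: float = 0.85
    dup_tol: float = 0.1
    max_saved: int = 10000
    rmsd_filter: float = 1.5
    cis_peptides: tuple[int, ...] = ()
    restraints_path: str | None = None
    out_prefix: str = "ibp"

    def __post_init__(self):
        self.sequence = validate_sequence(self.sequence)
        n = len(self.sequence)
        for lo, hi in self.helix_ranges:
            if not (1 <= lo <= hi <= n):
                raise ConfigurationError(f"helix range {lo}-{hi} outside 1-{n}")
        for r in self.cis_peptides:
            if not (2 <= r <= n):
                raise ConfigurationError(f"cis peptide residue {r} outside 2-{n}")

    def tolerances(self) -> ToleranceConfig:
        return ToleranceConfig(
            eps_x=self.pos_tol, eps_t=self.ang_tol, b=self.b,
            sigma_vdw=self.sigma_vdw, eps_dup=self.dup_tol,
        )

    def to_yaml(self) -> str:
        d = asdict(self)
        d["helix_ranges"] = [list(r) for r in self.helix_ranges]
        d["cis_peptides"] = list(self.cis_peptides)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        d["helix_ranges"] = tuple(tuple(r) for r in d.get("helix_ranges", ()))
        d["cis_peptides"] = tuple(d.get("cis_peptides", ()))
        return cls(**d)
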