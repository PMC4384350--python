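"""Atom references and realized conformations."""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np

from .errors import ConfigurationError
from .geometry import kabsch_rmsd

ALLOWED_ATOMS = ("N", "H", "CA", "HA", "C", "O", "CB")
BACKBONE_RMSD_ATOMS = ("N", "CA", "C")


class AtomRef(NamedTuple):
    """A backbone (or C-beta) atom: 1-based residue index plus PDB v3
    atom name.  ``H`` is the backbone amide hydrogen."""

    residue_index: int
    atom_name: str

    def validate(self) -> "AtomRef":
        if self.residue_index < 1:
            raise ConfigurationError(f"residue index {self.residue_index} must be >= 1")
        if self.atom_name not in ALLOWED_ATOMS:
            raise ConfigurationError(f"unknown atom name {self.atom_name!r}")
        return self


class Conformation:
    """An ordered map from atoms to 3-D coordinates (angstroms)."""

    def __init__(self, atoms: Iterable[AtomRef], coords: np.ndarray):
        self.atoms: list[AtomRef] = [AtomRef(*a) for a in atoms]
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ConfigurationError(
                f"coords shape {self.coords.shape} does not match {len(self.atoms)} atoms"
            )
        self._index = {a: i for i, a in enumerate(self.atoms)}
        if len(self._index) != len(self.atoms):
            raise ConfigurationError("duplicate atoms in conformation")

    def __len__(self) -> int:
        return len(self.atoms)

    def __contains__(self, atom: AtomRef) -> bool:
        return AtomRef(*atom) in self._index

    def __getitem__(self, atom: AtomRef) -> np.ndarray:
        try:
            return self.coords[self._index[AtomRef(*atom)]]
        except KeyError:
            raise ConfigurationError(f"atom {atom} not present in conformation") from None

    @property
    def n_residues(self) -> int:
        return max(a.residue_index for a in self.atoms)

    def subset(self, atoms: Iterable[AtomRef]) -> np.ndarray:
        return np.array([self[a] for a in atoms])

    def backbone_atoms(self) -> list[AtomRef]:
        return [a for a in self.atoms if a.atom_name in BACKBONE_RMSD_ATOMS]

    def backbone_rmsd(self, other: "Conformation") -> float:
        atoms = self.backbone_atoms()
        return kabsch_rmsd(self.subset(atoms), other.subset(atoms))

    def mirrored(self) -> "Conformation":
        """The global mirror image (z negated)."""
        coords = self.coords.copy()
        coords[:, 2] *= -1.0
        return Conformation(self.atoms, coords)
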