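"""Light structure model and PDB I/O.

A :class:`Structure` is chains → residues → atoms with Å coordinates,
parsed from PDB text with Biopython.  Residue identity is
``(chain_id, residue_number)`` (insertion codes are honoured by folding
them into the residue key order but models in this package address
residues by number, which suffices for the docking bookkeeping here).
Multi-model (NMR) files yield one :class:`Structure` per model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = ["Atom", "Residue", "Chain", "Structure", "PDBFormatError", "read_pdb", "write_pdb"]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PDBFormatError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float).reshape(3)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Residue:
    number: int
    name: str  # three-letter code
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        return np.array([a.coord for a in atoms]).reshape(len(atoms), 3)

    def backbone_coords(self) -> np.ndarray:
        by_name = {a.name: a for a in self.atoms}
        return np.array(
            [by_name[n].coord for n in BACKBONE_ATOMS if n in by_name]
        ).reshape(-1, 3)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise KeyError(f"residue {number} not in chain {self.id}")

    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def heavy_coords(self) -> np.ndarray:
        parts = [r.heavy_coords() for r in self.residues]
        return np.vstack([p for p in parts if len(p)]) if parts else np.empty((0, 3))

    def backbone_coords(self, residues: list[int] | None = None) -> np.ndarray:
        sel = self.residues if residues is None else [self.residue(n) for n in sorted(residues)]
        parts = [r.backbone_coords() for r in sel]
        parts = [p for p in parts if len(p)]
        return np.vstack(parts) if parts else np.empty((0, 3))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    model_index: int = 0

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in structure {self.id}")

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    return name[:1].upper() if name else "X"


def read_pdb(path, id: str | None = None) -> list[Structure]:
    """Parse a PDB file into one :class:`Structure` per model."""
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure(id or path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    structures = []
    for mi, model in enumerate(bio):
        chains = []
        for bc in model:
            residues = []
            for br in bc:
                hetflag, resnum, icode = br.id
                atoms = [
                    Atom(
                        a.get_name(),
                        (a.element or _guess_element(a.get_name())).upper(),
                        a.get_coord(),
                    )
                    for a in br
                ]
                residues.append(
                    Residue(resnum, br.get_resname().strip(), atoms, icode.strip())
                )
            if residues:
                chains.append(Chain(bc.id, residues))
        if chains:
            structures.append(Structure(bio.id, chains, mi))
    if not structures or all(s.n_atoms() == 0 for s in structures):
        raise PDBFormatError(f"{path}: no ATOM records")
    return structures


def write_pdb(structures: Structure | list[Structure], path) -> None:
    """Write one or more models as standard fixed-width PDB ATOM records."""
    if isinstance(structures, Structure):
        structures = [structures]
    multi = len(structures) > 1
    with open(path, "w") as fh:
        for mi, s in enumerate(structures, start=1):
            if multi:
                fh.write(f"MODEL     {mi:4d}\n")
            serial = 1
            for chain in s.chains:
                for res in chain.residues:
                    for atom in res.atoms:
                        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                        x, y, z = atom.coord
                        fh.write(
                            f"ATOM  {serial:5d} {name}{'':1s}{res.name:>3s} "
                            f"{chain.id:1s}{res.number:4d}{res.icode:1s}   "
                            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                            f"          {atom.element:>2s}\n"
                        )
                        serial += 1
                fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
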