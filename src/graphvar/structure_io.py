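"""Read, write and stitch protein structures in PDB format.

The in-memory unit is :class:`ProteinStructure`: an ordered list of residues,
each holding its atoms with 3-D coordinates in Angstrom. Parsing keeps the
first model and first chain only, drops heteroatoms/waters and alternate
locations other than the first, and renumbers residues contiguously from 1 —
the normal form every downstream graph builder assumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as _struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "PDBParseError",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "stitch_fragments",
]

#: canonical 20 one-letter codes, fixed order used for one-hot features
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"

_SUPPORTED_ELEMENTS = {"C", "N", "O", "S", "H"}


class PDBParseError(ValueError):
    """The file is not parseable as a PDB structure (e.g. no ATOM records)."""


class StructureError(ValueError):
    """The structure violates an invariant (e.g. a residue lacking its CA)."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    position: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom:
        a = self.atom("CA")
        if a is None:
            raise StructureError(f"residue at position {self.position} lacks a CA atom")
        return a


@dataclass
class ProteinStructure:
    id: str
    residues: list[Residue]
    source: str = "other"

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n_residues, 3) array of alpha-carbon coordinates."""
        return np.array([r.ca.coords for r in self.residues])

    def copy(self) -> "ProteinStructure":
        return ProteinStructure(
            id=self.id,
            residues=[
                Residue(r.position, r.aa, [Atom(a.name, a.element, a.coords.copy()) for a in r.atoms])
                for r in self.residues
            ],
            source=self.source,
        )


def _normalize_element(elem: str) -> str:
    e = elem.strip().upper()
    if e in _SUPPORTED_ELEMENTS:
        return e
    return e if e else "other"


def read_pdb(path) -> ProteinStructure:
    """Parse a PDB file into a :class:`ProteinStructure`.

    Keeps the first model and first chain, drops HETATM records, waters and
    non-first alternate locations, and renumbers residues to 1..N in order of
    residue sequence number.

    Raises
    ------
    PDBParseError
        If the file contains no ATOM records.
    StructureError
        If any kept residue has no CA atom (the residue position is named).
    """
    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises on empty coordinate blocks
        raise PDBParseError(f"{path}: no parseable ATOM records ({exc})") from None
    if arr.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    arr = arr[~arr.hetero]
    arr = arr[arr.res_name != "HOH"]
    if arr.array_length() == 0:
        raise PDBParseError(f"{path}: no non-hetero ATOM records")
    first_chain = arr.chain_id[0]
    arr = arr[arr.chain_id == first_chain]

    # stable order by residue id, then group
    order = np.argsort(arr.res_id, kind="stable")
    arr = arr[order]
    residues: list[Residue] = []
    for new_pos, res_id in enumerate(np.unique(arr.res_id), start=1):
        mask = arr.res_id == res_id
        res_name = arr.res_name[mask][0]
        aa = _THREE_TO_ONE.get(res_name, "X")
        atoms = [
            Atom(name=an, element=_normalize_element(el), coords=co)
            for an, el, co in zip(arr.atom_name[mask], arr.element[mask], arr.coord[mask])
        ]
        residues.append(Residue(position=new_pos, aa=aa, atoms=atoms))
    structure = ProteinStructure(id=str(path), residues=residues)
    for r in structure.residues:
        if r.atom("CA") is None:
            raise StructureError(f"residue at position {r.position} has no CA atom")
    return structure


def _to_atom_array(structure: ProteinStructure) -> _struc.AtomArray:
    n = sum(len(r.atoms) for r in structure.residues)
    arr = _struc.AtomArray(n)
    i = 0
    for res in structure.residues:
        for atom in res.atoms:
            arr.coord[i] = atom.coords
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element if atom.element != "other" else ""
            arr.res_id[i] = res.position
            arr.res_name[i] = _ONE_TO_THREE.get(res.aa, "UNK")
            arr.chain_id[i] = "A"
            arr.hetero[i] = False
            i += 1
    return arr


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write fixed-column PDB ATOM records (one chain) with TER and END."""
    if not structure.residues:
        raise StructureError("cannot write a structure with no residues")
    arr = _to_atom_array(structure)
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    last = structure.residues[-1]
    n_atoms = arr.array_length()
    ter = "TER   {:>5}      {:>3} {}{:>4}".format(
        n_atoms + 1, _ONE_TO_THREE.get(last.aa, "UNK"), "A", last.position
    )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
        fh.write(ter + "\n")
        fh.write("END\n")


def stitch_fragments(fragments: list[ProteinStructure]) -> ProteinStructure:
    """Concatenate fragment-wise predictions into one structure.

    Fragments are assumed to be consecutive, non-overlapping subsequences in
    the given order; coordinates are copied verbatim (no superposition) and
    residues are renumbered 1..sum(len(fragment)).
    """
    if not fragments:
        raise ValueError("stitch_fragments requires at least one fragment")
    residues: list[Residue] = []
    pos = 0
    for frag in fragments:
        for res in frag.residues:
            pos += 1
            residues.append(
                Residue(pos, res.aa, [Atom(a.name, a.element, a.coords.copy()) for a in res.atoms])
            )
    return ProteinStructure(id=fragments[0].id, residues=residues, source=fragments[0].source)
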