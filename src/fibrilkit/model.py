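"""In-memory structure hierarchy: Atom / Residue / Chain / MolecularModel.

Coordinates are Cartesian, in angstroms.  Residues use author numbering
(``seq_id`` plus optional insertion code) because the literature on these
fibrils refers to residues by author numbers.  The hierarchy is deliberately
small: file parsing lives in :mod:`fibrilkit.io`, geometry in the analysis
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

#: three-letter codes of the 20 canonical amino acids
AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Atom:
    """A single atom with label, element and position (angstrom)."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(), self.occupancy)


@dataclass
class Residue:
    """One residue; ``seq_id`` is the author number, ``icode`` the insertion code."""

    name: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple[int, str]:
        """Composite residue key (seq_id, insertion code)."""
        return (self.seq_id, self.icode)

    @property
    def is_amino(self) -> bool:
        return self.name in AMINO_ACIDS_3

    @property
    def is_backbone_complete(self) -> bool:
        names = {a.name for a in self.atoms}
        return {"N", "CA", "C"} <= names

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def require_atom(self, name: str) -> Atom:
        a = self.atom(name)
        if a is None:
            from .errors import MissingAtomError

            raise MissingAtomError(
                f"residue {self.name} {self.seq_id}{self.icode}: atom {name!r} absent"
            )
        return a

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_id, [a.copy() for a in self.atoms], self.icode)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if sorted(keys) != keys:
            self.residues = sorted(self.residues, key=lambda r: r.key)

    def residue(self, seq_id: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_id == seq_id and r.icode == icode:
                return r
        return None

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def coords(self, atom_name: str | None = None, heavy_only: bool = False) -> np.ndarray:
        pts = [
            a.position
            for r in self.residues
            for a in r.atoms
            if (atom_name is None or a.name == atom_name)
            and (not heavy_only or a.is_heavy)
        ]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def centroid(self, heavy_only: bool = True) -> np.ndarray:
        xyz = self.coords(heavy_only=heavy_only)
        if len(xyz) == 0:
            xyz = self.coords()
        return xyz.mean(axis=0)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class MolecularModel:
    """Ordered collection of chains plus free-form metadata.

    Common metadata keys: ``source`` (input file), ``format``, ``stack_of``
    (chain_id -> stack label for two-stack fibrils), ``layer_of``
    (chain_id -> integer layer index), ``label_seq`` (author -> label_seq
    mapping recorded when reading mmCIF).
    """

    chains: list[Chain] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def atoms(self) -> Iterator[Atom]:
        for c in self.chains:
            yield from c.atoms()

    @property
    def n_atoms(self) -> int:
        return sum(c.n_atoms for c in self.chains)

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        pts = [a.position for a in self.atoms() if not heavy_only or a.is_heavy]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def copy(self) -> "MolecularModel":
        return MolecularModel([c.copy() for c in self.chains], dict(self.metadata))

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "MolecularModel":
        """Return a rigidly moved copy: x -> R x + t."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        out = self.copy()
        for a in out.atoms():
            a.position = R @ a.position + t
        return out

    def stack_of(self) -> dict[str, str]:
        """Chain -> stack labels; single implicit stack when unannotated."""
        ann = self.metadata.get("stack_of")
        if ann:
            return dict(ann)
        return {cid: "A" for cid in self.chain_ids}


def subunits_identical(a: Chain, b: Chain) -> bool:
    """True when two chains have the same residue names and atom names in order."""
    if len(a.residues) != len(b.residues):
        return False
    for ra, rb in zip(a.residues, b.residues):
        if ra.name != rb.name:
            return False
        if [x.name for x in ra.atoms] != [x.name for x in rb.atoms]:
            return False
    return True


def concat_models(parts: Iterable[MolecularModel], metadata: dict | None = None) -> MolecularModel:
    chains: list[Chain] = []
    for p in parts:
        chains.extend(c.copy() for c in p.chains)
    return MolecularModel(chains, metadata or {})
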