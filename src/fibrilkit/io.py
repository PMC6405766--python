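"""Reading, writing and sub-selection of atomic models (PDB / mmCIF).

Parsing is delegated to gemmi; this module converts between gemmi's
hierarchy and the package's :class:`~fibrilkit.model.MolecularModel`,
applying a deterministic alternate-location policy (keep the highest
occupancy, ties broken by file order) and preserving author residue
numbering.
"""

from __future__ import annotations

import logging
import string
from pathlib import Path

import gemmi

from .errors import EmptyModelError, EmptySelectionError, FormatError
from .model import Atom, Chain, MolecularModel, Residue

logger = logging.getLogger(__name__)

_FORMATS = {
    "auto": gemmi.CoorFormat.Detect,
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
}

#: chain-id alphabet used when renaming for fixed-column PDB output
_PDB_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


def read_structure(path: str | Path, format: str = "auto") -> MolecularModel:
    """Read a PDB or mmCIF file into a :class:`MolecularModel`.

    All ATOM/HETATM records are loaded (hydrogens included; they are
    flagged via :attr:`Atom.is_heavy`).  Alternate locations are resolved
    to the highest-occupancy conformer, ties to the first encountered.
    Only the first model of multi-model files is used.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no coordinate model")

    label_seq: dict[str, dict[int, int]] = {}
    chains: list[Chain] = []
    for gch in st[0]:
        residues: list[Residue] = []
        for gres in gch:
            icode = gres.seqid.icode.strip()
            atoms: dict[str, Atom] = {}
            occ_of: dict[str, float] = {}
            for gat in gres:
                occ = gat.occ
                prev = occ_of.get(gat.name)
                if prev is not None and occ <= prev:
                    continue  # altloc policy: highest occupancy, ties -> first
                occ_of[gat.name] = occ
                atoms[gat.name] = Atom(
                    name=gat.name,
                    element=gat.element.name or "X",
                    position=(gat.pos.x, gat.pos.y, gat.pos.z),
                    occupancy=occ,
                )
            if atoms:
                residues.append(
                    Residue(gres.name, gres.seqid.num, list(atoms.values()), icode)
                )
                if gres.label_seq is not None:
                    label_seq.setdefault(gch.name, {})[gres.seqid.num] = gres.label_seq
        if residues:
            chains.append(Chain(gch.name, residues))

    model = MolecularModel(
        chains,
        {"source": str(path), "format": format},
    )
    if label_seq:
        model.metadata["label_seq"] = label_seq
    if model.n_atoms == 0:
        raise EmptyModelError(f"{path}: zero atoms")
    if not any(r.is_amino for c in model.chains for r in c.residues):
        logger.warning("%s: no protein residues found (only heteroatoms/waters)", path)
    return model


def select(
    model: MolecularModel,
    chain_ids: set[str] | None = None,
    seq_range: tuple[int, int] | None = None,
    heavy_only: bool = False,
) -> MolecularModel:
    """Return a new model restricted to chains / residue range / heavy atoms.

    ``seq_range`` is an inclusive (start, end) interval in author numbering.
    The input model is untouched; an empty result raises
    :class:`EmptySelectionError`.
    """
    if chain_ids is not None:
        missing = set(chain_ids) - set(model.chain_ids)
        if missing:
            raise KeyError(f"chains not in model: {sorted(missing)}")
    chains: list[Chain] = []
    for ch in model.chains:
        if chain_ids is not None and ch.chain_id not in chain_ids:
            continue
        residues = []
        for res in ch.residues:
            if seq_range is not None and not (seq_range[0] <= res.seq_id <= seq_range[1]):
                continue
            atoms = [a.copy() for a in res.atoms if not heavy_only or a.is_heavy]
            if atoms:
                residues.append(Residue(res.name, res.seq_id, atoms, res.icode))
        if residues:
            chains.append(Chain(ch.chain_id, residues))
    if not chains:
        raise EmptySelectionError(
            f"selection (chains={chain_ids}, seq_range={seq_range}, "
            f"heavy_only={heavy_only}) matched no atoms"
        )
    out = MolecularModel(chains, dict(model.metadata))
    stacks = model.metadata.get("stack_of")
    if stacks:
        kept = {c.chain_id for c in chains}
        out.metadata["stack_of"] = {k: v for k, v in stacks.items() if k in kept}
    return out


def _pdb_chain_names(chain_ids: list[str]) -> dict[str, str]:
    """Deterministic renaming for fixed-column PDB output.

    Single-character ids are kept when they do not collide; every other
    chain gets the first free character of A-Z a-z 0-9, in model order.
    """
    if len(chain_ids) > len(_PDB_CHAIN_ALPHABET):
        raise FormatError(
            f"{len(chain_ids)} chains exceed PDB chain-id capacity; write mmCIF instead"
        )
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for cid in chain_ids:
        if len(cid) == 1 and cid not in used:
            mapping[cid] = cid
            used.add(cid)
    for cid in chain_ids:
        if cid in mapping:
            continue
        new = next(c for c in _PDB_CHAIN_ALPHABET if c not in used)
        mapping[cid] = new
        used.add(new)
    return mapping


def to_gemmi(model: MolecularModel, rename_chains: dict[str, str] | None = None) -> gemmi.Structure:
    """Convert to a gemmi Structure (one model)."""
    st = gemmi.Structure()
    st.name = str(model.metadata.get("source", "fibrilkit"))
    gmodel = gemmi.Model("1")
    for ch in model.chains:
        name = rename_chains.get(ch.chain_id, ch.chain_id) if rename_chains else ch.chain_id
        gch = gemmi.Chain(name)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            for at in res.atoms:
                gat = gemmi.Atom()
                gat.name = at.name
                gat.element = gemmi.Element(at.element)
                gat.pos = gemmi.Position(*at.position)
                gat.occ = at.occupancy
                gres.add_atom(gat)
            gch.add_residue(gres)
        gmodel.add_chain(gch)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure(model: MolecularModel, path: str | Path, format: str | None = None) -> Path:
    """Write a model as PDB or mmCIF (format inferred from suffix if omitted).

    PDB output enforces the fixed-column limits: more than 99,999 atoms is
    refused (use mmCIF), and chain ids longer than one character are renamed
    deterministically (see :func:`_pdb_chain_names`); the applied mapping is
    logged.  mmCIF output preserves ids verbatim.
    """
    path = Path(path)
    if model.n_atoms == 0:
        raise EmptyModelError("refusing to write an empty model")
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format == "pdb":
        if model.n_atoms > 99_999:
            raise FormatError(
                f"{model.n_atoms} atoms exceed the PDB serial-number limit; write mmCIF"
            )
        mapping = _pdb_chain_names(model.chain_ids)
        if any(k != v for k, v in mapping.items()):
            logger.info("PDB chain renaming applied: %s", mapping)
        to_gemmi(model, mapping).write_pdb(str(path))
    elif format == "mmcif":
        to_gemmi(model).make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"format must be 'pdb' or 'mmcif', got {format!r}")
    return path
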