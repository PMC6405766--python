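"""Shared fixtures: text-format structure snippets and synthetic fibrils."""

from __future__ import annotations

import numpy as np
import pytest

from fibrilkit import HelicalSymmetry
from fibrilkit.synth import (
    FibrilSpec,
    build_fibril,
    human_like_spec,
    murine_like_spec,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.560   6.351  -6.510  1.00  0.00           C
ATOM      3  C   ALA A   1      13.276   5.262  -5.701  1.00  0.00           C
END
"""

GLYGLY_CIF = """\
data_glygly
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
ATOM 1 N N . GLY A 1 1 ? 0.000 0.000 0.000 1.00 0.00 1 A
ATOM 2 C CA . GLY A 1 1 ? 1.458 0.000 0.000 1.00 0.00 1 A
ATOM 3 C C . GLY A 1 1 ? 2.004 1.420 0.000 1.00 0.00 1 A
ATOM 4 O O . GLY A 1 1 ? 1.251 2.390 0.000 1.00 0.00 1 A
ATOM 5 N N . GLY A 1 2 ? 3.332 1.536 0.000 1.00 0.00 2 A
ATOM 6 C CA . GLY A 1 2 ? 3.988 2.839 0.000 1.00 0.00 2 A
ATOM 7 C C . GLY A 1 2 ? 5.504 2.693 0.000 1.00 0.00 2 A
ATOM 8 O O . GLY A 1 2 ? 6.030 1.581 0.000 1.00 0.00 2 A
"""

WATERS_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
HETATM    3  O   HOH A   3       6.000   0.000   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.458   0.000   0.000  0.40  0.00           C
ATOM      3  CA BSER A   1       1.500   0.100   0.000  0.60  0.00           C
ATOM      4  C   SER A   1       2.000   1.400   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def glygly_cif(tmp_path):
    p = tmp_path / "glygly.cif"
    p.write_text(GLYGLY_CIF)
    return p


@pytest.fixture
def waters_pdb(tmp_path):
    p = tmp_path / "waters.pdb"
    p.write_text(WATERS_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture(scope="session")
def plain_fibril():
    """Single-arch-free two-stack fibril, 6 layers, murine helical values."""
    spec = FibrilSpec(
        n_layers=6,
        sym=HelicalSymmetry(4.8, -1.15, 2),
        strand_length=9,
        arch="none",
        phi=-124.0,
        psi=132.0,
        radius=12.0,
    )
    return build_fibril(spec)


@pytest.fixture(scope="session")
def murine_fibril():
    """Murine-architecture stand-in: 9 layers per stack."""
    return build_fibril(murine_like_spec(n_layers=9))


@pytest.fixture(scope="session")
def human_fibril():
    """Human-architecture stand-in: 11 layers per stack."""
    return build_fibril(human_like_spec(n_layers=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)
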