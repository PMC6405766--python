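"""Peptide masses and proteolytic-fragment assignment.

Fibril proteins extracted from amyloid deposits are typically N-terminal
fragments of their precursor; intact-mass spectra are interpreted by
enumerating candidate fragments of the precursor sequence and matching
each observed mass within a tolerance (2 Da by default, matching
MALDI-TOF / ESI intact-protein accuracy).  Average masses are the default
for intact-protein work; monoisotopic masses are available.  No
post-translational modifications are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: average residue masses, Da (monomer minus water)
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
#: monoisotopic residue masses, Da
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_AVERAGE = 18.0153
WATER_MONOISOTOPIC = 18.010565


def peptide_mass(sequence: str, kind: str = "average") -> float:
    """Mass in Da of a peptide: sum of residue masses plus one water.

    The empty sequence returns the water mass.  Non-canonical characters
    raise a ValueError naming the offending position (1-based).
    """
    if kind == "average":
        table, water = AVERAGE_RESIDUE_MASS, WATER_AVERAGE
    elif kind == "monoisotopic":
        table, water = MONOISOTOPIC_RESIDUE_MASS, WATER_MONOISOTOPIC
    else:
        raise ValueError(f"kind must be 'average' or 'monoisotopic', got {kind!r}")
    total = water
    for i, ch in enumerate(sequence.upper()):
        try:
            total += table[ch]
        except KeyError:
            raise ValueError(
                f"non-canonical residue {ch!r} at position {i + 1}"
            ) from None
    return total


@dataclass(frozen=True)
class PrecursorSequence:
    """A precursor protein sequence with optional author numbering offset.

    Position ``i`` (1-based in the stored string) is reported as
    ``i + numbering_offset``, so a mature protein whose first stored
    residue is author position 2 uses ``numbering_offset=1``.
    """

    id: str
    residues: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        bad = [c for c in self.residues.upper() if c not in AVERAGE_RESIDUE_MASS]
        if bad:
            raise ValueError(f"{self.id}: non-canonical residues {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.residues)

    def fragment(self, start: int, end: int) -> str:
        """Subsequence by reported (offset) inclusive positions."""
        i = start - self.numbering_offset
        j = end - self.numbering_offset
        if not (1 <= i <= j <= len(self.residues)):
            raise IndexError(f"fragment ({start}, {end}) outside precursor")
        return self.residues[i - 1 : j]


@dataclass(frozen=True)
class FragmentMatch:
    """Assignment of an observed mass to a precursor fragment."""

    start: int
    end: int
    computed_mass: float
    observed_mass: float
    mass_kind: str

    @property
    def delta(self) -> float:
        return self.observed_mass - self.computed_mass


@dataclass(frozen=True)
class FragmentAssignment:
    matches: list[FragmentMatch] = field(default_factory=list)
    unassigned: list[float] = field(default_factory=list)

    def best_for(self, observed: float) -> FragmentMatch | None:
        cands = [m for m in self.matches if m.observed_mass == observed]
        return cands[0] if cands else None


def _candidate_fragments(precursor: PrecursorSequence, mode: str):
    n = len(precursor.residues)
    off = precursor.numbering_offset
    if mode == "nterm":
        return [(1 + off, k + off) for k in range(1, n + 1)]
    if mode == "cterm":
        return [(k + off, n + off) for k in range(1, n + 1)]
    if mode == "internal":
        return [
            (i + off, j + off) for i in range(1, n + 1) for j in range(i, n + 1)
        ]
    raise ValueError(f"mode must be nterm, cterm or internal, got {mode!r}")


def match_fragments(
    precursor: PrecursorSequence,
    observed: list[float],
    tolerance: float = 2.0,
    mode: str = "nterm",
    kind: str = "average",
) -> FragmentAssignment:
    """Assign observed masses (Da) to fragments of the precursor.

    For every observed mass, every candidate fragment whose computed mass
    lies within ``tolerance`` is reported, sorted by |delta| (best
    first).  Masses with no candidate are collected as unassigned, never
    raised.
    """
    if any(m <= 0 for m in observed):
        raise ValueError("observed masses must be positive")
    cands = []
    for start, end in _candidate_fragments(precursor, mode):
        cands.append((start, end, peptide_mass(precursor.fragment(start, end), kind)))
    matches: list[FragmentMatch] = []
    unassigned: list[float] = []
    for obs in observed:
        hits = [
            FragmentMatch(start, end, mass, obs, kind)
            for start, end, mass in cands
            if abs(obs - mass) <= tolerance
        ]
        if hits:
            hits.sort(key=lambda m: abs(m.delta))
            matches.extend(hits)
        else:
            unassigned.append(obs)
    return FragmentAssignment(matches, unassigned)
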