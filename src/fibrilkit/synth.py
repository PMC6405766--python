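"""Synthetic cross-beta fibril generator with known ground truth.

Builds idealized fibrils that emulate the architecture of AA amyloid
fibrils: one or two stacks of identical subunits related by screw symmetry
(rise ~4.7-4.8 A, twist ~+-1-2 deg, optional pseudo-2_1 two-start
arrangement), parallel in-register beta-sheets, controllable twist
handedness via the strand dihedrals, and an optional axial height
modulation of the chain.  Every analysis module is tested against this
generator, so the geometry is deliberately simple and fully deterministic:

* backbones are grown residue-by-residue at target phi/psi with ideal bond
  lengths and angles (N-CA 1.458, CA-C 1.525, C-N 1.329 A);
* a "beta-arch" subunit is two such strands, antiparallel in projection,
  joined by a four-residue connector; the strands interact through side
  chains only (no intramolecular backbone H-bonds), like the N-terminal
  beta-arch of the fibril proteins;
* side chains are CB-only, except for Asp/Glu/Lys/Arg/Ile which get
  minimal ideal-geometry (all-trans) side chains so that salt bridges and
  charged-vs-hydrophobic interface chemistry exist in the stand-ins.

Strand axes run along +y in the subunit frame, side chains along +-x
(radial), carbonyls along +-z (the fibril axis), which is the cross-beta
orientation after helical replication about +z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import BuildError
from .geometry import (
    FibrilAxis,
    HelicalSymmetry,
    Z_AXIS,
    apply_helical_symmetry,
)
from .model import Atom, Chain, MolecularModel, ONE_TO_THREE, Residue

# ideal backbone geometry (A, deg)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.526
ANG_N_CA_C = 111.0
ANG_CA_C_N = 116.6
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.5
OMEGA = 180.0

#: minimal side-chain extensions past CB: (atom, element, frame offset, bond, angle, torsion)
#: frames are indices into the atom list built so far for that residue,
#: counted from [N, CA, CB, <previous extension atoms...>]
_SIDE_CHAINS: dict[str, list[tuple[str, str, tuple[int, int, int], float, float, float]]] = {
    "ASP": [
        ("CG", "C", (0, 1, 2), 1.52, 113.8, 180.0),
        ("OD1", "O", (1, 2, 3), 1.25, 118.5, 0.0),
        ("OD2", "O", (1, 2, 3), 1.25, 118.5, 180.0),
    ],
    "GLU": [
        ("CG", "C", (0, 1, 2), 1.52, 113.8, 180.0),
        ("CD", "C", (1, 2, 3), 1.52, 113.8, 180.0),
        ("OE1", "O", (2, 3, 4), 1.25, 118.5, 0.0),
        ("OE2", "O", (2, 3, 4), 1.25, 118.5, 180.0),
    ],
    "LYS": [
        ("CG", "C", (0, 1, 2), 1.52, 113.5, 180.0),
        ("CD", "C", (1, 2, 3), 1.52, 113.5, 180.0),
        ("CE", "C", (2, 3, 4), 1.52, 113.5, 180.0),
        ("NZ", "N", (3, 4, 5), 1.49, 112.0, 180.0),
    ],
    "ARG": [
        ("CG", "C", (0, 1, 2), 1.52, 113.5, 180.0),
        ("CD", "C", (1, 2, 3), 1.52, 113.5, 180.0),
        ("NE", "N", (2, 3, 4), 1.46, 112.0, 180.0),
        ("CZ", "C", (3, 4, 5), 1.33, 124.0, 180.0),
        ("NH1", "N", (4, 5, 6), 1.33, 120.0, 0.0),
        ("NH2", "N", (4, 5, 6), 1.33, 120.0, 180.0),
    ],
    "ILE": [
        ("CG1", "C", (0, 1, 2), 1.53, 110.5, 180.0),
        ("CG2", "C", (0, 1, 2), 1.53, 110.5, -60.0),
        ("CD1", "C", (1, 2, 3), 1.53, 114.0, 180.0),
    ],
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural extension reference frame (NeRF) atom placement.

    Returns the point at distance ``bond`` from ``c``, with angle
    ``angle`` (deg) at b-c-new and torsion ``torsion`` (deg) for
    a-b-c-new.
    """
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB of an L-amino acid from its backbone (tetrahedral construction)."""
    u = (n - ca) / np.linalg.norm(n - ca)
    v = (c - ca) / np.linalg.norm(c - ca)
    bis = u + v
    bis /= np.linalg.norm(bis)
    perp = np.cross(u, v)
    perp /= np.linalg.norm(perp)
    return ca + BOND_CA_CB * (-bis / math.sqrt(3.0) + perp * math.sqrt(2.0 / 3.0))


def _build_strand(sequence: str, phi: float, psi: float) -> list[Residue]:
    """Grow a peptide at constant (phi, psi) with ideal covalent geometry."""
    n_res = len(sequence)
    if n_res < 1:
        raise BuildError("strand needs >= 1 residue")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(ANG_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for _ in range(1, n_res):
        N.append(place_atom(N[-1], CA[-1], C[-1], BOND_C_N, ANG_CA_C_N, psi))
        CA.append(place_atom(CA[-1], C[-1], N[-1], BOND_N_CA, ANG_C_N_CA, OMEGA))
        C.append(place_atom(C[-1], N[-1], CA[-1], BOND_CA_C, ANG_N_CA_C, phi))

    residues = []
    for i, one in enumerate(sequence):
        name = ONE_TO_THREE[one]
        atoms = [
            Atom("N", "N", N[i].copy()),
            Atom("CA", "C", CA[i].copy()),
            Atom("C", "C", C[i].copy()),
            Atom("O", "O", place_atom(N[i], CA[i], C[i], BOND_C_O, ANG_CA_C_O, psi + 180.0)),
        ]
        if name != "GLY":
            cb = _cb_position(N[i], CA[i], C[i])
            atoms.append(Atom("CB", "C", cb))
            frame = [N[i], CA[i], cb]
            for aname, elem, (ia, ib, ic), bond, bang, tor in _SIDE_CHAINS.get(name, []):
                pos = place_atom(frame[ia], frame[ib], frame[ic], bond, bang, tor)
                atoms.append(Atom(aname, elem, pos))
                frame.append(pos)
        residues.append(Residue(name, i + 1, atoms))
    return residues


def _orient_strand(residues: list[Residue]) -> None:
    """Rotate+translate in place: strand axis -> +y, carbonyls -> +-z,
    backbone centered at the origin."""
    ca = np.array([r.require_atom("CA").position for r in residues])
    if len(ca) < 2:
        return
    u = ca[-1] - ca[0]
    u /= np.linalg.norm(u)
    # mean carbonyl direction of even residues defines the H-bond axis
    w = np.zeros(3)
    for i in range(0, len(residues), 2):
        r = residues[i]
        w += r.require_atom("O").position - r.require_atom("C").position
    w -= (w @ u) * u
    if np.linalg.norm(w) < 1e-9:  # single residue or degenerate: keep frame
        w = np.array([0.0, 0.0, 1.0])
    w /= np.linalg.norm(w)
    ex = np.cross(u, w)
    R = np.array([ex, u, w])  # rows: maps ex->x, u->y, w->z
    bb = []
    for r in residues:
        for a in r.atoms:
            a.position = R @ a.position
            if a.name in ("N", "CA", "C"):
                bb.append(a.position)
    center = np.mean(bb, axis=0)
    for r in residues:
        for a in r.atoms:
            a.position = a.position - center


def _rotate_z180(residues: list[Residue]) -> None:
    flip = np.array([-1.0, -1.0, 1.0])
    for r in residues:
        for a in r.atoms:
            a.position = a.position * flip


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, t: float) -> np.ndarray:
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _build_turn(prev: Residue, nxt: Residue, n_res: int, seq_start: int,
                phi: float, psi: float) -> list[Residue]:
    """Connector residues closing the arch between the two strands.

    The two junction atoms are placed with ideal covalent geometry so the
    flanking strand residues keep their target dihedrals: the first
    connector N continues the first strand at its psi, and the last
    connector C approaches the second strand at its phi.  The interior
    backbone follows a smooth arc (approximate geometry); connector
    carbonyls point within the turn plane so stacked connectors do not
    register as beta-strands.
    """
    n_start = place_atom(
        prev.require_atom("N").position,
        prev.require_atom("CA").position,
        prev.require_atom("C").position,
        BOND_C_N, ANG_CA_C_N, psi,
    )
    c_end = place_atom(
        nxt.require_atom("C").position,
        nxt.require_atom("CA").position,
        nxt.require_atom("N").position,
        BOND_C_N, ANG_C_N_CA, phi,
    )
    chord = c_end - n_start
    mid = 0.5 * (n_start + c_end)
    ctrl = mid + np.array([0.0, 1.0, 0.0]) * max(4.0, 0.8 * np.linalg.norm(chord))
    # backbone trace N-CA-C per residue along the arc; anchors fixed
    n_pts = 3 * n_res
    ts = np.linspace(0.0, 1.0, n_pts)
    pts = [_bezier(n_start, ctrl, c_end, t) for t in ts]
    residues = []
    for j in range(n_res):
        n_pos, ca, c_pos = pts[3 * j], pts[3 * j + 1], pts[3 * j + 2]
        tangent = c_pos - n_pos
        tangent /= np.linalg.norm(tangent)
        normal = np.cross(tangent, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(normal) < 1e-9:
            normal = np.array([1.0, 0.0, 0.0])
        normal /= np.linalg.norm(normal)
        o_pos = c_pos + 1.231 * normal
        residues.append(
            Residue(
                "GLY",
                seq_start + j,
                [
                    Atom("N", "N", n_pos),
                    Atom("CA", "C", ca),
                    Atom("C", "C", c_pos),
                    Atom("O", "O", o_pos),
                ],
            )
        )
    return residues


@dataclass(frozen=True)
class FibrilSpec:
    """Recipe for a synthetic fibril with known ground truth.

    Lengths in angstrom, angles in degrees.  ``phi``/``psi`` are the
    strand dihedral targets (their sum sets the beta-sheet twist
    handedness statistic); ``radius`` places the subunit centroid at that
    distance from the fibril axis; ``height_modulation`` adds a linear
    axial ramp across the chain (the within-chain height change of the
    fibril proteins).  Arch parameters (used when ``arch="beta-arch"``):
    ``arch_separation`` is the signed radial offset of the second strand
    (positive = outward), ``arch_axial_offset`` its axial offset, and
    ``strand2_ramp`` an extra axial ramp across the second strand, which
    together set how the subunit interdigitates with its axial neighbors.
    """

    n_layers: int = 6
    sym: HelicalSymmetry = field(default_factory=lambda: HelicalSymmetry(4.8, -1.15, 2))
    strand_length: int = 8
    arch: str = "none"
    phi: float = -124.0
    psi: float = 132.0
    radius: float = 12.0
    noise_sd: float = 0.0
    seed: int = 0
    height_modulation: float = 0.0
    sequence: str | None = None
    sequence2: str | None = None
    arch_separation: float = 6.0
    arch_axial_offset: float = 0.0
    strand2_ramp: float = 0.0
    turn_length: int = 4

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.strand_length < 3:
            raise ValueError("strand_length must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.arch not in ("none", "beta-arch"):
            raise ValueError(f"arch must be 'none' or 'beta-arch', got {self.arch!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a fibril."""

    sym: HelicalSymmetry
    axis: FibrilAxis
    phi_psi_sum: float
    geometric_handedness: str
    sheet_handedness: str
    height_modulation: float
    seed: int


def _check_self_collision(residues: list[Residue], cutoff: float = 0.9) -> None:
    from scipy.spatial import cKDTree

    pts, owner = [], []
    for idx, r in enumerate(residues):
        for a in r.atoms:
            pts.append(a.position)
            owner.append(idx)
    tree = cKDTree(np.array(pts))
    for i, j in tree.query_pairs(cutoff):
        if abs(owner[i] - owner[j]) >= 2:
            ri, rj = residues[owner[i]], residues[owner[j]]
            raise BuildError(
                f"self-collision: {ri.name}{ri.seq_id} vs {rj.name}{rj.seq_id} "
                f"closer than {cutoff} A (unphysical phi/psi?)"
            )


def build_subunit(spec: FibrilSpec) -> MolecularModel:
    """Build one subunit chain (chain id "A", residues numbered from 1)."""
    seq1 = spec.sequence or "A" * spec.strand_length
    residues = _build_strand(seq1, spec.phi, spec.psi)
    _orient_strand(residues)

    if spec.arch == "beta-arch":
        seq2 = spec.sequence2 or "A" * spec.strand_length
        strand2 = _build_strand(seq2, spec.phi, spec.psi)
        _orient_strand(strand2)
        _rotate_z180(strand2)
        if spec.strand2_ramp:
            # tilt the strand rigidly about the radial (x) axis so its
            # axial extent equals the ramp; a rotation keeps the internal
            # covalent geometry and dihedrals exact
            ca = np.array([r.require_atom("CA").position for r in strand2])
            y_span = float(ca[:, 1].max() - ca[:, 1].min())
            theta = math.asin(min(1.0, spec.strand2_ramp / max(y_span, 1e-6)))
            # chain order of strand 2 runs toward -y after the 180 flip;
            # tilt so the axial offset grows along the chain
            ct, st = math.cos(theta), math.sin(theta)
            center = ca.mean(axis=0)
            for r in strand2:
                for a in r.atoms:
                    p = a.position - center
                    a.position = center + np.array(
                        [p[0], ct * p[1] + st * p[2], -st * p[1] + ct * p[2]]
                    )
        for r in strand2:
            shift = np.array(
                [spec.arch_separation, 0.0, spec.arch_axial_offset]
            )
            for a in r.atoms:
                a.position = a.position + shift
        turn = _build_turn(
            residues[-1],
            strand2[0],
            spec.turn_length,
            len(residues) + 1,
            spec.phi,
            spec.psi,
        )
        offset = len(residues) + spec.turn_length
        for j, r in enumerate(strand2):
            r.seq_id = offset + 1 + j
        residues = residues + turn + strand2

    if spec.height_modulation:
        # linear axial ramp along the chain, scaled so the first-to-last
        # carbonyl-carbon height change equals the requested value exactly
        # (the backbone pleat otherwise offsets it by a fraction of an A)
        n = len(residues)
        base = (
            residues[-1].require_atom("C").position[2]
            - residues[0].require_atom("C").position[2]
        )
        amp = spec.height_modulation - base
        for idx, r in enumerate(residues):
            dz = amp * (idx / (n - 1) if n > 1 else 0.0)
            for a in r.atoms:
                a.position = a.position + np.array([0.0, 0.0, dz])

    _check_self_collision(residues)
    chain = Chain("A", residues)
    model = MolecularModel([chain], {"generator": "fibrilkit.synth"})
    centroid = model.coords().mean(axis=0)
    target = np.array([spec.radius, 0.0, centroid[2]])
    for a in model.atoms():
        a.position = a.position + (target - centroid)
    return model


def sheet_handedness_of(phi: float, psi: float, eps: float = 0.5) -> str:
    s = phi + psi
    if abs(s) < eps:
        return "indeterminate"
    return "right" if s < 0 else "left"


def build_fibril(spec: FibrilSpec) -> tuple[MolecularModel, GroundTruth]:
    """Subunit + helical replication + seeded coordinate noise.

    Noise is applied after symmetry expansion so each chain's noise is
    independent and the symmetry ground truth stays exact underneath.
    """
    subunit = build_subunit(spec)
    fibril = apply_helical_symmetry(subunit, spec.sym, spec.n_layers, Z_AXIS)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        for a in fibril.atoms():
            a.position = a.position + rng.normal(0.0, spec.noise_sd, 3)
    twist = spec.sym.twist
    truth = GroundTruth(
        sym=spec.sym,
        axis=Z_AXIS,
        phi_psi_sum=spec.phi + spec.psi,
        geometric_handedness=(
            "right" if twist > 0 else "left" if twist < 0 else "untwisted"
        ),
        sheet_handedness=sheet_handedness_of(spec.phi, spec.psi),
        height_modulation=spec.height_modulation,
        seed=spec.seed,
    )
    fibril.metadata["ground_truth"] = {
        "rise": spec.sym.rise,
        "twist": spec.sym.twist,
        "starts": spec.sym.starts,
        "phi_psi_sum": truth.phi_psi_sum,
    }
    return fibril, truth


# ---------------------------------------------------------------------------
# Stand-in presets emulating the two studied fibril architectures.
# These are synthetic surrogates, not the deposited structures: their
# helical parameters, height changes, twist-handedness dihedrals and
# interface character (minimal reciprocal salt-bridge contact vs extended
# zipper-like contact) follow the published fibril descriptions, and the
# analysis modules then measure whatever geometry results.
# ---------------------------------------------------------------------------


def _inward_charged_sequence(spec: FibrilSpec, inner_names: dict[int, str]) -> str:
    """Sequence for strand 1 with given residues (1-based index) renamed."""
    seq = list(spec.sequence or "A" * spec.strand_length)
    for pos, one in inner_names.items():
        seq[pos - 1] = one
    return "".join(seq)


def murine_like_spec(n_layers: int = 12, seed: int = 0, noise_sd: float = 0.0) -> FibrilSpec:
    """Synthetic stand-in for the murine-type fibril architecture.

    Left-hand twisted sheets (phi+psi = +8 deg), rise 4.8 A, twist -1.15
    deg, pseudo-2_1 two-start.  The arch's second strand lies radially
    outward with a 6 A axial offset (interdigitation with layers i+-2);
    the only cross-stack contact is a reciprocal Asp/Arg pair whose side
    chains reach the fibril axis, emulating the minimal salt-bridge
    interface.
    """
    base = FibrilSpec(
        n_layers=n_layers,
        sym=HelicalSymmetry(4.8, -1.15, 2),
        strand_length=9,
        arch="beta-arch",
        phi=-124.0,
        psi=132.0,
        radius=9.35,
        noise_sd=noise_sd,
        seed=seed,
        arch_separation=6.0,
        arch_axial_offset=6.0,
    )
    # inner-pointing side chains alternate along the strand; indices 3 and 7
    # (1-based) point toward the axis and sit symmetrically about the strand
    # center, giving reciprocal Asp...Arg bridges under the 2-fold.
    seq1 = _inward_charged_sequence(base, {3: "D", 7: "R"})
    return replace(base, sequence=seq1)


def human_like_spec(n_layers: int = 12, seed: int = 0, noise_sd: float = 0.0) -> FibrilSpec:
    """Synthetic stand-in for the human-type fibril architecture.

    Right-hand twisted sheets (phi+psi = -2 deg), rise 4.7 A, twist +1.54
    deg, pseudo-2_1.  The first strand's inner hydrophobic (Ile) side
    chains form a self-complementary zipper-like cross-stack interface
    near the axis; the second strand lies radially outward with a large
    axial offset plus ramp, so each chain also interdigitates with
    same-stack neighbors up to four layers away.
    """
    base = FibrilSpec(
        n_layers=n_layers,
        sym=HelicalSymmetry(4.7, 1.54, 2),
        strand_length=9,
        arch="beta-arch",
        phi=-119.0,
        psi=117.0,
        radius=8.2,
        noise_sd=noise_sd,
        seed=seed,
        arch_separation=6.5,
        arch_axial_offset=11.75,
        strand2_ramp=9.5,
    )
    seq1 = _inward_charged_sequence(base, {3: "I", 5: "I", 7: "I"})
    return replace(base, sequence=seq1)
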