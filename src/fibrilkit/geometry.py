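"""Helical symmetry of cross-beta fibrils: generation, estimation, morphology.

A fibril is modelled as one or two stacks of identical protein subunits
related by a screw operation: a rise (angstrom per subunit along the fibril
axis) combined with a twist (degrees per subunit about it).  The two-start
("pseudo-2_1") arrangement generates the second stack from the first by a
screw of half the rise and half the twist plus 180 degrees, so that the
stacks interleave with an axial offset of half a cross-beta repeat.

Sign convention: twist > 0 is a right-handed screw advance when sighting
along the +axis direction; the axis direction points from the lowest- to
the highest-index subunit of the first stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InsufficientSubunitsError, NonHelicalModelError
from .model import Chain, MolecularModel, concat_models, subunits_identical


@dataclass(frozen=True)
class HelicalSymmetry:
    """Rise (A/subunit), signed twist (deg/subunit) and start number.

    ``starts=2`` denotes the pseudo-2_1 two-start arrangement: the second
    stack is offset by ``rise/2`` along the axis and rotated by
    ``twist/2 + 180`` degrees.
    """

    rise: float
    twist: float
    starts: int = 1
    rise_sd: float = 0.0
    twist_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError(f"rise must be positive, got {self.rise}")
        if not abs(self.twist) <= 180:
            raise ValueError(f"|twist| must be <= 180 deg, got {self.twist}")
        if self.starts not in (1, 2):
            raise ValueError(f"starts must be 1 or 2, got {self.starts}")


@dataclass(frozen=True)
class FibrilAxis:
    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis direction must be a nonzero vector")
        object.__setattr__(self, "direction", d / n)

    def axial(self, points: np.ndarray) -> np.ndarray:
        """Signed axial coordinate of points (projection onto the axis)."""
        return (np.atleast_2d(points) - self.point) @ self.direction

    def radial(self, points: np.ndarray) -> np.ndarray:
        """Distance of points from the axis line."""
        rel = np.atleast_2d(points) - self.point
        along = np.outer(rel @ self.direction, self.direction)
        return np.linalg.norm(rel - along, axis=1)


#: default axis used when generating fibrils from scratch: +z through origin
Z_AXIS = FibrilAxis(np.zeros(3), np.array([0.0, 0.0, 1.0]))


@dataclass(frozen=True)
class ScrewTransform:
    """Rotation by ``angle`` (deg) about an axis plus translation along it."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    angle: float
    translation: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, dtype=float))
        d = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            d = d / n
        object.__setattr__(self, "axis_direction", d)
        if not -180 < self.angle <= 180 + 1e-12:
            # angles accumulate past 180 when composing layers; normalize lazily
            pass

    def rotation(self) -> Rotation:
        return Rotation.from_rotvec(np.deg2rad(self.angle) * self.axis_direction)

    def apply(self, points: np.ndarray) -> np.ndarray:
        R = self.rotation()
        rel = np.atleast_2d(points) - self.axis_point
        return (
            self.axis_point
            + R.apply(rel)
            + self.translation * self.axis_direction
        )

    def apply_model(self, model: MolecularModel) -> MolecularModel:
        out = model.copy()
        for a in out.atoms():
            a.position = self.apply(a.position)[0]
        return out


@dataclass(frozen=True)
class MorphologySummary:
    """Model-derived morphological quantities (nm for lengths, deg for twist)."""

    crossover_distance: float
    width: float
    rise: float
    twist: float


def detect_stacks(model: MolecularModel, axis: FibrilAxis) -> dict[str, str]:
    """Partition chains into two stacks.

    Uses explicit ``stack_of`` annotations when present, otherwise
    deterministic two-means clustering of the chain-centroid azimuth unit
    vectors about the axis (initialized from the most separated pair).
    """
    if model.metadata.get("stack_of"):
        return dict(model.metadata["stack_of"])
    cents = np.array([c.centroid() for c in model.chains])
    rel = cents - axis.point
    axial = np.outer(rel @ axis.direction, axis.direction)
    radial = rel - axial
    norms = np.linalg.norm(radial, axis=1)
    norms[norms < 1e-9] = 1.0
    u = radial / norms[:, None]
    d2 = ((u[:, None, :] - u[None, :, :]) ** 2).sum(-1)
    i0, j0 = np.unravel_index(np.argmax(d2), d2.shape)
    if d2[i0, j0] < 1.0:  # all azimuths alike: a single stack
        return {c.chain_id: "A" for c in model.chains}
    centers = np.stack([u[i0], u[j0]])
    labels = np.zeros(len(u), dtype=int)
    for it in range(50):
        dist = ((u[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new = dist.argmin(axis=1)
        if it > 0 and (new == labels).all():
            break
        labels = new
        for k in (0, 1):
            if (labels == k).any():
                c = u[labels == k].mean(axis=0)
                n = np.linalg.norm(c)
                if n > 1e-9:
                    centers[k] = c / n
    return {
        ch.chain_id: ("A" if lab == 0 else "B")
        for ch, lab in zip(model.chains, labels)
    }


def _stack_centered_pca(centroids: np.ndarray, labels: list) -> tuple[np.ndarray, float]:
    """Principal direction of per-stack-centered centroids + variance fraction."""
    residuals = centroids.copy()
    for lab in set(labels):
        idx = [i for i, l in enumerate(labels) if l == lab]
        residuals[idx] -= centroids[idx].mean(axis=0)
    cov = np.cov(residuals.T)
    w, v = np.linalg.eigh(cov)
    total = w.sum()
    frac = float(w[-1] / total) if total > 0 else 0.0
    return v[:, -1], frac


def fit_fibril_axis(model: MolecularModel) -> FibrilAxis:
    """Fibril axis from the principal axis of the chain centroids.

    Requires at least three chains.  Each stack's centroids are centered
    on their own mean before the PCA, so the radial offset between two
    stacks does not masquerade as the axis.  Without stack annotations,
    candidate axes (the three global principal directions) each cluster
    the chains into stacks; the candidate whose per-stack residuals are
    most one-dimensional wins.  The direction is signed to point from the
    first to the last chain (model order) of the first stack.
    """
    if len(model.chains) < 3:
        raise InsufficientSubunitsError(
            f"need >= 3 chains to fit a fibril axis, got {len(model.chains)}"
        )
    centroids = np.array([c.centroid() for c in model.chains])
    mean = centroids.mean(axis=0)

    if model.metadata.get("stack_of"):
        stacks = model.stack_of()
        labels = [stacks[c.chain_id] for c in model.chains]
        direction, _ = _stack_centered_pca(centroids, labels)
    else:
        cov = np.cov((centroids - mean).T)
        _, v = np.linalg.eigh(cov)
        best = (None, -1.0, None)
        for k in range(3):
            cand = FibrilAxis(mean, v[:, k])
            cand_stacks = detect_stacks(model, cand)
            labels = [cand_stacks[c.chain_id] for c in model.chains]
            direction, frac = _stack_centered_pca(centroids, labels)
            if frac > best[1]:
                best = (direction, frac, labels)
        direction, _, labels = best
        stacks = {c.chain_id: l for c, l in zip(model.chains, labels)}

    first_stack = sorted(set(stacks.values()))[0]
    members = [c for c in model.chains if stacks[c.chain_id] == first_stack]
    span = members[-1].centroid() - members[0].centroid()
    if span @ direction < 0:
        direction = -direction
    return FibrilAxis(mean, direction)


def screw_for(sym: HelicalSymmetry, axis: FibrilAxis, k: float) -> ScrewTransform:
    """Screw operation advancing ``k`` subunits along a one-start helix."""
    return ScrewTransform(axis.point, axis.direction, k * sym.twist, k * sym.rise)


def apply_helical_symmetry(
    subunit: MolecularModel,
    sym: HelicalSymmetry,
    n_layers: int,
    axis: FibrilAxis = Z_AXIS,
    clash_cutoff: float = 1.5,
) -> MolecularModel:
    """Replicate a subunit into an ``n_layers``-layer fibril.

    One-start: copy ``k`` is the subunit rotated by ``k*twist`` and advanced
    by ``k*rise``.  Two-start: a second stack is generated from every layer
    of the first by the pseudo-2_1 screw (``twist/2 + 180`` deg,
    ``rise/2``).  Chain ids are ``<stack letter><layer index>`` ("A0",
    "B3", ...); a single-chain subunit keeps deterministic ids, a
    multi-chain asymmetric unit gets its chain id appended.

    A heavy-atom clash fraction above 1% (pairs closer than
    ``clash_cutoff``) logs a warning but does not fail.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    single = len(subunit.chains) == 1

    def renamed(part: MolecularModel, stack: str, layer: int) -> MolecularModel:
        out = part.copy()
        for ch in out.chains:
            ch.chain_id = (
                f"{stack}{layer}" if single else f"{stack}{layer}{ch.chain_id}"
            )
        return out

    parts: list[MolecularModel] = []
    stack_of: dict[str, str] = {}
    layer_of: dict[str, int] = {}
    stack_letters = ["A"] if sym.starts == 1 else ["A", "B"]
    for letter in stack_letters:
        base = subunit
        if letter == "B":
            base = ScrewTransform(
                axis.point, axis.direction, sym.twist / 2.0 + 180.0, sym.rise / 2.0
            ).apply_model(subunit)
        for k in range(n_layers):
            part = screw_for(sym, axis, k).apply_model(base)
            part = renamed(part, letter, k)
            for cid in part.chain_ids:
                stack_of[cid] = letter
                layer_of[cid] = k
            parts.append(part)

    fibril = concat_models(parts)
    fibril.metadata.update(
        {
            "stack_of": stack_of,
            "layer_of": layer_of,
            "symmetry": {"rise": sym.rise, "twist": sym.twist, "starts": sym.starts},
        }
    )
    _warn_on_clashes(fibril, clash_cutoff)
    return fibril


def _warn_on_clashes(model: MolecularModel, cutoff: float, max_fraction: float = 0.01) -> None:
    import logging

    from scipy.spatial import cKDTree

    xyz, owner = [], []
    for ci, ch in enumerate(model.chains):
        for a in ch.atoms():
            if a.is_heavy:
                xyz.append(a.position)
                owner.append(ci)
    xyz = np.asarray(xyz)
    if len(xyz) < 2 or cutoff <= 0:
        return
    pairs = cKDTree(xyz).query_pairs(cutoff)
    n_clash = sum(1 for i, j in pairs if owner[i] != owner[j])
    frac = 2.0 * n_clash / len(xyz)
    if frac > max_fraction:
        logging.getLogger(__name__).warning(
            "generated fibril has %.1f%% atoms in clashes < %.2f A", 100 * frac, cutoff
        )


def _ensure_stacks(model: MolecularModel, axis: FibrilAxis) -> MolecularModel:
    """Annotate the stack partition if absent, so interleaved two-start
    fibrils are described per stack rather than per layer."""
    if model.metadata.get("stack_of") or len(model.chains) < 4:
        return model
    out = model.copy()
    out.metadata["stack_of"] = detect_stacks(model, axis)
    return out


def _stack_chains_in_axial_order(
    model: MolecularModel, axis: FibrilAxis
) -> dict[str, list[Chain]]:
    stacks = model.stack_of()
    by_stack: dict[str, list[Chain]] = {}
    for ch in model.chains:
        by_stack.setdefault(stacks[ch.chain_id], []).append(ch)
    for label, chains in by_stack.items():
        chains.sort(key=lambda c: float(axis.axial(c.centroid())[0]))
    return by_stack


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[Rotation, np.ndarray, float]:
    """Best-fit rotation+translation mapping point set P onto Q; returns RMSD."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    R, rssd = Rotation.align_vectors(Q - cq, P - cp)
    rmsd = rssd / math.sqrt(len(P))
    t = cq - R.apply(cp)
    return R, t, rmsd


def estimate_helical_parameters(
    model: MolecularModel,
    axis: FibrilAxis | None = None,
    max_rmsd: float = 1.5,
) -> HelicalSymmetry:
    """Recover rise and twist from a fibril model by screw decomposition.

    Every consecutive same-stack chain pair is superposed (Kabsch); the
    rotation angle about the screw axis (signed by the fibril axis
    direction) gives the twist, the axial displacement of the centroid the
    rise.  Values are averaged over all pairs and reported with their
    population SD.  Pairs whose post-fit RMSD exceeds ``max_rmsd`` (in A)
    indicate a non-helical model and raise.
    """
    if axis is None:
        axis = fit_fibril_axis(model) if len(model.chains) >= 3 else Z_AXIS
    model = _ensure_stacks(model, axis)
    by_stack = _stack_chains_in_axial_order(model, axis)

    rotvecs: list[np.ndarray] = []
    displacements: list[np.ndarray] = []
    for chains in by_stack.values():
        for a, b in zip(chains, chains[1:]):
            if not subunits_identical(a, b):
                raise NonHelicalModelError(
                    f"chains {a.chain_id} and {b.chain_id} differ in composition"
                )
            P, Q = a.coords(), b.coords()
            R, t, rmsd = _kabsch(P, Q)
            if rmsd > max_rmsd:
                raise NonHelicalModelError(
                    f"chains {a.chain_id}->{b.chain_id}: RMSD {rmsd:.2f} A after "
                    f"superposition exceeds {max_rmsd} A"
                )
            rotvecs.append(R.as_rotvec())
            displacements.append(Q.mean(axis=0) - P.mean(axis=0))
    if not rotvecs:
        raise NonHelicalModelError("need >= 2 consecutive same-stack chains")

    # refine the axis direction from the screw itself: the mean rotation
    # vector is the helix axis (exact on noiseless data, robust under noise
    # because orthogonal noise components average out); fall back to the
    # centroid axis for untwisted fibrils
    mean_rv = np.mean(rotvecs, axis=0)
    if np.linalg.norm(mean_rv) > 1e-8:
        screw_dir = mean_rv / np.linalg.norm(mean_rv)
        if screw_dir @ axis.direction < 0:
            screw_dir = -screw_dir
    else:
        screw_dir = axis.direction
    # signed twist = axial component of each rotation vector (unbiased:
    # orthogonal noise components project out)
    twists = [math.degrees(rv @ screw_dir) for rv in rotvecs]
    rises = [float(d @ screw_dir) for d in displacements]

    starts = 2 if len(by_stack) == 2 else 1
    return HelicalSymmetry(
        rise=float(np.mean(rises)),
        twist=float(np.mean(twists)),
        starts=starts,
        rise_sd=float(np.std(rises)),
        twist_sd=float(np.std(twists)),
    )


@dataclass(frozen=True)
class CrossoverResult:
    """Crossover distance in nm; ``untwisted`` flags a straight fibril."""

    distance_nm: float
    untwisted: bool = False

    def __float__(self) -> float:
        return self.distance_nm


def crossover_distance(sym: HelicalSymmetry) -> CrossoverResult:
    """Axial distance over which the fibril twists by 180 deg, in nm.

    Closed form: ``rise * (180 / |twist|) / 10``.  A twist of zero yields an
    explicit untwisted result (infinite distance), not an exception.
    """
    if sym.twist == 0:
        return CrossoverResult(math.inf, untwisted=True)
    return CrossoverResult(sym.rise * (180.0 / abs(sym.twist)) / 10.0)


def fibril_width(
    model: MolecularModel, axis: FibrilAxis | None = None, percentile: float = 95.0
) -> float:
    """Fibril width in nm as twice a robust radial extent.

    Defined as 2x the ``percentile``-th percentile (default 95) of
    heavy-atom distances from the axis.  This is a model-side analogue of
    image-measured widths and only approximately comparable to them (image
    widths include projection and blur); the percentile is configurable.
    """
    if axis is None:
        axis = fit_fibril_axis(model)
    radii = axis.radial(model.coords(heavy_only=True))
    return float(2.0 * np.percentile(radii, percentile) / 10.0)


def axial_height_change(
    chain: Chain,
    axis: FibrilAxis,
    res_i: int,
    res_j: int,
    atom_name: str = "C",
) -> float:
    """Axial separation (A) between one named atom of two residues.

    Measures the within-chain height change along the fibril axis, e.g.
    between the carbonyl carbons of the first and last strand residues.
    """
    ri = chain.residue(res_i)
    rj = chain.residue(res_j)
    if ri is None or rj is None:
        from .errors import MissingAtomError

        missing = res_i if ri is None else res_j
        raise MissingAtomError(f"chain {chain.chain_id}: residue {missing} absent")
    pi = ri.require_atom(atom_name).position
    pj = rj.require_atom(atom_name).position
    return float(abs((pj - pi) @ axis.direction))


def strand_spacing(model: MolecularModel, axis: FibrilAxis | None = None) -> float:
    """Mean axial separation (A) of equivalent CA atoms in consecutive
    same-stack chains -- the cross-beta strand-strand spacing."""
    if axis is None:
        axis = fit_fibril_axis(model)
    model = _ensure_stacks(model, axis)
    by_stack = _stack_chains_in_axial_order(model, axis)
    seps: list[float] = []
    for chains in by_stack.values():
        for a, b in zip(chains, chains[1:]):
            ca_a, ca_b = a.coords(atom_name="CA"), b.coords(atom_name="CA")
            if len(ca_a) == 0 or len(ca_a) != len(ca_b):
                raise NonHelicalModelError(
                    f"chains {a.chain_id}/{b.chain_id}: CA sets not equivalent"
                )
            seps.append(float(np.mean(np.abs((ca_b - ca_a) @ axis.direction))))
    if not seps:
        raise NonHelicalModelError("need >= 2 same-stack chains for strand spacing")
    return float(np.mean(seps))


def mirror_model(model: MolecularModel) -> MolecularModel:
    """Reflect a model through the yz plane (x -> -x); flips handedness."""
    out = model.copy()
    for a in out.atoms():
        a.position = a.position * np.array([-1.0, 1.0, 1.0])
    return out


def morphology_summary(
    model: MolecularModel, axis: FibrilAxis | None = None
) -> MorphologySummary:
    """Crossover distance, width, rise and twist of a fibril model."""
    if axis is None:
        axis = fit_fibril_axis(model)
    sym = estimate_helical_parameters(model, axis)
    return MorphologySummary(
        crossover_distance=crossover_distance(sym).distance_nm,
        width=fibril_width(model, axis),
        rise=sym.rise,
        twist=sym.twist,
    )
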