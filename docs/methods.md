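# Methods

This note records the models, conventions and numerical choices behind
`fibrilkit`, and what the synthetic test fibrils do and do not emulate.

## Helical model and conventions

A fibril is one or two stacks of conformationally identical subunits
related by a screw operation: rise *d* (Å per subunit along the axis) and
twist *θ* (degrees per subunit about it). Twist is signed: positive means a
right-handed screw advance when sighting along the +axis direction, and the
axis direction points from the lowest- to the highest-index subunit of the
first stack. The two-start ("pseudo-2₁") arrangement generates the second
stack from the first by a screw of *d*/2 and *θ*/2 + 180°, so the stacks
interleave with an axial offset of half a cross-β repeat. With |θ| of order
1–2°, the crossover distance (apparent half-turn repeat in projection
images) is *d*·180/|θ| in Å; an untwisted fibril returns an explicit
"untwisted" result with infinite crossover rather than an error.

**Axis fitting** uses the principal direction of the chain centroids, with
each stack's centroids centered on their own mean so the radial offset
between two stacks cannot masquerade as the axis. When the stack partition
is unknown it is inferred by deterministic two-means clustering of the
centroid azimuths; each of the three global principal directions is tried
as the clustering axis and the candidate whose per-stack residuals are most
one-dimensional wins. This assumes the chains of one stack drift little in
azimuth over the model (true for |θ| of a few degrees; a steep one-start
helix whose chains wind far around the axis would defeat the clustering).

**Parameter estimation** superposes every pair of consecutive same-stack
chains (Kabsch, all atoms) and reads the screw off the transform. The axis
direction is then refined as the mean rotation vector of all pairs — exact
on noiseless data and unbiased under coordinate noise — and the twist of
each pair is the axial component of its rotation vector (again unbiased:
noise components orthogonal to the axis project out, whereas the norm of
the rotation vector is positively biased for small angles). Pairs whose
post-superposition RMSD exceeds 1.5 Å indicate a non-helical model and
raise. Reported SDs are population SDs over pairs.

**Width** is reported as twice the 95th-percentile heavy-atom radial
distance from the axis (percentile configurable). Image-measured widths
include projection and blur, so this model-side statistic is only an
approximate analogue; reports flag it as such.

## β-sheet twist statistic

Φ and Ψ follow the standard definitions (Φ = C(i−1)–N–CA–C,
Ψ = N–CA–C–N(i+1)); dihedral signs were cross-checked against an
independent implementation (biotite). Chain breaks (consecutive CA–CA >
4.5 Å) are treated as termini. The handedness statistic is the mean ±
population SD of Φ+Ψ over β-strand residues, pooled over all chains
(per-chain means are also reported); mean < 0 ⇒ right-handed sheet twist,
mean > 0 ⇒ left-handed, |mean| < 0.5° ⇒ indeterminate (below dihedral
reproducibility).

Strand assignment offers two methods. The default computes backbone
H-bonds with the Kabsch–Sander electrostatic energy
(E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
E < −0.5; amide H placed 1 Å from N opposite the preceding carbonyl;
sequence-adjacent pairs excluded). The ladder rule is adapted to
in-register cross-β stacking: the classic parallel/antiparallel bridge
index patterns never fire on an ideal in-register stack (its bond pattern
alternates parity along the strand), so a residue is labeled strand when it
has ≥ 2 inter-chain H-bonds and an adjacent residue is likewise bridged.
Manual per-chain residue ranges are a first-class alternative, because
published strand definitions are typically curated by hand and the
statistic depends on the residue selection.

## Contacts, neighbors, salt bridges

Contact search uses an exact spatial index (cKDTree); tests verify set
equality against the O(n²) oracle. Neighbor counts use a 5.0 Å heavy-atom
cutoff by default, with a sensitivity helper over 4.0–6.0 Å, since the
biological claim is a count, not a distance; counts are flagged
unconverged unless the target chain has at least two same-stack chains on
each axial side. Salt bridges pair explicit acid atoms (Asp OD1/OD2,
Glu OE1/OE2, C-terminal OXT/O) with base atoms (Arg NE/NH1/NH2, Lys NZ,
His ND1/NE2, N-terminal N) at a minimum N–O distance ≤ 4.0 Å; ≥ 2 atom
pairs within the cutoff marks a bidentate bridge.

## Interface energetics

SASA is Shrake–Rupley on probe-expanded spheres (probe 1.4 Å, 960
deterministic golden-spiral points per atom by default; quadrature error
< 0.5% against 4000 points, and the isolated sphere matches
4π(r+probe)² to < 1%). vdW radii: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80,
H 1.20 (hydrogens are ignored in SASA), unknown elements fall back to
1.70 Å with a warning.

The stack–stack energy model is deliberately simple and PISA-like in
spirit, not in numbers:

* buried area = [SASA(A) + SASA(B) − SASA(AB)] / 2;
* ΔG_int = Σ σ(class)·ΔASA per atom, with σ = −0.105 kJ/mol/Ų for C and S
  (hydrophobic burial favorable, the Chothia-scale ~25 cal/mol/Ų), +0.02
  for neutral N/O, +0.25 for charged-group N/O unless that atom takes part
  in a salt bridge within the complex (then 0);
* ΔG_diss = −ΔG_int − TΔS with a single rigid-body dissociation entropy
  term TΔS = 12 kJ/mol per two-stack complex (configurable). The default
  is calibrated so that per-layer interface strengths in the ~30:1 ratio
  reported for the two studied AA fibril morphologies (~13.7 vs ~0.4
  kJ/mol/layer) give stability thresholds bracketing the reported ~2 and
  ~30 layers (0.4·30 = 12 ≤ 13.7·2).

Absolute kJ/mol values from this model will not match PDBePISA, whose
internals are not re-derivable; the package claims signs, orderings and
the layer-number dependence only. The layer curve reports both the
asymptotic per-layer slope (mean increment of −ΔG_int for n ≥ 6) and the
overall per-layer mean, since either reading of "per layer" is defensible.

## Synthetic fibril generator

Backbones are grown residue-by-residue at target Φ/Ψ with ideal bond
lengths and angles (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231,
CA–CB 1.526 Å; ω = 180°); CB is placed tetrahedrally with L chirality
(validated against ideal residue templates). Asp, Glu, Lys, Arg and Ile
get minimal all-trans side chains (acid carboxylates built in the staff
plane) so that salt bridges and charged-vs-hydrophobic interface chemistry
exist in the stand-ins; other residues stop at CB. A β-arch subunit is two
such strands, antiparallel in projection and offset radially, joined by a
four-residue connector whose junction atoms are placed at the flanking
strands' target dihedrals (so the statistic of strand residues is
unpolluted) and whose interior follows a smooth arc with approximate
covalent geometry; connector carbonyls point within the turn plane so
stacked connectors never register as strands. Axial height structure
enters three ways: a whole-chain linear ramp (`height_modulation`, scaled
so the first-to-last carbonyl-carbon height change equals the set value
exactly), a constant axial offset of the second strand
(`arch_axial_offset`), and a rigid tilt of the second strand
(`strand2_ramp`, implemented as a rotation so internal dihedrals stay
exact). Gaussian coordinate noise (seeded, reproducible) is added after
symmetry expansion so per-chain noise is independent and the symmetry
ground truth stays exact underneath.

Two presets encode the studied fibril architectures as synthetic
stand-ins. The murine-like preset (rise 4.8 Å, twist −1.15°, pseudo-2₁,
Φ+Ψ = +8°) has its second strand radially outward with a 6 Å axial offset
— interdigitating with same-stack layers i±2 — and a single Asp/Arg pair
whose side chains reach the axis, forming reciprocal bidentate cross-stack
salt bridges and nothing else: six interaction partners per chain
(4 same-stack + 2 cross-stack) and a per-layer interface energy near zero.
The human-like preset (rise 4.7 Å, twist +1.54°, Φ+Ψ = −2°) carries inner
hydrophobic Ile side chains forming a self-complementary zipper-like
cross-stack interface near the axis, and a strongly tilted outer strand
that interdigitates up to i±4 in its own stack: ten partners per chain and
a large hydrophobic per-layer interface energy. Preset radii and offsets
were chosen so these architectural features produce deep (≳1 Å margin)
contacts, stable across contact cutoffs of 4.0–6.0 Å.

What the stand-ins do **not** emulate: real side-chain packing and
rotamers (tips may approach closer than van der Waals contact), solvent,
the specific sequences of the fibril proteins, the coupling between strand
dihedrals and supramolecular twist (the generator sets them independently,
so dihedral–twist consistency is only enforced under mirror symmetry,
where both must flip together), and the full seven/nine-strand folds of
the real subunits. Tests passing on these stand-ins therefore demonstrate
that the measurement machinery recovers known structural conditions — not
that the deposited models would yield identical numbers.

## Masses

Average residue masses are the default (intact-protein MALDI/ESI context,
±2 Da tolerance); monoisotopic masses are switchable. No post-translational
modifications or terminal chemistry beyond one water per peptide are
modeled. Fragment matching enumerates N-terminal prefixes (or suffixes, or
all substrings) and reports every candidate within tolerance sorted by
|Δ|; unmatched masses are reported, never raised.

## Problem sizes and determinism

Synthetic analyses use fibrils of 9 layers/stack (murine-like) and 11
layers/stack (human-like) — the smallest sizes with converged central-chain
neighbor counts — and layer-stability curves up to n = 12 (murine-like) and
n = 8 (human-like) at 480 SASA points per atom, which keeps the full test
suite under two minutes while leaving the curve shapes unchanged relative
to finer settings. All randomness flows through explicit integer seeds
(numpy Generator); reports contain no timestamps, so identical inputs give
byte-identical JSON.

## Known limitations

* Stack auto-detection assumes ≤ 2 stacks and small azimuthal drift.
* The Kabsch–Sander adaptation targets cross-β inter-chain ladders; it
  does not reproduce full DSSP (helices, turns, intra-chain sheets).
* PDB output renames chains deterministically when ids exceed one
  character; mmCIF preserves ids and is the preferred format.
* The interface energy is a solvation-area model: no explicit hydrogen
  bond, electrostatic screening or conformational entropy terms.
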