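# Methods

This note records the geometric conventions, the synthetic-data model and
the numerical choices behind `nucgeom`, in the spirit of a model
description: what is computed, under which assumptions, and what the
synthetic validation does and does not establish about real structures.

## Reference frames and parameter conventions

**Base frames.** Each base carries an embedded idealized planar template in
the standard nucleic-acid reference frame (origin in the pair plane, x
toward the major groove, y toward the strand-1 backbone, z along the
strand 5′→3′ direction; the Watson–Crick partner of an ideal pair is the
180° rotation about x). A frame is fitted by least-squares rigid
superposition (Kabsch/SVD, proper rotation enforced) of the template ring
atoms — 9 for purines, 6 for pyrimidines — onto the observed coordinates;
the fit RMSD is reported and a warning is raised above 1.0 Å. The fit
agrees with an independent quaternion (Horn) superposition to numerical
precision (tested).

**Basepair and step parameters.** The strand-2 frame is flipped to the
strand-1 sense (y, z negated). The relative rotation between two frames is
factored in the symmetric El Hassan–Calladine form
`R = Rz(ω/2 − φ) · Ry(Γ) · Rz(ω/2 + φ)`: the bend Γ splits into components
about the mid-frame y (roll, propeller) and x (tilt, buckle), and ω is the
twist/opening angle, kept in (−180°, 180°]. The mid frame is the geodesic
half-rotation with averaged origins; translations (shift/slide/rise) are
the origin displacement in mid-frame coordinates. This decomposition and
its exact inverse are shared by the analysis and the builder, so the
round-trip identity is structural, not approximate.

Two symmetry facts about this convention (both tested):
exchanging strand roles negates tilt and shift and preserves roll, twist,
slide, rise; for intra-pair parameters it negates buckle and preserves
propeller **and opening** — the inverse relative rotation combines with the
flip of the pair frame's y and z axes so that only the x rotation changes
sign. Published per-step values from other programs are therefore matched
within a convention tolerance (±2° angles, ±0.3 Å translations), not
bit-exactly.

**Zp.** For each step the two bridging phosphodiester phosphates (one per
strand, each on the step's 3′ side in its own strand sense) are expressed
in the mid-step frame; the strand-2 z is sign-corrected (the step dyad
flips z), and Zp is the mean. Classification: Zp > 1.3 Å A-like,
Zp ≤ 0.8 Å B-like, intermediate otherwise. The literal alternative of
taking both phosphates of the 3′-side basepair is available
(`convention="pair3"`) but mixes duplex-level and strand-level 3′
directions and offsets one contribution by rise/2.

**Local and global axes.** The local helix axis of a step is
`normalize((x₂ − x₁) × (y₂ − y₁))`, oriented toward increasing basepair
index; a pure translation degenerates and falls back to the mid-frame z
with a warning. The angle between axes of overlapping steps is the
successive bending angle. Global fragment axes (tetra-/pentanucleotide)
are total-least-squares lines through the **basepair centres** of the
fragment: a line fitted to raw C1′ atoms of a fragment this short tilts
with the helical phase of the partial turn it covers (lateral spread of
the sugar ring exceeds the fragment's axial extent), whereas the centres
sit on the helix axis at every fragment size. The signed inter-fragment
angle takes the sign of the axes' cross product against the mean pair-x
direction at the junction; this reference degenerates for a twist-free
roll-bent arc, where only the magnitude is meaningful.

## Backbone classification

Torsions follow the IUPAC sign convention (validated against an
independent implementation) and are reported in [0°, 360°). The linkage
n → n+1 carries ε, ζ from nucleotide n and α, β, γ from n+1; δ, χ and the
Altona–Sundaralingam pseudorotation P are reported for n+1. BI/BII is the
sign of ε − ζ wrapped to (−180°, 180°]: ≤ 0 BI, > 0 BII. The seven-state
α/γ/BI-BII classification uses half-open [lo, hi) ranges with 360° ≡ 0°;
rows with a specific BI/BII requirement are matched before wildcard rows
sharing the same ranges (precedence 1, 7, 2, 3, 5, 4, 6), and (α, γ)
combinations outside every row are reported as unclassified rather than
forced into a state, so state tallies are never silently padded.

## Regions and kinks

With the pseudo-dyad at SHL 0, the five basepairs within ±2 of each
integral SHL face the octamer with their major groove (region III), the
five at +3…+7 with their minor groove (region I), and the two steps
straddling the block boundaries are backbone-facing (region II); each
10-bp period contributes 4/4/2 steps and the layout is mirror-symmetric
about the dyad. A step is kinked when tilt or roll lies strictly beyond 3σ
of its free-B-DNA mean; the bundled roll (mean 1.2°, σ 5.3°) and slide
(mean 0.2 Å, σ 0.8 Å) references encode the published free-B-DNA bounds,
while the tilt mean/σ must be supplied by the user — no invented default.
A 1e-9° guard keeps values printed exactly on a bound inside the elastic
envelope. "Compensated" is formalized as: some step within ±2 positions
carries an opposite-sign roll deviation of at least the kink's own
magnitude; this is an interpretation of a narrative criterion.

## Curvature at the 36-mer scale

For every overlapping window of basepair centres (terminal basepairs
excluded; a 146-bp particle yields 109 windows), the package computes a
3-D circle fit (best-fit plane by principal axes, Kåsa algebraic seed,
Levenberg–Marquardt geometric refinement with 1e-15 tolerances; RMSD
measured in 3-D so out-of-plane writhe is penalized), the line-fit RMSD,
d/l (end-to-end distance over the contour length, defined as the sum of
consecutive centre separations), and moment-of-inertia ratios with unit
masses at the centres. Windows enter the per-structure summary only when
circle RMSD ≤ 1.5 Å and line RMSD ≥ 10.8 Å. Rigid-motion invariance holds
to 1e-7 for the iterative circle fit and to 1e-9 for the closed-form
metrics.

## Correlations

Per-lag Pearson correlation over the full overlap, each segment centred by
its own mean (lag 0 ≡ 1); series are indexed by dyad offset and truncated
to the common offset range so that zero lag aligns SHL 0 across structures
of different length. A biased, full-series-normalized estimator is
available behind a flag; estimator choice moves magnitudes, not peak
positions, and peak positions are the tested surface.

## The synthetic-data model

The builder composes basepair frames from step parameters with the exact
inverse of the analysis decomposition, splits the intra-pair rotation
symmetrically between the two bases, and places full heavy-atom
nucleotides rigidly from per-conformer templates. Templates are
constructed from internal coordinates (NeRF): the glycosidic torsion
places O4′, a one-dimensional root solve closes the deoxyribose ring at
the ideal C4′–O4′ bond length (the negative wedge branch selecting the
natural D-sugar), and the 3′ phosphate group (P, O5′, OP1, OP2 of the
next residue) is extended at an explicit ε/ζ pair, making the BI/BII/A
distinction an exact template property. The conformer internal
coordinates were calibrated once, at design time, against ideal helices
so that the assembled duplex has a continuous backbone (O5′–C5′ ≈ 1.45 Å),
canonical state-1 torsions on both strands, and the B-form (zp ≈ 0.3 Å
with propeller −12°) or A-form (zp ≈ 2.2 Å) bridging-phosphate position;
the resulting constants are frozen in `builder.py`.

The nucleosome preset phases a sinusoidal roll modulation to the
superhelix location — roll = A·cos(2π·s/10.2) with s the mid-step dyad
offset — so minor-groove-in blocks carry negative and major-groove-in
blocks positive roll; slide tracks the same phase (0.2 ± 0.35 Å), twist is
the 360°/10.2 baseline, rise 3.4 Å, propeller −12°. The amplitude
A = 9.3° closes one 360° bend per ≈ 77 bp of superhelical circumference
and yields a 36-mer radius of curvature of ≈ 42 Å, the nucleosomal value.
Optional Gaussian noise is applied to the parameters (angle and
displacement σ separately) before construction, so analysis error grows
monotonically with the injected noise.

What the generator does **not** emulate: sequence-dependent equilibrium
geometry, thermal/crystallographic disorder, protein contacts, stretching
defects, and backbone relaxation — in particular, a BII or A conformer
perturbs the emergent α/γ of the downstream linkage (rigid templates
cannot relax it), so synthetic BII linkages do not reproduce the canonical
state-7 α/γ signature, and the synthetic superhelix is smoother (ROC sd
≈ 0.1 Å) than crystal structures (≈ 2 Å). Passing the synthetic suite
therefore establishes the correctness of the geometry pipeline and its
conventions, not the statistical properties of real nucleosomal DNA;
reproducing the crystal-structure censuses requires the 29 PDB entries as
input, which the package analyses through the same manifest-driven
pipeline.

## Problem sizes used in tests and the acceptance script

Synthetic duplexes of 20–60 bp exercise unit-level oracles; the full
study conditions use one superhelix per particle length (145/146/147 bp),
a 79-step mixed A/B ensemble and a 48-bp canonical duplex. The complete
suite and the acceptance script each run in well under five minutes on a
single CPU.
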