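# Methods

`chondroshape` implements three connected models of oriented clonal growth
in sheet-shaped embryonic cartilage: an off-lattice simulation of clonal
chondrocyte proliferation (`cell_layer`), a growing-polarised-tissue
finite-element sheet model of nasal-capsule shape transitions
(`sheet_model`), and the clone-envelope micro-geometry statistics used to
quantify lineage-tracing data (`clone_metrics`), together with synthetic
ground-truth generators (`synthetic`) that make every statistic testable
without any external data.

## 1. Clonal cell-layer simulation

**Model.** Cells are equal-radius spheres (radius 0.5 in cell-diameter
units) in a laterally confined slab: rigid walls in x and y, free in z.
The founder population is a planar monolayer on a grid at the mid-plane
(z = 0), each founder its own clone — a laterally space-constrained
initial configuration. The simulation is event-driven: per-cell division
waiting times are Gamma-distributed with mean τ and coefficient of
variation `cv` (cv = 0 gives synchronous divisions), and each lineage
generation executes at most `n_max` divisions, so a founder clone grows to
at most 2^n_max cells.

**Division orientation.** A static polarization field prescribes the mean
division direction: `none` (isotropic), `one_sided` (+axis everywhere), or
`two_sided` (away from the founder mid-plane toward the nearer surface,
producing oppositional column growth). The realized direction is drawn
from a von Mises–Fisher distribution with concentration κ = b, the
*determinacy* of the response: b → 0 recovers uniformly random directions,
large b near-deterministic polarized divisions. vMF is the canonical
one-parameter family interpolating between those two prescribed limits.
A cell lying within half a radius of the mid-plane (in practice the
founder itself) has no defined side under the two-sided rule; its sign is
drawn at random per division, which is what seeds the up/down oppositional
columns — a deterministic tie-break would grow one-sided. Polarized cells
farther than `extent_L` from the mid-plane become permanently
non-proliferative (the thickness-control mechanism of a two-sided
gradient); they can still be displaced passively.

**Mechanics.** A daughter is placed one diameter from its mother along the
sampled direction; overlaps are then resolved by damped pairwise sphere
repulsion with rigid-wall projection (position-based sweeps with
contact-averaged corrections, neighbour lists via a k-d tree). Defaults:
overlap tolerance 1 % of a diameter, at most 500 sweeps, exactly
coincident cells separated along +x. This is the simplest mechanics
consistent with daughter cells pushing and intercalating into the layer.

**Observables.** The columnar order parameter S is the mean absolute
projection of the mother→daughter displacement unit vectors (recorded at
division time, before relaxation) on the sheet normal: S = 1 for perfect
columns, 1/2 for uniform random directions (E|cos θ| = 1/2 on the sphere),
0 for in-plane divisions. Alternatives (clone principal axes,
nearest-neighbour vectors) would also be defensible; displacement at
division is the least confounded by packing. The thickness map bins cells
laterally (default 1 diameter) and reports (max z + r) − (min z − r) per
occupied bin; regularity = 1 − CV over occupied bins, clipped to [0, 1].

**Behaviour and limitations.** Mean S rises monotonically with b
(≈ 0.50, 0.53, 0.70, 0.90, 0.99 at b = 0, 1, 3, 10, 100 under the default
16-founder, 4-round configuration) and is essentially independent of
division-time variability, because direction draws do not depend on
timing. The regularity advantage of a two-sided gradient over no gradient
is robust at biological column depths (clones of ~4 cells, matching the
~5–6 cells per column reported for control sheet cartilage) and is tested
there (64 founders, n_max = 2, 20 replicates). At unrealistically deep
columns (16 cells/clone) the advantage vanishes in this implementation:
the random up/down allocation at the founder plane offsets whole columns
vertically by a binomial imbalance, roughening the surface as much as
unpolarized growth does in a volume-conserving confined box. Mean
thickness itself is volume-dominated in the confined domain and is
reported but not compared across conditions.

## 2. Growing-sheet model of the nasal capsule

**Canvas.** A flat trapezoid (base width 1, tip width 0.6, height 1.2 —
proportions chosen to resemble the embryonic anlage; configurable) is
triangulated on a 30 × 30 grid with mirror-symmetric diagonals: exactly
1800 elements, never subdivided. Per-vertex factors, linearly interpolated
across elements (per-element value = vertex mean): POL (the polariser,
linear from 1 at the proximal base to 0 at the distal tip), MID (the
proximo-distal midline column), CHEEKS (two smooth Gaussian slow-zone
bands at ±0.6 of the half-width, σ = 0.12 laterally and 0.15
proximo-distally, centred mid-sheet; offset 10 % distally in the
free-midline variant).

**Setup phase (steps 0–12).** The flat sheet is carried by a prescribed
parametric mapping into the starting shape: an arched vault z ∝
cos(πu/2) scaled by the local trapezoid width, minus (in the midline
variants) a central Gaussian of equal amplitude so the midline sits at
z = 0 in a groove between two flank ridges (amplitude 0.25, groove σ =
0.25). The `no_midline` variant keeps the plain dome. At the end of setup
the rest geometry (edge lengths and hinge dihedrals) is re-baselined so
the starting shape is stress-free, and in the `fixed_midline` variant the
MID vertices become z-anchored (the nasal septum as a rigid anchor).

**Growth (from step 13).** The polarity regulatory network orients growth
by the in-plane finite-element gradient of POL, i.e. parallel to the
midline. The growth-rate network uses pro(n,x) = 1 + nx and
inh(n,x) = 1/(1 + nx): isotropic K = 0.05·inh(100, iCHEEKS) per step, or
anisotropic K∥ with the same law and K⊥ = 0. Each step scales per-edge
rest lengths (anisotropically via the growth tensor diag(1+K∥, 1+K⊥) in
the polarity frame, averaged over the edge's adjacent elements) and then
relaxes the connected sheet quasi-statically — the distinction between
specified and resultant growth.

**Elasticity.** The sheet is an edge-spring network (stiffness 1.0) with a
hinge-bending penalty k_b(θ − θ0)² per interior edge (k_b = 10⁻³ in
stretch units; analytic dihedral gradients, verified against finite
differences in the test suite). Relaxation is L-BFGS-B on the free
coordinates (anchored z dofs are eliminated, not penalised) to a projected
gradient below 10⁻⁶. Rigid-body drift is removed after each step by
rigidly re-pinning the base row onto its post-setup position — restricted
to in-plane modes when the midline is z-anchored, since a z translation
would fight the anchor. The model is fully deterministic.

**Shape metrics** are computed after putting grown and reference mesh in
the reference's intrinsic frame (metrics are therefore invariant to a
rigid motion applied to both): elongation ratio (tip-row to base-row
centroid distance over its post-setup value), lateral bend angle (mean
signed difference of cross-section slopes between the central region and
the outer flaps, positive = flaps folded ventrally), groove depth (flank
ridge minus midline z, as a change from the reference), flatness
(bounding-box z extent over x extent), and longitudinal bend (dorsal
rotation of the distal midline profile relative to the reference).

**Emergent behaviour.** With 15 growth steps (linear growth 1.05¹⁵ ≈ 2.1,
the scale of the modelled developmental transition): uniform unconstrained
growth reproduces the closed form (area × (1+K)^2t within 1 %); the
lateral bends appear only when the CHEEKS slow zones are enabled (|bend|
ratio ≈ 10²); anisotropic (polarized) growth elongates the anlage faster
than isotropic growth through mid-trajectory — the comparison is made at
step 10 because later the isotropic run's accumulated lateral stress
snap-buckles the structure longer while the anisotropic meridian is held
taut by the slow zones; the free-midline (groove) model flattens and curls
its tip dorsally while the no-midline dome curls ventrally — the inverted
longitudinal bend — and only the groove model keeps a positive groove
depth. The fixed midline stays exactly in the z-plane at every step.

**Limitations.** The original continuum finite-element elasticity is
replaced by the spring/hinge discretisation; stiffnesses are defaults, not
fitted. The starting-shape mapping and zone geometry are qualitative
reconstructions (exact trapezoid, band widths and setup target were only
ever shown graphically), so only orderings and signs of the scenario
outcomes are meaningful, not their magnitudes.

## 3. Clone-envelope geometry

For a clone cluster (≥ 2 distinct positions), the principal axis is the
leading eigenvector of the centred second-moment matrix; elongation ratio
√(λ₁/λ₂) with an infinite sentinel for collinear clusters. α is the angle
between that axis and the local surface normal, folded to [0°, 90°]:
small α = transverse clonal column, 90° = in-plane elongation. β is the
angle between the least-squares plane normals of the two opposing surface
patches framing the locality; β ≤ 20° (inclusive) classifies a locality as
sheet-like. Orientation data are axial, so all angles fold to [0, 90];
rose histograms use right-open bins (last bin closed), default width 10°.
The α–β association uses Spearman rank correlation with average-rank ties
(NaN sentinel for constant input). The summary t-test is the
pooled-variance unpaired Student form reconstructed from printed
mean ± s.e.m. and n (SD = sem·√n, df = n₁+n₂−2); on the published
olfactory-cartilage summaries (5.9 ± 0.23, n = 4 vs 4.3 ± 0.25, n = 3) it
returns p ≈ 0.0055, matching the published call to rounding. Same-label
cells can be split into spatially separate clusters by single-linkage
clustering with a 2-diameter cut, needed for dense real tracing; the
synthetic generator controls this regime so the default pipeline does not
re-cluster.

## 4. Synthetic data

`generate_clone_field` plants clones on a lateral grid inside a flat slab
whose faces are the surface patches (true β = 0): columnar envelopes stack
cells one spacing apart along a direction at a planted tilt (true α) from
the slab normal, with optional Gaussian angular jitter; spherical
envelopes are isotropic Gaussian blobs (the shape seen when the polarity
response is disrupted). Clone sizes are Poisson around the configured mean
truncated at 2 (no clone-size law is published; the default mean of 5
matches reported column sizes). `generate_surface_pair` builds two planar
point clouds at an exact dihedral with Gaussian out-of-plane noise.
`generate_directions` draws vMF samples; `estimate_concentration` is the
standard maximum-likelihood approximation b̂ = R̄(3 − R̄²)/(1 − R̄²). All
generators are deterministic under their seed and write truth as separate
JSON records, never inside the data tables. What the generators do *not*
emulate: imaging artefacts (point-spread, section thickness, colour
misassignment), curved slabs, or realistic in-vivo clone-size
distributions — so passing round-trip tests demonstrates correctness of
the estimators, not robustness to microscopy noise.

## Numerical choices

- Overlap relaxation: tolerance 1 % of a diameter, ≤ 500 sweeps,
  contact-averaged corrections (stable in dense packings), +x tie-break
  for coincident cells.
- Sheet relaxation: L-BFGS-B, projected-gradient tolerance 10⁻⁶, ≤ 3000
  iterations per step; dihedral rest angles are wrapped differences so
  angles near ±π cannot alias.
- Degenerate inputs raise explicit errors: empty division logs, empty
  thickness masks, clusters with coincident points, collinear surface
  patches, the inh pole at nx = −1, non-1800-element mesh resolutions.
- Replicated comparisons (order vs b, regularity vs gradient) use fixed
  seed sets 1000–1019 / 2000–2019; all randomness flows through
  `numpy.random.default_rng`.

## Problem sizes

Defaults were chosen so a full test run stays lightweight: cell-layer
replicates use 16–64 founders with 2–4 division rounds (≤ 256 cells); the
canvas is the fixed 1800-element mesh with 15 growth steps; direction
samples for estimator checks use 10⁴–10⁵ draws.
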