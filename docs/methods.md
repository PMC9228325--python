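# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `bovimetry`. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## The synthetic heifer

### Body plan

The generator's animal is a union of smooth solids in a fixed convention
(x muzzle→tail, y lateral, z up, ground at z = 0):

* **trunk** — an elliptical cylinder (lateral semi-axis b, vertical
  semi-axis c) closed by two half-ellipsoid caps of lengths `cap_front`
  and `cap_rear`;
* **legs** — four vertical cylinders of radius r with hemispherical feet,
  attached under the cylindrical part of the trunk;
* **neck and head** — a horizontal cylinder buried at one end in the front
  cap and at the other in an ellipsoidal head.

This body plan makes every published trait a closed form: chest depth is
2c; heart girth is the exact ellipse perimeter (complete elliptic
integral); withers height is ground clearance + 2c; hip/buttock widths are
the lateral section extents at the landmark stations (the rear-cap taper
makes the buttock width adjustable independently of the trunk width);
trunk/leg/head volumes and areas are textbook formulas. The only
non-closed-form pieces are the three primitive overlaps (leg∩trunk,
neck∩front-cap, neck∩head). Their volume and hidden-area corrections are
computed by low-dimensional quadrature (1D in the leg and neck angle, 2D
over the neck disk; the neck∩head overlap is fully closed-form). The
resulting ground truth is accurate to ~10⁻⁴ relative — far below the 3%
round-trip tolerance the measurement tests use — without a voxel oracle.

### Meshing

Meshes are extracted from a signed-distance field (minimum over the
primitives' approximate SDFs; every zero set is exact) by marching cubes.
`resolution` is the number of cells along the longest bounding-box axis;
128 (the default used in tests) puts every measured trait within ~0.5% of
ground truth, and a degenerate sphere preset reproduces 4πr²/（4/3)πr³ to
0.1% at resolution 256. Marching cubes can emit isolated zero-area
slivers where the surface is tangent to grid planes; components carrying
< 10⁻⁶ of the total area are discarded before the watertightness check.

### Stage presets and growth model

Seven presets (`month02` … `month20`) are solved at run time from a
bundled reference table of published stage means for five growing Holstein
heifers (ages ~62–605 days): CD fixes c, HG fixes b by exact
ellipse-perimeter inversion, WH fixes the leg length, KW fixes the
rear-cap taper at the buttock station, and the published image volume
fixes the trunk length. Two caveats are deliberate and documented:

* **The reference table's "hip width" column is stored as withers
  height.** Its values (e.g. 1335.3 mm at 12 months) coincide with the
  withers heights quoted in the accompanying text (133.5 cm at one year),
  not with a plausible hip width; true hip widths were evidently not
  published. The generator ties hip width to the trunk width instead
  (width/girth ≈ 0.25) and the package treats WH and HW as distinct
  traits throughout.
* **The preset BSA runs ~10% below the published image BSA** (4.65 m² vs
  5.21 ± 0.32 m² at 12 months — inside the ±2 SD envelope, but low).
  Smooth primitives carry none of the fine surface detail (folds, ears,
  tail, coat) of a scanned hide, and at fixed girth, depth and volume the
  body plan's area saturates: enlarging appendages adds area but also
  volume, which the trunk-length solver removes again. Appendage sizing
  (leg radius 0.085 m, neck radius 0.095 m, head 0.40 × 0.14 m at the
  12-month scale, scaled by withers height elsewhere) was chosen once to
  sit as close to the published BSA as the plan allows.

Growth over age: BW follows a monomolecular (Brody) curve — the standard
"asymptotic" growth form in cattle — with parameters fitted at run time to
the reference table's BW-vs-age means (the fitted asymptote is large
because heifers to 20 months are far from mature weight, making the curve
near-linear over the observed range, ~0.9 kg/d). Each linear trait and BSA
follows an allometry a·BW^b fitted on the same table (girth exponent
≈ 1/3, as geometric similarity predicts). Volume is BW divided by a
constant body density of 900 kg/m³, so volume-based weight equations are
recoverable by construction. Herd simulation draws per-animal deviations
(CV 10% on the mature weight, half that on the rate — giving a ~9% BW
spread at one year, matching the reference table's ~13% order) plus
per-visit measurement noise (defaults: 20 mm on girth, 8–12 mm on the
other linear traits, 0.10 m² on BSA, 0.012 m³ on volume, 5 kg scale
noise). One integer seed drives everything; animal i uses stream seed+i.

### Acquisition defects

* `inject_skirt` webs each lateral leg pair with a box membrane whose
  height grows with severity (fully webbed at 1.0). The membrane is
  *concatenated* with the closed input mesh: both parts are closed
  2-manifolds, so the result still satisfies the watertightness invariant
  (every edge shared by exactly two faces) while its signed volume
  double-counts the overlap — deliberately, since the artifact being
  emulated inflates volume and area. No CSG union backend is available,
  and a true union is not needed for the artifact's purpose.
* `remove_region` crops the head+neck (forward 27% of the axial extent)
  or the legs (below 55% of the height), leaving an open surface, as when
  part of the animal fails to digitize.

## Reconstruction

The reconstruction stage is a contract — produce a cleaned, watertight,
outward-oriented mesh from an oriented point cloud — not a re-derivation
of any particular published algorithm.

* **Normals**: per-point PCA over k nearest neighbours (default 16), sign
  consistency by propagation over a minimum-spanning tree of the kNN graph
  (edge weight 1 − |nᵢ·nⱼ|), global flip to point away from the centroid.
  On 10 k noiseless sphere samples, 99% of normals are within 1.5° of
  radial.
* **Implicit method (default)**: signed distance as the inverse-distance
  weighted mean of point-to-plane projections onto the 8 nearest samples'
  tangent planes, evaluated only in a narrow band (3 cells) around the
  samples; off-band signs come from flood-filling the complement from the
  grid boundary. Marching cubes at 2^depth cells (default depth 8) along
  the longest axis; components below 1% of total area are dropped;
  residual holes are fan-filled. A 100 k-point, 2 mm-noise sampling of
  the 12-month preset reconstructs its volume to ~0.1%.
* **Alpha fallback** (for clouds without usable normals): voxels holding
  samples are dilated by a closing radius (default 2× the median
  8th-neighbour spacing), the enclosed cavity is flood-filled, the
  dilation is eroded back, and the occupancy is meshed. Like the scanner
  software it stands in for, a closing radius large against the gap
  between body parts webs them together — sparse leg coverage produces
  exactly the membrane artifacts seen on real scans (a 40 k-point heifer
  cloud reconstructs ~11% over-volume for this reason; the default
  implicit path does not web).
* `make_watertight` fills boundary loops by centroid fans, splitting
  pinched loops into simple cycles, iterating until closed; it refuses
  meshes with a boundary loop longer than 30% of all edges (there is no
  honest fan for half a body).

## Measurement

Volume is the signed divergence-theorem volume (refused on open meshes —
never a silent partial value); BSA is the triangle-area sum (only
reported on closed meshes, since an open scan's area is an
underestimate). The body frame comes from planar PCA of the vertices
(front = the slimmer end by cross-section area; meshes with in-plane
principal extent ratio < 1.1 are rejected as axis-ambiguous). Landmark
stations are fractions of body length — heart girth at 0.30, hip at 0.78,
buttock at 0.92, configurable — rather than learned anatomical detection:
fractions are transparent, testable, and match how the presets are built.
Girth is the convex-hull perimeter of the chest cross-section, the way a
taut rule-tape bridges concavities; heights are referenced to the lowest
mesh point (animals stand on a floor). `measure_all` fails soft per
trait: a partially digitized animal still yields its measurable linear
traits, with the rest recorded as missing.

## Quality scoring

Scores mirror field practice: 4 sufficient, 3 some defects, 2 partially
usable, 1 not used. The operationalisation (visual in the original
practice) is: skirt severity = webbed fraction of 10 slices through the
leg zone (lowest 40% of the height; a slice is webbed when a leg-like —
axially narrow — component spans more than half the body width, or fewer
than two remain); flag above 0.2; severity ≤ 0.4 with nothing else wrong
scores 3; exactly one serious defect (heavy skirt, missing region, or an
open surface not explained by a missing region) scores 2; two or more
score 1. An open surface *caused by* a missing region counts as one
defect, not two — such scans are the canonical "partially usable" case
whose linear traits survive. Missing regions are detected
orientation-independently: a body that ends abruptly (≥ 35% of the
maximum section area at an axial extreme) lost its forward anatomy; a
lower body with no separated leg-like components lost its legs.
Downstream analyses gate BSA and volume on score ≥ 3 and keep valid
linear traits from score-2 records.

Two leg-zone conventions existed as candidates (slices below 0.55× the
withers height vs the lowest 40% of total height); the 40% zone is used
because on every preset the belly line sits at 0.43–0.48× the height, so
slices between belly and 0.55×WH would cut the trunk and be
unclassifiable.

## Weight models and refitting

The eight published equations are built in with their coefficients kept
as decimal strings (serialization round-trips them exactly). Units are
declared per predictor and per model: the heifer volume+hip-width refit
declares hip width in millimetres, because its printed coefficient
(−0.36) is only dimensionally plausible at that scale, while the
adult-cow multi-trait equation declares metres; the ambiguity is in the
sources and is surfaced, not resolved (evaluating the adult multi-trait
form at the 12-month stage means in metres does not reproduce the
published one-year estimate, so neither convention is forced).

Refitting is OLS (statsmodels). Through-origin fits report the uncentered
R² — the convention required to compare forced and free fits. Backward
elimination drops the least significant predictor while its p-value
exceeds α/(2m) for m initial candidates: the Bonferroni factor m controls
the familywise false-retention rate, and the extra factor 2 absorbs the
downward bias that sequential refitting imparts to surviving p-values.
Simulation (n = 69 records, four spurious predictors collinear with body
size) puts the familywise false-retention rate near the nominal 5% under
this rule, whereas a per-test threshold of α retains a spurious predictor
in roughly one run in five.

## Growth analysis

BW is interpolated linearly in age between weighing dates (gaps of 14–28
days; no extrapolation). Stage summaries use windows of ±0.5 month around
the reference stage ages; within a window each animal contributes its
visit nearest the window centre, and SDs use the n−1 denominator (a
single record reports no SD). The surface-to-volume decay is fitted as a
power law in BW on the log–log scale — geometric scaling predicts
BSA/volume ∝ BW^(−1/3), and the noiseless isometric oracle recovers
b = 1/3 to 10⁻⁶ — with an exponential form `a·e^(−k·BW)` available
behind a flag.

## What the synthetic data does and does not show

The generator reproduces the *magnitudes and scaling* of a real growing
herd (stage means of five animals), known-truth geometry, and the defect
mechanisms. It does not reproduce: real surface detail (hence its BSA
sits low), posture variation, anatomical landmark ambiguity, real
measurement-error covariance between traits, or the original study's
animal-level scatter (per-animal raw data were never deposited). Passing
tests therefore demonstrate correctness of the geometry, measurement and
statistics pipeline under realistic magnitudes — not field accuracy on
live animals.

## Problem sizes

Defaults used by the tests and the acceptance script: meshes at marching
cubes resolution 128 (≈ 50 k faces), reconstruction from 100 k points at
depth 8, herd simulations of ≤ 100 animals, 200 Monte-Carlo replicates
for the elimination-rate and unbiasedness checks. These sizes keep every
quantity's Monte-Carlo error well inside the tolerances asserted on it.
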