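# Methods

This note documents the models, conventions and numerical choices behind
`retinotopo`, what the synthetic-retina generator does and does not
emulate, and the design decisions taken where a convention had to be fixed.

## Coordinate frame and compartments

A retina is a simple closed contour polygon (mm) with the optic-nerve (ON)
head strictly inside it.  All analyses run in a **canonical frame**: ON at
the origin, nasal along +x, superior along +y.  Right-eye tables are
translated only; left-eye tables are additionally mirrored about the
vertical axis (x → −x) so that nasal maps to +x for every retina.  Both
operations are isometries, so neighbor counts and all distance-derived
quantities are unchanged; mirroring is required so that maps from left and
right eyes superimpose coherently in normalized maps.  Physical mounting
conventions orient tissue, not coordinates, so a single numeric convention
like this one must be imposed; it is a package convention, not an inferred
property of any particular dataset.

Compartments are defined on top of that frame:

* **Quadrants** SN/ST/IN/IT split along the canonical axes through the ON.
  Points exactly on a boundary go to the nasal (x = 0) or superior (y = 0)
  side.  The tie rule is ours; axis ties have measure zero in real data.
* **Hemiretinas**: nasal x ≥ 0, temporal x < 0.
* **CMZ**: distance to the nearest contour edge ≤ 0.100 mm, boundary
  inclusive.  The rim band is conventionally "about 100 µm"; we fix it at
  exactly 0.100 mm and expose it as a parameter (`band`).
* The four radial flattening cuts of a physical whole-mount are *not*
  modelled: the contour is one polygon.  Cut petals are a preparation
  artifact, not an analysis object, and the synthetic contour is a fine
  256-gon disc.

Units are mm at retina scale and µm for soma outlines (each outline lives
in its own local frame), which keeps numbers near 1 in both regimes.

## Synthetic retina generator

The generator produces, deterministically per seed, one retina with the
statistical structure the analyses assume.  What it emulates:

* **Geometry**: a 2.2 mm-radius polygonal disc (~15.2 mm²).
* **Brn3a⁺ RGCs** (default 38 500 pigmented / 45 880 albino): rejection
  sampling from a density that decays exponentially with eccentricity
  (scale 1.1 mm) and is boosted (+100%) inside a horizontal streak centred
  0.30 mm dorsal to the ON (σ = 0.25 mm) — the rodent high-density visual
  streak.  The published-scale totals and the central/streak-weighted decay are
  the study conditions; the functional form (exponential × Gaussian streak)
  is our choice, since no parametric density is published.
* **ipRGCs in the GCL** (1020 / 960): each cell draws a quadrant from the
  configured weights (pigmented temporal-heavy: SN .21, ST .31, IN .19,
  IT .29; albino superior-heavy: SN .31, ST .31, IN .19, IT .19), then a
  position in that sector with radial density ∝ r^(1+β), β = 2 — an
  eccentricity-increasing acceptance weight expressing "more abundant in
  the periphery"; any monotone-increasing weight would satisfy the
  contract, and β is exposed in the config.  GCL ipRGCs are kept out of the
  0.100 mm rim band so the rim population is a separately controlled
  compartment.
* **CMZ plexus** (nasal 34 / temporal 14 pigmented; 56 / 26 albino —
  the published per-hemiretina traced+untraced means): melanopsin cells
  confined to the rim band, nasal-biased by construction.
* **Displaced ipRGCs** (147 / 46) in the INL, superior-biased quadrant
  weights (SN .30, ST .30, IN .20, IT .20) with the same peripheral bias,
  rim band allowed (d-ipRGCs are observed in the CMZ).
* **Labeling**: OHSt is Bernoulli per cell with a per-compartment
  probability (pigmented: GCL 0.997, displaced 0.857, CMZ 0.792; albino:
  0.989, 0.717, 0.744 — the published traced fractions for optic-nerve
  tracing); Brn3a co-expression in melanopsin cells with probability
  0.0193 / 0.0078.  Placement counts are exact; only labeling is
  stochastic.
* **Soma outlines**: 32-vertex noisy ellipses (aspect ratio U(0.70, 0.95),
  3% radial vertex noise) rescaled so each outline's fine-step chord-mean
  diameter equals a per-cell target drawn from N(µ, σ) per compartment
  (GCL 13.5 ± 1.8 µm pigmented / 14.8 ± 2.2 albino; INL 11.8 ± 1.6 /
  12.9 ± 2.3).  The vertex count is a rendering decision.

What it does **not** emulate — and hence what passing tests do not show
about real data: staining intensity and detection failure, flattening
distortion, the precise published map shapes (the pigmented "C" and the
albino arc are represented only through quadrant weights and the radial
bias), cut petals, optic-disc shadowing, and any correlation between soma
size and position.  Tests against the generator validate the *analysis
contracts* (counting, partitioning, accounting, estimation), not the
biology of any particular retina.

The generator emits the retina in a raw image-like frame (ON offset, left
eyes mirrored) so that the pipeline's canonicalisation step is always
exercised.

## Topography

* **Neighbor counts** use a k-d tree with an inclusive (≤ r) Euclidean
  radius, default r = 0.165 mm, excluding the cell itself.  An O(n²)
  brute-force oracle in the test suite asserts exact equality, so the
  accelerated index can never change results.
* **Colour scales** are parameterised by (n_classes, low, high): counts
  ≤ low take class 0, ≥ high the top class, and the integers strictly
  between are split into equal-width lower-inclusive intervals.  Named
  presets carry the published endpoint pairs: `single` (1 → 11, 11
  classes, unit-width interior) and `normalized3` (3 → 28, 14 classes,
  width-2 interior).  Only the endpoints are published; equal interior
  widths are our choice.
* **Normalized maps** pool ≥ 2 canonical tables and recompute counts on
  the pooled set; the map total is exactly the sum of the inputs.
* **Isodensity grids** tile the contour's bounding box with square bins of
  area 0.2161/36 mm² by default — the published acquisition-frame area
  subdivided 6×6.  The subdivision factor is our choice (the original
  sampling grid is unpublished); it is configurable.  Bins that do not
  touch the contour are dropped; bin counts always sum to the filtered
  population.  No smoothing or interpolation is applied, and no kernel
  density estimation: the published maps are discrete-binned.
* **Radial profiles** use half-open lower-inclusive bins [k·w, (k+1)·w),
  default w = 0.165 mm, reported overall and per quadrant; the per-quadrant
  histograms sum bin-wise to the overall one by construction.

## Colocalization and accounting

Percentages are always 100·n_double/n_reference with the raw counts kept
alongside; an empty reference yields a flagged undefined percentage, never
0%.  Display formatting **truncates** toward zero at the reported
precision (one decimal for tracing tables, two for the sub-1% Brn3a
fractions) — the convention that reproduces the published tables exactly —
while all stored values keep full precision.

`match_points` pairs two coordinate channels by mutual nearest neighbors
within a tolerance (default 0.010 mm ≈ one soma radius), greedy by
ascending distance, each point in at most one pair.  Mutual-NN greedy runs
in O(n log n); at microscopy jitter scales it coincides with the optimal
assignment, which the test suite asserts against an exhaustive
linear-assignment oracle.  Matching is optional: the native table format
carries per-cell boolean flags.

Displaced accounting groups the rare IPL-resident cell with the INL
population.  The CMZ account includes melanopsin cells of all layers in
the rim (rim d-ipRGCs are part of the rim plexus); compartment-pure
fractions (e.g. rim GCL cells only) are available through the mask API and
are what the pipeline's colocalization block reports.

## Morphometry

Soma diameter is the mean of the chords through the outline's **area
centroid** (not the vertex mean) at angles 0°, 2°, …, 178° — 90 chords,
since a chord at θ and θ+180° is the same segment.  Chords are computed by
intersecting the centroid line with every polygon edge; for non-convex
outlines with multiple crossing intervals the chord is the outermost span
(calliper-style reading), and such cells are flagged in the output.  A
centroid outside the outline (strongly non-convex soma) is a geometry
error.  Population statistics use the sample SD (n−1).  The 2° estimator
agrees with a 0.01°-step oracle to well under 0.5% on convex shapes and is
exactly invariant under rotations by multiples of the step.

## Statistics

Mann–Whitney U uses the exact enumerated null when n_a·n_b ≤ 400 and the
pooled sample is tie-free, otherwise the normal approximation with tie and
continuity correction; the two branches agree to < 0.01 absolute p at the
boundary.  Kruskal–Wallis (≥ 3 groups) uses the tie-corrected H with a
χ²(k−1) p-value; two groups are redirected to Mann–Whitney.  The t test is
Welch by default (no variance-homogeneity assumption is published), all
alternatives are two-sided, no multiple-testing correction is applied, and
significance is p < 0.05.  Identical-group degenerate inputs return H = 0,
p = 1 rather than an error.

## Problem sizes and determinism

The analysis drivers and the acceptance script use three retinas per
strain at full published scale (~40 000–47 000 cells each), matching the
three-retina normalized-map design; the parameter-recovery test pools 20
seeded full-scale retinas per strain.  Recovery is checked with
Clopper–Pearson binomial intervals and a χ² goodness-of-fit on quadrant
counts, Bonferroni-split so the five checks per strain have joint 95%
coverage.  Every stochastic step draws from one `numpy` Generator seeded
explicitly; a config plus seed reproduces byte-identical cell tables, and
the pipeline summary is deterministic given inputs and config.

## Known limitations

* The contour is a single polygon: no cut-petal geometry, no flattening
  distortion correction, no 3-D eye-cup model.
* Inputs are dotted cells; there is no pixel-level segmentation and no
  intensity-based (Manders/Pearson) colocalization.
* The isodensity grid is a faithful-by-contract substitute for the
  original proprietary binning routine, not a pixel-level clone of its
  maps.
* Preset quadrant weights and the radial-bias exponent summarise published
  *tendencies*; they are not fits to the published map figures.
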