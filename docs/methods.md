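# Methods

## Problem and scope

`axonmorph` quantifies the 3D ultrastructure of myelinated axons from
segmented serial block-face scanning electron microscopy (SBF-SEM) label
volumes, as used to study retinal ganglion cell axons in optic nerve before
and after injury. The package takes segmentation as given (a multi-page TIFF
of integer labels per z-slice) and measures; it does not segment, render, or
simulate electron optics.

The measurement chain is: trace each axon instance through the stack
(centerline), measure 2D sections at fixed arc intervals (slice
morphometry), assemble longitudinal profiles and scores (profiles), locate
nodes of Ranvier and nodal mitochondria (nodes), and compare experimental
groups (stats). A phantom generator with exact ground truth closes the loop
for validation.

## Coordinate and unit conventions

Stacks are indexed `(z, y, x)`, 0-based; the physical position of a voxel
centre is `(index + 0.5) * spacing` per axis. Voxel spacing is given in
nanometres (acquisition default 5 × 5 × 50 nm; 2000 slices of a
10000 × 10000 px image cover 50 × 50 × 100 µm). Every reported measurement
is in µm (µm² for areas), converted exactly once at measurement time.

Semantic classes live in disjoint label-id ranges of a single stack: axons
1–999, compact myelin `axon_id + 1000`, decompacted myelin
`axon_id + 2000`, mitochondria 3001–3999 (instance ids overlaid inside the
axon interior). The offset pairing makes the axon–myelin association
explicit without a second channel.

## Centerline tracing and measured length

An axon is traced from the first slice in which its label appears until it
leaves the volume. Per slice the traced point is the area centroid of the
in-plane connected component (hole-filled, since mitochondria punch
own-label holes in the axon mask); when several components share the id,
the one with the largest voxel overlap against the previous slice is
followed. Runs of up to `max_gap = 2` missing slices are bridged;
longer gaps terminate the trace with a warning rather than stitching
different axons.

The *measured length* is the centre-to-centre polyline arc plus one slice
thickness (half a slice at each end), so an axon spanning all 2000 slices
measures exactly 100 µm. Measurement positions are placed every 5 µm of arc
length by default (`0, 5, 10, …` up to the measured length, each mapped to
the nearest slice). Arc length is the default reading of "along the axon";
a z-distance mode (`use_arc=False`) is available since the two coincide for
near-axial axons.

## Per-section morphometry

Sections are taken in the acquisition z-plane — never resampled
perpendicular to the axon — because that is what serial-section microscopy
records. A tilted axon therefore presents an elongated ellipse; all
diameter-like quantities use the **minimum caliper (Feret) width**, which is
invariant to that elongation (verified for tilts up to 45°, where the
deviation stays below one in-plane voxel while the area inflates by
1/cos(tilt)).

- **Area**: axon voxel count × pixel area.
- **Minimum diameter**: minimum width of the convex hull of the voxel
  corner points. The minimum width of a convex polygon is attained
  perpendicular to one of its edges, so the exact value is the smallest
  over hull edges of the farthest-vertex distance. Because whole voxel
  squares represent the region, the width of a rasterized smooth shape can
  exceed the underlying ideal width by up to `dx|cosθ| + dy|sinθ| ≤ √2` px;
  this bound, not half a voxel, is the correct comparison tolerance for
  strongly elongated sections.
- **Myelin thickness**: 360 rays cast from the axon centroid; per ray the
  thickness is the length of the ray's intersection with the sheath
  (compact or decompacted), sampled at half-voxel steps; the minimum over
  rays that hit myelin is reported. If fewer than half the rays hit myelin
  the section is treated as unmyelinated (nodal) and the thickness is 0 —
  this single rule also drives node detection.
- **Fiber diameter**: minimum caliper of axon ∪ myelin (identical to the
  axon diameter on unmyelinated sections). An additive mode
  (diameter + 2 × thickness) was considered and rejected: the caliper is
  the obliquity-robust reading and is oracle-testable.
- **G-ratio**: axon diameter / fiber diameter, in (0, 1]; defined as 1 on
  unmyelinated sections.
- **Percent decompaction**: of the rays that hit any myelin, the percentage
  whose intersection contains at least one decompacted voxel. Scoring over
  myelin-hitting rays (not all 360°) keeps the quantity well defined for
  partial wraps next to nodes.

The caliper implementation is validated against an independent directional
sweep: widths at 0.5° steps, with each local minimum of the sweep polished
by a bounded 1D search (a plain grid sweep alone overestimates the minimum
by up to ~`w''·(0.25°)²`, around 1e-4 µm on elongated masks). Exact and
sweep values agree to better than 1e-6 µm.

## Longitudinal profile statistics

Per axon, each metric's mean, min, max and range (max − min) are computed
over the sampled sections only (not every slice), matching the 5 µm
measurement procedure. The decompaction score counts sampled sections whose
percent decompaction **strictly exceeds** 40% — sections at exactly 40.0%
never score — and divides by the measured length, giving points/µm (the
per-length unit is recorded in table headers). Axons shorter than two
sampling intervals are excluded from range statistics.

Single-section sampling utilities mirror conventional 2D morphometry: one
section per axon at a fixed arc position (e.g. 30/60/90 µm), and n randomly
chosen axons from one slice (seeded, without replacement).

## Nodes of Ranvier and mitochondria

Every traced slice is classified myelinated/unmyelinated by the 50%-ray
rule. A maximal run of ≥ 3 consecutive unmyelinated slices is one node
(shorter runs are treated as segmentation dropouts); runs touching the
trace ends are discarded because their gap cannot be delimited. The
**paranodal gap** is the arc distance between the two myelin termini, each
estimated at the midpoint of its myelinated→unmyelinated transition. The
midpoint convention is unbiased under uniform sub-slice terminus position
(worst-case error one slice); measuring flank-centre to flank-centre would
instead carry a systematic +2 slices.

Mitochondrion length is the pure z-span of the label — first slice in view
to last, times dz — matching how such lengths are read from serial stacks;
no 3D skeleton length is attempted. A mitochondrion is *nodal* when the arc
position of its z-midpoint lies within 10 µm of a node centre; each
mitochondrion is assigned to at most one node (the nearest on its own
axon).

## Cohort statistics

- Thickness-on-diameter relation by ordinary least squares (slope,
  intercept, R² = 1 − SS_res/SS_tot), over myelinated sampled sections.
- Per-axon means of sheath metrics (myelin thickness, G-ratio, fiber
  diameter) are taken over myelinated sections only. Nodal sections carry
  conventional placeholders (thickness 0, G-ratio 1), not sheath
  measurements; averaging them in would couple the mean to paranodal gap
  length rather than sheath structure. Area and axon diameter are averaged
  over all sampled sections.
- Group contrasts by two-sided unpaired t-tests; classic Levene's test
  (deviations from group means) at α = 0.05 gates Student's pooled form
  versus Welch. Zero-variance equal-mean inputs return t = 0, p = 1. The
  gated procedure's type-I error is calibrated (0.049 over 20000 null
  replicates at n = 30/group).
- One-way repeated-measures ANOVA via the subject-blocked two-way
  decomposition (SS_total = SS_subject + SS_condition + SS_error; condition
  tested against MS_error), with Tukey HSD on condition means using the
  same error mean square through the studentized-range distribution. This
  is implemented in-package because off-the-shelf Tukey routines use a
  between-subjects error term; `pingouin` cross-checks the F statistic in
  the test suite. Dunnett's post-hoc is out of scope.

## Phantom generator

The generator emulates the acquisition's geometry and the study's biology
with exact ground truth recorded before rasterization:

- **Geometry**: desk-scale default 256 × 256 px at 20 nm with 400 slices of
  100 nm (5.12 × 5.12 × 40 µm), preserving the strong z anisotropy of the
  real 5/50 nm acquisition while keeping µm-scale axons a few dozen pixels
  wide; cohort volumes are 192 × 192 × 300 (30 µm), one axon each.
- **Axons**: smooth splines through randomly tilted waypoints (tilt capped
  at 8° by default — axons wander but remain roughly axial), sinusoidal
  caliber `r(z) = r₀(1 + 0.25 sin(2πz/T))` with r₀ ~ U(0.38, 0.55) µm and
  period T ~ U(14, 24) µm, giving section diameters of roughly 0.6–1.4 µm,
  the caliber range of optic-nerve axons.
- **Myelin**: annulus of thickness `0.20 × diameter + 0.13` µm (the healthy
  caliber–thickness relation), plus Gaussian thickness noise whose SD is
  solved analytically from the designed caliber variance so that the
  diameter–thickness R² on the design equals the condition target (0.45
  normal, 0.25 injured).
- **Nodes**: one per axon, myelin suppressed over the designed gap;
  paranodal gap ~ N(1.5, 0.3) µm normal, N(3.0, 0.5) µm injured.
- **Decompaction**: angular sectors of the annulus re-labelled and widened
  radially ×1.5, covering 2% of the z-extent at angular fraction 0.2
  (normal) versus 25% at 0.45 (injured). The injured fraction is kept below
  0.5 deliberately: with the 1.5× widening, a sector wider than half the
  circumference would leave no antipodal pair of compact directions and
  would shift the minimum fiber caliper — contradicting the observed null
  result for fiber diameter and G-ratio after injury. 0.45 still clears the
  40% scoring threshold with margin.
- **Mitochondria**: 1–2 interior ellipsoids per axon near the node
  (within ±6 µm, alternating sides so spans never collide), length
  ~ N(1.4, 0.2) µm normal versus N(0.8, 0.15) µm injured.
- **Matched cohorts**: all randomness flows through child generators keyed
  `(seed, axon_index, stream)`, so the same seed produces identical axon
  geometry in both condition presets, with only condition parameters
  differing. Injury contrasts are therefore isolated from sampling noise in
  the shared geometry, and the null comparisons (caliber, thickness,
  G-ratio, area) hold for any seed rather than on average.

What the phantoms do **not** emulate: grayscale texture (decompaction is a
provided label class, not detected), non-circular cross-sections,
axon branching, glia, segmentation errors beyond simple slice dropouts, and
real biological variance structure (per-axon parameters are independent
draws, not nested within animals). Passing phantom tests therefore
demonstrates the correctness of the measurement chain on known geometry,
not the accuracy of upstream segmentation on real tissue.

## Validation summary (what the suite computes)

Parameter recovery on 20 tortuous phantoms: per-slice radius RMSE ≈ 0.2
voxel (bound: 1), paranodal gap within 2 slices, mitochondrion length
within 1 slice, percent decompaction within ~1.1 points of the designed
fraction (bound: 2). Matched 30-axon cohorts reproduce the injury pattern:
decompaction score and paranodal gap up, nodal mitochondrion length down
(all p < 0.05), with caliber/thickness/G-ratio/area nulls retained, and the
diameter–thickness R² dropping from ≈ 0.45 to ≈ 0.25–0.3.

## Numerical choices and edge cases

- Problem sizes (desk-scale phantom volumes, 180 rays for bulk cohort
  measurements vs 360 by default, 20-phantom recovery runs, 30-axon
  cohorts) were chosen to keep a full validation run in a few minutes on
  one core while leaving discretization error well inside every tolerance.
- Single-voxel masks return min(dx, dy) as their caliper width.
- Fragmented sections: the component chosen by centerline linking is
  measured; others are ignored with a log entry.
- Degenerate statistics (zero-variance groups, constant responses) return
  conventional values (t = 0/p = 1, R² = 0) rather than NaN.
- Ties in nearest-slice sampling resolve to the earlier slice; sample
  positions are strictly increasing by construction.
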