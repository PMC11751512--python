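# Methods

## Problem and scope

`pistonalign` quantifies the orientation of cells in a monolayer relative to the
projected footprint of a microstructure suspended above them (a PDMS
"micro-piston" shaped as a circle, equilateral triangle, or square).  The
observable is label-free: nothing is stained or tracked; the only inputs are
hand-drawn (or simulated) closed polygons outlining whole cell bodies, plus a
geometric description of the reference shape.  The package implements the
measurement (ellipse-fit orientation), the shape-relative angle transformation,
the four-class angle binning, the group statistics, and a synthetic monolayer
generator used to validate the whole chain.

## Cell orientation from outlines

The cell axis is defined as the major axis of the ellipse with the same
second-order area moments as the filled outline polygon.  Moments are computed
in closed form from the shoelace/Green's-theorem contour sums, not by
rasterization: results are exact, resolution-free, and orientation-independent,
and the pixel-based "fit ellipse" of interactive image software converges to
this value as pixel size shrinks.  The orientation is

    alpha = 1/2 * atan2(2*mu11, mu20 - mu02),   folded to [0, 180),

with `mu` the per-unit-area central second moments.  Axis lengths take the
moment tensor's eigenvalue ratio and are scaled so the ellipse area equals the
polygon area.  Orientations are axial quantities (a cell axis has no head or
tail); all angle arithmetic is performed modulo 180 degrees.

**Degenerate outlines.**  When `(mu20 - mu02)^2 + 4*mu11^2 < 1e-12 * (mu20 +
mu02)^2` the moment tensor is isotropic to machine-level tolerance (regular
polygons, essentially round cells) and no major axis exists.  Such cells are
flagged `orientation_defined = False`, excluded from angle statistics, and
counted in a per-reason exclusion tally rather than silently dropped.  No
minimum-aspect filter is applied by default; `score_region(min_aspect=...)`
enables one.

## Shape-relative angles

Only cells whose outline crosses the projected periphery are scored, matching
the measurement procedure.  "Crosses" means the filled polygon meets the
periphery curve; for the circle this is decided exactly from centre distances
(no polygonal approximation of the circle), for polygons with an exact
polygon–ring intersection test.

* **Circle.**  With the cell centroid at `(x_cell, y_cell)` relative to the
  piston centroid, the position angle is `beta = atan2(y_cell, x_cell)`
  (quadrant-aware; a principal-branch arctan would be ambiguous across
  quadrants and agrees after the axial fold anyway), and the tangent-relative
  elongation angle is `90 - (beta - alpha)` folded to [0, 180).  90 deg means
  the cell lies along the radius, 0/180 along the periphery.
* **Triangle / square.**  The cell angle is re-expressed against the direction
  of the *nearest* polygon edge (minimum point-to-segment distance from the
  cell centroid; ties broken toward the lowest edge index) as
  `fold180(alpha - edge_angle)`.  Edge directions are the fabricated canonical
  directions (0/60/120 or 0/90) plus the correction angle `k` measured on the
  device.

The two formulations agree identically for the circle when the "edge" is taken
as the tangent at the ray–periphery intersection; this equivalence is asserted
to 1e-9 degrees in the acceptance suite, as is invariance of all relative
angles under whole-scene rotation (0.1-degree tolerance, dominated by the
ellipse-fit tolerance).

**Binning.**  Relative angles partition into radial `[70, 110]`, peripheral
`[0, 20) ∪ (160, 180)`, oblique-near `[50, 70) ∪ (110, 130]`, and oblique-far
`[20, 50) ∪ (130, 160]`.  The published grouping leaves some endpoint
inclusivities open; this half-open partition is one consistent choice and a
measure-zero decision for continuous data.  Under uniformly random
orientations the expected bin fractions are the bin widths over 180:
40/180, 40/180, 40/180, 60/180.

**Controls.**  A control group re-uses the same reference geometry placed at a
seeded uniformly random position inside the field of view whose footprint does
not overlap the true piston region (bounded rejection sampling; infeasible
configurations raise rather than degrade).

## Statistics

Two procedures are applied to the binned counts:

* **Pearson chi-square** on the 2 x 4 piston-vs-control contingency table,
  without continuity correction, df = 3.  Bins empty in both groups are
  dropped with df reduced and a warning attached.
* **Two-sample t-test between percents** for a single bin's percentage: with
  pooled proportion `pbar = (p1*n1 + p2*n2) / (100*(n1 + n2))`,

      t = (p1 - p2) / (100 * sqrt(pbar*(1-pbar)*(1/n1 + 1/n2))),

  referred two-sidedly to Student's t with `n1 + n2 - 2` df.  This is the
  classical pooled two-proportion z statistic with a t reference distribution;
  the two converge (checked to 1e-4 at n = 10^4 per group).  The exact recipe
  behind the published "t-test between percents" is not documented anywhere in
  the source material; this formulation was selected because it reproduces
  every cleanly-printed p-value to print precision, and that reproduction is a
  test, not an assumption.

No multiple-testing correction is applied (none was applied in the source
analysis).  Significance is flagged at p < 0.05.

**Reconstructing counts from printed tables.**  The packaged fixtures carry the
published percentages and group sizes.  Integer counts are recovered as
`round(pct * n / 100)`; a row whose rounded counts do not sum to `n` is refused
(`IrreconcilableRowError`) instead of silently repaired.  Exactly one row
fails: the circle-control Day-2 row, whose printed n = 70 is inconsistent with
its own percentages (they reconstruct at n = 57, the size the companion figure
caption lists for that group).  That row is excluded from the reproduction
suite; all 77 remaining printed p-values reproduce within one unit of their
last printed decimal.

## Synthetic monolayers

The generator emulates the statistical structure the analysis assumes — it is
a stand-in for the study's raw images, which were not deposited.

* **Geometry.**  Cells are ellipses polygonized at `outline_vertices` (default
  48) points with multiplicative radial jitter (`vertex_noise`, default 0.03);
  jitter of a star-shaped polygon preserves simplicity.  Areas are lognormal
  around `mean_cell_area` (default 300 um^2, a plausible spread epithelial
  cell), aspect ratios lognormal with median 2.2 (sigma 0.35), floored at 1.
* **Packing.**  Centres are placed by sequential rejection sampling with a
  minimum spacing of 0.7 x the mean cell diameter — a cheap surrogate for
  monolayer packing, not a physics model.  Saturation raises
  `PlacementInfeasibleError` rather than producing an unrealistically sparse
  field.
* **Orientations.**  Within a periphery zone (default width 0.15 x shape size)
  a cell is shape-aligned with probability `align_fraction`; aligned cells draw
  their shape-relative angle from an axial von Mises centred at 90 deg
  (radial), sampled on the doubled angle with concentration `kappa`, then
  converted to the absolute frame through the local tangent/edge direction.
  All other cells — outside the zone, the complementary mixture component, and
  every cell of a control field — are uniform on [0, 180).  The bias is
  restricted to the zone because only periphery-crossing cells are ever scored.
* **Growth.**  Cell count follows `n0 * g^(day/2)` with `g = growth_day2 = 1.8`,
  the observed ~80% increase in cell number by Day 2.
* **Defaults.**  `align_fraction = 0.7`, `kappa = 3` put the expected radial
  fraction of periphery cells near 58%, inside the 40–70% band the published
  piston groups span.  This is a calibration of the simulator to the reported
  effect sizes, not an inference about mechanism.
* **Determinism.**  One seed fixes everything; `(seed, day, region)` seeds a
  dedicated PCG64 stream, so ground-truth tables are byte-identical across
  runs.

**What passing simulation tests does and does not show.**  The generator
reproduces orientation mixtures, packing density, growth, and outline noise —
not cell shape irregularity beyond radial jitter, not migration or division
dynamics, not segmentation/drawing error of human annotators, and not any
mechanism of the alignment itself.  Green simulation tests certify that the
pipeline recovers known statistical structure from synthetic fields; they
cannot certify microscope-image performance.

## Validation experiments (problem sizes)

* *Type-I error*: 1000 seeded replicates of piston-vs-control chi-square with
  `align_fraction = 0`, ~100 scored cells per region per replicate; the
  rejection rate at p < 0.05 must land in 5% +/- 2%.
* *Power*: 200 replicates at `align_fraction = 0.9`, `kappa = 4`, ~100 cells
  per region; p < 0.001 required in at least 95% of replicates.
* *Mixture recovery*: the moment estimator
  `(f_radial - 40/180) / (m_radial(kappa) - 40/180)` of the aligned fraction is
  validated over 100 replicates of 500 periphery cells.
* These replicated experiments generate cells directly on the periphery curve
  (every cell is scored), which exercises the orientation model, the crossing
  selection, the ellipse fit and the statistics without filler cells far from
  the periphery; the full-field monolayer path (packing + growth + zone logic)
  is exercised end-to-end in its own tests.

## Numerical choices and edge cases

* All angle folds are exact modular arithmetic; edge directions within 1e-9 of
  the 180-degree fold are snapped to 0.
* Zero-area or self-intersecting outlines raise `InvalidOutlineError` at the
  point of use; readers validate polygons on import.
* `rotation_k` is normalized to [0, 60) for triangles and [0, 90) for squares —
  the period of the *edge-direction* set.  For the triangle this is shorter
  than the 120-degree symmetry of the vertex set, so two triangles differing by
  a 60-degree rotation share one representation; fabricated correction angles
  are a few degrees, where the representation is faithful.  This is a known
  limitation for large `k`.
* ImageJ ROI files are written canonically (version 228, polygon type,
  sub-pixel float coordinates, deterministic integer bounding box), so
  write -> read -> write is byte-stable; coordinates survive round-trip to
  float32 precision (~1e-4 of a pixel here).
* ImageJ images are y-down; importers flip to the package's mathematical y-up
  frame when the image height is supplied.  Angles are scale-invariant, so
  pixel size only matters for length columns.
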