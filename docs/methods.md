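# Methods

This note records the models, parameter choices and numerical conventions
behind `phrenoscope`, in the order of the processing chain.

## Coordinate conventions

Graph inputs are Cartesian micrometres with y increasing dorsally. Raster
inputs are 0-based images with pixel centres at integer coordinates; pixel
`(row, col)` maps to `(x, y) = origin + (col, row)·scale`, default scale
1 µm/px. All geometric measures are invariant under rigid motion and under
mirror reflection of their inputs, which the test suite asserts.

## Nerve morphometry

**Endplate tangent.** The band is traced by hand in the original assay; here
the tangential line is defined reproducibly as the major principal axis of
the band's foreground pixel coordinates through their centroid (a
total-least-squares line). A band whose major/minor axis ratio is ≤ 1.2 has
no meaningful tangent and is rejected (`DegenerateShape`). Polygon outlines
are accepted and rasterised internally.

**Defasciculation distance** is the perpendicular point-to-line distance
from the entry point to the tangent, equivalent to intersecting the tangent
with its perpendicular through the entry point.

**Counting line.** The fascicle-counting line is parallel to the tangent at
`fraction × distance` from the entry point, measured toward the endplate.
The source protocol states the position once as one quarter of the distance
from the endplate and once as 80% of the distance from the entry point;
these coincide only approximately, and the implementation takes the
fraction from the entry point with default 0.8, user-configurable.

**Fascicle identity.** On graph input, a fascicle is a maximal chain of
same-order edges (an edge continues its parent's fascicle iff it has the
same order and is the unique such child); a fascicle is counted once no
matter how many of its segments cross the line, and only crossings between
the extreme projections of the two primary branches count. Order-1
(primary) edges are excluded by default because the counted structures are
the secondary branches between the two primaries. On raster input the same
count is obtained as the number of 8-connected foreground components in a
1-pixel band centred on the counting line, restricted to the same span and,
when an order label image is available, to the requested orders. A
`merge_gap` option (default 0 µm) merges crossings closer than a tolerance.

**Split angle** is the angle between the mean unit direction vectors of the
first three edges of each primary branch. On raster input the two primary
directions are estimated from the foreground pixels in an annulus of 5–15 px
around the entry point (narrower than the innermost secondary branch),
clustered into two arcs by cutting the sorted pixel bearings at their two
largest circular gaps; this estimator is accurate to ~1–2° on synthetic
patterns and is this package's own construction.

**Endplate thickness** divides the band into 30 equal-length bins along the
fitted axis and averages the per-bin perpendicular extent
(max − min projection plus one pixel footprint) — an extent, not
area/length, matching the width-of-rectangles definition.

**Ratio aggregation.** Left/right asymmetry is summarised as per-embryo R/L
ratios, mean ± SEM (SEM = sd(n−1)/√n). A ratio-of-group-means variant is
provided (`method="ratio_of_means"`) but is not the default; the published
2.1-fold endplate-thickness figure is the ratio of the printed group means.

## Explant outgrowth

Ring k around the explant border contains pixels whose Euclidean distance to
the border (distance transform of the border polygon's complement) lies in
`((k−1)·25, k·25]` pixels, so rings plus the explant interior tile the image
exactly and ring areas conserve total foreground. Total outgrowth area is
the summed per-ring labeled surface; maximal distance is the outer offset of
the farthest occupied ring.

Fascicle **widths** are run lengths of foreground along the ring's
mid-offset iso-distance contour. The protocol does not define "width"; the
run-length-along-contour definition was chosen because it needs no fascicle
segmentation. Contours are resampled at 0.25 px arc steps so that run-end
quantisation stays well below one pixel; runs wrapping around a closed
contour are merged. The defasciculation index is the total proximal width
(second ring) divided by the total width in the first ring whose outer
offset exceeds 30% of the maximal distance. Note the distal ring therefore
sits at ~30% of the growth extent: a bifurcation planted beyond it cannot
change the index, so the generator's `split_at` must be placed proximal to
it (the drivers use 0.25) for splitting to register.

## Transcript lateralization

Probes are *expressed* iff called present in at least one sample of every
embryo and their maximal normalised intensity over all samples is ≥ 200 (the
two gates commute; the call gate is applied first). A probe is
right-enriched iff all per-embryo log2(R/L) ratios are > 0, their mean
strictly exceeds log2(fold) and at least `min_embryos` (default 2) embryos
individually exceed it; left-enrichment is the sign mirror. "Over 1.5 on
average" is interpreted as the mean of per-embryo log2 ratios exceeding
0.5849, not the log of the mean ratio. A log2 ratio of exactly 0 in any
embryo breaks the same-sign requirement. Zero intensities are floored at 1.0
before logs (configurable). The strict ">" comparisons carry a 1e-9 guard so
that data sitting exactly at the fold threshold are never called on account
of floating-point rounding. Analysis operates at probe level; gene-level
collapse is out of scope of the detector and can be done upstream.

qPCR relative expression is `2^−(Ct_target − Ct_reference)` per sample
(reference, e.g. GAPDH), with per-embryo R/L ratios.

## Assay quantifiers

**Surface ratios.** The intensity threshold is computed by Otsu's method on
the sum-projection of the designated reference side restricted to its ROI
(the protocol fixes the cross-application but not the threshold method;
Otsu was chosen as the standard parameter-free choice, with a fixed-value
override). The threshold is applied identically to both sides; each side's
surface is normalised to its ROI area, and log2(right/left) is returned. A
zero surface on either side is raised as `ZeroSurface` carrying the signed
infinity rather than silently returned.

**Zymography** reports, per side, the percentage of marker-positive cells
that are activity-positive; marker-negative cells are ignored entirely.

**Blot normalisation** rescales each replicate so its left+right sum equals
the grand mean of the raw sums (the normalisation constant is unspecified in
the protocol; any common constant leaves within-replicate R/L ratios
unchanged, which is the invariant that matters and is tested to 1e-9).

## Exact rank tests

Small samples (a handful of embryos) make asymptotic p-values unreliable,
so both tests compute their exact permutation null: all `C(n1+n2, n1)` rank
assignments for the Mann-Whitney U, all `2^n` sign assignments for the
signed-rank W⁺, both via dynamic programs that enumerate the identical
distributions without materialising every arrangement (the test suite
checks them against literal brute-force enumeration). Exact mode applies up
to total n = 20 and, for the rank-sum test, only without ties; otherwise
midranks with tie-corrected variance, continuity correction and the normal
approximation are used and recorded in the result. Exact two-sided
p-values double the smaller tail (capped at 1). Zero differences are
dropped before ranking (the original convention); the Pratt variant is
available via `zero_method="pratt"`.

## Synthetic data

The generators emulate the study conditions: 3 embryos with paired L/R
samples and ~20,000 probes for the arrays; N = 9/8/18 embryo cohorts at
E13.5/E14.5/E15.5 for the diaphragm morphometry; ~800 cells per side for
the zymography; 5 replicates for the blots. Stage presets carry the
published group means (distances 32.76/94.82, 42.56/135.71, 77.16/188.51 µm;
counts 6/9, 8/11, 6/11 after rounding to integers; split angles 166°/132°
for all stages since they were only measured near the time of the primary
split; endplate thickness 254.9/529.3 µm at E15.5 and nominal values scaled
with diaphragm growth at earlier stages, where no measurement exists).

Synthetic patterns place the entry at the planted perpendicular distance
below a rectangular band whose principal axis is the tangent; secondaries
attach to the primaries at evenly spaced abscissae within
`0.56·d·tan(θ/2)` so that every one of them attaches below 56% of the
distance and therefore crosses the counting line at 80%. Right-side
patterns are the exact reflection of the left-side construction. Branches
are rasterised as 1-px polylines dilated to ~3 px. Array baselines are
log-normal around 1000 and quantised to even integers — array summaries are
effectively integers, and this keeps exact fold relations exact in floating
point, so the boundary behaviour of the strict 1.5-fold rule is
deterministic. Planted lateralized baselines are floored at 300 so the
expression gate cannot hide the planted truth. All generators draw from a
single `numpy.random.default_rng(seed)` and echo their parameters in a
`SimTruth` serialised with each artifact.

What the generators do *not* emulate: imaging noise and segmentation error
(masks are clean), tissue deformation, probe cross-hybridisation,
gene-level probe redundancy, or any correlation structure between probes.
Passing tests therefore demonstrate correctness of the quantifications and
filters on well-posed inputs, not robustness to raw-microscopy artifacts —
segmentation and tracing are explicitly upstream of this package.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
oracle-equivalence checks use 100–200 random instances (rank tests at
n ≤ 8, patterns on ~600 µm bands), the lateralization screen 2,000–20,000
probes, the type-I-error simulation 10,000 null draws at n1 = n2 = 9
(matching the largest balanced design in the study), all completing in
seconds thanks to the cached exact null distributions.

## Known limitations

- The counting-line span restriction relies on the two primary branches
  being identifiable; patterns without a clean bifurcation are rejected
  rather than guessed at.
- Raster-only inputs without an order label image count *all* fascicles
  crossing the band, including primaries if they reach it.
- The raster split-angle estimator assumes the annulus around the entry
  contains only the two primaries; extremely proximal secondary branching
  would bias it.
- The explant width measure is contour-based and slightly smooths
  sub-pixel fascicle edges; ratios of widths (the index) are accurate to a
  few percent, absolute widths to ~1 px.
- Exact rank-sum p-values with ties fall back to the approximation; a
  tie-aware exact permutation test is not implemented.
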