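# Methods

## The measurement model

`rodquant` treats a rod-shaped bacterium as a solid of revolution about its
medial axis.  Everything downstream of segmentation follows from two
measured curves per cell: the axis polyline (subpixel, ~1 px arclength
spacing, pole tip to pole tip) and the local diameter at each axis sample
(the chord through the sample perpendicular to the local axis direction,
clipped to the subpixel contour).  Volume is the sum of 1-sample-thick
disks, π·(dᵢ/2)²·step; envelope area is the corresponding surface of
revolution built from frustum elements, 2π·r̄·√(step² + Δr²).  The slope
correction matters: with plain cylinder elements the area of a
hemispherically capped rod is underestimated by >4%, with frusta the capsule
closed form is matched to <1% at 0.01 μm sampling.  A profile of N samples
spans N intervals (the last flat), so a constant profile reproduces the
cylinder closed forms exactly at any sampling.

## Steady-state age assignment

In a steady-state culture the age density is 2·ln2·2^(−a) on [0, 1) (young
cells are over-represented because every division creates two newborns).
Cell length is a monotone proxy for age, so ages are assigned by rank:
age(i) = ln(1 − 0.5·i/(n−1))/ln(0.5) with 0-based rank i, which is exactly
the inverse CDF 1 − log₂(2 − u) evaluated on the uniform rank grid.  Rank 0
maps to age 0 and rank n−1 to age 1 identically.  Ranking is a stable sort,
ties keep input order, and the formula needs n ≥ 2.  Ages are reported in
percent.

## Segmentation and axis tracing

Detection inverts the phase image, thresholds with Otsu, fills holes and
labels connected components.  The working contour level is then re-estimated
as the midpoint of the two class medians: for a symmetric PSF the blurred
edge profile crosses its mid-level exactly at the true boundary, so subpixel
contours extracted at that level sit on the unblurred cell outline.  This is
what makes the diameter measurement accurate to ~1 px without any
deconvolution.

The axis is traced from the region centroid outward in both directions
along the principal axis: 1-px steps, each re-centered on the mask-weighted
centroid of a slit 1.5 × local diameter wide (local diameter from the
Euclidean distance transform) and 3 px thick, perpendicular to the heading.
The perpendicular correction is clamped to 0.3 px per step (≈17°/px turn
rate) so tracing cannot reverse inside the cell.  The walk stops one tube
radius before the mask boundary (the polar cap); from there the axis is
extended in 0.5-px steps along the heading, rotated by the curvature
estimated from the already-traced axis, to the subpixel 0.5-crossing of the
mask.  The curvature-aware extension keeps curved ("banana") cells accurate:
a circular-arc test cell is traced to within 2% of its analytic arc length,
and straight rods show a mean signed length error below 0.5 px over random
orientations.

Accept/reject tests run in a fixed order so every rejection carries exactly
one primary reason code: `border` (bounding box within `border_margin` of
the image edge), `shape` (too small or solidity < 0.85 — this is what
catches fused cell pairs), `degenerate` (no usable elongation, e.g.
circles), `length` (< 1.0 μm), `diameter` (mean outside 0.5–1.5 μm),
`bending` (net curvature > 30°/μm).  Bending is estimated from the
chord-to-arclength ratio of the axis (inverting chord/arc = sinc(θ/2)),
which measures genuine curvature and is insensitive to subpixel tracing
jitter; summed segment angles are not, and would reject straight cells.
Defaults suit ~1 μm wide rods at 14.98 px/μm and are all configurable.

## Profile map

Each accepted cell contributes one column per channel.  The fluorescence
value at axis sample i integrates the 1-px-thick band perpendicular to the
axis, implemented as nearest-axis-sample assignment of every pixel within
the contour dilated by a PSF margin (default 4 px ≈ 3σ of the default PSF);
pixels in the overlap of two dilated cells go to the nearest cell.  This
construction conserves the image's total signal across columns exactly, and
makes Σ(profile) = FluorTotal an identity rather than an approximation.
Cells whose dilated footprint touches the image border are excluded and
logged.  The diameter column stores μm directly; converting it to a
brightness-coded image is left to the writer.

Orientation by a leader channel flips a whole cell (all channels plus the
diameter vector) when the summed leader fluorescence in its second half
exceeds the first half, mapping the bright pole to index 0; ties keep the
original orientation, making the operation idempotent.  Length
normalization resamples the cumulative sum at 100 + 1 evenly spaced edges
and differences, conserving the total to machine precision for any length
ratio.  Collective profiles average the normalized profiles within equal
age intervals (half-open bins, last closed); empty groups yield NaN
profiles with a logged zero count.

## Quantification

* **Background**: the modal pixel value, found with a 256-bin histogram and
  refined as the median of the modal-bin neighbourhood, is subtracted per
  image (per frame — illumination drifts between fields).  Negative
  residuals are clipped at 0 by default; a config switch allows signed
  residuals.
* **Registration**: the fluorescence image is translated to maximize the
  fluorescence summed under all cell contours; the objective over integer
  shifts is a mask×image cross-correlation evaluated via FFT, with the
  argmax taken inside ±`max_shift` (default 5 px).  A flat objective (blank
  channel, no cells) returns (0, 0) with a warning.
* **FCPlus**: the midcell window is the central 0.8 μm of the axis (±0.4 μm
  around the arclength midpoint, rounded to an odd number of samples so
  mid + rest = whole cell exactly).  FCPlus = (F_mid/V_mid −
  F_rest/V_rest)·V_mid is signed; it is exactly 0 for uniform concentration
  and undefined (flagged) for cells shorter than the window.
* **Calibration**: F = n_avg / mean(FluorTotal over qualified cells), in
  proteins per fluorescence unit, where n_avg is the externally known copy
  number of the average cell (e.g. from ribosome profiling); MolsCPlus =
  FCPlus·F.  Multiplying all fluorescence by k leaves MolsCPlus unchanged.
  The same volume-based FCPlus formula is applied to envelope-bound
  channels; their concentration *plots* use ConcWall instead of ConcTotal,
  but the midcell surplus definition is deliberately uniform.
* **Statistics**: age-binned means use 5% bins over [0, 100] (20 bins, last
  closed) with t-based 95% confidence intervals; bins with n < 2 report no
  CI.  Qualifiers are pandas predicates that flag cells out of statistics,
  maps and sorting without deleting their rows; clearing the flags restores
  the original statistics exactly.

## The synthetic-scene generator

The generator is the package's test bench and defines the conditions under
which the pipeline's accuracy claims hold.  It emulates fixed,
immunolabeled cells on agar imaged by wide-field phase contrast and
epifluorescence:

* **Population**: ages i.i.d. from the steady-state distribution (inverse
  CDF sampling); length = birth_length · 2^age (exponential single-cell
  growth; the doubling factor is a parameter so other growth laws can be
  tested); constant diameter.  Defaults — birth length 2.0 μm, diameter
  1.0 μm — are typical of slow-growing *E. coli* in minimal medium.  An
  optional length CV adds biological scatter; it defaults to 0 because the
  deterministic length–age map makes ground-truth comparisons exact.
* **Shape**: capsule (hemispherical caps); constriction is a Gaussian notch
  (σ 0.15 μm) in the local diameter at midcell whose depth ramps linearly
  from onset (default age 0.6) to a 50% depth at division.
* **Optics**: pixel scale 14.98 px/μm; Gaussian PSF σ 0.08 μm (≈ wide-field
  100×/NA 1.35); each molecule deposits `photons_per_molecule` (default
  20 AU) by bilinear splatting before blurring, so the noise-free channel
  integrates to molecules × photons/molecule exactly (photon conservation,
  up to PSF truncation at the border).  The default photon yield puts the
  per-pixel cell signal well above the read noise (SNR ≈ 15), as in usable
  immunofluorescence data.  Background 50 AU, Gaussian read noise σ 2 AU,
  optional Poisson shot noise, optional (dx, dy) misalignment applied to
  fluorescence channels only via Fourier shift.
* **Patterns**: cytoplasmic (uniform in the 3D volume, projected),
  membrane (uniform on the surface, slope-corrected), midcell ring (axial
  σ 0.05 μm on the membrane circle, optional onset age for structures that
  assemble mid-cycle), polar gradient (exponential axial decay).  Copy
  numbers scale with cell volume (cytoplasmic) or envelope area (membrane)
  so concentrations are constant over the cycle unless a linear `ramp` is
  programmed; ring counts are fixed per cell.
* **Placement**: uniform random positions/orientations with ≥ 3 px
  clearance between capsule surfaces (bounded retries, then a capacity
  error); a requested number of deliberately fused pairs (two capsules
  joined at a pole, bent 40°) exercises the rejection logic.
* **Phase contrast** is modelled as dark capsules on a bright background
  with analytic per-pixel coverage and the same PSF — no halo or shade-off
  artifacts.  That suffices for the segmentation contract; performance on
  real phase-contrast images with halos is untested and thresholding is
  configurable for that reason.

What passing tests therefore show: the chain recovers lengths to ≤ 2 px,
diameters to ~1 px, programmed concentrations/ramps/ring counts to within
5–15% under realistic noise — for well-separated capsule-shaped cells under
a symmetric PSF.  They do not certify behaviour on crowded fields, strongly
curved or branched cells, out-of-focus planes, or phase halos.

## Numerical choices and edge cases

* Coordinates are 0-based with pixel centers at integer positions; contours
  and axes live in pixel-center space; (x, y) ordering in all geometry.
* Axis resampling picks round(arclength) + 1 evenly spaced samples, so the
  step is ≈1 px and samples are disk centers.
* The diameter at a sample whose perpendicular fails to cut the contour
  twice is interpolated from neighbours; endpoint diameters are 0 (the
  poles are on the contour).  Polar samples (within one radius of a pole)
  are excluded from the mean-diameter statistic.
* Constriction is the minimum of the 3-sample-smoothed diameter within the
  central 50% of the axis; fewer than 5 samples → not measurable.
* Axis direction tie-break: before any leader orientation, sample 0 is the
  walk's backward pole; `sort` is stable everywhere, and equal-length cells
  keep id order.
* Scenes, and hence entire pipeline runs, are bit-reproducible given
  (parameters, seed); analysis itself uses no randomness.

## Problem sizes

The bundled validation uses 500-cell populations (≈1740² px scenes) for the
end-to-end recovery experiments, 150 cells for the segmentation contract,
and 50–100-cell scenes for everything else — large enough that binomial
noise on the recovery statistics sits well inside the stated tolerances,
small enough to keep a full validation run to a few minutes on one core.
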