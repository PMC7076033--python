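# Methods

This note records how each quantity is computed, the parameter choices
that matter, what the synthetic generator does and does not emulate, and
the numerical conventions adopted where the underlying definitions leave
room.

## Collagen-fiber orientation index (CFOI)

The analysis operates on square crops (default 512 × 512 px at
0.32 μm/px) of a single-channel SHG image.

1. **Windowing.** The crop is mean-subtracted and multiplied by a
   centred isotropic Gaussian with σ = N/6 (pixel (x, y) weighted by
   `exp(−((x−c)² + (y−c)²) / 2σ²)`, c = (N−1)/2). Mean subtraction
   removes the DC pedestal; the window suppresses the wrap-around edge
   discontinuity that would otherwise streak leakage across the
   spectrum. σ = N/6 keeps the corner weight below e⁻⁴·⁵ while
   retaining most of the field of view; the windowing reference used in
   the field states no σ, so the value is this package's choice.
2. **Angular spectrum.** The 2D DFT magnitude |F| is computed (the
   magnitude, not the power |F|² — where the wording of the source
   method is ambiguous we sum magnitudes, which weights faint oriented
   structure more evenly). The DC bin and the innermost ring
   (radius < 2 cycles/image, dominated by residual window leakage) are
   discarded, and a low-pass filter keeps only spatial periods
   ≥ 10 px (≈ 3.2 μm), removing fiber undulation and shot noise.
   Remaining samples are summed into 360 one-degree bins by the polar
   angle of their frequency vector. Only one half-plane is binned and
   mirrored, so f(θ) = f(θ+180°) holds exactly and the profile total
   equals the retained spectral magnitude. No interpolation is used;
   per-pixel binning conserves magnitude exactly.
3. **Wedge partition.** For each candidate direction d ∈ {0°, …, 179°},
   S(d) sums the profile over the 90°-wide double wedge {d ± 45°} ∪
   {d+180° ± 45°} (half-open: [d−45°, d+45°)). The wedge of d and the
   wedge of d+90° partition the circle, so S(d) + S(d+90°) is constant.
   The major orientation maximizes S; ties are resolved toward the
   direction with the larger profile value, then toward the smaller
   angle (a wedge sum is flat while an isolated peak slides inside the
   wedge, so the peak is the natural representative; a fully uniform
   profile reports 0°).
4. **CFOI** = S_minor / S_major ∈ [0, 1]: 1 when the magnitude splits
   evenly (isotropic fibers), → 0 when one wedge holds everything
   (parallel fibers). Note that the reported major orientation lies in
   frequency space, i.e. orthogonal to the dominant real-space fiber
   direction.

A 90° image rotation is lattice-exact and leaves CFOI unchanged to
better than 10⁻⁶; a 30° rotation (which requires interpolation) changes
it by well under 0.05 on clean textures.

## Cell eccentricity

For each labeled region, the covariance matrix of pixel coordinates
gives the equivalent ellipse; axis lengths are L = 4√λ for its
eigenvalues, and eccentricity = `sqrt(1 − L²_minor/L²_major)`, 0 for a
circle, 1 for a line. This is the standard moment-based estimator used
by bioimage region-feature tools (verified against scikit-image's
`regionprops` in the tests). Regions under 5 px are rejected: moment
axes are unstable below that. Orientation is measured from the +x
(column) axis toward +y (row), matching the fiber-angle convention.

Because eccentricity depends on the *ratio* of nearly equal axis
lengths near 0, rasterization bias matters there: a disk rasterized
about a fractional centre measures ≈ 0.12 rather than < 0.05. The
synthetic generator therefore rasterizes cells about integer centres.

## Radius profile and OCI

A cell's angular signature g(θ) is the mean centroid-to-boundary
distance per 1° bin. Boundary pixels are region pixels with a
background 8-neighbour; half a pixel is added to each distance because
boundary pixel *centres* sit about half a pixel inside the true edge
(with the correction, a rasterized disk of radius r reproduces r within
1 px in every bin). A ~1300 px cell has only 120–160 boundary pixels,
so interleaved empty bins are normal and are filled by circular linear
interpolation; regions populating fewer than 90 of 360 bins are
rejected as too small.

The OCI between f(θ) and g(θ) is the Pearson-style circular
correlation at a 90° shift: both profiles are mean-centered and
ℓ2-normalized, and `OCI = Σ_θ f̂(θ) ĝ((θ+τ) mod 360)` with τ = 90°.
The raw cross-correlation integral of the underlying definition is
unbounded; centering and normalizing is this package's choice to give
the stated range [−1, 1] with Cauchy–Schwarz equality exactly at a
shifted match. The 90° shift compensates for the fiber spectrum being
orthogonal to the fibers: cells elongated along the fibers score near
+1. Profiles that are isotropic to machine precision (zero variance)
make the index undefined and raise an error rather than returning 0.
Per-cell OCI (one g per cell) and field-level OCI (g averaged over
cells) are both reported, since either aggregation is defensible.

## Motility and deformation

**Mean velocity** of a track is the unweighted mean of per-interval
speeds (displacement / elapsed time), the convention of time-lapse
tracking software; tracks with missing frames use each interval's
actual duration, and no noise floor is subtracted. Cohort summaries
report one value per cell, with the sample SD over cells (0 for a
single cell).

**CDI** between two frames is |A△B| / |A∪B| for the pixel sets of one
label: 0 for an identical footprint, 1 for disjoint ones. The
denominator is not fixed by the method's originating description; the
union convention is this package's choice because it makes both
endpoints exact and keeps the index in [0, 1]. CDI is symmetric in its
two frames and non-decreasing under increasing translation.

## Synthetic data: what it emulates, what it does not

The generator exists so that every metric can be validated against a
known ground truth, and its defaults define the package's test
conditions.

* **Fiber textures** — 2000 anti-aliased line segments (length 0.1–0.2
  of the canvas, Gaussian cross-section of width 2 px) with axial
  orientations drawn by the doubled-angle von Mises construction:
  sample 2θ ~ vonMises(2μ, κ) and halve, so κ = 0 is exactly uniform
  and κ ≳ 20 essentially parallel. Segments combine by per-pixel
  maximum — SHG brightness saturates where fibers cross rather than
  adding — and Gaussian background noise (SD 0.05) is added, clipped to
  [0, 1]. Many short segments keep the spatial spectrum flat enough
  that a κ = 0 field measures as isotropic (CFOI ≈ 0.92 at 512 px);
  with long additive fibers, crossing interference put enough energy in
  the minor wedge to invert the κ = 8 vs κ = 32 ordering. Even so, the
  single-crop isotropic limit fluctuates (≈ 0.89–0.97 across seeds)
  because a handful of high-magnitude low-frequency samples dominate
  the wedge sums — matching the observation that real isotropic fields
  score well below 1.
* **Cell populations** — ellipses with half-axes solved from area and
  eccentricity (so the programmed eccentricity holds exactly before
  rasterization; default area 1257 px ≈ a 13-μm cell at 0.32 μm/px),
  placed overlap-free by rejection sampling (≤ 1000 retries per cell,
  1 px margin, fully inside the canvas).
* **Tracks** — persistent random walks sampled every 10 min for 3 h
  (19 points): every step has exactly length speed × Δt while the
  heading diffuses with a per-step SD of 20° by default, so cohort mean
  velocity recovers the programmed speed to numerical precision.
* **Deforming mask pairs** — the second frame translates each region
  along a canvas axis by `ceil(level · (extent + 1))` px toward the
  canvas interior: level 0 is an identical copy, level 1 guarantees
  disjoint footprints (CDI = 1), intermediate levels partial overlap.
  Boundary roughening is not simulated.
* **Scenarios** — `day10like` (κ = 32, cell eccentricity 0.9, cells
  aligned with the fiber mean, faster tracks at 0.5 μm/min) versus
  `day21like` (κ = 0, eccentricity 0.25, random orientations,
  0.2 μm/min); the fiber mean direction varies with the seed.

The generator does not emulate instrument noise statistics, fiber
curvature, depth attenuation, segmentation errors, or 3D structure (all
generation is 2D, as the analysis operates on maximum-intensity
projections). Passing tests therefore demonstrate correctness of the
*metrics* and their stated invariances, not robustness to every
property of real microscopy data.

## Numerical conventions and degenerate inputs

* Angular profiles are fixed at 360 one-degree bins.
* A constant image (zero variance after windowing) has no angular
  spectrum and raises a degenerate-input error, as do all-zero
  profiles, zero-variance profiles in the OCI, regions under 5 px, and
  empty masks/track sets.
* All generators are bit-deterministic under their seed; pipeline runs
  with the same config produce byte-identical TSV output, and the run
  manifest (config + package version) suffices to reproduce a run.
* Metrics TSV files are written with shortest round-trip float
  formatting and read back with round-trip parsing, so a file re-read
  equals the in-memory table exactly.

## Problem sizes used in the validation suite

The test suite and acceptance script work at the analysis's native crop
size (512 px) with 10–20 seeds per stochastic claim: 80 textures for
the CFOI bound and concentration sweep, 20 fiber-plus-cell scenes for
the OCI bound, 10-seed scenario pairs for the stage-contrast trends,
and 60–168-track cohorts for velocity recovery.
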