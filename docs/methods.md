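# Methods

This note records the model, the numerical choices, and the reasoning behind
the parameters that matter, in the order the pipeline applies them.

## Input model and conventions

The unit of analysis is a 3D binary airway-tree segmentation with voxel
spacing in mm. On load every volume is reoriented so that axis 0 is
left–right (the coronal-diameter axis), axis 1 anterior–posterior (the
sagittal-diameter axis), and axis 2 points superiorly; all slice indices in
the package refer to this canonical frame. Any nonzero label is foreground,
since segmentation tools disagree on label schemes. CT volumes are paired
with masks only when shape and spacing match exactly — the package never
resamples silently, because the roughness measures live at the millimetre
scale that resampling would corrupt.

## Trachea extraction

The carina is defined operationally on the axial stack: tracking the largest
26-connected airway component from the top, the carina is the last slice on
which the cross-section is a single 8-connected component before it splits
into ≥ 2 components that each cover at least `min_branch_area_mm2` (default
20 mm², about the lumen of a 5 mm bronchus) and persist for
`branch_persistence` slices (default 3). The persistence requirement rejects
single-slice pinches from segmentation noise. Both thresholds are
configurable and recorded in the config hash.

The analysis segment runs from `top_offset_mm` (default 5 mm, rounded to
whole slices) below the most superior airway slice down to the carina
inclusive, and must span at least `min_length_mm` (default 20 mm). Within
each slice only the component continuous with the tracheal lumen (largest
overlap with the slice above) is retained, which strips esophageal air and
other distractors slice by slice.

## Surface mapping

Each retained slice is sampled by `n_theta` rays (default 360) from an
interior origin: the centroid when it lies inside the lumen, otherwise the
distance-transform maximum (strongly non-convex sections can put the
centroid outside). The boundary reference point on a ray is the first
outward position where the bilinear interpolation of the mask crosses 0.5 —
sub-voxel, and single-valued by construction, which a height map requires.
Rays that leave and re-enter the lumen are counted and flagged; isolated
failed rays (< 2 % of a slice) are filled by circular interpolation, worse
slices abort the case with a named error.

The per-slice boundary curves are then re-expressed as radii about the
*segment-mean axis* (the mean of the per-slice centroids), by exact polar
resampling of the boundary points, so that bending of the airway appears in
the total surface. Radii and centroids are finally resampled along z to a
uniform `dz_mm` grid (default 1 mm, the acquisition slice thickness the
method assumes), making downstream quantization independent of the stored
slice spacing.

## Shape / curvature decomposition

With m(z) the per-slice circumferential mean radius, m̄ its average, and
trend(z) a moving average of m(z) over `smoothing_span_mm` (default 15 mm —
long against texture, short against anatomical caliber changes):

* curvature: C(θ, z) = d_x(z)·cos θ + d_y(z)·sin θ + (trend(z) − m̄), where
  d(z) is the per-slice centroid minus the segment-mean centroid. The first
  term is the first-order signature of a bent axis; the second is the
  smooth axial caliber profile.
* shape: S(θ, z) = r(θ, z) − m(z) − drift projection. This has exactly zero
  circumferential mean at every z.
* baseline: r̄(z) = m(z) − trend(z) + m̄ absorbs the remaining axial
  high-frequency caliber fluctuation, so r = r̄ + C + S holds to machine
  precision on every case.

The three constraints usually quoted for such a decomposition (additivity
with a per-slice mean, zero-mean shape, smoothed trend in curvature) cannot
all hold simultaneously; this assignment keeps the first two exact and puts
the leftover axial fluctuation in the baseline, where it affects neither
SR_S nor SR_C. Second-order contamination of the shape surface by strong
axis drift scales as d²/2r (≈ 0.25 mm for a 5 mm bow of a 9 mm lumen, well
under one gray level).

## Height maps and box counting

Each surface component is resampled along θ so one pixel subtends the same
arc (at the mean radius) as one axial step — the counting grid is isotropic
in physical mm and independent of `n_theta` — then shifted to a zero
minimum and quantized at 1 gray level per mm (round half-up). For a 9 mm
radius trachea segment this yields maps of roughly 57 × 75 pixels.

Differential box counting covers the map with an s × s cell grid; edge
cells that overhang the border are weighted by the in-image fraction of
their footprint (the integer-ratio device), so every integer s is
admissible. Per cell, the occupied gray interval [g_min, g_max + 1) is
covered by

    n = max(1, (g_max − g_min + 1) / h),  h = s · max(n_gray, 24) / min(dims)

boxes. Two deliberate choices here:

* **Fractional occupancy.** Integer ceil-counts quantize the per-cell
  contribution so coarsely on low-relief maps that the fitted slope jumps
  with box-stack alignment (several SR points under a θ-origin shift) and
  saturates non-monotonically in texture amplitude. The continuous
  relaxation is exact on flat cells, monotone in the cell's range, and
  reduced the ray-count sensitivity of SR_S to < 0.3 points. All cell
  arithmetic is integer until one final division, so the optimized counter
  and the brute-force oracle agree exactly.
* **Dynamic-range floor.** The classical height normalization
  h = s·n_gray/min(dims) degenerates when the map spans only a few gray
  levels: clamping h at one level destroys the h ∝ s scaling (slope pinned
  at 2), while leaving it unclamped lets one-level noise dominate. Flooring
  the range at 24 levels keeps h ∝ s with h ≥ 3 levels at the smallest
  fitted scale; maps spanning more than 24 levels are unaffected.

The box-size ladder is every integer s in [min(dims)/8, min(dims)/4]. The
upper bound keeps ≥ 4 cells per axis; the lower bound excludes the fine
scales where per-cell ranges collapse to a level or two and the
quantization floor biases the local slope toward 2 (on fractional-Brownian
oracle surfaces this octave recovers D = 3 − H with the least bias; mean
errors at 256², 10 seeds: −0.11, −0.03, +0.06 for H = 0.3, 0.5, 0.7).
Explicit ladders can be passed everywhere and are recorded in results.

D is the OLS slope of log N(s) on log(1/s), clamped to [2, 3] with the raw
value retained, and SR = (D − 2) × 100. A single-gray-level map short
circuits to D = 2, SR = 0. The linear SR mapping anchors a flat surface at
0 % and a space-filling one at 100 %; measured trachea-like phantoms with
realistic texture fall in the 10–30 % range, the same order as clinical
cohort values reported for this family of measurements.

## Tracheal index and LAA950

Per axial position, d_c and d_s are the maximal left–right and
anterior–posterior extents of the sub-voxel boundary; TI is the minimum
d_c/d_s over the window from `ti_offset_mm` (default 20 mm) above the
carina to the segment top, with the attaining slice reported. Because TI is
a minimum statistic over ~50–80 slices, per-slice boundary noise (≈ ±0.15
mm) biases it a few hundredths low relative to the construction ratio of a
phantom; this is inherent to the definition, not noise in the estimate.
LAA950 is the percentage of lung-mask voxels strictly below −950 HU.

## Phantom generator

`make_tube_mask` voxelizes r(θ, z) = e(θ; ratio(z)) + p(θ, z) around a
straight or bowed centerline: `e` is an ellipse with d_c/d_s = ratio and
geometric-mean radius `base_radius`, and `p` is either a deterministic
sinusoid or a fractional-Brownian field synthesized spectrally
(PSD ∝ f^−(2H+2)), periodic in θ and generated on a doubled, cropped z
domain so it does not wrap axially. For tube surfaces the field's k_θ = 0
and k_θ = ±1 Fourier modes are projected out before application: a
circumferentially uniform perturbation is a caliber change and a k = 1 mode
is centerline wander, both of which have dedicated controls
(`cross_section_ratio`, `bow_amplitude_mm`); what remains is pure wall
texture at the requested RMS. Below an optional split plane the lumen
becomes two disjoint child tubes (radius 0.55 r, initial lateral offset
0.65 r, opening at `branch_angle_deg`) that still overlap the parent
footprint across the split, keeping the tree 26-connected; the recorded
ground-truth carina is the lowest single-lumen slice. Default spacing is
0.6 × 0.6 × 1.0 mm, matching a 1 mm slice-thickness inspiratory protocol;
defaults of 9 mm radius and 110 mm length give a ~75-slice analysis
segment. All randomness flows through explicit seeds.

What the phantoms emulate: lumen scale and ellipticity, global bow,
multi-scale wall texture with a known roughness exponent, a carina, and
distractor/pinch artifacts (constructed in tests). What they do not:
CT attenuation, reconstruction kernels, segmentation errors correlated with
anatomy, cartilage-ring periodicity, and expiratory collapse. Passing the
phantom suite therefore validates the measurement chain, not the clinical
variability of SR on real scans.

## Experiment sizes used by tests and the acceptance script

Oracle equivalence uses 200 random maps (8–32 px, up to 16 levels, every
valid box size). Dimension recovery uses 256² fBm maps, 10 seeds per
H ∈ {0.3, 0.5, 0.7}, amplitude 16 levels RMS. Pipeline experiments use the
default phantom at 5 seeds per texture amplitude {0, 0.5, 1, 2} mm RMS for
monotonicity, and two populations of 10 (normal-like: 0.8 mm texture,
ratio 0.85; disease-like: 1.6 mm, ratio 0.70) for the direction contrast —
sizes chosen so the full acceptance run completes in well under a minute
while the stochastic checks are stable across seeds.

## Known limitations

* SR has a grid-alignment sensitivity of a few points on ~60–130 px maps
  (re-rolling the θ origin moves SR_S by up to ~7 points on rough 128²
  test fields); the pipeline's θ origin is fixed and deterministic, so
  per-case results are bitwise reproducible, but SR should be read at
  whole-percent resolution.
* The estimator slightly underestimates D for very rough surfaces
  (H ≤ 0.3), a known property of differential box counting.
* Sub-millimetre textures (≲ 0.5 mm RMS) are at the edge of what a 1 mm
  height quantization can register; SR_S responds monotonically but with
  compressed dynamic range there.
* TI uses lumen diameters only, since the pipeline consumes lumen masks;
  outer-wall TI would require a wall segmentation.
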