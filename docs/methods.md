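# Methods

## Scope and data model

The pipeline converts ordered per-slice multichannel rasters into a
volumetric dataset and quantifies fluorescent-tracer spread. The canonical
containers are:

* `SliceStack` — ordered 2-D multichannel slices with in-plane spacing
  (default 10.4 μm/pixel) and axial spacing (default 70 μm, the section
  thickness);
* `VolumeGrid` — per-channel 3-D rasters indexed (slice, row, column),
  0-based, with spacing (axial, row, col) in μm and a boolean brain mask;
* `BinaryVolume` — tracer-positive voxels plus threshold provenance;
* `DistanceSample` / group summaries — the spread statistic.

Lymph-node analysis is purely 2-D (16 μm cryosections at 0.65 μm/pixel);
no volumetric reconstruction is attempted there.

## Rigid registration

Serial sections are aligned by rotation + translation only. Elastic
registration is deliberately not offered: tears, folds and missing tissue
in vibratome sections turn deformable models into artifact generators.
`RigidTransform2D` rotates about the geometric image centre by
`angle_deg`, then translates by `(dx, dy)` = (column, row) pixels;
composition and inversion are closed, and `estimate_rigid_transform(fixed,
moving)` returns the transform mapping *moving* onto *fixed*.

The similarity objective is normalized cross-correlation (NCC), invariant
to the linear per-slice brightness changes that `equalize_brightness`
later removes. Three details matter in practice and are part of the
design:

* **Tissue-masked scoring.** NCC is evaluated only over an eroded
  Otsu-foreground mask of the fixed image intersected with the warped
  moving foreground. Slice-to-slice shape change (sections shrink and grow
  through the stack) otherwise lets the high-contrast tissue/background
  edge ring drag the estimate by a pixel or more.
* **Coarse-to-fine search.** A grid over rotation (1° steps, ±8° pairwise,
  ±10° anchored) with, per angle, the translation peak of FFT-based
  normalized template matching of the rotated moving image's central crop
  inside the fixed image (`skimage.feature.match_template`). Whole-frame
  phase correlation was evaluated and rejected: with partial overlap
  (relative shifts up to ~20 px) its peak is unreliable. The top five
  candidates are polished by Nelder-Mead over (angle, dx, dy); refining
  several candidates matters because the best coarse score does not always
  sit in the right basin.
* **Cubic resampling.** Warps use cubic B-spline interpolation; bilinear
  resampling was measured to cost several tenths of a pixel of recovery
  precision. Spline overshoot is clipped back to the source intensity
  range when slices are resampled (masks use nearest-neighbour).

`register_stack` anchors the middle slice (identity), propagates pairwise
estimates outward (each raw slice registered to its already-aligned
neighbour), then runs an anchored pass (each slice re-estimated directly
against the reference slice, with the chain estimate as an extra start)
and two groupwise polish passes against the mean of all registered slices.
The chain provides robust initialization; the anchored/groupwise passes
make per-slice errors independent instead of cumulative — sequential
chaining alone accumulates a random walk of small per-pair errors that
breaches half-pixel accuracy by the stack ends.

On a 20-slice phantom (96×128, misalignments σ = 4 px / 2°, bounded at
10 px / 5°, 8-bit noise σ = 3) the full procedure recovers ≥ 95% of slices
within 0.5 px and 0.5°; the acceptance script recomputes this rate.

## Brightness equalization, assembly, projections

Each nuclei-channel slice is linearly rescaled so its foreground-mean
matches the stack-wide median of foreground means (zero-mean slices are
left unscaled with a warning); other channels are untouched. Registered
slices are stacked into a `VolumeGrid` with spacing (70, 10.4, 10.4) μm by
default. The brain mask is derived from the nuclei channel: pooled Otsu
threshold, per-slice hole filling, largest 3-D connected component.
Maximum projections map axis names to array axes as: horizontal → axial
index (axis 0; sections are cut horizontally), coronal → rows,
sagittal → columns.

## Tracer segmentation and hemisphere split

`otsu_threshold` maximizes between-class variance over classes {≤ t} and
{> t}, ties broken toward the smallest t; positivity is strict
(intensity > t) and restricted to the brain mask. The implementation is
exhaustive-scan exact and is cross-checked in tests against an independent
brute-force oracle.

The hemisphere separation surface is a user-supplied per-slice polyline in
(row, col) coordinates, extruded axially; a voxel is classified by the
sign of its column offset from the boundary column interpolated at its
row. Voxels exactly on the surface are counted separately rather than
assigned by tie-break, which makes the conservation identity
ipsi + contra + on-surface = total exact by construction.

## Spread statistic

Distances are always physical: the exact anisotropic Euclidean distance
transform (`scipy.ndimage.distance_transform_edt` with per-axis sampling,
a feature-transform algorithm, not a chamfer approximation) gives each
non-positive voxel its μm distance to the nearest positive voxel. Reported
summaries use linear interpolation of order statistics for quantiles.

Sampling defaults to exhaustive; `sample_n` (e.g. 3450) with a seed gives
a uniform subsample without replacement. Group comparison runs on pooled
voxel-level distances (KS/Lilliefors normality per group, Kruskal-Wallis,
Dunn-Bonferroni pairwise) — and because pooling voxels across brains
inflates the effective n (pseudo-replication), per-brain medians are
always emitted alongside, with a caveat line in the report.

## Lymph-node quantification

The red (autofluorescence) channel is brought to the green channel's
brightness scale by matching 99th percentiles over background-excluded
pixels (those above each channel's median) — compensating exposure
differences between channels — then subtracted pixelwise with negatives
clipped to zero. The corrected image is Otsu-thresholded and pixels above
threshold are counted.

Otsu always returns *some* threshold, so a signal-free corrected image
(pure clipped noise residual) would otherwise be cut inside its own noise
and report spurious tracer. A robust guard therefore declares an image
tracer-free when the mean of its above-threshold class does not exceed
`5 × σ̂`, where σ̂ is the 84.1th percentile of the corrected image — the
Gaussian-σ estimator appropriate for a zero-clipped residual and
insensitive to the few true signal pixels. The guard is compared to the
above-threshold mean rather than the threshold itself because the
smallest-t tie-break legitimately places the cut at the top of the noise
when a far signal cluster exists.

## Vessel-vs-parenchyma intensity

Per image, manually drawn vessel / surrounding-tissue / artifact masks
(pairwise disjoint) define regions; artifact pixels are excluded from all
measurements; each region reports total intensity divided by pixel area.
Pairing is within-image (vessel minus tissue), tested by Shapiro-Wilk on
the differences and a paired t test. Group aggregation across animals uses
an unpaired Mann-Whitney U test; the source protocol describes this
comparison as "Mann-Whitney for paired data", which is internally
inconsistent (Mann-Whitney is unpaired), so the outcome carries an
explicit caveat note.

## Statistical tests

All tests are two-sided with α = 0.05 and return a uniform `TestOutcome`.
scipy/statsmodels routines back Shapiro-Wilk, KS/Lilliefors (estimated
mean/sd), Kruskal-Wallis (tie-corrected, χ² with k−1 df), Wilcoxon
signed-rank, Mann-Whitney U and the paired t test; every outcome is
cross-checked in tests against enumeration, hand-formula or simulation
oracles. Dunn's post hoc test is implemented directly: z on mean ranks
with the tie term Σ(t³−t)/(12(N−1)), raw p from the normal tail, corrected
p = min(1, raw × k(k−1)/2), validated against a permutation null.

Exact-vs-approximate switchovers (recorded in each outcome's notes):
Wilcoxon uses the exact null for ≤ 25 untied nonzero differences (zeros
dropped); Mann-Whitney uses the exact null for pooled n ≤ 12 without
ties; both fall back to tie-corrected normal approximations. Type-I error
for each test at n = 20/group is calibrated to 5% ± 1.5% over 2000 null
simulations in the acceptance checks.

## Synthetic phantoms: what they emulate, and what they do not

The generator is the package's stand-in for non-deposited raw data; all
of its outputs are pure functions of a `PhantomSpec` including the seed.

* **Brain mask**: per-slice ellipses forming an ellipsoid with a midline
  notch (unambiguous hemispheres). The axial semi-axis extends ~25% past
  the stack so end slices keep substantial tissue, as a real cutting
  range does.
* **Nuclei texture**: a dominant slice-shared component with sharp band
  boundaries (laminar, cell-dense vs cell-poor anatomy, quantile-banded
  smoothed noise) plus shared fine grain and weak per-slice detail
  (σ = 0.8 px in-plane) emulating section-to-section cellular variation.
  The shared component is what makes serial-section registration
  well-posed; the detail amplitude (0.15 of texture scale) sets the
  practical precision floor.
* **Diffusive ("sacrificed") field**: the free-space 3-D Green's function
  c(r,t) = M(4πDt)^{−3/2} exp(−r²/4Dt) at voxel centres, masked and
  renormalized to mass M. Defaults D = 150 μm²/min, t = 30 or 90 min give
  a half-maximum radius of order 100 μm — a compact deposit around the
  injection site. t = 0 degenerates to a delta at the injection voxel.
  The analytic form (rather than a numeric PDE) makes the generator
  testable against a closed form; no quantitative transport parameters
  are claimed for real tissue.
* **Advective ("living") field**: a Gaussian tube (width 15 μm) around a
  random branching skeleton grown by a biased walk from the injection
  site across the midline (reach 1500 μm arclength), amplitude decaying
  exponentially in arclength, plus a small injection-site pool; masked
  and renormalized to M. This is the simplest field that reproduces
  spread along vessel/fiber-tract paths into the contralateral
  hemisphere.
* **Sectioning**: each axial plane becomes a slice, independently
  perturbed by zero-mean rigid jitter (σ = 3 px / 1.5°, clipped at
  10 px / 5° — physical slide placement is bounded), with additive
  Gaussian noise (σ = 3, 8-bit units) and quantization emulating PNG
  export.
* **Lymph nodes**: non-overlapping discs inside an elliptical node —
  tracer particles bright in green only, autofluorescent particles
  equally bright in green and red (a `red_gain` knob emulates exposure
  mismatch), nuclei texture in blue, noise and quantization as above.

Not emulated: point-spread functions, bleaching, tissue deformation,
vascular anatomy, hemodynamics, or any CSF/ISF compartment physics.
Passing tests therefore demonstrate the *pipeline's* correctness on data
whose ground truth is known — registration recovery, conservation laws,
oracle-exact distances, direction of the live/dead effect — not the
biological magnitudes of the original experiment, whose raw data are not
public. Absolute distance medians or intensity differences from real
tissue are out of scope by design.

## Problem sizes and numerical choices

Default analysis sizes are chosen for desk-scale reproducibility: phantoms
of 16-20 slices at 64×96 to 96×128 pixels, 600-position positive sets for
matched-count comparisons, 1500-voxel distance subsamples, 2000 null
simulations for calibration. Registration precision targets (0.5 px,
0.5°) are met at the 96×128 frame; smaller frames trade precision for
speed and the unit tests assert proportionally looser bounds. Ties in
Otsu resolve to the smallest threshold; degenerate inputs (constant
images, empty regions, all-zero differences) raise errors rather than
returning conventions, except where a documented guard (lymph-node noise
floor) deliberately returns zero.

## Known limitations

* Sequential + anchored registration assumes a single connected tissue
  profile per slice; it has no tear repair and no anatomical detector
  (e.g. cerebellum exclusion is input curation, not detection).
* The hemisphere surface is always user- or phantom-supplied.
* Voxel-level group comparison is pseudo-replicated; per-brain medians
  are reported but no mixed-effects model is fitted.
* The KS normality p-values use the Lilliefors table approximation and
  saturate at its bounds.
* Exact Wilcoxon requires untied |differences|; ties force the normal
  approximation regardless of n.
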