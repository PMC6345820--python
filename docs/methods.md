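# Methods

This note documents the models, parameter choices and numerical conventions
behind `clearquant`, and what its synthetic-data validation does and does
not demonstrate about real cleared-organ data.

## Imaging model and conventions

3D stacks are single-channel intensity grids indexed `(z, y, x)` with a
physical voxel size `(dz, dy, dx)` in µm; 2D photographs are `(y, x)`
grayscale or RGB. All derived physical quantities are products of element
counts and element volume/area: an object of `N` voxels has volume
`N·dz·dy·dx` µm³; a silhouette of `N` pixels at `p` pixels/cm has area
`N/p²` cm². Centroids are unweighted means of element indices scaled to µm
(0-based origin). No sub-voxel modelling is attempted: partial-volume
effects at object boundaries are treated as noise bounded by the validation
tolerances below.

## Core primitives

* **Median filter.** Window sides must be odd; borders are handled by edge
  replication. Zero padding would create an artificial dark rim whose
  histogram mass biases a subsequent Otsu threshold toward the background;
  replication avoids this at the cost of slightly correlated border
  statistics.
* **Otsu threshold.** 256 equal-width bins over `[min, max]` (the de facto
  standard for data of 8-bit origin), between-class variance maximised by
  cumulative scan, first bin wins exact ties. The returned threshold is a
  bin center, so it is invariant (up to float rounding) under affine
  intensity rescaling with correspondingly rescaled bin edges. The
  criterion can plateau exactly across empty histogram bins between two
  well-separated modes; any plateau member yields the same binarization up
  to the (empty) bins between them. Constant images raise a
  degenerate-input error rather than returning an arbitrary value.
* **Binary morphology.** Footprints are centered balls/disks (default
  radius 1, the least destructive choice) or cubes/squares; out-of-grid
  space is background. Closing is computed on a mask padded by the
  footprint radius so that it remains extensive at the grid border (the
  unpadded finite-grid composition of dilation and erosion is not). Hole
  filling marks every background component not connected to the border,
  with minimal (face-adjacency) background connectivity — the standard
  complement of maximal foreground connectivity.
* **Connected components.** Default adjacency is 26 in 3D and 8 in 2D:
  maximal connectivity keeps a blurred, slightly fragmented glomerular
  shell as a single object. Labels are explicitly remapped to raster-scan
  first-encounter order, so label maps are bit-reproducible across runs and
  library versions, and size ties in "largest object" resolve to the first
  object in raster order.

## Glomeruli pipeline

Stage order: median filter (3³) → Otsu → threshold (`>=`) → binary opening
(ball r=1) → hole filling → connected components → features → two-class
classification. Opening precedes hole filling, mirroring the 2D silhouette
pipeline where the order matters and is fixed; on 3D stacks the order is
immaterial for well-separated objects. Hole filling converts stained shells
(basement-membrane-dominated staining leaves the capsule interior dimmer)
into solid objects, so voxel counts measure whole-glomerulus volume.

**Two-class model.** With only a few manually labelled positive examples,
nothing richer than a nearest-centroid rule on object volume is
identifiable; the classifier therefore stores per-class feature centroids
(default feature: `volume_um3`; mean intensity can be added) and assigns
each object its nearest centroid, ties to class 2. Two operational rules
encode how partially visible objects are handled: objects touching the
stack border are forced to class 2 regardless of size (their measured
volume is meaningless), and when no negative examples are labelled the
class-2 centroid defaults to the smallest-volume unlabelled object — the
natural prototype of the debris class. When no manual labels are provided
at all, supervision is emulated by splitting object volumes in two classes
(Otsu on the volume values) and taking the three objects nearest the median
of the large class: an operator labels typical, fully visible big objects,
not extremes. A plain median over all objects is *not* used because scenes
where small background objects outnumber glomeruli would put the median in
the wrong mode.

**Volume histogram.** Six equal-width bins spanning `[min, max]` of the
class-1 volumes, rightmost edge inclusive; group 0 (smallest volumes) is
rendered red. Equal-width was chosen over equal-count as the conventional
reading of a "volume histogram"; if all volumes coincide the edges are
widened by a machine-epsilon step and all objects land in group 0. With no
class-1 objects the histogram is the empty marker `None`, not an error.

## Vessel pipeline

Median filter → global threshold (Otsu default, fixed override) → opening
(ball r=1, skippable) → removal of components below 27 voxels (a 3³
speck). The dye fills vessel lumina, so tubes are solid bright structures
and a global threshold suffices; no centerline, radius or branching
statistics are computed (deliberately out of scope). On clean data (little
blur, low noise) the median filter and opening only erode thin tubes, so
configs for such data should set `median_window=1` and `opening_radius=0`;
the defaults are tuned to noisy acquisitions.

## Shrinkage pipeline

Silhouette segmentation follows a fixed stage order: median 3×3 → fixed
threshold → opening → hole fill → dilation → hole fill → particle filter →
largest object. The fixed threshold defaults to the photo's post-median
mid-range value, which separates a lit organ from a dark background without
per-photo tuning, and is overridable per image. The particle filter splits
component sizes into two classes (Otsu on the size values) and keeps the
large class; fewer than three components, or uniform sizes, pass through
unchanged. The scale object is handled by a user-supplied rectangular ROI
(casual phone photographs make automatic ruler detection unreliable);
foreground inside the ROI is excluded from organ candidates, and
calibration takes the largest thresholded object in the ROI and divides its
longest bounding-box extent by the known physical length (1 cm by default).

Dilation (radius 1 by default) biases area upward by roughly one perimeter
worth of pixels; accuracy-critical measurements (and the synthetic
validation) set `dilation_radius=0`. RGB photos are converted to grayscale
with ITU-R 709 luminance weights.

**Statistics.** Paired two-sided t-test on differences `d = after − before`:
`t = mean(d)/(sd(d)/√n)` with `n−1` degrees of freedom, p-value from the
t-distribution's survival function, significance at p < 0.05. Conventions
for degenerate inputs: identical pairs give `t = 0, p = 1`; nonzero
differences with zero variance give `t = ±∞, p = 0`; `n < 2` is an error.
`run_study` tests across the records it is given (one per organ); testing
per organ across animals is done by calling `paired_t_test` on that
grouping directly.

## Synthetic scenes

**Kidney stacks.** Default: 128³ voxels at 5 µm isotropic (a 640 µm cube —
43 glomeruli in that volume ≈ 150/mm³, a realistic adult-mouse cortical
density). Glomeruli are spheres with truncated-normal radii 36 ± 3 µm on
[30, 44] µm (resampled, so no probability atom sits at the bounds); the
mean digitized volume is ≈ 2×10⁵ µm³. Each is rendered as a bright shell
(10 µm, intensity 200 — the basement membrane binds most dye) over a
dimmer interior (120 — the capillary tuft also carries dye; a fully dark
interior would be unrealistic for an intravascular stain). Three glomeruli
are planted cut by the volume border (center slightly outside the grid) to
emulate partially visible objects. Vessels are face-to-face quadratic
Bézier tubes (radius 15 µm — at 5 µm sampling, tubes much thinner than
3 voxels are below what threshold segmentation resolves), optionally
branching off earlier tubes; 12 small bright spheres (10–16 µm) stand in
for tubule debris and dye aggregates. All objects keep ≥ 45 µm surface
clearance (9 voxels, comfortably above the 3× median window needed to keep
objects separable), via rejection sampling with a bounded attempt budget.
Rendering order: intensities → anisotropic Gaussian blur σ = (5, 2, 2) µm
(axial-dominant, light-sheet-like) → Poisson noise (gain 1) → additive
Gaussian noise (sd 2), giving peak SNR ≈ 13. The elevated-background
regime (`KidneySceneSpec.pei_s()`) raises the tubule intensity from 10 to
80, reproducing the qualitative contrast loss of a low-molecular-weight
conjugate that leaks into tubules.

**Organ photos.** 512² images; the organ is a disk of radius 90 px
perturbed by random low-order Fourier harmonics (orders 2–5, relative
amplitude ≤ 8%), intensity 180 on a background of 30, with a 230-intensity
ruler bar of known pixel length (100 px ≡ 1 cm by default), a ±5%
horizontal illumination ramp, 1 px Gaussian blur and sd-4 sensor noise.
The after-photo scales the contour by the linear shrink factor about the
organ center, so planted pixel areas obey the s² law up to digitization.

**What passing tests show — and don't.** The generators validate the
*computational* pipeline: that segmentation, feature extraction,
classification, calibration and statistics recover planted truth under
controlled blur and noise. They do not model refractive-index-mismatch
artifacts, depth-dependent attenuation, clearing-induced deformation
fields, touching or non-spherical glomeruli, perspective or colour effects
in photographs, or real staining heterogeneity. Results on real organs
depend on those factors and on acquisition settings the defaults cannot
anticipate; every relevant parameter is therefore exposed in the configs.

## Problem sizes used in validation

The test suite and the acceptance script run the study conditions at
desk scale: 128³ stacks (the generators' default), 20 scenes for count
recovery, 5–10 scenes for volume/Dice/summary statistics, and 1,000 random
samples for the t-test numerics — sizes chosen so the full validation
completes in a few minutes on one CPU while keeping every check at its
stated tolerance.

## Known limitations

* Structuring elements are isotropic in voxel units; with anisotropic
  voxels a "ball" is physically an ellipsoid. For the default isotropic
  5 µm sampling this is moot; for strongly anisotropic data choose radii
  with the coarsest axis in mind.
* The nearest-centroid classifier is one-dimensional by default; objects
  whose volume falls between the two modes (e.g. a large debris clump) are
  assigned by distance alone. The 40-vs-43 count structure is a property of
  border truncation handling, not a claim that the classifier reproduces
  any particular proprietary implementation.
* Otsu on sparse-foreground stacks is sensitive to the relative population
  of the modes; scenes dominated by background with very few bright voxels
  can pull the threshold into the background shoulder. The vessel pipeline
  accepts a fixed threshold for exactly this case.
* Label maps written to disk are 16-bit (≤ 65,535 objects).
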