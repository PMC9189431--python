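# Methods

## Scope and model

`embryoseg` segments nuclei and cells in 3D fluorescence volumes with a
fixed-order pipeline and quantifies per-cell morphology and protein
expression.  The pipeline assumes:

* a **volumetric nuclear marker** (e.g. DAPI) in one channel;
* optionally a **cell marker**, either membrane-localised (e.g. E-cadherin)
  or volumetric, in a second channel;
* bright objects on a darker background;
* an anisotropic but axis-aligned voxel grid, described by a physical
  spacing `(dz, dy, dx)` in μm.  The design target is confocal embryo
  imaging at ~0.1 x 0.1 x 1.0 μm.

All physical parameters (scales, radii, sigmas) are given in μm and
converted to voxel units per axis internally; the axis order is (z, y, x)
and coordinates are 0-based, with the physical position of voxel `i` taken
as `i * spacing`.

## Pipeline stages

**1. Nuclear-centre detection.**  Two interchangeable blob detectors
estimate one seed point per nucleus.

* *Basic (LoG)*: the scale-normalised Laplacian of Gaussian at the scale
  implied by the expected blob radius r (`sigma = r / sqrt(3)` per axis,
  physical units), negated so bright blobs respond positively.  Fast, but
  tuned to roughly ellipsoidal objects.
* *Advanced (Hessian)*: the image is Gaussian-smoothed at a scale s and the
  3x3 matrix of second derivatives (in μm units, by central differences of
  the smoothed volume) is evaluated per voxel.  All three eigenvalues
  negative indicates the interior of a bright structure of any shape; the
  blobness score is the geometric mean of the eigenvalue magnitudes
  (`|l1*l2*l3|^(1/3)`), zero elsewhere.  Eigenvalues are obtained with the
  closed-form trigonometric solution for symmetric 3x3 matrices, which is
  orders of magnitude faster than batched LAPACK calls at millions of
  voxels.

Detections are 26-neighbourhood local maxima of the response above a
user-set quality threshold; the *quality* of a detection is defined as the
detector response at the maximum, so thresholds are implementation-relative
and always recorded in the parameter file.  Flat neighbourhoods are
rejected (a constant image yields no detections).  No suppression beyond
the 3x3x3 non-maximum rule is applied.

**2. Noise and background suppression.**  Gaussian smoothing with per-axis
physical sigmas (reflective boundaries, mean-preserving), then a white
top-hat (input minus grayscale opening) with a *flat ellipsoidal*
structuring element of physical radius — a voxel-unit ball would be badly
anisotropic at 10:1 spacing.  For speed the volume can be block-averaged
laterally by an integer factor before the top-hat and linearly resampled
back afterwards; on smooth backgrounds the approximation error is well
below the foreground contrast.

**3. Nuclear segmentation.**  A one-voxel seed mask is built from the
detections; the anisotropic Euclidean distance transform (distance of every
voxel to its nearest seed, in μm) is flooded from the seeds by
marker-controlled watershed, restricted to a foreground mask obtained by
global histogram thresholding (Otsu, triangle, isodata, mean, li or yen) of
the top-hat output.  Label i corresponds to detection i; seeds that fall on
background produce empty labels and a warning, so label ids always index
the detection list.  Global (not adaptive) thresholding is deliberate: a
z-adaptive threshold can always be tuned to one dataset but not universally,
and the pipeline favours reproducibility over per-dataset tricks.

**4. Cell segmentation.**  The segmented nuclei are multi-voxel seeds.  The
flooded map is

* *volume-marker mode*: the anisotropic EDT of the nuclei;
* *membrane-marker mode*: an image-weighted geodesic distance in which a
  step between 26-neighbour voxels i, j costs

      d(i, j) = sqrt( (lam * ||x_i - x_j||^2 + (I_i - I_j)^2) / (lam + 1) )

  with `||x_i - x_j||` in μm.  Bright membranes inflate path costs and act
  as barriers, so region growth stops at membranes even where the Euclidean
  midpoint would lie elsewhere.  As `lam -> inf` the metric collapses to
  the Euclidean graph distance (the normalisation by `lam + 1` fixes the
  constant so that limit is exact); as `lam -> 0` intensity differences
  dominate.  The transform is an exact multi-source Dijkstra on the
  26-neighbour voxel graph (numba-compiled binary heap), with distances
  zero on nucleus voxels and ties broken by (distance, seed id), making the
  output deterministic.  Tests pin the transform against exhaustive
  shortest-path search on small grids.

Flooding is restricted to a global threshold mask of the smoothed cell
channel, with nucleus voxels always included so nucleus i is contained in
cell i by construction.

**5. Measurement.**  Volumes are voxel counts times the voxel volume;
centroids are intensity-unweighted means of voxel centres (μm).  Per
channel: nuclear mean, cytoplasmic mean (cell minus nucleus),
nuclear/cytoplasmic ratio of means (mean, not integrated, intensities —
recorded in column names), and optionally the nuclear mean divided by the
nuclear mean of a normalisation channel (e.g. DAPI) to correct for
depth-dependent signal loss.

**6. Inner/outer classification.**  The embryo centroid is the unweighted
average of all nuclear centroids.  With `D_i` the distance of cell i's
nuclear centroid from it and `D_m = max_j D_j`, cell i is *inner* iff
`D_i < D_T * D_m` (strict; the boundary and the most distant cell are
outer).  `D_T` defaults to 0.5 and the classification is insensitive to
~±10% changes except for cells whose `D_i` lies near the threshold radius.
A single-cell embryo (`D_m = 0`) is classed inner by convention, with a
warning.  Group summaries report medians and IQRs with two-sided
Mann-Whitney (two-sample Wilcoxon) tests, exact where sample sizes and ties
allow; no multiplicity correction is applied.

## Simulated embryos

The simulator provides ground truth for validation:

* **Geometry.**  `n` ellipsoidal nuclei (default full axes 10.0 x 7.5 x 7.5
  μm) with uniformly random orientations are placed by rejection sampling:
  centres uniform in a packing sphere, hard non-overlap (surface sampling
  with a 0.2 μm safety margin), whole cell required to fit in the imaged
  volume.  An attempt cap turns infeasible densities into an explicit
  packing error.  Cell bodies are the nearest-nucleus (EDT/Voronoi)
  partition clipped to a maximum reach beyond the nucleus surface;
  membranes are the inter-cell boundary faces plus the outer shell, of
  configurable thickness.  The cell channel additionally carries a diffuse
  cytoplasmic component (default 20% of the membrane brightness) inside
  cells, as real membrane markers do via their unbound pool; without it the
  embryo occupies so little of the histogram that no global threshold can
  recover the cell extent.
* **Imaging.**  On a finer grid than the output: paint baseline +
  fluorophore, attenuate by `exp(-attenuation * depth)` with depth from the
  first z slice (default 0.01/μm — scattering dims deep slices), blur with
  a Gaussian PSF (default sigma 0.8 μm axial, 0.2 μm lateral), block-average
  to the output spacing, then apply unit-mean multiplicative gamma noise.
* **SNR.**  Defined, here and everywhere in the package, as
  `(mean fg - mean bg) / std bg` with fg the eroded true nucleus mask and
  bg the complement of its dilation.  The gamma shape is fixed (25, i.e.
  ~20% coefficient of variation) and the *fluorophore contrast* is solved,
  from the noiseless render, so the output hits the target SNR.  The
  alternative — fixing the contrast and inflating the noise variance —
  needs gamma shapes far below 1 at low SNR, i.e. sparse huge spikes that
  are locally indistinguishable from nuclei; solving the contrast instead
  keeps every point of the SNR axis a plausible weakly-stained acquisition
  while preserving exactly the statistical structure the validation sweeps
  use (an SNR axis, a density axis, known centroids).
* **Scale presets.**  The full-size geometry (80 x 800 x 800 output voxels
  at 0.1 x 0.1 x 1.0 μm laterally/axially) produces ~100M-voxel renders and
  is impractical for routine sweeps.  The *half-scale preset* used by the
  validation grid and the test suite shrinks the embryo geometry by 2
  (nuclei 5.0 x 3.75 x 3.75 μm full axes, packing radius 15 μm, cell reach
  1.5 μm) and coarsens lateral sampling to 0.2 μm while keeping the 1 μm
  axial spacing, giving 40 x 192 x 192 output voxels per embryo.  Relative
  crowding at the top of the density axis (nearest-neighbour distances
  comparable to the nuclear long axis) is preserved.  The full-size nuclei
  cannot be packed 32-fold into a volume of this voxel budget at all, so
  scaling the geometry rather than only the field of view is forced.
* **Determinism.**  Identical parameters + seed give bit-identical volumes
  and truth; the grid driver derives per-embryo seeds from one master seed.

## Validation metrics

* `E_c = |N_gt - N_seg|`: absolute cell-count error, with `N_seg` the
  number of non-empty segmented labels.
* `E_nl`, `E_cl`: Euclidean distances between ground-truth nucleus/cell
  centroids and the centroids of the matched segmented objects.  Matching
  is an optimal one-to-one (Hungarian) assignment minimising total
  distance, discarding pairs beyond a match radius; the radius defaults to
  the nuclear long axis (5 μm at half scale), since nuclei closer than
  that overlap substantially.  Hungarian rather than greedy matching makes
  the metrics order-independent.  Localisation errors are emitted both
  pooled per matched nucleus and aggregated per embryo.
* Sensitivity: matched / N_gt.
* Nearest-neighbour analysis: per-nucleus nearest-neighbour centroid
  distance joined with detection success, for density-vs-detectability
  summaries.

The validation grid defaults to SNR in {1, 2, 3, 4, 5, 7, 10, 15, 20} and
cell counts in {2, 4, 8, 12, 16, 24, 32}, 3 replicates per condition (189
embryos), all overridable.  Per-embryo failures are recorded, not fatal.
The shipped sweep settings (`default_grid_config`) use LoG radius 2.4 μm
with quality threshold 0.7 and Hessian scale 1.5 μm with threshold 0.1,
chosen once on pilot renders so that the weakest true response (deepest
nucleus at SNR 1) clears the noise-maximum floor for both detectors; the
cell stage uses membrane mode with `lam = 1`.

## Numerical choices and edge cases

* Distances and flooding use the 26-neighbour graph throughout; watershed
  output is deterministic (ties toward the smaller seed id).
* The nuclear-segmentation EDT is computed in physical μm, not voxels.
* Thresholding a constant image returns an empty mask with a warning;
  `measure_snr` of a constant image is defined as 0 with a warning.
* Empty cytoplasm (cell == nucleus) yields missing cytoplasmic statistics,
  not an error.
* Config files are flat YAML; unknown keys are an error (a silently
  ignored typo would break reproducibility); round-trips are lossless.
* Label volumes are written as uint16 OME-TIFF; >65535 labels is an error.

## What the simulations do and do not show

The simulator reproduces the statistical structure validation needs —
known centroids and labels, an SNR axis, a density axis, depth attenuation,
anisotropic PSF — but not real optics (aberrations, measured PSFs), real
chromatin texture (nuclei are homogeneous ellipsoids), autofluorescence,
or touching/deforming cell boundaries.  Passing the validation sweep shows
the pipeline recovers counts and centroids under controlled degradation;
it does not certify accuracy on any particular real acquisition, where
threshold method and detector scale must still be chosen to match the
data.

## Known limitations

* TIFF/OME-TIFF input only; no proprietary formats, no GUI, no OMERO.
* Global thresholding only (by design, see above).
* No sub-voxel detection refinement; centroid accuracy in z is limited by
  the coarse axial sampling.
* The Hessian detector is several times slower than the LoG detector.
* No time-lapse support; volumes are treated independently.
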