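# Methods

## Scope and model

The package quantifies 3D refractive-index (RI) tomograms of intestinal
organoids. Tomographic reconstruction itself (deconvolution of raw
intensity measurements, aberration correction) is out of scope: the input
is a reconstructed scalar RI volume with known anisotropic voxel spacing,
or a synthetic phantom standing in for it.

The physical model is the linear RI–concentration relation for protein,
`n = n_m + α·ρ` with the specific refractive increment `α = 0.185 mL/g`
and medium RI `n_m` (default 1.337, always recorded explicitly — it is a
configuration value, not something inferred from data). Density is
reported in g/mL, which is numerically identical to pg/µm³, so
`mass [pg] = density [g/mL] × volume [µm³]`; dry mass is reported in ng.
Densities printed elsewhere as "ng/µm³" at the ~0.1 scale are on the same
numeric scale as g/mL; the package uses the dimensionally consistent
convention throughout. Negative per-voxel densities (sub-medium RI under
noise) are retained in all statistics so means stay unbiased under
symmetric noise.

## Coordinate and unit conventions

Volumes are indexed `[x, y, z]`; TIFF page k is axial slice z = k, rows
map to y and columns to x; z = 0 is the slice nearest the coverslip. All
coordinates are 0-based and all ranges half-open. Lengths are µm, times
hours, growth rates h⁻¹.

## Synthetic phantoms

The generator emulates the *statistical* structure the analysis depends
on, not the optics. An organoid is a solid region (sphere for the
enterocystic stage; a body with spherical buds for the multilobular
stage) split by a Euclidean distance transform into an epithelial shell
of configurable thickness and an enclosed lumen.

- **Cell texture.** The shell is partitioned into Voronoi domains of
  ~10 µm diameter (one seed per cell-sized volume); each domain receives
  one density draw, so fixed-size subvolume cubes contain whole-cell-like
  regions and the between-cell variance the subvolume statistics rely on
  is present. Default density statistics are the measured live/dead
  epithelial values: live 0.115 ± 0.050 g/mL, dead 0.101 ± 0.048 g/mL,
  with a per-cell live/dead Bernoulli draw at `dead_fraction`.
  Negative draws are clipped at zero (physical density is nonnegative);
  for these parameters the clipping raises the expected mean by
  ≈ 2–3 × 10⁻⁴ g/mL, which is why recovery tests carry an explicit
  5 × 10⁻⁴ bias allowance on top of their 3-s.e.m. tolerance.
- **Lumen.** Lumen fluid has a small constant density (0.02 g/mL — dilute
  but above medium, as real lumina read), plus 2–5 µm spherical debris
  blobs drawn from the dead distribution, emulating exfoliated material.
- **Noise.** Additive Gaussian RI noise (default SD 0.002) on top of the
  piecewise-constant field. There is no diffraction, transfer function,
  aberration, or spatially correlated noise: a green segmentation test
  therefore establishes correctness of the masking logic on
  well-contrasted data, not robustness to reconstruction artifacts.
- **Growth.** Time-lapse series scale all linear dimensions by
  `exp(k·t/3)` so true volume follows `V₀·exp(k·t)` exactly (default
  k = 0.02 h⁻¹, hourly frames). A per-frame `dead_fraction` schedule
  emulates a cytotoxic response.
- **Tiling.** A master phantom is cut into grid tiles with 15 µm nominal
  overlap; each tile's true cut position adds uniform integer jitter
  (±5 voxels by default), emulating stage imprecision. The master volume
  is returned as the stitching oracle.
- **Determinism.** Identical spec + seed gives bit-identical volumes.
- Default voxel spacing is the instrument's 0.155 × 0.155 × 0.947 µm;
  tests and examples use coarser round spacings (e.g. 1 × 1 × 2 µm) to
  stay fast — the density statistics, not the grid, carry the signal.
- A solid (lumen-free) calibration phantom is obtained with
  `shell_thickness_um == outer_radius_um` and, optionally,
  `uniform_density` for exact-oracle tests. An organoid may be clipped
  axially (`allow_axial_clip`) since instrument depth range is finite;
  lateral clipping is always a geometry error.

## Stitching

One integer 2D lateral offset per tile pair, estimated jointly over all
z of the overlap (a stage error applies to the whole stack), by
exhaustive search of the `(2r+1)²` window (default r = 10 voxels) for
the maximum Pearson correlation of overlapping RI values; ties break
toward the smallest displacement from nominal, then lexicographically.
Constant-valued overlaps (undefined correlation) fall back to the
nominal offset with a warning flag. No subvoxel interpolation: offsets
are integer, avoiding resampling blur.

Global positions anchor tile 0 at the origin and accumulate pairwise
offsets along a maximum-correlation spanning tree (deterministic
tie-break on weight then endpoints); loop residuals of non-tree edges
are reported, not redistributed. Blending is per-slice Laplacian-pyramid
with a half-overlap seam mask and `⌊log₂(overlap)⌋` levels by default;
outside overlap bands the mosaic equals the contributing tile exactly,
and blended values are clipped to the contributing tiles' per-slice
range because pyramid reconstruction can ring slightly at seams.
Canvas voxels covered by no tile are zero.

## Segmentation

The per-slice Sobel gradient magnitude (raw 3×3 kernels, reflective
borders, no cross-slice coupling) drives two decisions. The in-focus
axial range is the smallest half-open slice interval containing every
slice whose mean gradient is ≥ 20% (configurable, recorded in output)
of the maximum per-slice mean. Organoid masks come from either

- a **supervised pixel classifier** (random forest over a fixed bank of
  multi-scale smoothed RI and gradient features, trained on sparse
  background/organoid annotations, deterministic seed) — the stand-in
  for interactive annotation tools, preserving the contract
  (features + sparse labels → mask) without the tool; or
- an **unsupervised fallback**: Otsu threshold on the slice-smoothed RI
  deviation from n_m, refused when the threshold does not clear 3× the
  robust (MAD) noise floor, then extended to dim epithelium by
  morphological reconstruction above a weak raw threshold
  (max of 0.25 × Otsu and 3× noise floor).

Post-processing fills holes with tolerance: dilate by the closing radius
(default 8 µm, anisotropy-aware EDT on a padded array), fill per slice,
erode back, union with the original candidate, fill again. This bridges
the windows that dim (low-density) cells punch through the shell —
otherwise the lumen fill leaks — while leaving locally convex outer
boundaries exact. Components below 500 µm³ are dropped;
26-connectivity labels the rest (largest first). Manual trimming of an
interactive workflow is replaced by this minimum-volume filter.

The lumen is the low-density enclosed interior of the per-slice-filled
mask: seeds are voxels below a robust threshold between the cavity-fluid
level (5th percentile of in-mask smoothed density) and the epithelium
median, intersected with low gradient (below the 75th percentile of the
shell's smoothed gradient — the median collapses to the noise floor on
piecewise-constant interiors); the largest component is opened at half
the cell diameter (5 µm) to shave single dim-cell bumps, grown back by a
bounded (3-iteration) geodesic dilation within the low-density region to
recover the rim the gradient gate vetoes, hole-filled per slice (debris
belongs to the lumen), and must be enclosed: if more than 5% of its
boundary touches the mask exterior, or it is smaller than 2% of the
mask, the lumen is empty with a warning.

## Quantification and statistics

Volume is the exact voxel count × voxel volume; masses and volumes are
additive over disjoint masks; the density conversion is invertible to
machine precision. Histograms are restricted to in-mask voxels, with
out-of-range values clipped into the outer bins so counts always sum to
the in-mask voxel count. Time-lapse tables normalize each region's
volume/density/mass by its first-frame value; growth is the
least-squares slope of log V vs t with its standard error.

Subvolume tables tile the mask's bounding box (anchored at its minimum
corner, so cube content is independent of padding) with
50 × 50 × 10 µm cubes; per cube the mean density is over in-mask voxels
only (flagged in metadata), cubes under 50% coverage are dropped —
half-full cubes of mask voxels approximate "contains a whole cell"
without instance segmentation. Group comparison is the closed-form
two-tailed unpaired t test, pooled-variance by default (Welch optional
since group SDs can differ), accepting raw samples or (mean, SD, n)
summaries interchangeably; both routes agree to machine precision, and
zero-variance-equal-means degenerates to t = 0, p = 1 by convention.
The optional dead-like/live-like thresholding (off by default in the
pipeline) reports a viability fraction with a 95% Wilson interval.

## Known limitations

- No optical forward model: robustness to reconstruction artifacts,
  aberrations or correlated noise is untested by construction.
- The unsupervised fallback assumes background-dominated volumes for its
  noise estimate; densely packed fields of view should use the
  supervised route.
- Lumen segmentation is ambiguous where a dim cell's density matches the
  cavity fluid; accuracy is bounded by that overlap (phantom Dice ≈ 0.93).
- Axial (z) registration, rotation/scale registration and illumination
  flat-fielding are out of scope for stitching.
- Subvolume statistics treat cubes as independent samples; cells spanning
  cube boundaries induce mild spatial correlation that the t test ignores.
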