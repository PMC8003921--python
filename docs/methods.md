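# Methods

`coreshell` quantifies scaffold-free core-shell multicellular tumor
spheroids (MCTS) from two-channel confocal z-stacks: a nuclear channel that
stains every cell (DAPI-like) and a shell channel that marks the cells
seeded second, around a pre-formed core (a pre-seeding cytoplasmic dye such
as Far Red DDAO-SE).  Because such experiments rarely deposit raw stacks,
the package ships a phantom generator whose ground truth makes every stage
verifiable by parameter recovery.

## Coordinate conventions

Voxel grids are indexed `(x, y, z)`, 0-based; the physical position of a
voxel is `index · spacing` at the voxel center, with spacing in µm per
axis.  Spherical coordinates follow the geometry of a spheroid resting in a
microwell: azimuth θ ∈ [−π, π] measured in the x–y plane from +x, and
elevation (polar angle) φ ∈ [−π/2, π/2], with φ = −π/2 pointing at the
well bottom (−z).

## Pipeline

1. **Isotropic interpolation.**  Confocal stacks are acquired with square
   pixels (default 0.4393 µm) and coarser optical sectioning (0.9 µm).  The
   z axis is linearly resampled to 0.45 µm (endpoint preserving: the new
   slice count is `round((nz−1)·dz/target)+1`), giving approximately
   isotropic voxels before any 3D operation.
2. **Smoothing.**  Channel-wise Gaussian filter; sigma is specified in µm
   and converted per axis.  Default 0.5 µm — sub-nuclear, enough to
   suppress shot noise without moving nuclear boundaries.
3. **Adaptive thresholding.**  A voxel is foreground iff its intensity
   exceeds the mean over a per-axis box of side `dimension/8` (minimum 3
   voxels) scaled by `(1+sensitivity)`; default sensitivity 0.  Boundary
   neighborhoods use mirrored padding.  The neighborhood is per-axis
   rectangular, not cubic.  A range-relative epsilon (`1e-9 · (max−min)`)
   guards the comparison: the separable running-sum implementation of the
   box mean can land a few ulp below a constant background value, and
   without the guard whole flat regions flip to foreground.  The guard
   scales with the data, so thresholding at sensitivity 0 remains invariant
   to affine intensity rescaling, and a constant channel still yields an
   empty mask.  Note the method is inherently *relative*: a large perfectly
   homogeneous bright object is not foreground against itself, which is why
   the nuclear mask is hole-filled afterwards and why textured (cellular)
   data is the intended regime.
4. **Cleanup.**  26-connected components smaller than `min_object_volume`
   are removed (default: half the volume of a sphere with the default mean
   nucleus radius of 4 µm, i.e. ~134 µm³ — the "small object" scale is tied
   to the nuclear scale).  Holes (6-connected enclosed background) are
   filled in the nuclear channel only; the shell channel legitimately
   contains a large cavity — the core — that must not be filled.
5. **Nucleus separation.**  Euclidean distance transform (physical
   spacing, hence anisotropy-aware), negated; regional minima below depth
   `h` are suppressed (H-minima, default h = 1.0 µm: below a typical
   nucleus radius, above discretization ripple); the surviving minima seed
   a watershed of the negated distance transform.  One refinement pass
   removes seeds whose basin is smaller than 70% of the median basin volume
   and re-floods; basins in components that contain no seed at all (thin,
   sub-`h` structures) remain unlabelled, exactly as a marker-imposed
   watershed leaves them.  Label count recovery is exact on phantoms with
   resolvable nuclei for h anywhere in [0.5, 1.5] µm.
6. **Morphometry.**  The whole-spheroid mask is the union of the two
   channel masks, ball-closed (default 5 µm — must exceed half the largest
   inter-nucleus gap), hole-filled, largest component kept (one spheroid
   per stack).  Volume is voxel-count volume.  Surface area comes from a
   marching-cubes isosurface at level 0.5 after one voxel of Gaussian
   smoothing of the indicator field: a raw binary isosurface is a staircase
   whose area is ~8% inflated *independent of resolution*, which would bias
   the sphericity Ψ = π^(1/3)(6V)^(2/3)/A down to ~0.92 even for perfect
   balls.  The smoothing preserves flat faces exactly and rounds convex
   corners at the voxel scale, so Ψ carries a mesh tolerance of order
   σ/L (shape size L): balls ≥ 40 voxel radius measure Ψ ≥ 0.99, a
   100-voxel cube measures within 2% of the closed form (π/6)^(1/3).
   Equivalent diameter is (6V/π)^(1/3).  Cell count is total nuclear-mask
   volume divided by the median watershed basin volume.
7. **Radial line analysis.**  The core center is the nuclear-intensity
   weighted centroid of (nuclear mask ∖ shell mask).  Directions come from
   a deterministic spherical Fibonacci lattice (endpoint variant, z from +1
   to −1 inclusive, golden-angle azimuths); 5000 by default.  For each
   direction the surface point is the last in-mask voxel along the ray
   (found by dense sampling at a quarter voxel), and the center-to-surface
   digital line is a 3D Bresenham-family line (driving-axis DDA with
   half-up rounding): 26-connected, per-axis monotone, exact endpoints,
   `max |Δ| + 1` voxels.  The direction-corrected voxel length is
   `r / (line voxel count)`, so per-line step lengths sum exactly to r.
   Per line: shell thickness = shell-positive voxels × step (non-contiguous
   positives all count), core radius = leading-negative run × step
   (undefined for uncovered lines and excluded from core statistics),
   covered = any positive.  Coverage % = covered lines / all lines.  The
   thickness mean is reported both over all lines (zeros included) and over
   covered lines only.  Angular trends are per-bin mean ± sd of thickness
   in π/10 azimuth and π/20 polar bins.
8. **Compartments.**  The union of leading-negative runs of all covered
   lines is the core "shadow"; ball closing (default 6 µm, ≥3× the
   inter-line gap at the core surface for 5000 directions at a ~35 µm
   core), hole filling, intersection with the whole mask and largest
   component give the core mask; the shell mask is the set difference, so
   core and shell always partition the spheroid exactly.  Content per
   compartment: shell-channel positive voxel fraction, and nuclei counts as
   compartment nuclear volume / median nucleus volume (a nucleus straddling
   the boundary contributes fractionally to both sides).  Both pooled
   (positive vs negative, all compartments) and per-compartment counts are
   emitted.

Ball-structured morphology everywhere is computed from Euclidean distance
transforms (dilation = EDT of the background ≤ r) rather than a voxelized
structuring element: identical for Euclidean balls, anisotropy-aware, and
much faster at 10+-voxel radii on ~2·10⁷-voxel grids.

## The phantom generator

`PhantomSpec` describes one spheroid: grid, spacing, center, core radius,
shell thickness, shell coverage, nucleus counts and sizes, label mixing,
blur, noise, seed.  Three renderers share it:

* `render_geometry_phantom` — exact binary masks: whole = ball of
  `core_radius + shell_thickness`, shell = the annulus restricted to
  directions outside a polar cap, true core = inner ball.  Coverage is a
  single spherical cap around `cap_axis` (default −z, the well bottom,
  where acoustic-trap seeding leaves the shell thinnest); the cap half
  angle is closed-form, `α = arccos(2·coverage − 1)`.
* `render_content_phantom` — adds per-voxel independent Bernoulli
  shell-channel labels: shell voxels positive at `shell_label_purity`,
  core voxels at `core_contamination`.  Ground truth records the realized
  fractions.
* `render_image_phantom` — intensity stacks: non-overlapping axis-aligned
  ellipsoidal nuclei (semi-axes from a ±3 sd truncated normal, default
  4.0 ± 0.3 µm) placed by rejection sampling in core and covered shell,
  with a minimum surface clearance (default 1.0 µm, at least one voxel —
  sub-voxel gaps would alias into merged objects at the emulated sampling);
  a 5%-of-dynamic-range background offset; optional per-axis Gaussian blur
  then noise (Gaussian or Poisson).  Bit-identical output for identical
  spec and seed.

Default geometric parameters are the population means of the imaged
spheroid cohort the pipeline was built for: core radius 34.3 µm, shell
thickness 23.2 µm, coverage 91.2%, outer line-analysis radius 64.0 µm,
shell/core positive-voxel fractions 70.2% / 7.6%, 37 + 256 nuclei (2:1
shell:core seeding).  `presets` builds the recovery fixtures from these at
the acquisition voxel sizes (0.45 µm isotropic for geometry runs; native
0.4393/0.9 µm for the image-phantom run, which then passes through the
full interpolation path).

What the phantoms deliberately do **not** emulate: depth-dependent
attenuation, spectral bleed-through, refractive-index clearing artifacts,
non-ellipsoidal or dividing nuclei, cell-scale (correlated) label texture.
Passing recovery tests therefore demonstrates correctness of the analysis
geometry and estimators on idealized optics, not robustness to every real
acquisition artifact.

## Recovery experiments and their problem sizes

`coreshell.recovery` holds the from-scratch experiments the acceptance
suite and `scripts/acceptance.py` run:

* coverage, thickness/core-radius, and radius runs — noise-free geometry
  phantoms at 0.45 µm (grids ~264³–292³), 5000 lines; recovery tolerances
  are half a voxel for length means and 1% absolute for coverage.
* content run — stochastic Bernoulli phantom, same geometry; compartment
  geometry is derived from the volume-filtered shell mask (isolated label
  noise cannot outline a core boundary: at 7.6% the contamination sits
  below the 26-connected percolation threshold and is removed, while the
  70.2% shell percolates and survives), and the content fractions are then
  measured with the *raw* label field inside the reconstructed masks.
  Tolerance 2% absolute at ≥10⁵ voxels per compartment; the main residual
  is the leading-negative overshoot of the core boundary (~(1−p)/p voxels,
  i.e. +0.2 µm at p = 0.7) plus the closing's preference for the outer
  envelope of the per-ray boundary estimates, worth ~+1% on the core
  fraction.
* cell-count run — noise-free image phantom with 293 nuclei at acquisition
  spacing (~270×270×136 before interpolation), full segmentation +
  two-pass watershed; tolerance 5% relative.  The estimator's residual
  (~+1%) is the mean/median skew of the basin-volume distribution.

## Numerical choices and edge cases

* Watershed flooding uses the library's deterministic priority flood; ties
  break by raster scan order, so repeated runs are bit-identical.
* Exactly one watershed refinement pass (not iterated); if every basin
  falls below threshold the largest seed is kept with a warning.
* Rays that leave the grid while still inside the mask clamp the surface
  point to the last in-grid voxel and warn.
* An empty core∖shell difference falls back to the unweighted nuclear-mask
  centroid with a warning; empty compartments report NaN fractions, never
  zero.
* Per-ray surface radii satisfy r ≤ R on digital balls; a single ray can
  stop up to ~1.6 voxels short when it exits through a voxel corner, while
  the mean deficit stays under half a voxel — aggregate radius statistics
  are accurate to the half-voxel level, individual rays are not.
* The equivalent diameter is always computed from the measured volume by
  (6V/π)^(1/3); at the cohort-mean volume of 1.21·10⁶ µm³ this gives
  ~132 µm.

## Known limitations

* One spheroid per stack (largest-component selection); no multi-instance
  separation or time series.
* The line-based shell metrics assume the center sees the surface along
  straight rays; strongly non-convex spheroids violate this.
* Adaptive local-mean thresholding cannot segment large homogeneous bright
  volumes against themselves (see above); deconvolution, illumination and
  bleaching correction are out of scope.
* "Equally spaced" surface points are realized as a Fibonacci lattice;
  exact solid-angle uniformity correction weights are not applied.
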