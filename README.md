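# coreshell

Quantitative 3D image analysis of **core-shell multicellular tumor
spheroids** (MCTS) from two-channel confocal z-stacks, plus a synthetic
phantom generator that makes every analysis stage verifiable by parameter
recovery.

Core-shell spheroids — a core of one cell population enclosed in a shell of
a second, pre-labelled population — are an in-vitro model of the spatial
architecture of solid tumors.  Imaging them yields two channels: a nuclear
stain marking every cell (e.g. DAPI) and a cytoplasmic dye marking the
shell-seeded cells (e.g. Far Red DDAO-SE).  This package answers, per
spheroid: how big and how spherical is it, how many cells does it contain,
how thick is the shell and how completely does it cover the core, and what
is in the core vs. the shell.

## Method

After z-interpolation to isotropic voxels, Gaussian smoothing, local-mean
adaptive thresholding and morphological cleanup, the pipeline:

* separates nuclei with a two-pass seeded watershed on the distance
  transform (H-minima seeds; undersized basins below 70% of the median
  volume lose their seeds in a second pass) and estimates the cell count as
  total nuclear volume / median single-nucleus volume;
* measures volume V, surface area A (smoothed marching-cubes mesh),
  equivalent diameter (6V/π)^(1/3) and sphericity

      Ψ = π^(1/3) (6V)^(2/3) / A ;

* casts 5000 center-to-surface rays (spherical Fibonacci lattice) through
  the shell mask using 3D Bresenham lines; per ray, with the
  direction-corrected voxel length s = r / (voxels on the line):
  shell thickness = (positive voxels)·s, core radius = (leading negative
  voxels)·s, and coverage % = rays containing any positive voxel.  Trends
  of thickness vs. azimuth θ and elevation φ expose directional deficits
  (e.g. a thinner shell at the well bottom, φ → −π/2);
* builds the core mask from the union of leading-negative ray segments
  (the core "shadow", solidified by ball closing), takes the shell mask as
  the complement within the spheroid, and reports per-compartment positive
  voxel fractions and nuclei counts.

The phantom generator renders spheroids with known core radius, shell
thickness, polar-cap coverage, per-voxel shell-label purity and core
contamination, and non-overlapping ellipsoidal nuclei — with the ground
truth serialized alongside — so each estimator above can be tested for
recovery of the constructed truth.  See `docs/methods.md` for assumptions,
parameter defaults and numerical choices.

## Worked example

```python
from coreshell import PhantomSpec, PipelineConfig
from coreshell.phantom import render_image_phantom
from coreshell.pipeline import run_pipeline

spec = PhantomSpec(
    grid_shape=(128, 128, 64), spacing=(0.9, 0.9, 1.8),
    core_radius=22.0, shell_thickness=14.0, coverage_fraction=0.9,
    n_core_nuclei=12, n_shell_nuclei=40,
    shell_label_purity=0.7, rng_seed=42,
)
stack, truth = render_image_phantom(spec)
config = PipelineConfig(target_z_spacing=0.9, min_object_volume=100.0,
                        n_surface_points=2000)
report = run_pipeline(stack, config)
```

which prints, via the summary fields:

```
cells: 52  (true 52)
coverage: 92.2 %  (true 90.0 %)
shell thickness: 10.5 um  (true 14.0 um)
core radius: 22.0 um  (true 22.0 um)
sphericity: 0.592
shell FarRed fraction: 0.752  (purity 0.7)
```

Cell count and core radius recover exactly.  The measured shell thickness
is the *positive-voxel* path length, so on a 70%-pure shell it reads
≈ 0.7 × the geometric thickness — the same behavior the method has on real
spheroids, where the shell is cells interleaved with unlabelled volume.
The low sphericity reflects the ragged surface of a textured shell at
coarse voxels.  `report` also carries the per-line table, concentric-layer
profile, angular trends, all masks and the nuclei table; `summary()` gives
a JSON-ready dict embedding the config and its hash for provenance.

## Command line

```sh
coreshell simulate --spec phantom.yaml --out stack.ome.tif   # + truth JSON
coreshell segment  stack.ome.tif --out-dir seg/              # channel masks
coreshell analyze  stack.ome.tif --out-dir out/              # full report
coreshell report   out1/summary.json out2/summary.json --out cohort.csv
```

Stacks are OME-TIFF with physical voxel sizes in metadata (override with
`--spacing-x/-y/-z` for plain TIFF).  All tunables live in a YAML/JSON
config and are echoed into every report.

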