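# Methods

## Data model and coordinate conventions

A capture area is modeled as counts (sparse genes × spots, non-negative
integers), a spot table (barcode, in-tissue flag, array indices,
full-resolution pixel center), scale factors, raster images keyed by
resolution tag, per-spot covariates, and low-dimensional projections.
Pixel coordinates are `(row, col)`, 0-based, row increasing downward —
raster indexing — so Space Ranger's `pxl_row_in_fullres` /
`pxl_col_in_fullres` columns map directly with no axis swap, and rendering
needs no y-flip beyond inverting the y-axis direction. The Visium lattice
parity (`array_row + array_col` even) is validated on every spot table.

Multi-sample datasets align every sample to a shared gene universe defined
as the *intersection* of gene ids, ordered as in the first sample. An
intersection (rather than union) guarantees any plotted gene exists in
every panel; an empty intersection is an error. Covariates supplied for
barcodes absent from the count matrix are dropped with a logged warning —
keeping silent phantom values would let a plot disagree with the matrix.

## Spot-to-image geometry

Centers in a target frame are the full-resolution centers times that
frame's scale factor (`fullres` ≡ 1), a purely linear map; the rendered
radius is `spot_diameter_fullres × scalef / 2 × point_size_multiplier`.
The multiplier (default 1, dimensionless) trades physical fidelity for
legibility; 2.25 is a practical value for lowres rendering of sparse
arrays.

## QC and normalization

Per-spot QC: UMI sum, genes detected, and percent mitochondrial expression
(100 × mito UMI / total UMI, 0 for zero-count spots, which are logged).
Mitochondrial genes are matched by gene-symbol prefix (default `MT-`,
configurable), because Space Ranger's features file carries no chromosome
annotation; all feature rows participate by default. Gene expression maps
use `log2(1 + count × 10⁴ / librarySize)` — a deterministic library-size
log transform chosen because it needs no fitted model; the plotting layer
accepts any precomputed continuous vector, so model-based normalizations
(scran pooling factors, Pearson residuals) can be substituted upstream
without touching the renderer.

## Color scales and palettes

Exactly nine continuous scales are registered: viridis, magma, inferno,
plasma, cividis, rocket, mako, turbo, greys — seven perceptually-uniform
colorblind-friendly ramps plus turbo and greys. Each is stored as 256 RGB
triples sampled once at import (rocket and mako from seaborn's
colormaps), and each is reversible; reversal flips the gradient so the
minimum value takes the normally-high-end color (reversed magma renders
low values near-white). Continuous mapping is linear min–max with
interpolation between stops; an all-constant vector maps to the scale
midpoint and non-finite values to a configurable NA color (mid-grey).
Categorical palettes draw from a frozen 36-color cycle (tab20 followed by
tab20b's first 16) assigned in sorted-label order — a pure function of the
label set, which is what keeps cluster colors identical across samples and
across plots. Beyond 36 labels the cycle repeats with geometrically
darkened shades (factor 0.7 per cycle) and a warning, preserving
injectivity.

## Image operators

All operators are defined precisely here rather than inheriting
undocumented third-party semantics, so outputs are bit-reproducible:

- **normalize** — per-channel linear stretch to [0, 255] after clipping
  the darkest 2% and brightest 1% of pixels (both configurable, 0% giving
  an exact min→0 / max→255 map); constant channels are untouched.
- **equalize** — per-channel histogram equalization by the standard CDF
  remap `v′ = round(255 (cdf(v) − cdf_min)/(1 − cdf_min))`.
- **enhance** — one pass of edge-preserving 3×3 smoothing: each pixel
  becomes the weighted mean of itself (weight 2) and those neighbors whose
  Euclidean RGB distance to it is ≤ 15% of the maximum distance √3·255
  (weight 1 each); borders use existing neighbors only.
- **transparent** — pixels within `fuzz`% of the maximum RGB distance of
  the key color (named colors from a small CSS-basic table; `pink` =
  (255, 192, 203)) get alpha 0. Fuzz-as-percentage-of-max-distance makes
  the transparent set monotone in fuzz by construction.
- **brightness** — RGB scaled by percent/100 and clipped; 100 is identity.

Only `transparent` writes the alpha channel; every operator preserves
dimensions.

## Rendering

Spots are drawn as true-radius circle patches in data (pixel) units — not
point-sized scatter markers — so their footprint is exact at any figure
DPI. Out-of-tissue spots are excluded by default (toggleable). Grid plots
use ⌈√n⌉ columns and share one color range (global min–max) or one palette
(union of labels) across panels, computed before any panel renders.
Figures carry a metadata dict (centers, colors, radius, range, palette,
legend) so tests probe plotted data rather than rasterized pixels. Exports
are PDF or PNG, validated by magic bytes in tests.

## Annotation

Polygon selection uses the even-odd ray-casting rule on spot *centers*,
with centers on the boundary counted inside (a deterministic, documented
tie rule; distance tolerance 1e-9 px). This small primitive is implemented
directly because the tie rule is part of the contract; the test suite
cross-checks it against shapely's independent containment predicate on
simple polygons. Labels are upserted one-per-spot ((sample, barcode)
unique); an empty label deletes. Annotations round-trip through a
three-column CSV and can be materialized as a categorical covariate for
plotting, with unannotated spots missing.

## Synthetic data generator

The generator emulates the layered expression structure of laminar tissue:

- **Geometry** — the interleaved hex lattice with array columns stepping
  by 2 and parity-matched offsets; centers at `col·d/2`, `row·d·√3/2` plus
  a one-pitch margin, making every adjacent pair exactly `d` apart
  (default pitch d = 100 fullres px; spot diameter 0.55·d, the Visium
  55 µm / 100 µm footprint-to-pitch ratio; full array 78 × 128 = 4,992
  spots — platform conventions, all configurable).
- **Counts** — negative binomial (gamma–Poisson, `var = μ + φμ²`,
  dispersion φ = 0.5 by default so normalization sees realistic
  over-dispersion) with base mean 2 per gene per spot; each of 4 layers
  (horizontal bands of array rows) elevates its 5 marker genes 5-fold;
  10 mitochondrial genes (`MT-…` symbols) get a common mean solving
  `n_mt·μ_mt = f/(1−f) · Σ μ_non-mt` so the expected mitochondrial
  fraction is f (default 0.15, a typical mid-range tissue value).
- **Image** — a radially shaded elliptical blob over a pink background
  (the pink background deliberately exercises color-keyed transparency);
  the lowres scale factor is computed from the image/lattice extents.

Everything is a pure function of the seed; written directories are
byte-identical across runs. The generator does **not** simulate histology
texture, within-band spatial autocorrelation, cell-type mixtures, empty
droplets, or hires/fullres rasters — so passing tests demonstrate
correctness of the import/QC/render/annotate machinery on
format-conformant data, not robustness to real-tissue artifacts.

## Problem sizes

Unit fixtures use 12 × 14 arrays (42 spots) with 120 genes; round-trip and
geometry checks use 20 × 24 / 200 genes; the multi-sample grid check uses
twelve 8 × 10 samples; QC brute-force comparisons run 20 seeds; polygon
selection is validated on 100 random simple polygons. These sizes exercise
every code path (multi-row parity, multi-layer bands, >1 panel row) while
keeping the suite fast to iterate on.

## Interactive layer and CLI

The interactive application is a pure state machine over the library: a
serializable state (sample, variable, scale, styling, pending selection,
annotations) plus transitions, with every view a deterministic function of
state and all computation delegated to the core modules — no duplicated
plotting or QC logic. A minimal stdlib HTTP wrapper serves the current
view as PNG; the contractual surface is the state transitions and the
PNG/CSV download payloads. The CLI is a thin click layer: subcommands
simulate / import / qc / plot / edit-image / annotate / serve, a flat
key=value `--config` file merged beneath explicit flags (keys are option
parameter names), exit codes 0/1/2 (success / runtime / usage), and
write-then-rename output handling so interrupted runs leave only
`.partial` files. The bundle written by `import` is a plain directory:
`manifest.json` plus, per sample, a Space Ranger-style tree
(gzipped matrix triplet, headered positions, scale factors, PNGs) with
`covariates.csv`, `reduced_dims/*.csv` and a `meta.json` recording
covariate kinds.

## Known limitations

No HDF5 matrix input, no Loupe files, no non-Visium platforms, no fullres
rendering or image tiling, one label per spot, and the interactive layer
is intentionally minimal (no concurrent editing, no authentication).
Self-intersecting selection polygons follow the even-odd rule, which may
differ from winding-rule tools.
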