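# visiumview

Import, quality-control, visualize, and manually annotate spatially-resolved
transcriptomics data from the 10x Genomics Visium platform.

Visium measures transcriptome-wide gene expression at barcoded *spots*
arranged on a hexagonal lattice under a tissue section, alongside a
histology image of the same section. The preprocessing pipeline (Space
Ranger) emits, per capture area, a sparse gene × spot UMI count matrix, the
spot positions (array indices and full-resolution pixel centers), scale
factors mapping those centers into down-sampled copies of the histology
image, and optional clustering / dimension-reduction result tables.
`visiumview` reads all of that, computes standard per-spot QC covariates,
and renders continuous or categorical spot maps over the histology — for
one sample or a grid of many samples sharing one color scale — with
configurable point size, transparency, and nine reversible continuous
color scales. It also supports deterministic histology edits (contrast
stretch, histogram equalization, denoising, color-keyed transparency,
brightness) and polygon-based manual spot annotation with CSV round-trips.

## What it computes

- **Spot geometry.** A spot's center in the image frame tagged `res` is its
  full-resolution center times the frame's scale factor
  (`fullres` ≡ 1); the rendered spot radius is
  `spot_diameter_fullres × scalef / 2 × point_size`, so a `point_size`
  of 2.25 draws spots at 2.25× their physical footprint.
- **QC covariates.** Per spot: total UMI
  (`sum_umi = Σ_g c_gs`), genes detected (`Σ_g 1[c_gs > 0]`), and percent
  mitochondrial expression
  (`100 × Σ_{g∈MT} c_gs / Σ_g c_gs`, 0 for empty spots), with
  mitochondrial genes identified by symbol prefix `MT-`.
- **Expression maps.** `log2(1 + c_gs × 10⁴ / sum_umi)` (log CP10K), or any
  user-supplied continuous covariate.
- **Color mapping.** Continuous values map linearly from their (global,
  when plotting multi-sample grids) min–max onto one of nine reversible
  scales; categorical labels map through a deterministic 36-color cycle in
  sorted-label order, so a cluster keeps its color across samples.

A synthetic data generator (`visiumview.fixtures`) writes complete,
standards-compliant Space Ranger-style directories — hex lattice, layered
negative-binomial counts with marker genes and a controlled mitochondrial
fraction, fake histology — so the whole toolchain runs offline with a known
ground truth.

## Worked example

```sh
$ visiumview simulate --rows 10 --cols 12 --seed 7 --out sim1
wrote 60 spots x 200 genes to sim1

$ visiumview import --dir sim1 --sample-id s1 --out bundle
imported s1: 200 genes x 60 spots into bundle

$ visiumview qc --bundle bundle --out qc.csv
wrote QC for 60 spots to qc.csv

$ head -2 qc.csv
sample_id,barcode,sum_umi,sum_genes_detected,expr_chrM_percent
s1,SPOT-000-000-1,473,151,12.896405919661733

$ visiumview plot --bundle bundle --gene SIMG000015 --scale magma \
    --reverse-scale --point-size 2.25 --out fig.pdf
wrote pdf figure to fig.pdf

$ visiumview edit-image --bundle bundle --ops enhance,normalize,equalize \
    --transparent-color pink --transparent-fuzz 40 --out edited.png
wrote edited image to edited.png

$ visiumview annotate --bundle bundle --polygon "0,0:0,80:80,80:80,0" \
    --label WM --out ann.csv
labeled 12 spots 'WM'; annotation table now has 12 rows at ann.csv
```

The QC line reads: spot `SPOT-000-000-1` captured 473 UMIs across 151
distinct genes, 12.9% of them from mitochondrial (`MT-`) genes — on real
tissue a high value flags stressed or poorly permeabilized regions. The
plot command renders log-CP10K expression of the requested gene over the
histology with the reversed magma scale (low values light) at 2.25× point
size; the annotate command labels the 12 spots whose centers fall inside
the given polygon (row,col pixel coordinates in the lowres frame,
boundary-inclusive even-odd rule) as `"WM"`.

The same operations are available as a library (`visiumview.viz_static`,
`visiumview.qc_norm`, ...) and through a minimal interactive layer
(`visiumview.app_interactive`, `visiumview serve`).

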