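"""Synthetic Visium data generator.

Produces complete, standards-compliant Space Ranger-style directories —
hexagonal spot lattice, over-dispersed layered counts, mitochondrial genes,
a fake histology raster, clustering and projection CSVs — so every other
module is exercisable offline with a known ground truth.

The simulated tissue is a stack of horizontal "layers" (bands of array
rows), each with its own marker genes whose negative-binomial means are
elevated within the layer. This emulates the layered expression structure
of laminar tissue such as cortex, where markers (and the mitochondrial
fraction) follow the anatomy. What it does *not* emulate: real histology
texture, spatial autocorrelation beyond the layer bands, cell-type mixing
within spots, or empty-droplet barcodes.

Geometry defaults follow Visium platform conventions: 100 (fullres px)
center-to-center pitch stand-in, spot diameter 0.55 × pitch (the 55 µm /
100 µm ratio), and a full array of 78 rows × 128 array columns (64 spots
per row). All are configurable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spaceranger_io as srio
from .core_model import (CountMatrix, RGBAImage, ScaleFactors, SpatialSample,
                         SpotTable)


@dataclass
class SimConfig:
    """Parameters of one synthetic capture area; the seed fixes everything."""

    n_array_rows: int = 20
    n_array_cols: int = 24
    n_genes: int = 200
    n_mito_genes: int = 10
    n_layers: int = 4
    marker_genes_per_layer: int = 5
    marker_fold_change: float = 5.0
    base_mean: float = 2.0
    mito_target_fraction: float = 0.15
    nb_dispersion: float = 0.5  # var = mu + dispersion * mu^2
    spot_pitch_fullres: float = 100.0  # center-to-center distance d
    image_height: int = 200
    image_width: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_array_rows", "n_array_cols", "n_genes", "n_layers",
                     "image_height", "image_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_mito_genes < 0 or self.marker_genes_per_layer < 0:
            raise ValueError("gene counts must be non-negative")
        if not (0 <= self.mito_target_fraction < 1):
            raise ValueError("mito_target_fraction must be in [0, 1)")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must exceed 1")
        if self.base_mean < 0:
            raise ValueError("base_mean must be non-negative")
        n_special = self.n_mito_genes + self.n_layers * self.marker_genes_per_layer
        if self.n_genes < n_special:
            raise ValueError(f"n_genes={self.n_genes} too small for "
                             f"{n_special} mito + marker genes")


@dataclass
class SimTruth:
    """Ground-truth record returned alongside generated data."""

    config: SimConfig
    counts: CountMatrix
    spots: SpotTable
    scalefactors: ScaleFactors
    image: RGBAImage
    layer_of_spot: np.ndarray  # 1-based layer index per counted spot
    marker_genes: dict[int, list[str]]  # layer -> gene ids
    mito_gene_ids: list[str]
    umap: np.ndarray = field(default=None)


def make_hex_grid(cfg: SimConfig) -> SpotTable:
    """Generate the Visium hex lattice of spot positions.

    Array columns step by 2 within each row, offset alternating with row
    parity, so ``array_row + array_col`` is always even. Full-resolution
    centers place adjacent spots (same-row and diagonal neighbors alike)
    exactly ``spot_pitch_fullres`` apart: columns at ``array_col * d/2``,
    rows at ``array_row * d * √3/2``, plus a one-pitch margin.
    """
    d = cfg.spot_pitch_fullres
    margin = d
    rows, cols = [], []
    for r in range(cfg.n_array_rows):
        for c in range(r % 2, cfg.n_array_cols, 2):
            rows.append(r)
            cols.append(c)
    rows = np.array(rows)
    cols = np.array(cols)
    barcodes = np.array([f"SPOT-{r:03d}-{c:03d}-1"
                         for r, c in zip(rows, cols)], dtype=object)
    return SpotTable(
        barcode=barcodes,
        in_tissue=np.ones(len(rows), dtype=bool),
        array_row=rows,
        array_col=cols,
        pxl_row_fullres=rows * (d * np.sqrt(3.0) / 2.0) + margin,
        pxl_col_fullres=cols * (d / 2.0) + margin,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        if dispersion > 0:
            size = 1.0 / dispersion
            p = size / (size + mean[pos])
            out[pos] = rng.negative_binomial(size, p)
        else:
            out[pos] = rng.poisson(mean[pos])
    return out


def assign_layers(cfg: SimConfig, spots: SpotTable) -> np.ndarray:
    """1-based layer per spot: horizontal bands of array_row."""
    band = cfg.n_array_rows / cfg.n_layers
    return np.minimum(spots.array_row // band, cfg.n_layers - 1).astype(int) + 1


def simulate_counts(cfg: SimConfig,
                    spots: SpotTable) -> tuple[CountMatrix, np.ndarray,
                                               dict[int, list[str]], list[str]]:
    """Simulate layered negative-binomial counts.

    Returns (counts, layer_of_spot, marker_genes, mito_gene_ids). Marker
    genes of layer L have mean ``base_mean * marker_fold_change`` inside L
    and ``base_mean`` elsewhere; mitochondrial genes (symbols ``MT-001``…)
    share a mean chosen so the expected mitochondrial fraction of total UMI
    equals ``mito_target_fraction``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_spots = len(spots)
    layer = assign_layers(cfg, spots)

    gene_ids = [f"SIMG{i:06d}" for i in range(cfg.n_genes)]
    symbols = []
    mito_ids = []
    marker_genes: dict[int, list[str]] = {l: [] for l in
                                          range(1, cfg.n_layers + 1)}
    idx = 0
    for m in range(cfg.n_mito_genes):
        symbols.append(f"MT-{m+1:03d}")
        mito_ids.append(gene_ids[idx])
        idx += 1
    for l in range(1, cfg.n_layers + 1):
        for k in range(cfg.marker_genes_per_layer):
            symbols.append(f"L{l}MARK{k+1}")
            marker_genes[l].append(gene_ids[idx])
            idx += 1
    for j in range(idx, cfg.n_genes):
        symbols.append(f"BG{j+1:05d}")

    n_background_like = cfg.n_genes - cfg.n_mito_genes
    # expected non-mito UMI per spot, averaged over marker elevation
    mean = np.full((cfg.n_genes, n_spots), cfg.base_mean, dtype=float)
    for l, genes in marker_genes.items():
        rows = [gene_ids.index(g) for g in genes]
        in_layer = layer == l
        for r in rows:
            mean[r, in_layer] *= cfg.marker_fold_change
    nonmito_total = mean[cfg.n_mito_genes:, :].sum(axis=0)
    if cfg.n_mito_genes and cfg.mito_target_fraction > 0:
        f = cfg.mito_target_fraction
        mito_mean = (f / (1.0 - f)) * nonmito_total / cfg.n_mito_genes
        mean[:cfg.n_mito_genes, :] = mito_mean[None, :]
    else:
        mean[:cfg.n_mito_genes, :] = 0.0
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)
    cm = CountMatrix(counts=counts, gene_ids=gene_ids, gene_symbols=symbols,
                     barcodes=list(spots.barcode))
    assert n_background_like >= 0
    return cm, layer, marker_genes, mito_ids


def render_tissue_image(cfg: SimConfig,
                        spots: SpotTable) -> tuple[RGBAImage, ScaleFactors]:
    """Render a lowres fake-histology raster and matching scale factors.

    A shaded elliptical tissue blob covers the spot extent over a pink
    background (so color-keyed transparency with key "pink" has something
    to key on). Lowres scale factor = image_width / fullres extent;
    spot diameter = 0.55 × pitch, per the Visium footprint/pitch ratio.
    """
    d = cfg.spot_pitch_fullres
    fullres_w = float(spots.pxl_col_fullres.max() + d)
    fullres_h = float(spots.pxl_row_fullres.max() + d)
    lowres_scalef = min(cfg.image_width / fullres_w,
                        cfg.image_height / fullres_h)
    sf = ScaleFactors(
        spot_diameter_fullres=0.55 * d,
        fiducial_diameter_fullres=0.85 * d,
        tissue_hires_scalef=min(1.0, 2.0 * lowres_scalef),
        tissue_lowres_scalef=lowres_scalef,
    )
    h, w = cfg.image_height, cfg.image_width
    px = np.empty((h, w, 4), dtype=np.uint8)
    px[:, :, :3] = (255, 192, 203)  # pink background
    px[:, :, 3] = 255
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    cr = (spots.pxl_row_fullres.mean()) * lowres_scalef
    cx = (spots.pxl_col_fullres.mean()) * lowres_scalef
    ar = (spots.pxl_row_fullres.max() - spots.pxl_row_fullres.min() + d) \
        * lowres_scalef / 2.0 + 1.0
    ac = (spots.pxl_col_fullres.max() - spots.pxl_col_fullres.min() + d) \
        * lowres_scalef / 2.0 + 1.0
    inside = ((rr - cr) / ar) ** 2 + ((cc - cx) / ac) ** 2 <= 1.0
    # radial shading: darker toward the blob center, vaguely eosin-like
    radial = np.sqrt(((rr - cr) / ar) ** 2 + ((cc - cx) / ac) ** 2)
    shade = np.clip(120 + 100 * radial, 0, 235)
    px[:, :, 0] = np.where(inside, np.round(shade * 0.9), px[:, :, 0])
    px[:, :, 1] = np.where(inside, np.round(shade * 0.55), px[:, :, 1])
    px[:, :, 2] = np.where(inside, np.round(shade * 0.75), px[:, :, 2])
    return RGBAImage(px, "lowres"), sf


def simulate_sample(cfg: SimConfig, sample_id: str = "sim") -> SimTruth:
    """Generate one full synthetic capture area in memory."""
    spots = make_hex_grid(cfg)
    counts, layer, markers, mito_ids = simulate_counts(cfg, spots)
    image, sf = render_tissue_image(cfg, spots)
    rng = np.random.default_rng(cfg.seed + 1)
    # toy projection: layer structure plus noise, 2-D
    umap = np.column_stack([layer + rng.normal(0, 0.3, len(layer)),
                            rng.normal(0, 1.0, len(layer))])
    truth = SimTruth(config=cfg, counts=counts, spots=spots, scalefactors=sf,
                     image=image, layer_of_spot=layer, marker_genes=markers,
                     mito_gene_ids=mito_ids, umap=umap)
    truth.sample_id = sample_id
    return truth


def truth_to_sample(truth: SimTruth, sample_id: str = "sim") -> SpatialSample:
    """Assemble the in-memory truth into a SpatialSample (no disk I/O)."""
    return SpatialSample(
        sample_id=sample_id, counts=truth.counts, spots=truth.spots,
        scalefactors=truth.scalefactors,
        images={"lowres": truth.image},
        spot_covariates={"graphclust": truth.layer_of_spot.astype(str)
                         .astype(object)},
        reduced_dims={"umap": truth.umap},
    )


def write_spaceranger_dir(cfg: SimConfig, out_path: str,
                          positions_dialect: str = "v1",
                          gz: bool = True) -> SimTruth:
    """Write a complete synthetic Space Ranger-style directory.

    Layout: matrix triplet (gz by default), ``spatial/`` with positions
    (v1 headerless by default, v2 headered on request), scale factors and
    lowres PNG, plus ``analysis/clustering/graphclust/clusters.csv`` (the
    true layers posing as a graph-based clustering) and a 2-D UMAP
    projection. Returns the in-memory truth for round-trip tests.
    """
    truth = simulate_sample(cfg)
    os.makedirs(out_path, exist_ok=True)
    srio.write_counts(truth.counts,
                      os.path.join(out_path, "filtered_feature_bc_matrix"),
                      gz=gz)
    spatial = os.path.join(out_path, "spatial")
    os.makedirs(spatial, exist_ok=True)
    pos_name = ("tissue_positions_list.csv" if positions_dialect == "v1"
                else "tissue_positions.csv")
    srio.write_tissue_positions(truth.spots, os.path.join(spatial, pos_name),
                                dialect=positions_dialect)
    srio.write_scalefactors(truth.scalefactors,
                            os.path.join(spatial, "scalefactors_json.json"))
    srio.write_image_png(truth.image,
                         os.path.join(spatial, "tissue_lowres_image.png"))
    clust_dir = os.path.join(out_path, "analysis", "clustering", "graphclust")
    os.makedirs(clust_dir, exist_ok=True)
    pd.DataFrame({"Barcode": truth.counts.barcodes,
                  "Cluster": truth.layer_of_spot}).to_csv(
        os.path.join(clust_dir, "clusters.csv"), index=False)
    umap_dir = os.path.join(out_path, "analysis", "umap", "2_components")
    os.makedirs(umap_dir, exist_ok=True)
    pd.DataFrame({"Barcode": truth.counts.barcodes,
                  "UMAP-1": truth.umap[:, 0],
                  "UMAP-2": truth.umap[:, 1]}).to_csv(
        os.path.join(umap_dir, "projection.csv"), index=False)
    return truth
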