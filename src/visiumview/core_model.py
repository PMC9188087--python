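"""In-memory data model for Visium spatial transcriptomics samples.

The unit of observation is the *spot*: a barcoded capture location on the
Visium slide's hexagonal lattice. A :class:`SpatialSample` bundles the UMI
count matrix, the spot positions (array indices plus full-resolution pixel
centers), the scale factors that map full-resolution pixels into the stored
low/high-resolution histology rasters, the rasters themselves, and any
per-spot covariates or low-dimensional projections imported alongside.

Coordinate convention: pixel coordinates are ``(row, col)``, 0-based, with
the row axis increasing downward — i.e. raster indexing. The Space Ranger
``tissue_positions`` columns ``pxl_row_in_fullres`` / ``pxl_col_in_fullres``
map onto this directly, with no axis swap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

RESOLUTION_TAGS = ("lowres", "hires", "fullres")


@dataclass
class SpotTable:
    """Per-spot array indices, tissue flags, and full-resolution pixel centers.

    Visium arrays interleave rows of a hexagonal lattice: within each array
    row, occupied columns share the row's parity, so ``array_row + array_col``
    is even for every real spot. That parity is validated here.
    """

    barcode: np.ndarray
    in_tissue: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    pxl_row_fullres: np.ndarray
    pxl_col_fullres: np.ndarray

    def __post_init__(self) -> None:
        self.barcode = np.asarray(self.barcode, dtype=object)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        self.array_row = np.asarray(self.array_row, dtype=np.int64)
        self.array_col = np.asarray(self.array_col, dtype=np.int64)
        self.pxl_row_fullres = np.asarray(self.pxl_row_fullres, dtype=float)
        self.pxl_col_fullres = np.asarray(self.pxl_col_fullres, dtype=float)
        n = len(self.barcode)
        for name in ("in_tissue", "array_row", "array_col",
                     "pxl_row_fullres", "pxl_col_fullres"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SpotTable field {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if len(set(self.barcode)) != n:
            raise ValueError("SpotTable barcodes are not unique")
        if n and (self.array_row.min() < 0 or self.array_col.min() < 0):
            raise ValueError("array_row/array_col must be non-negative")
        if n and np.any((self.array_row + self.array_col) % 2 != 0):
            bad = int(np.flatnonzero((self.array_row + self.array_col) % 2)[0])
            raise ValueError(
                "Visium hex-lattice parity violated: array_row + array_col "
                f"must be even (first offender: barcode {self.barcode[bad]!r})")
        if n and not (np.all(np.isfinite(self.pxl_row_fullres))
                      and np.all(np.isfinite(self.pxl_col_fullres))):
            raise ValueError("pixel coordinates must be finite")

    def __len__(self) -> int:
        return len(self.barcode)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "barcode": self.barcode,
            "in_tissue": self.in_tissue.astype(int),
            "array_row": self.array_row,
            "array_col": self.array_col,
            "pxl_row_in_fullres": self.pxl_row_fullres,
            "pxl_col_in_fullres": self.pxl_col_fullres,
        })

    def reindex(self, barcodes) -> "SpotTable":
        """Return a SpotTable restricted/reordered to ``barcodes``.

        Raises ``KeyError`` listing any barcode absent from the table.
        """
        pos = {b: i for i, b in enumerate(self.barcode)}
        missing = [b for b in barcodes if b not in pos]
        if missing:
            raise KeyError(f"barcodes not in SpotTable: {missing[:5]}"
                           + (" ..." if len(missing) > 5 else ""))
        idx = np.array([pos[b] for b in barcodes], dtype=np.intp)
        return SpotTable(
            barcode=self.barcode[idx],
            in_tissue=self.in_tissue[idx],
            array_row=self.array_row[idx],
            array_col=self.array_col[idx],
            pxl_row_fullres=self.pxl_row_fullres[idx],
            pxl_col_fullres=self.pxl_col_fullres[idx],
        )


@dataclass
class ScaleFactors:
    """Scale factors from ``scalefactors_json.json``.

    ``tissue_lowres_scalef`` and ``tissue_hires_scalef`` convert
    full-resolution pixel coordinates into the stored low/high-resolution
    image frames; the fullres frame has an implicit scale factor of 1.
    """

    spot_diameter_fullres: float
    tissue_hires_scalef: float
    tissue_lowres_scalef: float
    fiducial_diameter_fullres: float | None = None

    def __post_init__(self) -> None:
        for name in ("spot_diameter_fullres", "tissue_hires_scalef",
                     "tissue_lowres_scalef"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.fiducial_diameter_fullres is not None \
                and self.fiducial_diameter_fullres <= 0:
            raise ValueError("fiducial_diameter_fullres must be positive")
        if self.tissue_lowres_scalef > self.tissue_hires_scalef:
            raise ValueError("tissue_lowres_scalef exceeds tissue_hires_scalef")

    def scalef(self, resolution_tag: str) -> float:
        """Scale factor for a resolution tag (fullres ≡ 1)."""
        if resolution_tag == "lowres":
            return self.tissue_lowres_scalef
        if resolution_tag == "hires":
            return self.tissue_hires_scalef
        if resolution_tag == "fullres":
            return 1.0
        raise ValueError(
            f"unknown resolution tag {resolution_tag!r}; "
            f"valid tags: {', '.join(RESOLUTION_TAGS)}")


@dataclass
class CountMatrix:
    """Sparse genes × spots matrix of non-negative integer UMI counts."""

    counts: sparse.spmatrix
    gene_ids: list[str]
    gene_symbols: list[str]
    barcodes: list[str]
    feature_types: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.gene_symbols = list(self.gene_symbols)
        self.barcodes = list(self.barcodes)
        ng, ns = self.counts.shape
        if len(self.gene_ids) != ng or len(self.gene_symbols) != ng:
            raise ValueError(
                f"matrix declares {ng} genes but identifier lists have "
                f"{len(self.gene_ids)} ids / {len(self.gene_symbols)} symbols")
        if len(self.barcodes) != ns:
            raise ValueError(f"matrix declares {ns} spots but barcode list "
                             f"has {len(self.barcodes)}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != ng:
            raise ValueError("gene_ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        """Row index for a gene given by id or symbol.

        Symbol lookups that hit several gene ids raise, listing the ids;
        unknown genes raise with nearest-symbol suggestions.
        """
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            pass
        hits = [i for i, s in enumerate(self.gene_symbols) if s == gene]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            ids = [self.gene_ids[i] for i in hits]
            raise ValueError(f"gene symbol {gene!r} is ambiguous; matching "
                             f"gene ids: {ids}")
        import difflib
        near = difflib.get_close_matches(gene, self.gene_symbols, n=3)
        hint = f"; did you mean {near}?" if near else ""
        raise KeyError(f"unknown gene {gene!r}{hint}")


@dataclass
class RGBAImage:
    """Histology raster: H × W × 4 uint8 with an explicit resolution tag."""

    pixels: np.ndarray
    resolution_tag: str = "lowres"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3 and px.shape[2] == 3:  # promote RGB to RGBA, opaque
            alpha = np.full(px.shape[:2] + (1,), 255, dtype=np.uint8)
            px = np.concatenate([px.astype(np.uint8), alpha], axis=2)
        if px.ndim != 3 or px.shape[2] != 4:
            raise ValueError("pixels must be H x W x 4 (or H x W x 3)")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1 x 1")
        if self.resolution_tag not in RESOLUTION_TAGS:
            raise ValueError(f"unknown resolution tag {self.resolution_tag!r};"
                             f" valid tags: {', '.join(RESOLUTION_TAGS)}")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def copy(self) -> "RGBAImage":
        return RGBAImage(self.pixels.copy(), self.resolution_tag)


@dataclass
class SpatialSample:
    """One Visium capture area: counts + spots + geometry + images + covariates.

    ``spot_covariates`` vectors are aligned to ``counts.barcodes`` order
    (one value per counted spot); continuous covariates are float arrays,
    categorical ones object arrays with ``None`` marking missing labels.
    """

    sample_id: str
    counts: CountMatrix
    spots: SpotTable
    scalefactors: ScaleFactors
    images: dict[str, RGBAImage] = field(default_factory=dict)
    spot_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    reduced_dims: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spot_set = set(self.spots.barcode)
        missing = [b for b in self.counts.barcodes if b not in spot_set]
        if missing:
            raise ValueError(
                f"sample {self.sample_id!r}: {len(missing)} counted barcodes "
                f"missing from SpotTable (e.g. {missing[:3]})")
        n = self.counts.n_spots
        for name, vec in self.spot_covariates.items():
            if len(vec) != n:
                raise ValueError(f"covariate {name!r} has {len(vec)} values, "
                                 f"expected {n} (one per counted spot)")
        for name, mat in self.reduced_dims.items():
            if mat.shape[0] != n:
                raise ValueError(f"reduced_dims {name!r} has {mat.shape[0]} "
                                 f"rows, expected {n}")
        for tag in self.images:
            self.scalefactors.scalef(tag)  # raises on unknown tag

    @property
    def n_spots(self) -> int:
        return self.counts.n_spots

    def counted_spots(self) -> SpotTable:
        """SpotTable restricted to counted barcodes, in matrix column order."""
        return self.spots.reindex(self.counts.barcodes)

    def set_covariate(self, name: str, values_by_barcode: dict,
                      kind: str = "continuous") -> None:
        """Attach a per-spot covariate keyed by barcode.

        Values for barcodes absent from the count matrix are dropped with a
        logged warning. Unlisted counted barcodes get a missing value
        (NaN for continuous, None for categorical).
        """
        known = set(self.counts.barcodes)
        dropped = [b for b in values_by_barcode if b not in known]
        if dropped:
            logger.warning("sample %s covariate %r: dropping %d values for "
                           "barcodes absent from the count matrix",
                           self.sample_id, name, len(dropped))
        if kind == "continuous":
            vec = np.full(self.counts.n_spots, np.nan, dtype=float)
        else:
            vec = np.full(self.counts.n_spots, None, dtype=object)
        for i, b in enumerate(self.counts.barcodes):
            if b in values_by_barcode:
                vec[i] = values_by_barcode[b]
        self.spot_covariates[name] = vec


@dataclass
class SpatialDataset:
    """Ordered multi-sample collection sharing a gene universe."""

    samples: list[SpatialSample]
    gene_universe: list[str]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids: {ids}")
        for s in self.samples:
            if s.counts.gene_ids != self.gene_universe:
                raise ValueError(f"sample {s.sample_id!r} counts are not "
                                 "aligned to the gene universe")

    def __len__(self) -> int:
        return len(self.samples)

    def get_sample(self, sample_id: str) -> SpatialSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"unknown sample {sample_id!r}; have "
                       f"{[s.sample_id for s in self.samples]}")


def to_image_coords(spots: SpotTable, sf: ScaleFactors,
                    resolution_tag: str) -> np.ndarray:
    """Spot centers in the target image's pixel frame.

    Returns an ``(n, 2)`` array of ``(row_px, col_px)`` obtained by scaling
    the full-resolution centers with the tag's scale factor (fullres ≡ 1).
    Order follows the SpotTable.
    """
    scale = sf.scalef(resolution_tag)
    return np.column_stack([spots.pxl_row_fullres,
                            spots.pxl_col_fullres]) * scale


def spot_radius_px(sf: ScaleFactors, resolution_tag: str,
                   point_size_multiplier: float = 1.0) -> float:
    """Rendered spot radius in target-frame pixels.

    The physical spot footprint is ``spot_diameter_fullres``; the multiplier
    scales it for display (e.g. 2.25 to make small spots legible).
    """
    if not point_size_multiplier > 0:
        raise ValueError(f"point_size_multiplier must be > 0, "
                         f"got {point_size_multiplier}")
    scale = sf.scalef(resolution_tag)
    return sf.spot_diameter_fullres * scale / 2.0 * point_size_multiplier


def align_gene_universe(samples: list[SpatialSample]) -> SpatialDataset:
    """Align samples to their common gene set and build a SpatialDataset.

    The universe is the intersection of gene ids across samples, ordered as
    in the first sample; every count matrix is row-subset and reordered to
    it. An empty intersection is an error: a multi-sample plot must never
    silently show a gene missing from one of its panels.
    """
    if not samples:
        raise ValueError("need at least one sample")
    for s in samples:
        if s.counts.n_genes == 0:
            raise ValueError(f"sample {s.sample_id!r} has no genes")
    common = set(samples[0].counts.gene_ids)
    for s in samples[1:]:
        common &= set(s.counts.gene_ids)
    if not common:
        raise ValueError("gene intersection across samples is empty")
    universe = [g for g in samples[0].counts.gene_ids if g in common]
    aligned = []
    for s in samples:
        pos = {g: i for i, g in enumerate(s.counts.gene_ids)}
        idx = np.array([pos[g] for g in universe], dtype=np.intp)
        cm = CountMatrix(
            counts=s.counts.counts[idx, :],
            gene_ids=[s.counts.gene_ids[i] for i in idx],
            gene_symbols=[s.counts.gene_symbols[i] for i in idx],
            barcodes=s.counts.barcodes,
            feature_types=([s.counts.feature_types[i] for i in idx]
                           if s.counts.feature_types else None),
        )
        aligned.append(SpatialSample(
            sample_id=s.sample_id, counts=cm, spots=s.spots,
            scalefactors=s.scalefactors, images=s.images,
            spot_covariates=s.spot_covariates, reduced_dims=s.reduced_dims))
    return SpatialDataset(samples=aligned, gene_universe=universe)
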