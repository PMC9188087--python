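"""Readers and writers for Space Ranger on-disk dialects and result CSVs.

Space Ranger emits, per capture area, a feature-barcode matrix triplet
(Matrix Market ``matrix.mtx[.gz]`` + ``features.tsv[.gz]`` +
``barcodes.tsv[.gz]``), a ``spatial/`` directory with spot positions
(v1 headerless ``tissue_positions_list.csv`` or v2 headered
``tissue_positions.csv``), ``scalefactors_json.json`` and down-sampled
tissue images, and optionally an ``analysis/`` tree of clustering and
dimension-reduction CSVs. This module reads all of those into the
:mod:`core_model` types, writes them back (used by the synthetic fixture
generator and by the bundle store), and handles the package's own
annotation/result CSVs.
"""

from __future__ import annotations

import csv
import glob
import gzip
import io
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import io as spio
from scipy import sparse

from .annotation import ANNOTATION_COLUMNS, AnnotationTable
from .core_model import (CountMatrix, RGBAImage, ScaleFactors, SpatialSample,
                         SpotTable)

logger = logging.getLogger(__name__)

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                    "pxl_row_in_fullres", "pxl_col_in_fullres"]
IMAGE_FILES = {"lowres": "tissue_lowres_image.png",
               "hires": "tissue_hires_image.png"}


@dataclass
class SpaceRangerDir:
    """Resolved layout of one Space Ranger-style output directory."""

    root_path: str
    matrix_dir: str
    positions_path: str
    scalefactors_path: str
    spatial_dir: str
    analysis_dir: str | None

    @classmethod
    def detect(cls, root_path: str) -> "SpaceRangerDir":
        root = str(root_path)
        if not os.path.isdir(root):
            raise FileNotFoundError(f"not a directory: {root}")
        matrix_dir = None
        for cand in ("filtered_feature_bc_matrix", "raw_feature_bc_matrix", "."):
            d = os.path.join(root, cand)
            if _find_maybe_gz(d, "matrix.mtx"):
                matrix_dir = d
                break
        if matrix_dir is None:
            raise FileNotFoundError(
                f"no matrix.mtx[.gz] triplet found under {root}")
        spatial_dir = os.path.join(root, "spatial")
        if not os.path.isdir(spatial_dir):
            spatial_dir = root
        positions = None
        for name in ("tissue_positions.csv", "tissue_positions_list.csv"):
            p = os.path.join(spatial_dir, name)
            if os.path.exists(p):
                positions = p
                break
        if positions is None:
            raise FileNotFoundError(
                f"no tissue_positions[_list].csv under {spatial_dir}")
        scalefactors = os.path.join(spatial_dir, "scalefactors_json.json")
        if not os.path.exists(scalefactors):
            raise FileNotFoundError(f"missing {scalefactors}")
        analysis = os.path.join(root, "analysis")
        return cls(root_path=root, matrix_dir=matrix_dir,
                   positions_path=positions, scalefactors_path=scalefactors,
                   spatial_dir=spatial_dir,
                   analysis_dir=analysis if os.path.isdir(analysis) else None)


def _find_maybe_gz(directory: str, name: str) -> str | None:
    for cand in (name, name + ".gz"):
        p = os.path.join(directory, cand)
        if os.path.exists(p):
            return p
    return None


def _open_maybe_gz(path: str, mode: str = "rt"):
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_counts(srdir: SpaceRangerDir) -> CountMatrix:
    """Read the feature-barcode matrix triplet (gz or plain).

    Gene ids come from column 1 of ``features.tsv``, symbols from column 2,
    feature types (column 3, when present) are preserved but unused. Values
    must be integers — Visium filtered matrices are UMI counts.
    """
    mtx_path = _find_maybe_gz(srdir.matrix_dir, "matrix.mtx")
    feat_path = _find_maybe_gz(srdir.matrix_dir, "features.tsv")
    bc_path = _find_maybe_gz(srdir.matrix_dir, "barcodes.tsv")
    missing = [n for n, p in [("matrix.mtx", mtx_path),
                              ("features.tsv", feat_path),
                              ("barcodes.tsv", bc_path)] if p is None]
    if missing:
        raise FileNotFoundError(
            f"matrix dir {srdir.matrix_dir} missing: {missing}")
    try:
        with _open_maybe_gz(mtx_path, "rb") as fh:
            mat = spio.mmread(fh)
    except Exception as exc:
        raise ValueError(f"malformed Matrix Market file {mtx_path}: {exc}") from exc
    mat = sparse.csr_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"{mtx_path} contains non-integer values; "
                         "expected UMI counts")
    mat = mat.astype(np.int64)

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    if feats.shape[1] < 2:
        raise ValueError(f"{feat_path}: expected at least 2 tab-separated "
                         f"columns (id, symbol), got {feats.shape[1]}")
    ng, ns = mat.shape
    if len(feats) != ng:
        raise ValueError(f"MTX header declares {ng} genes but {feat_path} "
                         f"has {len(feats)} rows")
    if len(barcodes) != ns:
        raise ValueError(f"MTX header declares {ns} barcodes but {bc_path} "
                         f"has {len(barcodes)} rows")
    ftypes = feats.iloc[:, 2].tolist() if feats.shape[1] >= 3 else None
    return CountMatrix(counts=mat, gene_ids=feats.iloc[:, 0].tolist(),
                       gene_symbols=feats.iloc[:, 1].tolist(),
                       barcodes=barcodes, feature_types=ftypes)


def read_tissue_positions(path: str) -> SpotTable:
    """Parse a spot-positions CSV, auto-detecting the dialect.

    Space Ranger v1 writes a headerless 6-column ``tissue_positions_list.csv``;
    v2 writes ``tissue_positions.csv`` whose first line starts with
    ``barcode``. Both map, in column order, to barcode, in_tissue, array_row,
    array_col, pxl_row_in_fullres, pxl_col_in_fullres.
    """
    with _open_maybe_gz(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"empty positions file: {path}")
    has_header = first.split(",")[0].strip().lower() == "barcode"
    df = pd.read_csv(path, header=0 if has_header else None, dtype=str)
    if df.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {df.shape[1]}")
    df.columns = POSITION_COLUMNS
    numeric = {}
    for col in POSITION_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"{path}: non-numeric value in column {col!r} "
                             f"at data row {row}")
        numeric[col] = vals.to_numpy()
    return SpotTable(
        barcode=df["barcode"].to_numpy(dtype=object),
        in_tissue=numeric["in_tissue"].astype(int).astype(bool),
        array_row=numeric["array_row"].astype(int),
        array_col=numeric["array_col"].astype(int),
        pxl_row_fullres=numeric["pxl_row_in_fullres"],
        pxl_col_fullres=numeric["pxl_col_in_fullres"],
    )


def read_scalefactors(path: str) -> ScaleFactors:
    """Read ``scalefactors_json.json``; unknown keys are ignored."""
    with open(path) as fh:
        data = json.load(fh)
    required = ["spot_diameter_fullres", "tissue_hires_scalef",
                "tissue_lowres_scalef"]
    for key in required:
        if key not in data:
            raise ValueError(f"{path}: missing required key {key!r}")
    for key in required + (["fiducial_diameter_fullres"]
                           if "fiducial_diameter_fullres" in data else []):
        if not (isinstance(data[key], (int, float)) and data[key] > 0):
            raise ValueError(f"{path}: {key} must be a positive number, "
                             f"got {data[key]!r}")
    return ScaleFactors(
        spot_diameter_fullres=float(data["spot_diameter_fullres"]),
        tissue_hires_scalef=float(data["tissue_hires_scalef"]),
        tissue_lowres_scalef=float(data["tissue_lowres_scalef"]),
        fiducial_diameter_fullres=(
            float(data["fiducial_diameter_fullres"])
            if "fiducial_diameter_fullres" in data else None),
    )


def read_analysis_clusters(srdir: SpaceRangerDir,
                           valid_barcodes=None) -> dict[str, dict[str, int]]:
    """Read ``analysis/clustering/<method>/clusters.csv`` files.

    Returns one barcode → integer-label mapping per clustering found
    (e.g. ``graphclust``, ``kmeans_2_clusters``). A missing analysis
    directory yields an empty mapping. Rows whose barcode is not in
    ``valid_barcodes`` (when given) are dropped with a logged warning.
    """
    out: dict[str, dict[str, int]] = {}
    if srdir.analysis_dir is None:
        return out
    pattern = os.path.join(srdir.analysis_dir, "clustering", "*", "clusters.csv")
    for path in sorted(glob.glob(pattern)):
        name = os.path.basename(os.path.dirname(path))
        df = pd.read_csv(path)
        if not {"Barcode", "Cluster"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns Barcode, Cluster")
        labels = dict(zip(df["Barcode"].astype(str),
                          df["Cluster"].astype(int)))
        if valid_barcodes is not None:
            known = set(valid_barcodes)
            unknown = [b for b in labels if b not in known]
            if unknown:
                logger.warning("%s: dropping %d rows with barcodes absent "
                               "from the matrix (e.g. %s)",
                               path, len(unknown), unknown[:3])
                labels = {b: v for b, v in labels.items() if b in known}
        out[name] = labels
    return out


def read_analysis_projections(srdir: SpaceRangerDir,
                              valid_barcodes=None
                              ) -> dict[str, pd.DataFrame]:
    """Read ``analysis/{pca,umap,tsne}/*/projection.csv`` files.

    Returns one barcode-indexed DataFrame (spots × k) per projection found.
    """
    out: dict[str, pd.DataFrame] = {}
    if srdir.analysis_dir is None:
        return out
    for method in ("pca", "umap", "tsne"):
        pattern = os.path.join(srdir.analysis_dir, method, "*",
                               "projection.csv")
        for path in sorted(glob.glob(pattern)):
            df = pd.read_csv(path)
            if "Barcode" not in df.columns:
                raise ValueError(f"{path}: expected a Barcode column")
            df = df.set_index(df["Barcode"].astype(str)).drop(columns="Barcode")
            if df.shape[1] == 0:
                raise ValueError(f"{path}: projection has 0 components")
            if valid_barcodes is not None:
                known = set(valid_barcodes)
                unknown = [b for b in df.index if b not in known]
                if unknown:
                    logger.warning("%s: dropping %d rows with unknown "
                                   "barcodes", path, len(unknown))
                    df = df.loc[[b for b in df.index if b in known]]
            out[method] = df.astype(float)
    return out


def load_images(srdir: SpaceRangerDir) -> dict[str, RGBAImage]:
    images = {}
    for tag, fname in IMAGE_FILES.items():
        path = os.path.join(srdir.spatial_dir, fname)
        if os.path.exists(path):
            with Image.open(path) as im:
                images[tag] = RGBAImage(np.asarray(im.convert("RGBA")), tag)
    return images


def load_sample(root_path: str, sample_id: str) -> SpatialSample:
    """Load one complete Space Ranger-style directory as a SpatialSample.

    Spots are restricted to the barcodes present in the count matrix;
    analysis clusterings become categorical covariates (labels stored as
    strings for stable palette assignment) and projections become
    reduced_dims matrices.
    """
    try:
        srdir = SpaceRangerDir.detect(root_path)
        counts = read_counts(srdir)
        positions = read_tissue_positions(srdir.positions_path)
        sf = read_scalefactors(srdir.scalefactors_path)
        images = load_images(srdir)
        spots = positions.reindex(counts.barcodes)
        clusters = read_analysis_clusters(srdir, counts.barcodes)
        projections = read_analysis_projections(srdir, counts.barcodes)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"sample {sample_id!r}: {exc}") from exc
    except Exception as exc:
        raise ValueError(f"sample {sample_id!r}: {exc}") from exc
    covariates: dict[str, np.ndarray] = {}
    for name, labels in clusters.items():
        covariates[name] = np.array(
            [str(labels[b]) if b in labels else None for b in counts.barcodes],
            dtype=object)
    reduced = {}
    for name, df in projections.items():
        reduced[name] = df.reindex(counts.barcodes).to_numpy(dtype=float)
    return SpatialSample(sample_id=sample_id, counts=counts, spots=spots,
                         scalefactors=sf, images=images,
                         spot_covariates=covariates, reduced_dims=reduced)


# ---------------------------------------------------------------------------
# writers


def write_counts(cm: CountMatrix, matrix_dir: str, gz: bool = True) -> None:
    """Write a feature-barcode matrix triplet (gzipped by default)."""
    os.makedirs(matrix_dir, exist_ok=True)
    suffix = ".gz" if gz else ""
    buf = io.BytesIO()
    spio.mmwrite(buf, sparse.coo_matrix(cm.counts), field="integer")
    opener = gzip.open if gz else open
    with opener(os.path.join(matrix_dir, "matrix.mtx" + suffix), "wb") as fh:
        fh.write(buf.getvalue())
    ftypes = cm.feature_types or ["Gene Expression"] * cm.n_genes
    with opener(os.path.join(matrix_dir, "features.tsv" + suffix), "wt") as fh:
        for gid, sym, ft in zip(cm.gene_ids, cm.gene_symbols, ftypes):
            fh.write(f"{gid}\t{sym}\t{ft}\n")
    with opener(os.path.join(matrix_dir, "barcodes.tsv" + suffix), "wt") as fh:
        for bc in cm.barcodes:
            fh.write(bc + "\n")


def write_tissue_positions(spots: SpotTable, path: str,
                           dialect: str = "v1") -> None:
    """Write spot positions in the v1 (headerless) or v2 (headered) dialect."""
    if dialect not in ("v1", "v2"):
        raise ValueError(f"dialect must be 'v1' or 'v2', got {dialect!r}")
    df = spots.to_dataframe()
    df.columns = POSITION_COLUMNS
    df.to_csv(path, index=False, header=(dialect == "v2"))


def write_scalefactors(sf: ScaleFactors, path: str) -> None:
    data = {"spot_diameter_fullres": sf.spot_diameter_fullres,
            "tissue_hires_scalef": sf.tissue_hires_scalef,
            "tissue_lowres_scalef": sf.tissue_lowres_scalef}
    if sf.fiducial_diameter_fullres is not None:
        data["fiducial_diameter_fullres"] = sf.fiducial_diameter_fullres
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def write_image_png(img: RGBAImage, path: str) -> None:
    Image.fromarray(img.pixels, mode="RGBA").save(path, format="PNG")


def write_results_csv(table: pd.DataFrame, path: str) -> None:
    """Write a result table as a quoted-where-needed CSV with header."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    table.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def write_annotations(ann: AnnotationTable, path: str) -> None:
    """Write an annotation table (columns sample_id, barcode, label)."""
    ann.df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def read_annotations(path: str) -> AnnotationTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise ValueError(f"{path}: expected columns {ANNOTATION_COLUMNS}, "
                         f"got {list(df.columns)}")
    return AnnotationTable(df)


# ---------------------------------------------------------------------------
# bundle store: the CLI's on-disk representation of an imported dataset.
# A bundle is a directory with a manifest.json listing sample ids; each
# sample sub-directory is a Space Ranger-style tree plus covariates.csv
# (non-clustering covariates) and meta.json (covariate kinds).


def save_sample_to_bundle(sample: SpatialSample, bundle_path: str) -> None:
    os.makedirs(bundle_path, exist_ok=True)
    manifest_path = os.path.join(bundle_path, "manifest.json")
    manifest = {"samples": []}
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    sdir = os.path.join(bundle_path, sample.sample_id)
    write_counts(sample.counts,
                 os.path.join(sdir, "filtered_feature_bc_matrix"))
    spatial = os.path.join(sdir, "spatial")
    os.makedirs(spatial, exist_ok=True)
    write_tissue_positions(sample.spots,
                           os.path.join(spatial, "tissue_positions.csv"),
                           dialect="v2")
    write_scalefactors(sample.scalefactors,
                       os.path.join(spatial, "scalefactors_json.json"))
    for tag, img in sample.images.items():
        write_image_png(img, os.path.join(spatial, IMAGE_FILES[tag]))
    kinds = {}
    cov_df = pd.DataFrame({"barcode": sample.counts.barcodes})
    for name, vec in sample.spot_covariates.items():
        if np.issubdtype(np.asarray(vec).dtype, np.number):
            kinds[name] = "continuous"
            cov_df[name] = np.asarray(vec, dtype=float)
        else:
            kinds[name] = "categorical"
            cov_df[name] = [v if v is not None else "" for v in vec]
    if len(cov_df.columns) > 1:
        cov_df.to_csv(os.path.join(sdir, "covariates.csv"), index=False)
    for name, mat in sample.reduced_dims.items():
        rd_dir = os.path.join(sdir, "reduced_dims")
        os.makedirs(rd_dir, exist_ok=True)
        rd = pd.DataFrame(mat, columns=[f"{name}_{i+1}"
                                        for i in range(mat.shape[1])])
        rd.insert(0, "Barcode", sample.counts.barcodes)
        rd.to_csv(os.path.join(rd_dir, f"{name}.csv"), index=False)
    with open(os.path.join(sdir, "meta.json"), "w") as fh:
        json.dump({"sample_id": sample.sample_id, "covariates": kinds}, fh)
    if sample.sample_id not in manifest["samples"]:
        manifest["samples"].append(sample.sample_id)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh)


def load_bundle(bundle_path: str) -> list[SpatialSample]:
    """Load every sample stored in a bundle directory, in manifest order."""
    manifest_path = os.path.join(bundle_path, "manifest.json")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"not a bundle (no manifest.json): {bundle_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    samples = []
    for sid in manifest["samples"]:
        sdir = os.path.join(bundle_path, sid)
        sample = load_sample(sdir, sid)
        meta_path = os.path.join(sdir, "meta.json")
        kinds = {}
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                kinds = json.load(fh).get("covariates", {})
        cov_path = os.path.join(sdir, "covariates.csv")
        if os.path.exists(cov_path):
            cov = pd.read_csv(cov_path, dtype=str, keep_default_na=False)
            cov = cov.set_index("barcode").reindex(sample.counts.barcodes)
            for name in cov.columns:
                if kinds.get(name, "continuous") == "continuous":
                    sample.spot_covariates[name] = pd.to_numeric(
                        cov[name], errors="coerce").to_numpy(dtype=float)
                else:
                    sample.spot_covariates[name] = np.array(
                        [v if v != "" else None for v in cov[name]],
                        dtype=object)
        rd_dir = os.path.join(sdir, "reduced_dims")
        if os.path.isdir(rd_dir):
            for path in sorted(glob.glob(os.path.join(rd_dir, "*.csv"))):
                name = os.path.splitext(os.path.basename(path))[0]
                df = pd.read_csv(path).set_index("Barcode")
                sample.reduced_dims[name] = df.reindex(
                    sample.counts.barcodes).to_numpy(dtype=float)
        samples.append(sample)
    return samples
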