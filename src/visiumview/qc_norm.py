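"""Per-spot QC covariates and a simple expression normalization.

The QC covariates — total UMI, number of genes detected, and percent
mitochondrial expression — are the standard continuous variables plotted
over histology to judge capture quality; in brain tissue the mitochondrial
percentage tracks anatomical layers, which makes it a useful sanity map.

Mitochondrial genes are identified by gene-symbol prefix (default ``MT-``),
because Space Ranger's ``features.tsv`` carries no chromosome annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import SpatialSample

logger = logging.getLogger(__name__)


@dataclass
class QCTable:
    """Per-spot QC covariates, aligned to the sample's counted barcodes."""

    barcodes: list[str]
    sum_umi: np.ndarray
    sum_genes_detected: np.ndarray
    expr_chrM_percent: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "barcode": self.barcodes,
            "sum_umi": self.sum_umi,
            "sum_genes_detected": self.sum_genes_detected,
            "expr_chrM_percent": self.expr_chrM_percent,
        })


def compute_qc(sample: SpatialSample, mito_prefix: str = "MT-") -> QCTable:
    """Compute per-spot QC covariates.

    ``sum_umi`` is the column sum; ``sum_genes_detected`` the per-spot count
    of genes with nonzero counts; ``expr_chrM_percent`` is
    100 × mito UMI / total UMI, defined as 0 for zero-count spots.
    """
    counts = sample.counts.counts.tocsc()
    if counts.shape[0] == 0:
        raise ValueError("count matrix has no genes")
    sum_umi = np.asarray(counts.sum(axis=0)).ravel().astype(np.int64)
    detected = np.asarray((counts > 0).sum(axis=0)).ravel().astype(np.int64)
    mito_mask = np.array([s.startswith(mito_prefix)
                          for s in sample.counts.gene_symbols])
    if mito_mask.any():
        mito_sum = np.asarray(
            counts[mito_mask, :].sum(axis=0)).ravel().astype(np.int64)
    else:
        mito_sum = np.zeros_like(sum_umi)
    n_zero = int((sum_umi == 0).sum())
    if n_zero:
        logger.info("compute_qc: %d zero-count spots; their mito percent "
                    "is reported as 0", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(sum_umi > 0, 100.0 * mito_sum / np.maximum(sum_umi, 1), 0.0)
    return QCTable(barcodes=list(sample.counts.barcodes), sum_umi=sum_umi,
                   sum_genes_detected=detected, expr_chrM_percent=percent)


def attach_qc_covariates(sample: SpatialSample,
                         mito_prefix: str = "MT-") -> QCTable:
    """Compute QC and register each column as a continuous spot covariate."""
    qc = compute_qc(sample, mito_prefix)
    sample.spot_covariates["sum_umi"] = qc.sum_umi.astype(float)
    sample.spot_covariates["sum_genes_detected"] = \
        qc.sum_genes_detected.astype(float)
    sample.spot_covariates["expr_chrM_percent"] = qc.expr_chrM_percent
    return qc


def log_norm_expression(sample: SpatialSample, gene: str) -> np.ndarray:
    """Library-size-normalized log expression of one gene.

    Per spot: ``log2(1 + count * 1e4 / sum_umi)`` (counts per 10k, then
    log2(1+x)). Spots with zero total UMI get 0. The gene may be given by
    id or by symbol; an ambiguous symbol raises, listing the candidate ids.

    This is a deterministic, dependency-free transform; the plotting layer
    also accepts any precomputed continuous covariate, so alternative
    normalizations (scran pooling, Pearson residuals, ...) plug in upstream.
    """
    idx = sample.counts.gene_index(gene)
    counts = sample.counts.counts
    sum_umi = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    gene_counts = np.asarray(counts[idx, :].todense()).ravel().astype(float)
    out = np.zeros_like(gene_counts)
    nz = sum_umi > 0
    out[nz] = np.log2(1.0 + gene_counts[nz] * 1e4 / sum_umi[nz])
    return out
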