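"""Single-cell preprocessing: QC, normalization, HVG selection, covariate
regression, scaling and PCA.

The chain follows the standard scRNA-seq workflow: cells with fewer than
200 detected genes and genes detected in fewer than 3 cells are dropped
(single pass on the original matrix), counts are depth-normalized to a
fixed target sum and log1p-transformed, highly variable genes are selected
by mean-binned normalized dispersion, total counts and mitochondrial
fraction are regressed out per gene, genes are z-scored with clipping, and
cells are embedded with PCA.  Every step is deterministic; the PCA sign
convention forces the largest-magnitude loading of each component to be
positive so repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

MITO_PREFIX = "mt-"


class PreprocessError(ValueError):
    pass


@dataclass
class NormMatrix:
    """Dense cells x genes matrix of normalized log1p expression."""

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise PreprocessError(
                f"values shape {self.values.shape} does not match IDs"
            )
        if not np.all(np.isfinite(self.values)):
            raise PreprocessError("non-finite normalized values")

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from normalized matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, mask) -> "NormMatrix":
        return NormMatrix(self.cell_ids, self.gene_ids[mask], self.values[:, mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class PCAEmbedding:
    """Cells x K PC coordinates with nonincreasing explained variance."""

    cell_ids: np.ndarray
    coordinates: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise PreprocessError("explained_variance must be nonincreasing")

    def rows_for(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise KeyError(f"cells absent from embedding: {missing}")
        return np.array([lookup[c] for c in cells], dtype=int)


def qc_filter(
    counts: CountMatrix, min_genes_per_cell: int = 200, min_cells_per_gene: int = 3
) -> CountMatrix:
    """Drop low-complexity cells and rarely detected genes.

    Both criteria are evaluated on the original matrix in a single pass
    (not iterated to a fixed point): a retained cell has at least
    ``min_genes_per_cell`` genes with nonzero count, a retained gene has
    nonzero count in at least ``min_cells_per_gene`` cells.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise PreprocessError("QC thresholds must be >= 0")
    nnz = counts.counts.copy()
    nnz.data = np.ones_like(nnz.data)
    genes_per_cell = np.asarray(nnz.sum(axis=1)).ravel()
    cells_per_gene = np.asarray(nnz.sum(axis=0)).ravel()
    cell_mask = genes_per_cell >= min_genes_per_cell
    gene_mask = cells_per_gene >= min_cells_per_gene
    return counts.subset(cell_mask, gene_mask)


def normalize_log1p(counts: CountMatrix, target_sum: float = 10_000.0) -> NormMatrix:
    """Scale each cell to ``target_sum`` total counts, then ln(1 + x)."""
    totals = np.asarray(counts.counts.sum(axis=1)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        raise PreprocessError(
            f"cells with zero total counts: {list(counts.cell_ids[zero][:5])}"
        )
    dense = counts.to_dense().astype(float)
    values = np.log1p(dense / totals[:, None] * target_sum)
    return NormMatrix(counts.cell_ids, counts.gene_ids, values)


def select_hvg(
    norm: NormMatrix,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
    min_disp: float = 0.5,
    n_bins: int = 20,
) -> np.ndarray:
    """Highly variable genes by mean-binned normalized dispersion.

    Statistics are computed on back-transformed normalized counts
    (exp(values) - 1): dispersion = variance / mean, then log-transformed,
    with gene means on the log1p scale (the scale on which the default
    thresholds 0.0125 and 3 are defined).  Genes are binned into ``n_bins``
    equal-width bins of mean and the dispersion is z-scored within its bin;
    single-gene bins use the raw dispersion over the bin mean.  A gene is
    retained iff min_mean < mean < max_mean and normalized dispersion
    exceeds ``min_disp``.  Returns a boolean mask over genes.
    """
    if n_bins < 1:
        raise PreprocessError("n_bins must be >= 1")
    if norm.values.shape[0] < 2:
        raise PreprocessError("need at least 2 cells for HVG selection")
    expr = np.expm1(norm.values)
    mean = expr.mean(axis=0)
    var = expr.var(axis=0, ddof=1)
    mean_safe = np.where(mean == 0, 1e-12, mean)
    dispersion = var / mean_safe
    defined = dispersion > 0
    log_disp = np.where(defined, np.log(np.where(defined, dispersion, 1.0)), np.nan)
    log_mean = np.log1p(mean)

    df = pd.DataFrame({"mean": log_mean, "disp": log_disp})
    df["bin"] = pd.cut(df["mean"], bins=n_bins)
    grouped = df.groupby("bin", observed=True)["disp"]
    bin_mean = grouped.transform("mean")
    bin_std = grouped.transform("std")
    singleton = bin_std.isna() | (bin_std == 0)
    # singleton / zero-spread bins: scale by the bin mean instead so the
    # statistic stays finite (a lone gene cannot stand out from itself)
    denom = np.where(singleton, np.abs(bin_mean.to_numpy()), bin_std.to_numpy())
    center = np.where(singleton, 0.0, bin_mean.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        disp_norm = (df["disp"].to_numpy() - center) / denom
    disp_norm = np.where(np.isfinite(disp_norm), disp_norm, 0.0)

    mask = (
        defined
        & (log_mean > min_mean)
        & (log_mean < max_mean)
        & (disp_norm > min_disp)
    )
    return np.asarray(mask, dtype=bool)


def mito_fraction(counts: CountMatrix) -> np.ndarray:
    """Per-cell fraction of counts from genes prefixed ``mt-``."""
    is_mito = np.array([str(g).startswith(MITO_PREFIX) for g in counts.gene_ids])
    totals = np.asarray(counts.counts.sum(axis=1)).ravel().astype(float)
    totals[totals == 0] = 1.0
    if not is_mito.any():
        return np.zeros(counts.n_cells)
    mito = np.asarray(counts.counts[:, is_mito].sum(axis=1)).ravel().astype(float)
    return mito / totals


def regress_out(norm: NormMatrix, covariates: np.ndarray) -> NormMatrix:
    """Remove linear covariate effects per gene by ordinary least squares.

    ``covariates`` is a cells x k array (e.g. columns total_counts and
    pct_mito).  Each gene is regressed on [1, covariates]; the returned
    values are the residuals plus the fitted intercept, so per-gene means
    are preserved.
    """
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != len(norm.cell_ids):
        raise PreprocessError(
            f"covariate rows ({cov.shape[0]}) do not match cells ({len(norm.cell_ids)})"
        )
    # centering the covariates leaves the residuals unchanged but makes the
    # fitted intercept the mean prediction, so adding it back preserves
    # per-gene means
    X = np.column_stack([np.ones(cov.shape[0]), cov - cov.mean(axis=0)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise PreprocessError(
            "rank-deficient covariate design; consider dropping a constant "
            "or collinear covariate"
        )
    beta, *_ = np.linalg.lstsq(X, norm.values, rcond=None)
    residuals = norm.values - X @ beta
    return NormMatrix(norm.cell_ids, norm.gene_ids, residuals + beta[0])


def scale_genes(norm: NormMatrix, max_value: float = 10.0) -> NormMatrix:
    """Per-gene z-scoring (population sd, ddof=0) with clipping.

    Zero-variance genes map to all-zero columns; values are clipped to
    [-max_value, +max_value].
    """
    if norm.values.shape[0] < 2:
        raise PreprocessError("need at least 2 cells to scale")
    mean = norm.values.mean(axis=0)
    sd = norm.values.std(axis=0, ddof=0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    scaled = (norm.values - mean) / safe_sd
    scaled[:, sd == 0] = 0.0
    scaled = np.clip(scaled, -max_value, max_value)
    return NormMatrix(norm.cell_ids, norm.gene_ids, scaled)


def pca_embed(scaled: NormMatrix, n_pcs: int = 40) -> PCAEmbedding:
    """Project cells onto the top principal components.

    Coordinates are the projections of the column-centered matrix onto its
    top right singular vectors; explained variances are the singular values
    squared over (cells - 1), matching a covariance eigendecomposition.
    If ``n_pcs`` exceeds the matrix rank it is reduced with a logged
    warning.  Sign convention: within each component the loading of
    largest absolute value is positive.
    """
    X = scaled.values
    n_cells, n_genes = X.shape
    if n_pcs < 1:
        raise PreprocessError("n_pcs must be >= 1")
    if n_pcs > min(n_cells, n_genes):
        raise PreprocessError(
            f"n_pcs={n_pcs} exceeds min(cells, genes)={min(n_cells, n_genes)}"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S[0] * max(Xc.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int(np.sum(S > tol))
    k = min(n_pcs, max(rank, 1))
    if k < n_pcs:
        logger.warning("n_pcs=%d exceeds matrix rank %d; using %d", n_pcs, rank, k)
    coords = U[:, :k] * S[:k]
    components = Vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            coords[:, i] *= -1.0
    explained = (S[:k] ** 2) / max(n_cells - 1, 1)
    return PCAEmbedding(scaled.cell_ids, coords, explained)


@dataclass
class PreprocessResult:
    qc_counts: CountMatrix
    norm: NormMatrix  # all retained genes, pre-regression
    hvg_mask: np.ndarray
    scaled: NormMatrix  # HVG subset after regression and scaling
    embedding: PCAEmbedding


def run_preprocess(
    counts: CountMatrix,
    min_genes_per_cell: int = 200,
    min_cells_per_gene: int = 3,
    target_sum: float = 10_000.0,
    n_pcs: int = 40,
    max_scale: float = 10.0,
) -> PreprocessResult:
    """QC -> normalize -> HVG -> regress -> scale -> PCA, in one call.

    Regression covariates are per-cell total counts and mitochondrial
    fraction computed on the QC-filtered raw matrix; a covariate that is
    constant (e.g. no ``mt-`` genes present) is dropped with a log note.
    """
    qc = qc_filter(counts, min_genes_per_cell, min_cells_per_gene)
    if qc.n_cells == 0 or qc.n_genes == 0:
        raise PreprocessError("QC removed all cells or genes")
    norm = normalize_log1p(qc, target_sum=target_sum)
    hvg = select_hvg(norm)
    if hvg.sum() < 2:
        raise PreprocessError("fewer than 2 highly variable genes selected")

    totals = np.asarray(qc.counts.sum(axis=1)).ravel().astype(float)
    pct_mito = mito_fraction(qc)
    covs, names = [], []
    for vec, name in ((totals, "total_counts"), (pct_mito, "pct_mito")):
        if np.ptp(vec) > 0:
            covs.append(vec)
            names.append(name)
        else:
            logger.info("dropping constant covariate %s", name)
    hv = norm.subset_genes(hvg)
    regressed = regress_out(hv, np.column_stack(covs)) if covs else hv
    scaled = scale_genes(regressed, max_value=max_scale)
    k = min(n_pcs, min(scaled.values.shape))
    embedding = pca_embed(scaled, n_pcs=k)
    return PreprocessResult(qc, norm, hvg, scaled, embedding)
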