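"""Count-matrix containers, 10x-triplet input, per-replicate QC, and
log-CP10K normalization.

The count container is gene-major (genes as rows, cells as columns),
matching the MatrixMarket layout CellRanger emits.  QC keeps cells whose
number of detected genes falls inside a per-replicate window and whose
mitochondrial fraction is at most a cap; genes are never removed.  The
default thresholds are derived per replicate from the data itself
(median +/- 3 MAD on log1p genes-detected, mito <= 0.2), standing in for
replicate-specific cutoffs chosen by eye on the same two distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from germscreen.errors import ConfigError, EmptyResultError, FormatError

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "symbol", "gene_class", "is_mito"]
CELL_COLUMNS = ["barcode", "replicate_id", "analysis_id"]


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene x cell counts with metadata.

    Attributes
    ----------
    counts
        CSR matrix, shape (n_genes, n_cells), integer dtype.
    genes
        One row per gene: gene_id, symbol, gene_class, is_mito.
    cells
        One row per cell: barcode, replicate_id, analysis_id.
    """

    counts: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.genes):
            raise FormatError(
                f"matrix has {self.counts.shape[0]} rows but gene table has "
                f"{len(self.genes)} entries"
            )
        if self.counts.shape[1] != len(self.cells):
            raise FormatError(
                f"matrix has {self.counts.shape[1]} columns but cell table has "
                f"{len(self.cells)} entries"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """New matrix keeping cells where mask is True; order preserved."""
        mask = np.asarray(mask, dtype=bool)
        return CountMatrix(
            counts=self.counts[:, mask].tocsr(),
            genes=self.genes.copy(),
            cells=self.cells.loc[mask].reset_index(drop=True),
        )

    def to_anndata(self):
        """Cells x genes AnnData view for interoperability with scanpy."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cells.set_index("barcode", drop=False),
            var=self.genes.set_index("gene_id", drop=False),
        )

    @staticmethod
    def concat_cells(matrices: list["CountMatrix"]) -> "CountMatrix":
        """Column-wise concatenation of matrices sharing one gene table."""
        first = matrices[0]
        for m in matrices[1:]:
            if not first.genes["gene_id"].equals(m.genes["gene_id"]):
                raise FormatError("cannot pool matrices with different gene tables")
        return CountMatrix(
            counts=sp.hstack([m.counts for m in matrices]).tocsr(),
            genes=first.genes.copy(),
            cells=pd.concat([m.cells for m in matrices], ignore_index=True),
        )


@dataclass
class NormMatrix:
    """Gene x cell normalized expression on the natural-log scale.

    Zero counts stay exactly zero, so sparsity is preserved.
    """

    values: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame
    normalization: str = "log-CP10K"

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class QCThresholds:
    """Per-replicate cell-filtering thresholds."""

    min_genes_per_cell: int = 0
    max_genes_per_cell: float = float("inf")
    max_mito_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.min_genes_per_cell > self.max_genes_per_cell:
            raise ConfigError("min_genes_per_cell exceeds max_genes_per_cell")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ConfigError("max_mito_fraction must be in [0, 1]")


def read_tenx(directory: str | Path) -> CountMatrix:
    """Read a 10x-style triplet (matrix.mtx, features.tsv, barcodes.tsv).

    features.tsv carries up to four tab-separated columns
    (gene_id, symbol, gene_class, is_mito); missing columns are filled with
    defaults.  MTX 1-based coordinates become 0-based internal indices.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    feat_path = directory / "features.tsv"
    bc_path = directory / "barcodes.tsv"
    for p in (mtx_path, feat_path, bc_path):
        if not p.exists():
            raise FormatError(f"missing triplet file: {p}")

    counts = sp.csr_matrix(mmread(mtx_path))
    features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)

    if counts.shape[0] != len(features):
        raise FormatError(
            f"{mtx_path} declares {counts.shape[0]} genes but {feat_path} has "
            f"{len(features)} lines"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path} declares {counts.shape[1]} cells but {bc_path} has "
            f"{len(barcodes)} lines"
        )

    genes = pd.DataFrame({"gene_id": features[0]})
    genes["symbol"] = features[1] if features.shape[1] > 1 else features[0]
    genes["gene_class"] = features[2] if features.shape[1] > 2 else "protein_coding"
    if features.shape[1] > 3:
        genes["is_mito"] = features[3].map({"True": True, "False": False}).fillna(False)
    else:
        genes["is_mito"] = genes["symbol"].str.startswith("mt:")
    genes["is_mito"] = genes["is_mito"].astype(bool)

    cells = pd.DataFrame({"barcode": barcodes[0]})
    cells["replicate_id"] = barcodes[1] if barcodes.shape[1] > 1 else ""
    cells["analysis_id"] = barcodes[2] if barcodes.shape[1] > 2 else ""
    return CountMatrix(counts=counts.astype(np.int64), genes=genes, cells=cells)


def mito_fraction(matrix: CountMatrix) -> np.ndarray:
    """Per-cell fraction of counts in mitochondrial-flagged genes.

    Cells with zero total counts get fraction 0 and a logged warning.
    """
    mito_mask = matrix.genes["is_mito"].to_numpy(dtype=bool)
    totals = matrix.cell_totals().astype(float)
    mito = np.asarray(matrix.counts[mito_mask].sum(axis=0)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        logger.warning("%d cells have zero total counts; mito fraction set to 0", zero.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(zero, 0.0, mito / np.where(zero, 1.0, totals))
    return frac


def default_thresholds(matrix: CountMatrix, max_mito_fraction: float = 0.2) -> QCThresholds:
    """Automatic per-replicate thresholds: median +/- 3 MAD of
    log1p(genes detected), mito fraction capped at 0.2."""
    lg = np.log1p(matrix.genes_detected().astype(float))
    med = np.median(lg)
    mad = np.median(np.abs(lg - med))
    lo, hi = med - 3 * mad, med + 3 * mad
    return QCThresholds(
        min_genes_per_cell=int(np.floor(np.expm1(lo))) if np.expm1(lo) > 0 else 0,
        max_genes_per_cell=float(np.ceil(np.expm1(hi))),
        max_mito_fraction=max_mito_fraction,
    )


def qc_filter(matrix: CountMatrix, thresholds: QCThresholds) -> CountMatrix:
    """Keep cells passing the genes-detected window and the mito cap.

    Genes are never removed.  Raises if every cell fails, naming the
    replicate(s) involved.
    """
    detected = matrix.genes_detected()
    mito = mito_fraction(matrix)
    keep = (
        (detected >= thresholds.min_genes_per_cell)
        & (detected <= thresholds.max_genes_per_cell)
        & (mito <= thresholds.max_mito_fraction)
    )
    replicates = sorted(set(matrix.cells["replicate_id"].astype(str)))
    if not keep.any():
        raise EmptyResultError(
            f"QC removed all {matrix.n_cells} cells (replicates: {', '.join(replicates)})"
        )
    logger.info(
        "QC (replicates %s): kept %d of %d cells", ",".join(replicates), keep.sum(), keep.size
    )
    return matrix.subset_cells(keep)


def normalize_cp10k(matrix: CountMatrix) -> NormMatrix:
    """log-CP10K: value = ln(1 + 1e4 * count / cell_total).

    A monotone per-cell normalization standing in for variance-stabilizing
    transforms; rank-based downstream statistics depend only on the
    within-cell monotonicity.  Zero counts map to exactly zero.
    """
    totals = matrix.cell_totals().astype(float)
    if (totals == 0).any():
        n = int((totals == 0).sum())
        raise EmptyResultError(
            f"{n} cells have zero total counts; run qc_filter before normalization"
        )
    x = matrix.counts.tocoo().astype(float)
    data = np.log1p(1e4 * x.data / totals[x.col])
    values = sp.csr_matrix((data, (x.row, x.col)), shape=matrix.counts.shape)
    return NormMatrix(
        values=values,
        genes=matrix.genes.copy(),
        cells=matrix.cells.copy(),
        normalization="log-CP10K",
    )
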