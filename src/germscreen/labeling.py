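"""Germline/soma labeling from marker-gene expression, and dot-plot stats.

Each cell gets a marker score: the unweighted mean of the normalized
expression of the four marker genes (vasa plus the three synaptonemal-
complex central-region genes).  Cells are split into germline and soma by
the Otsu criterion — the cut maximizing between-class variance, searched
exhaustively over the observed scores.  This replaces graph clustering
followed by marker-based cluster labeling: the downstream statistics only
need the binary partition, and the marker criterion is the labeling rule
itself.  Externally computed labels can be injected via
``CellLabeling.from_labels`` where a clustering is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from germscreen.errors import ConfigError, DegenerateInputError, EmptyResultError
from germscreen.io_qc import CountMatrix, NormMatrix


@dataclass
class CellLabeling:
    """Binary germline/soma partition with provenance."""

    labels: np.ndarray  # "germline" | "soma", one per cell
    scores: np.ndarray
    method: str
    threshold: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels.size != self.scores.size:
            raise ConfigError("labels and scores lengths differ")

    @property
    def germline_mask(self) -> np.ndarray:
        return self.labels == "germline"

    @classmethod
    def from_labels(cls, labels: np.ndarray, scores: np.ndarray | None = None) -> "CellLabeling":
        """Adopt an external partition (e.g. from graph clustering)."""
        labels = np.asarray(labels, dtype=object)
        if scores is None:
            scores = np.zeros(labels.size)
        return cls(labels=labels, scores=scores, method="external", threshold=float("nan"))


def marker_score(norm: NormMatrix, marker_gene_ids: list[str]) -> np.ndarray:
    """Per-cell mean normalized expression of the marker genes."""
    gene_ids = norm.genes["gene_id"]
    idx = []
    for gid in marker_gene_ids:
        hits = np.flatnonzero(gene_ids == gid)
        if hits.size == 0:
            raise ConfigError(f"marker gene not found in gene table: {gid!r}")
        idx.append(hits[0])
    block = norm.values[idx, :]
    return np.asarray(block.mean(axis=0)).ravel()


def otsu_threshold(scores: np.ndarray) -> float:
    """Otsu's criterion by exhaustive search over observed values.

    Candidate cuts are the observed unique scores; the returned threshold t
    maximizes the between-class variance of the split
    {x <= t} vs {x > t}, excluding cuts that empty either side.
    """
    scores = np.asarray(scores, dtype=float)
    values = np.unique(scores)
    if values.size < 2:
        raise DegenerateInputError("scores are constant; cannot threshold")
    # cuts at each unique value except the max (which would empty the upper class)
    best_t, best_var = values[0], -np.inf
    total_mean = scores.mean()
    n = scores.size
    order = np.sort(scores)
    csum = np.cumsum(order)
    for t in values[:-1]:
        k = np.searchsorted(order, t, side="right")  # size of lower class
        mean_lo = csum[k - 1] / k
        mean_hi = (csum[-1] - csum[k - 1]) / (n - k)
        w_lo, w_hi = k / n, (n - k) / n
        between = w_lo * (mean_lo - total_mean) ** 2 + w_hi * (mean_hi - total_mean) ** 2
        if between > best_var:
            best_var, best_t = between, float(t)
    return best_t


def assign_germline(scores: np.ndarray, method: str = "otsu", min_cells: int = 10) -> CellLabeling:
    """Threshold marker scores into germline (strictly above) vs soma.

    Ties exactly at the threshold go to soma.  Requires at least
    ``min_cells`` cells and a non-constant score distribution, and both
    classes must be non-empty after thresholding.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < min_cells:
        raise ConfigError(f"need >= {min_cells} cells to threshold, got {scores.size}")
    t = otsu_threshold(scores)
    labels = np.where(scores > t, "germline", "soma").astype(object)
    n_germ = int((labels == "germline").sum())
    if n_germ == 0 or n_germ == scores.size:
        raise EmptyResultError(
            "Otsu threshold left one class empty; supply a manual threshold"
        )
    return CellLabeling(labels=labels, scores=scores, method=method, threshold=t)


def dotplot_stats(
    norm: NormMatrix,
    counts: CountMatrix,
    labeling: CellLabeling,
    gene_ids: list[str],
) -> pd.DataFrame:
    """Mean normalized expression and expressing-cell fraction per
    (group, gene) — the two dot-plot channels (color and diameter).
    """
    gene_index = {g: i for i, g in enumerate(norm.genes["gene_id"])}
    missing = [g for g in gene_ids if g not in gene_index]
    if missing:
        raise ConfigError(f"gene ids not in gene table: {missing}")
    rows = []
    for group in ("germline", "soma"):
        mask = labeling.labels == group
        if not mask.any():
            raise EmptyResultError(f"group {group!r} is empty")
        for gid in gene_ids:
            i = gene_index[gid]
            nvals = np.asarray(norm.values[i, mask].todense()).ravel()
            cvals = np.asarray(counts.counts[i, mask].todense()).ravel()
            rows.append(
                {
                    "group": group,
                    "gene_id": gid,
                    "mean_norm_expr": float(nvals.mean()),
                    "fraction_expressing": float((cvals > 0).mean()),
                }
            )
    return pd.DataFrame(rows)
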