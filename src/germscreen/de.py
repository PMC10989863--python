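"""Germline-vs-rest differential expression per analysis.

The test is the two-sample Wilcoxon rank-sum (Mann-Whitney U) on
normalized expression, with midranks for ties.  Small problems
(n_in * n_out <= 64 and C(n, n_in) <= 1e5) are solved exactly by
enumerating every assignment of the pooled midranks to the in-group;
larger problems use the normal approximation with tie-corrected variance
and a 0.5 continuity correction.  Multiplicity control is Bonferroni over
the genes tested in the analysis, and the reported significance flag
is one-sided in effect: adjusted p < 0.05 AND lnFC > 0 ("positive genes").

lnFC follows the expm1-mean convention on the natural-log scale with a
pseudocount of 1:

    lnFC = ln( (mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1) )

which, for log-CP10K input, compares pseudocounted mean CP10K abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal, rankdata

from germscreen.errors import ConfigError, EmptyResultError
from germscreen.io_qc import CountMatrix, NormMatrix
from germscreen.labeling import CellLabeling

P_FLOOR = 1e-300  # keeps downstream -log / ranking finite
EXACT_MAX_PRODUCT = 64
EXACT_MAX_ARRANGEMENTS = 100_000


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def _exact_p(ranks: np.ndarray, n_in: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating in-group index subsets.

    All C(n, n_in) assignments of pooled midranks are equally likely under
    the null; p = 2 * min(P(U <= u), P(U >= u)) capped at 1, which reduces
    to the usual symmetric tail doubling when there are no ties.
    """
    n = ranks.size
    lo = hi = 0
    total = 0
    offset = n_in * (n_in + 1) / 2.0
    eps = 1e-9
    for subset in combinations(range(n), n_in):
        u = ranks[list(subset)].sum() - offset
        total += 1
        if u <= u_obs + eps:
            lo += 1
        if u >= u_obs - eps:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_rank_sum(
    x_in: np.ndarray, x_out: np.ndarray, method: str = "auto"
) -> tuple[float, float, float]:
    """Wilcoxon rank-sum test of x_in vs x_out.

    Returns (U, z, p_two_sided).  U is the Mann-Whitney statistic of the
    in-group, computed from midranks.  ``method`` is "auto" (exact when
    enumerable, else normal approximation), "exact", or "approx"; the
    exact-enumeration path reports z = nan.
    """
    if method not in ("auto", "exact", "approx"):
        raise ConfigError(f"unknown method {method!r}")
    x_in = np.asarray(x_in, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    n1, n2 = x_in.size, x_out.size
    if n1 == 0 or n2 == 0:
        raise ConfigError("both groups must be non-empty")

    pooled = np.concatenate([x_in, x_out])
    ranks = rankdata(pooled)
    r_in = ranks[:n1].sum()
    u = r_in - n1 * (n1 + 1) / 2.0

    enumerable = n1 * n2 <= EXACT_MAX_PRODUCT and comb(n1 + n2, n1) <= EXACT_MAX_ARRANGEMENTS
    if method == "exact" and not enumerable:
        raise ConfigError("problem too large for exact enumeration")
    if method == "exact" or (method == "auto" and enumerable):
        return u, float("nan"), _exact_p(ranks, n1, u)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:  # all values identical
        return u, 0.0, 1.0
    diff = u - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * _normal.sf(abs(z)))
    return u, float(z), float(p)


def log_fold_change(norm_in: np.ndarray, norm_out: np.ndarray) -> float:
    """Natural-log fold change between groups of normalized values."""
    norm_in = np.asarray(norm_in, dtype=float)
    norm_out = np.asarray(norm_out, dtype=float)
    return float(
        np.log((np.expm1(norm_in).mean() + 1.0) / (np.expm1(norm_out).mean() + 1.0))
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, p * m) for m tests."""
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"p must lie in [0, 1], got {p}")
    if m < 1:
        raise ConfigError(f"m must be >= 1, got {m}")
    return min(1.0, p * m)


@dataclass
class DEResult:
    """Per-gene differential-expression table for one analysis."""

    analysis_id: str
    table: pd.DataFrame  # gene_id, U, z, p, p_adj, lnfc, n_in, n_out, significant

    def significant_genes(self) -> set[str]:
        return set(self.table.loc[self.table["significant"], "gene_id"])


def de_table(
    norm: NormMatrix,
    counts: CountMatrix,
    labeling: CellLabeling,
    analysis_id: str = "",
) -> DEResult:
    """Test every gene, germline vs all other cells.

    Genes silent in every cell get p = 1 and lnFC = 0.  The Bonferroni
    factor m is the total number of genes tested (all genes in the table).
    Significance = (p_adj < 0.05) AND (lnFC > 0).
    """
    in_mask = labeling.germline_mask
    out_mask = ~in_mask
    n_in, n_out = int(in_mask.sum()), int(out_mask.sum())
    if n_in == 0 or n_out == 0:
        raise EmptyResultError("labeling must contain both germline and soma cells")

    x = np.asarray(norm.values.todense())
    n_genes = x.shape[0]

    # Midranks for all genes at once, then split the rank sums by group.
    ranks = rankdata(x, axis=1)
    r_in = ranks[:, in_mask].sum(axis=1)
    u = r_in - n_in * (n_in + 1) / 2.0

    n = n_in + n_out
    mu = n_in * n_out / 2.0
    tie = np.array([_tie_term(x[g]) for g in range(n_genes)])
    var = n_in * n_out / 12.0 * ((n + 1) - tie / (n * (n - 1)))

    diff = u - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    z = np.where(var > 0, z, 0.0)
    p = np.where(var > 0, np.minimum(1.0, 2.0 * _normal.sf(np.abs(z))), 1.0)
    p = np.maximum(p, P_FLOOR)

    expm1_in = np.expm1(x[:, in_mask]).mean(axis=1)
    expm1_out = np.expm1(x[:, out_mask]).mean(axis=1)
    lnfc = np.log((expm1_in + 1.0) / (expm1_out + 1.0))

    silent = np.asarray((counts.counts > 0).sum(axis=1)).ravel() == 0
    p = np.where(silent, 1.0, p)
    lnfc = np.where(silent, 0.0, lnfc)

    p_adj = np.minimum(1.0, p * n_genes)
    table = pd.DataFrame(
        {
            "gene_id": norm.genes["gene_id"].to_numpy(),
            "U": u,
            "z": z,
            "p": p,
            "p_adj": p_adj,
            "lnfc": lnfc,
            "n_in": n_in,
            "n_out": n_out,
            "significant": (p_adj < 0.05) & (lnfc > 0),
        }
    )
    return DEResult(analysis_id=analysis_id, table=table)
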