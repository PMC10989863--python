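"""GO Biological Process over-representation of the candidate list.

Per term, the over-representation p-value is the hypergeometric upper
tail: drawing n candidates from a background of N genes of which K carry
the term, the probability of seeing k or more term genes among the
candidates.  The tail is summed in log space (log-gamma binomials +
log-sum-exp) for numerical stability.  Term p-values are adjusted with
Benjamini-Hochberg.  Term gene sets are taken as given — no ontology-graph
propagation is performed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from germscreen.errors import ConfigError

logger = logging.getLogger(__name__)


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space.

    k: candidates carrying the term, K: background genes carrying it,
    n: candidates tested, N: background size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ConfigError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ConfigError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    # support: n - i <= N - K
    i = i[(n - i) <= (N - K)]
    if i.size == 0:
        return 0.0
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, np.array([n]))
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_adjust(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if (pvals < 0).any() or (pvals > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return q


def go_overrepresentation(
    candidates: set[str],
    background: set[str],
    annot: dict[str, tuple[str, set[str]]],
    min_term_size: int = 10,
    max_term_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric ORA of candidates against the expressed background.

    ``annot`` maps term id -> (term name, gene id set).  Terms are
    restricted to the background before the size filter; annotated genes
    outside the background are dropped with a logged count.  Output is
    sorted by ascending p and carries a -log10(p) column for plotting.
    """
    candidates = set(candidates)
    background = set(background)
    stray = candidates - background
    if stray:
        raise ConfigError(
            f"{len(stray)} candidate genes missing from background, e.g. "
            f"{sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(candidates)
    rows = []
    n_outside = 0
    for term_id, (term_name, members) in annot.items():
        in_bg = members & background
        n_outside += len(members) - len(in_bg)
        K = len(in_bg)
        if not min_term_size <= K <= max_term_size:
            continue
        k = len(in_bg & candidates)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": hypergeom_upper(k, K, n, N),
            }
        )
    if n_outside:
        logger.info("%d annotated gene memberships fell outside the background", n_outside)
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p"]
    )
    if not table.empty:
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["neg_log10_p"] = -np.log10(np.maximum(table["p"], 1e-300))
        table = table.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        table["q"] = []
        table["neg_log10_p"] = []
    return table


def read_annotation(
    gene_term_path: str | Path, term_name_path: str | Path | None = None
) -> dict[str, tuple[str, set[str]]]:
    """Load a two-column gene<TAB>term file (optional term<TAB>name file)."""
    df = pd.read_csv(gene_term_path, sep="\t", header=None, names=["gene_id", "term_id"])
    names = {}
    if term_name_path is not None:
        nd = pd.read_csv(term_name_path, sep="\t", header=None, names=["term_id", "name"])
        names = dict(zip(nd["term_id"], nd["name"]))
    annot: dict[str, tuple[str, set[str]]] = {}
    for term_id, grp in df.groupby("term_id"):
        annot[str(term_id)] = (names.get(term_id, str(term_id)), set(grp["gene_id"].astype(str)))
    return annot
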