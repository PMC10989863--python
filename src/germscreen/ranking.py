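"""Cross-analysis candidate prioritization.

Per analysis, significant positive genes are ranked by ascending adjusted
p-value (average rank for ties).  Genes significant in *every* analysis
are kept, ordered by mean rank across analyses; ties are broken by mean
lnFC rank (rank 1 = largest lnFC within each analysis), then
alphabetically by gene id.  Untestable gene classes (mitochondrial genes,
CR-designated pseudogenes, various non-coding RNA classes) and ribosomal
structural proteins are culled after aggregation, before the top-N cut, so
the full ranked audit trail survives in the report.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from germscreen.errors import ConfigError, EmptyResultError
from germscreen.de import DEResult

logger = logging.getLogger(__name__)


@dataclass
class AnalysisRanks:
    """Significant-gene ranks for one analysis.

    table columns: gene_id, p_adj, lnfc, rank (ascending p_adj, average
    for ties), lnfc_rank (1 = largest lnFC).
    """

    analysis_id: str
    table: pd.DataFrame

    def gene_set(self) -> set[str]:
        return set(self.table["gene_id"])


def rank_within_analysis(de: DEResult) -> AnalysisRanks:
    """Rank the analysis's significant genes by ascending adjusted p."""
    sig = de.table.loc[de.table["significant"]].copy()
    if sig.empty:
        raise EmptyResultError(f"no significant genes in analysis {de.analysis_id!r}")
    sig["rank"] = rankdata(sig["p_adj"].to_numpy(), method="average")
    sig["lnfc_rank"] = rankdata(-sig["lnfc"].to_numpy(), method="average")
    return AnalysisRanks(
        analysis_id=de.analysis_id,
        table=sig[["gene_id", "p_adj", "lnfc", "rank", "lnfc_rank"]].reset_index(drop=True),
    )


def intersect_analyses(ranks: list[AnalysisRanks]) -> set[str]:
    """Genes significant in every analysis."""
    if not ranks:
        raise ConfigError("need at least one analysis")
    out = ranks[0].gene_set()
    for r in ranks[1:]:
        out &= r.gene_set()
    if not out:
        logger.warning("intersection of significant genes across analyses is empty")
    return out


@dataclass
class AggregateRanking:
    """Ordered candidate table across analyses.

    table columns: gene_id, rank_<analysis> per analysis, mean_rank,
    mean_lnfc_rank, cull_reason (empty string if retained), position
    (1-based over retained genes, NaN for culled ones).
    """

    table: pd.DataFrame
    analysis_ids: list[str]

    def retained(self) -> pd.DataFrame:
        return self.table.loc[self.table["cull_reason"] == ""].reset_index(drop=True)


def aggregate_rank(ranks: list[AnalysisRanks], intersection: set[str]) -> AggregateRanking:
    """Order the intersection by mean rank, tie-break by mean lnFC rank.

    lnFC rank is descending in lnFC (rank 1 = largest).  Remaining ties
    break alphabetically by gene id, so the ordering is total and
    deterministic.
    """
    if not intersection:
        raise EmptyResultError("intersection is empty; nothing to aggregate")
    genes = sorted(intersection)
    cols = {"gene_id": genes}
    per_rank = np.zeros((len(genes), len(ranks)))
    per_lnfc_rank = np.zeros_like(per_rank)
    for j, ar in enumerate(ranks):
        t = ar.table.set_index("gene_id")
        missing = [g for g in genes if g not in t.index]
        if missing:
            raise ConfigError(
                f"genes in intersection missing from analysis {ar.analysis_id!r}: "
                f"{missing[:5]}"
            )
        per_rank[:, j] = t.loc[genes, "rank"].to_numpy()
        per_lnfc_rank[:, j] = t.loc[genes, "lnfc_rank"].to_numpy()
        cols[f"rank_{ar.analysis_id}"] = per_rank[:, j]
    table = pd.DataFrame(cols)
    table["mean_rank"] = per_rank.mean(axis=1)
    table["mean_lnfc_rank"] = per_lnfc_rank.mean(axis=1)
    table = table.sort_values(
        ["mean_rank", "mean_lnfc_rank", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    table["cull_reason"] = ""
    table["position"] = np.arange(1, len(table) + 1, dtype=float)
    return AggregateRanking(table=table, analysis_ids=[r.analysis_id for r in ranks])


@dataclass
class GeneClassRules:
    """Ordered cull rules; first match wins.

    Each rule is (name, class_labels, symbol_regex): a gene is culled if
    its gene_class is in class_labels or its symbol matches the regex.
    """

    rules: list[tuple[str, frozenset[str], re.Pattern]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "GeneClassRules":
        """Load rules from YAML; defaults to the packaged rule file."""
        if path is None:
            text = resources.files("germscreen").joinpath("data/cull_rules.yaml").read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        rules = [
            (
                r["name"],
                frozenset(r.get("classes", [])),
                re.compile(r.get("symbol_regex", r"(?!)")),
            )
            for r in raw["rules"]
        ]
        return cls(rules=rules)

    def cull_reason(self, symbol: str, gene_class: str) -> str:
        """Name of the first matching rule, or '' if the gene is retained."""
        for name, classes, pattern in self.rules:
            if gene_class in classes or pattern.search(symbol):
                return name
        return ""


def cull_genes(
    ranking: AggregateRanking,
    rules: GeneClassRules,
    gene_table: pd.DataFrame,
) -> AggregateRanking:
    """Flag untestable gene classes and renumber the retained genes.

    Culled genes stay in the table with their reason; ``position`` is
    recomputed over retained genes only.
    """
    meta = gene_table.set_index("gene_id")
    table = ranking.table.copy()
    reasons = []
    for gid in table["gene_id"]:
        if gid in meta.index:
            symbol = str(meta.at[gid, "symbol"])
            gene_class = str(meta.at[gid, "gene_class"])
        else:
            symbol, gene_class = gid, ""
        reasons.append(rules.cull_reason(symbol, gene_class))
    table["cull_reason"] = reasons
    retained = table["cull_reason"] == ""
    table["position"] = np.where(retained, retained.cumsum().astype(float), np.nan)
    return AggregateRanking(table=table, analysis_ids=list(ranking.analysis_ids))


def top_n(ranking: AggregateRanking, n: int = 500) -> pd.DataFrame:
    """First min(n, available) retained genes, positions 1..n."""
    if n < 0:
        raise ConfigError("n must be >= 0")
    return ranking.retained().head(n).reset_index(drop=True)
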