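"""Rule-based classification and tallying of the RNAi cytology screen.

Each scored germarium record captures what a human scorer recorded per
ovary: overall ovary development, Orb localization (cyst development and
oocyte specification), synaptonemal-complex state in region 2A and in the
region-3 oocyte, SC aggregates (polycomplexes), and gamma-H2AV double-
strand-break signal in region 2A plus the focus count in the region-3
oocyte.  A line is called defective in a category when at least 50% of its
scored germaria (inclusive at the boundary) show that defect and at least
10 germaria were scored; underdeveloped ovaries dominate every other call,
and developmental defects take precedence over SC/DSB categories because
SC and DSB staging cannot be read reliably in developmentally abnormal
germaria.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from germscreen.errors import ConfigError

ORB_STATES = {"absent", "weak_2A", "too_few_cysts", "no_single_focus", "abnormal_cyst", "normal"}
SC_2A_STATES = {"full_length", "too_few_nuclei", "absent_or_punctate"}
SC_R3_STATES = {"full_length", "fragmented", "absent"}

#: defect categories, in call-precedence order
CATEGORIES = [
    "underdeveloped",
    "developmental",
    "sc_assembly",
    "sc_maintenance",
    "polycomplex",
    "dsb_initiation",
    "dsb_repair",
]

MIN_GERMARIA = 10
DEFECT_FRACTION = 0.5  # "at least 50%", inclusive
DSB_REPAIR_MIN_FOCI = 2  # >= 2 region-3 foci = unrepaired/late breaks


@dataclass
class GermariumScore:
    """One scored germarium (or, for underdeveloped lines, one ovary)."""

    line_id: str
    germarium_id: str
    underdeveloped_ovary: bool = False
    orb_status: str = "normal"
    sc_2A: str = "full_length"
    sc_region3: str = "full_length"
    polycomplex_present: bool = False
    gH2AV_2A_present: bool = True
    gH2AV_region3_foci: int = 0

    def __post_init__(self) -> None:
        if self.orb_status not in ORB_STATES:
            raise ConfigError(f"orb_status: invalid value {self.orb_status!r}")
        if self.sc_2A not in SC_2A_STATES:
            raise ConfigError(f"sc_2A: invalid value {self.sc_2A!r}")
        if self.sc_region3 not in SC_R3_STATES:
            raise ConfigError(f"sc_region3: invalid value {self.sc_region3!r}")
        if self.gH2AV_region3_foci < 0:
            raise ConfigError("gH2AV_region3_foci: must be >= 0")


def classify_germarium(score: GermariumScore) -> dict[str, bool]:
    """Per-category defect flags for one germarium."""
    return {
        "underdeveloped": score.underdeveloped_ovary,
        "developmental": score.orb_status != "normal",
        "sc_assembly": score.sc_2A in ("too_few_nuclei", "absent_or_punctate"),
        "sc_maintenance": score.sc_region3 in ("fragmented", "absent"),
        "polycomplex": score.polycomplex_present,
        "dsb_initiation": not score.gH2AV_2A_present,
        "dsb_repair": score.gH2AV_region3_foci >= DSB_REPAIR_MIN_FOCI,
    }


@dataclass
class LineClassification:
    """Line-level call with the per-category defect fractions behind it."""

    line_id: str
    gene_id: str
    category: str  # one of CATEGORIES, "wild_type", or "insufficient_germaria"
    fractions: dict[str, float]
    n_germaria: int

    @property
    def has_germarium_phenotype(self) -> bool:
        """Developmental/SC/DSB call (the Table-1 'phenotypes in germaria' row)."""
        return self.category not in ("underdeveloped", "wild_type", "insufficient_germaria")


def classify_line(
    scores: list[GermariumScore], gene_id: str = "", strict: bool = False
) -> LineClassification:
    """Classify one RNAi line from its germarium records.

    Underdeveloped ovaries dominate (such lines yield no scorable
    germaria, so no minimum-n applies).  Otherwise a category needs defect
    fraction >= 0.5 over >= 10 germaria; among qualifying categories,
    developmental precedes the SC/DSB ones and the remaining precedence
    follows scoring order (SC assembly, SC maintenance, polycomplex, DSB
    initiation, DSB repair).  With fewer than 10 germaria and defects
    present, the call is withheld ("insufficient_germaria"; an error when
    ``strict``).
    """
    if not scores:
        raise ConfigError("no germarium scores supplied")
    line_ids = {s.line_id for s in scores}
    if len(line_ids) != 1:
        raise ConfigError(f"scores span multiple lines: {sorted(line_ids)}")
    line_id = scores[0].line_id

    flags = [classify_germarium(s) for s in scores]
    n = len(flags)
    fractions = {c: sum(f[c] for f in flags) / n for c in CATEGORIES}

    if any(f["underdeveloped"] for f in flags):
        return LineClassification(line_id, gene_id, "underdeveloped", fractions, n)

    any_defect = any(fractions[c] > 0 for c in CATEGORIES[1:])
    if n < MIN_GERMARIA and any_defect:
        if strict:
            raise ConfigError(
                f"line {line_id!r}: insufficient germaria ({n} < {MIN_GERMARIA}) for a call"
            )
        return LineClassification(line_id, gene_id, "insufficient_germaria", fractions, n)

    for category in CATEGORIES[1:]:
        if fractions[category] >= DEFECT_FRACTION and n >= MIN_GERMARIA:
            return LineClassification(line_id, gene_id, category, fractions, n)
    return LineClassification(line_id, gene_id, "wild_type", fractions, n)


def tally(classifications: list[LineClassification], gene_table: pd.DataFrame) -> dict:
    """Table-1-style summary of line- and gene-level calls.

    Line-level categories {underdeveloped, germaria_phenotype, wild_type}
    partition the lines.  A gene counts in a defect category if at least
    one of its lines does; a gene is wild-type only if every line is.
    Genes with both an underdeveloped line and a germaria-phenotype line
    are tracked as overlap, and CG-designated (uncharacterized) genes get
    their own sub-tallies.
    """
    known = set(gene_table["gene_id"].astype(str))
    for c in classifications:
        if c.gene_id not in known:
            raise ConfigError(f"unknown gene id {c.gene_id!r} for line {c.line_id!r}")

    lines_under = sum(c.category == "underdeveloped" for c in classifications)
    lines_germ = sum(c.has_germarium_phenotype for c in classifications)
    lines_wt = sum(c.category == "wild_type" for c in classifications)

    by_gene: dict[str, list[LineClassification]] = {}
    for c in classifications:
        by_gene.setdefault(c.gene_id, []).append(c)

    genes_under = {g for g, cs in by_gene.items() if any(c.category == "underdeveloped" for c in cs)}
    genes_germ = {g for g, cs in by_gene.items() if any(c.has_germarium_phenotype for c in cs)}
    genes_wt = {g for g, cs in by_gene.items() if all(c.category == "wild_type" for c in cs)}

    symbols = dict(zip(gene_table["gene_id"].astype(str), gene_table["symbol"].astype(str)))
    is_cg = {g for g in by_gene if symbols.get(g, g).startswith("CG")}

    per_category = {cat: sum(c.category == cat for c in classifications) for cat in CATEGORIES}
    return {
        "lines": {
            "underdeveloped": lines_under,
            "germaria_phenotype": lines_germ,
            "wild_type": lines_wt,
            "tested": len(classifications),
        },
        "lines_by_category": per_category,
        "genes": {
            "underdeveloped": len(genes_under),
            "germaria_phenotype": len(genes_germ),
            "wild_type": len(genes_wt),
            "tested": len(by_gene),
            "overlap_underdeveloped_and_germaria": len(genes_under & genes_germ),
        },
        "cg_genes": {
            "tested": len(is_cg),
            "underdeveloped": len(genes_under & is_cg),
            "germaria_phenotype": len(genes_germ & is_cg),
        },
    }


def percent_of_genes(count: int, total: int) -> int:
    """Round(100 * count / total) to the nearest integer, half away from zero."""
    if total <= 0:
        raise ConfigError("total must be > 0")
    x = 100.0 * count / total
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def read_scores(path: str | Path) -> list[GermariumScore]:
    """Load germarium scores from CSV.

    Header: line_id, germarium_id, underdeveloped_ovary, orb_status,
    sc_2A, sc_region3, polycomplex_present, gH2AV_2A_present,
    gH2AV_region3_foci.  Booleans are 'true'/'false' (case-insensitive)
    or 0/1.
    """
    df = pd.read_csv(path, dtype=str).fillna("")

    def to_bool(v: str) -> bool:
        return str(v).strip().lower() in ("true", "1", "yes")

    out = []
    for _, row in df.iterrows():
        out.append(
            GermariumScore(
                line_id=row["line_id"],
                germarium_id=row["germarium_id"],
                underdeveloped_ovary=to_bool(row["underdeveloped_ovary"]),
                orb_status=row["orb_status"] or "normal",
                sc_2A=row["sc_2A"] or "full_length",
                sc_region3=row["sc_region3"] or "full_length",
                polycomplex_present=to_bool(row["polycomplex_present"]),
                gH2AV_2A_present=to_bool(row["gH2AV_2A_present"]),
                gH2AV_region3_foci=int(row["gH2AV_region3_foci"] or 0),
            )
        )
    return out
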