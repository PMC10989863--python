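"""End-to-end orchestration: simulate (optional) -> QC -> label -> DE per
analysis -> rank aggregation -> culling -> top-N -> enrichment (optional).

`run_all` drives the whole chain from a RunConfig and writes per-stage
TSVs plus a JSON manifest recording the configuration, seeds, and stage
outputs.  Every stage is also callable on its own (see the CLI), so
partial reruns are a matter of pointing a stage at the previous stage's
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from germscreen.errors import GermscreenError
from germscreen.io_qc import (
    CountMatrix,
    default_thresholds,
    normalize_cp10k,
    qc_filter,
    read_tenx,
    QCThresholds,
)
from germscreen.labeling import assign_germline, marker_score
from germscreen.de import de_table
from germscreen.ranking import (
    GeneClassRules,
    aggregate_rank,
    cull_genes,
    intersect_analyses,
    rank_within_analysis,
    top_n,
)
from germscreen.enrichment import go_overrepresentation, read_annotation
from germscreen.simulate import SimConfig, synthetic_annotation, simulate_analyses

logger = logging.getLogger(__name__)

DEFAULT_MARKERS = ["vas", "c(3)G", "cona", "corolla"]


@dataclass
class RunConfig:
    """One-file configuration for an end-to-end run."""

    out_dir: Path
    input_dir: Path | None = None  # None => simulate
    sim: SimConfig | None = None
    marker_gene_ids: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    qc_thresholds: dict[str, QCThresholds] = field(default_factory=dict)  # replicate -> thresholds
    auto_qc: bool = True
    cull_rules_path: Path | None = None
    n_top: int = 500
    annotation_path: Path | None = None
    min_term_size: int = 10
    max_term_size: int = 500
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = None
        if raw.get("sim"):
            sim_kwargs = dict(raw["sim"])
            if "marker_gene_ids" in sim_kwargs:
                sim_kwargs["marker_gene_ids"] = tuple(sim_kwargs["marker_gene_ids"])
            sim = SimConfig(**sim_kwargs)
        qc = {
            rep: QCThresholds(**vals) for rep, vals in (raw.get("qc_thresholds") or {}).items()
        }
        return cls(
            out_dir=Path(raw["out_dir"]),
            input_dir=Path(raw["input_dir"]) if raw.get("input_dir") else None,
            sim=sim,
            marker_gene_ids=list(raw.get("marker_gene_ids", DEFAULT_MARKERS)),
            qc_thresholds=qc,
            auto_qc=bool(raw.get("auto_qc", True)),
            cull_rules_path=Path(raw["cull_rules"]) if raw.get("cull_rules") else None,
            n_top=int(raw.get("n_top", 500)),
            annotation_path=Path(raw["annotation"]) if raw.get("annotation") else None,
            seed=int(raw.get("seed", 1)),
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def load_analyses(input_dir: Path) -> dict[str, CountMatrix]:
    """Read <input>/<analysis>/<replicate>/ triplets, pooling replicates."""
    per_analysis: dict[str, CountMatrix] = {}
    for adir in sorted(p for p in input_dir.iterdir() if p.is_dir()):
        mats = []
        for rdir in sorted(p for p in adir.iterdir() if p.is_dir()):
            m = read_tenx(rdir)
            m.cells["replicate_id"] = rdir.name
            m.cells["analysis_id"] = adir.name
            mats.append(m)
        if mats:
            per_analysis[adir.name] = CountMatrix.concat_cells(mats)
    if not per_analysis:
        raise GermscreenError(f"no analysis directories found under {input_dir}")
    return per_analysis


def _qc_analysis(matrix: CountMatrix, config: RunConfig) -> CountMatrix:
    """QC each replicate with its own thresholds, then re-pool."""
    pieces = []
    for rid, sub in _split_by_replicate(matrix):
        thr = config.qc_thresholds.get(rid)
        if thr is None:
            thr = default_thresholds(sub) if config.auto_qc else QCThresholds()
        pieces.append(qc_filter(sub, thr))
    return CountMatrix.concat_cells(pieces)


def _split_by_replicate(matrix: CountMatrix):
    for rid in pd.unique(matrix.cells["replicate_id"]):
        mask = (matrix.cells["replicate_id"] == rid).to_numpy()
        yield rid, matrix.subset_cells(mask)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from germscreen import __version__

    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    truth = None
    stage = "input"
    try:
        if config.input_dir is not None:
            analyses = load_analyses(Path(config.input_dir))
            manifest["stages"]["input"] = {"dir": str(config.input_dir)}
        else:
            sim = config.sim or SimConfig(seed=config.seed)
            analyses, truth = simulate_analyses(sim)
            manifest["stages"]["simulate"] = {
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(sim).items()
                }
            }

        stage = "qc"
        qc_report = []
        for aid in list(analyses):
            before = analyses[aid].n_cells
            analyses[aid] = _qc_analysis(analyses[aid], config)
            qc_report.append(
                {"analysis_id": aid, "cells_in": before, "cells_out": analyses[aid].n_cells}
            )
        pd.DataFrame(qc_report).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        manifest["stages"]["qc"] = {"report": "qc_report.tsv", "analyses": qc_report}

        stage = "label"
        labelings = {}
        norms = {}
        label_rows = []
        for aid, matrix in analyses.items():
            norm = normalize_cp10k(matrix)
            scores = marker_score(norm, config.marker_gene_ids)
            labeling = assign_germline(scores)
            norms[aid], labelings[aid] = norm, labeling
            for bc, lab, sc in zip(matrix.cells["barcode"], labeling.labels, scores):
                label_rows.append(
                    {"analysis_id": aid, "barcode": bc, "label": lab, "marker_score": sc}
                )
        pd.DataFrame(label_rows).to_csv(out / "labels.tsv", sep="\t", index=False)
        manifest["stages"]["label"] = {
            "file": "labels.tsv",
            "markers": config.marker_gene_ids,
            "n_germline": {
                aid: int(lab.germline_mask.sum()) for aid, lab in labelings.items()
            },
        }

        stage = "de"
        de_results = []
        de_files = []
        for aid, matrix in analyses.items():
            de = de_table(norms[aid], matrix, labelings[aid], analysis_id=aid)
            fname = f"de_{aid}.tsv"
            de.table.to_csv(out / fname, sep="\t", index=False)
            de_results.append(de)
            de_files.append(fname)
        manifest["stages"]["de"] = {"files": de_files}

        stage = "rank"
        ranks = [rank_within_analysis(de) for de in de_results]
        intersection = intersect_analyses(ranks)
        agg = aggregate_rank(ranks, intersection)
        rules = GeneClassRules.from_yaml(config.cull_rules_path)
        gene_table = next(iter(analyses.values())).genes
        agg = cull_genes(agg, rules, gene_table)
        agg.table.to_csv(out / "ranking_full.tsv", sep="\t", index=False)
        top = top_n(agg, config.n_top)
        top.to_csv(out / "top_candidates.tsv", sep="\t", index=False)
        manifest["stages"]["rank"] = {
            "full": "ranking_full.tsv",
            "top": "top_candidates.tsv",
            "n_intersection": len(intersection),
            "n_culled": int((agg.table["cull_reason"] != "").sum()),
            "n_top": len(top),
        }

        stage = "enrich"
        annot = None
        if config.annotation_path is not None:
            annot = read_annotation(config.annotation_path)
        elif truth is not None:
            annot = synthetic_annotation(truth.genes, seed=config.seed)
        if annot is not None:
            # background = all expressed genes (detected in >= 1 cell, any analysis)
            expressed: set[str] = set()
            for matrix in analyses.values():
                det = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
                expressed |= set(matrix.genes.loc[det > 0, "gene_id"])
            candidates = set(top["gene_id"]) & expressed
            enrich = go_overrepresentation(
                candidates,
                expressed,
                annot,
                min_term_size=config.min_term_size,
                max_term_size=config.max_term_size,
            )
            enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrich"] = {
                "file": "enrichment.tsv",
                "n_terms": len(enrich),
            }
    except GermscreenError as exc:
        raise GermscreenError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["outputs"] = {
        p.name: _digest(p) for p in sorted(out.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
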