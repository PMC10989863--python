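"""Shared fixtures: tiny simulated worlds and hand-built toy matrices."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from germscreen.io_qc import CountMatrix
from germscreen.simulate import SimConfig


def make_count_matrix(dense, gene_ids=None, symbols=None, classes=None, mito=None,
                      replicate_id="rep1", analysis_id="analysis1"):
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols or gene_ids,
            "gene_class": classes or ["protein_coding"] * n_genes,
            "is_mito": mito if mito is not None else [False] * n_genes,
        }
    )
    cells = pd.DataFrame(
        {
            "barcode": [f"bc{j}" for j in range(n_cells)],
            "replicate_id": replicate_id,
            "analysis_id": analysis_id,
        }
    )
    return CountMatrix(counts=sp.csr_matrix(dense), genes=genes, cells=cells)


@pytest.fixture
def tiny_config():
    """Small but non-degenerate simulated world (fast to draw)."""
    return SimConfig(
        n_analyses=2,
        replicates_per_analysis=2,
        cells_per_replicate=200,
        n_genes=300,
        n_enriched=25,
        n_mito_genes=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_run():
    """The reference end-to-end scenario, run once per session.

    4 analyses x 3 replicates x 800 cells, 25% germline, 3,000 genes,
    150 enriched genes with lnFC in [ln 2, ln 4], seed 1.  Shared by the
    labeling, DE and aggregation recovery tests to stay inside the time
    budget.
    """
    import germscreen as gs
    from germscreen.ranking import GeneClassRules
    from germscreen.simulate import simulate_analyses

    cfg = SimConfig(seed=1)
    analyses, truth = simulate_analyses(cfg)
    tcells = truth.cells.set_index("barcode")
    labelings, des, accs = {}, [], {}
    for aid, m in analyses.items():
        norm = gs.normalize_cp10k(m)
        scores = gs.marker_score(norm, list(cfg.marker_gene_ids))
        lab = gs.assign_germline(scores)
        lineage = tcells.loc[m.cells["barcode"], "lineage"].to_numpy()
        accs[aid] = ((lineage == "germline") == lab.germline_mask).mean()
        labelings[aid] = lab
        des.append(gs.de_table(norm, m, lab, analysis_id=aid))
    ranks = [gs.rank_within_analysis(d) for d in des]
    agg = gs.aggregate_rank(ranks, gs.intersect_analyses(ranks))
    agg = gs.cull_genes(agg, GeneClassRules.from_yaml(), analyses["analysis1"].genes)
    top = gs.top_n(agg, 500)
    return {
        "config": cfg,
        "analyses": analyses,
        "truth": truth,
        "labelings": labelings,
        "accuracy": accs,
        "de": des,
        "aggregate": agg,
        "top": top,
    }
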