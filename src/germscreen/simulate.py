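"""Synthetic multi-analysis ovary scRNA-seq count data with known truth.

The generator emulates post-alignment 10x count matrices from several
"analyses" (datasets), each with several replicates.  Every replicate
contains a minority germline population and a majority somatic population.
Counts are negative-binomial with Var = mu + mu^2/theta.  A configured set
of genes is truly germline-enriched: in germline cells their NB mean is
base_mean * exp(lnFC).  The four marker genes (vasa and the three
synaptonemal-complex genes) are simulated as the strongest enriched genes —
top-of-range fold change at the top baseline abundance — so that marker
rank recovery is a meaningful end-to-end check.  Gene-level properties
(baselines, fold changes, class labels) are drawn once from the master seed
and shared by all replicates; only the cell-level sampling differs, via a
per-replicate seed derived with a stable CRC32 hash.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from germscreen.errors import ConfigError
from germscreen.io_qc import CountMatrix

DEFAULT_MARKERS = ("vas", "c(3)G", "cona", "corolla")

#: culled-class decoys cycled over the tagged genes: (symbol prefix, gene class)
_CULLED_CLASSES = [
    ("CR", "pseudogene"),
    ("RpL", "ribosomal_protein"),
    ("RpS", "ribosomal_protein"),
    ("asRNA:sim", "asRNA"),
    ("snoRNA:sim", "snoRNA"),
    ("lncRNA:sim", "lncRNA"),
    ("snRNA:sim", "snRNA"),
    ("sisRNA:sim", "sisRNA"),
]


@dataclass
class SimConfig:
    """Parameters of the simulated world.

    Defaults describe the reference scenario used throughout the test
    suite: 4 analyses x 3 replicates x 800 cells, 25% germline, 3,000
    genes of which 150 are germline-enriched with natural-log fold changes
    between ln 2 and ln 4.
    """

    n_analyses: int = 4
    replicates_per_analysis: int = 3
    cells_per_replicate: int = 800
    germline_fraction: float = 0.25
    n_genes: int = 3000
    marker_gene_ids: tuple[str, ...] = DEFAULT_MARKERS
    n_enriched: int = 150
    lnfc_low: float = float(np.log(2.0))
    lnfc_high: float = float(np.log(4.0))
    base_mean_low: float = 0.1
    base_mean_high: float = 10.0
    nb_dispersion: float = 2.0
    n_mito_genes: int = 13
    mito_mean: float = 20.0
    culled_class_fraction: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "n_analyses",
            "replicates_per_analysis",
            "cells_per_replicate",
            "n_genes",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 < self.germline_fraction < 1.0:
            raise ConfigError("germline_fraction must lie strictly in (0, 1)")
        if len(self.marker_gene_ids) != 4:
            raise ConfigError("marker_gene_ids must list exactly 4 gene ids")
        if self.n_enriched < 0:
            raise ConfigError("n_enriched must be >= 0")
        if self.n_enriched + 4 + self.n_mito_genes > self.n_genes:
            raise ConfigError("n_enriched + 4 markers + n_mito_genes exceeds n_genes")
        for name in ("base_mean_low", "base_mean_high", "nb_dispersion", "mito_mean"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.lnfc_low > self.lnfc_high:
            raise ConfigError("lnfc_low exceeds lnfc_high")
        if not 0.0 <= self.culled_class_fraction < 1.0:
            raise ConfigError("culled_class_fraction must lie in [0, 1)")

    @property
    def analysis_ids(self) -> list[str]:
        return [f"analysis{i + 1}" for i in range(self.n_analyses)]

    @property
    def replicate_ids(self) -> list[str]:
        return [f"rep{i + 1}" for i in range(self.replicates_per_analysis)]


@dataclass
class TruthTable:
    """Simulation ground truth.

    genes: gene_id, is_marker, is_enriched, is_mito, is_culled_class,
    true_lnfc (0 for non-enriched).  cells: barcode, lineage
    (germline | soma).
    """

    genes: pd.DataFrame
    cells: pd.DataFrame


def replicate_seed(seed: int, analysis_id: str, replicate_id: str) -> int:
    """Stable per-replicate seed: master seed + CRC32 of the ids."""
    crc = zlib.crc32(f"{analysis_id}|{replicate_id}".encode()) & 0x7FFFFFFF
    return (seed + crc) % (2**31)


def gene_truth(config: SimConfig) -> pd.DataFrame:
    """Gene table plus truth columns, drawn once from the master seed.

    Markers sit at the top of both the abundance and fold-change ranges;
    enriched genes get log-uniform baselines and uniform lnFC in the
    configured band; mitochondrial genes are flat at mito_mean; a fraction
    of the remaining genes carries culled-class symbols/classes.
    """
    rng = np.random.default_rng([config.seed, 0x9E3779B9 % (2**31)])
    n = config.n_genes
    ids = np.array([f"CG{10000 + i}" for i in range(n)], dtype=object)
    classes = np.full(n, "protein_coding", dtype=object)
    is_mito = np.zeros(n, dtype=bool)
    is_marker = np.zeros(n, dtype=bool)
    is_enriched = np.zeros(n, dtype=bool)
    is_culled = np.zeros(n, dtype=bool)
    lnfc = np.zeros(n, dtype=float)

    base_mean = np.exp(
        rng.uniform(np.log(config.base_mean_low), np.log(config.base_mean_high), size=n)
    )

    # Lay out marker / enriched / mito roles over a shuffled index so role
    # and matrix position are uncorrelated.
    order = rng.permutation(n)
    markers = order[:4]
    enriched = order[4 : 4 + config.n_enriched]
    mito = order[4 + config.n_enriched : 4 + config.n_enriched + config.n_mito_genes]

    ids[markers] = list(config.marker_gene_ids)
    is_marker[markers] = True
    is_enriched[markers] = True
    lnfc[markers] = config.lnfc_high
    base_mean[markers] = config.base_mean_high

    is_enriched[enriched] = True
    lnfc[enriched] = rng.uniform(config.lnfc_low, config.lnfc_high, size=enriched.size)

    ids[mito] = [f"mt:sim{i + 1}" for i in range(mito.size)]
    classes[mito] = "mitochondrial"
    is_mito[mito] = True
    base_mean[mito] = config.mito_mean

    plain = order[4 + config.n_enriched + config.n_mito_genes :]
    n_culled = int(np.floor(config.culled_class_fraction * n))
    culled = plain[:n_culled]
    for j, g in enumerate(culled):
        prefix, cls = _CULLED_CLASSES[j % len(_CULLED_CLASSES)]
        if prefix in ("CR", "RpL", "RpS"):
            ids[g] = f"{prefix}{40000 + j}"
        else:
            ids[g] = f"{prefix}{j + 1}"
        classes[g] = cls
        is_culled[g] = True

    return pd.DataFrame(
        {
            "gene_id": ids,
            "symbol": ids,
            "gene_class": classes,
            "is_mito": is_mito,
            "is_marker": is_marker,
            "is_enriched": is_enriched,
            "is_culled_class": is_culled,
            "true_lnfc": lnfc,
            "base_mean": base_mean,
        }
    )


def simulate_replicate(
    config: SimConfig,
    analysis_id: str,
    replicate_id: str,
    seed: int | None = None,
    genes: pd.DataFrame | None = None,
) -> tuple[CountMatrix, TruthTable]:
    """One replicate of NB counts with germline structure.

    The first floor(germline_fraction * cells_per_replicate) cells are
    germline; enriched genes have mean base_mean * exp(lnFC) there.
    Deterministic given (seed, analysis_id, replicate_id).
    """
    if genes is None:
        genes = gene_truth(config)
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(replicate_seed(master, analysis_id, replicate_id))

    n_cells = config.cells_per_replicate
    n_germ = int(np.floor(config.germline_fraction * n_cells))
    lineage = np.array(["germline"] * n_germ + ["soma"] * (n_cells - n_germ), dtype=object)

    base = genes["base_mean"].to_numpy()
    lnfc = genes["true_lnfc"].to_numpy()
    mu = np.tile(base[:, None], (1, n_cells))
    mu[:, :n_germ] *= np.exp(lnfc)[:, None]

    # Gamma-Poisson mixture == NB with Var = mu + mu^2/theta
    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    barcodes = [f"{analysis_id}-{replicate_id}-cell{i:05d}" for i in range(n_cells)]
    cells = pd.DataFrame(
        {"barcode": barcodes, "replicate_id": replicate_id, "analysis_id": analysis_id}
    )
    matrix = CountMatrix(
        counts=sp.csr_matrix(counts),
        genes=genes[["gene_id", "symbol", "gene_class", "is_mito"]].copy(),
        cells=cells,
    )
    truth = TruthTable(
        genes=genes.drop(columns=["base_mean"]).copy(),
        cells=pd.DataFrame({"barcode": barcodes, "lineage": lineage}),
    )
    return matrix, truth


def simulate_analyses(
    config: SimConfig,
) -> tuple[dict[str, CountMatrix], TruthTable]:
    """All analyses, each with its replicates pooled column-wise.

    Returns a mapping analysis_id -> pooled CountMatrix plus a TruthTable
    whose cell table covers every simulated cell.
    """
    genes = gene_truth(config)
    per_analysis: dict[str, CountMatrix] = {}
    cell_truths = []
    for aid in config.analysis_ids:
        mats = []
        for rid in config.replicate_ids:
            m, t = simulate_replicate(config, aid, rid, genes=genes)
            mats.append(m)
            cell_truths.append(t.cells)
        per_analysis[aid] = CountMatrix.concat_cells(mats)
    truth = TruthTable(
        genes=genes.drop(columns=["base_mean"]).copy(),
        cells=pd.concat(cell_truths, ignore_index=True),
    )
    return per_analysis, truth


def write_tenx_triplet(matrix: CountMatrix, directory: str | Path) -> list[Path]:
    """Write matrix.mtx / features.tsv / barcodes.tsv under ``directory``.

    MTX is coordinate integer general with 1-based indices and genes as
    rows; the triplet round-trips exactly through
    :func:`germscreen.io_qc.read_tenx`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    try:
        p = directory / "matrix.mtx"
        mmwrite(p, matrix.counts.tocoo(), field="integer")
        paths.append(p)
        p = directory / "features.tsv"
        matrix.genes[["gene_id", "symbol", "gene_class", "is_mito"]].to_csv(
            p, sep="\t", header=False, index=False
        )
        paths.append(p)
        p = directory / "barcodes.tsv"
        matrix.cells[["barcode", "replicate_id", "analysis_id"]].to_csv(
            p, sep="\t", header=False, index=False
        )
        paths.append(p)
    except OSError as exc:
        raise OSError(f"failed writing {p}: {exc}") from exc
    return paths


def write_run(config: SimConfig, out_dir: str | Path) -> dict:
    """Simulate every replicate and write 10x triplets plus truth/manifest.

    Layout: <out>/<analysis>/<replicate>/{matrix.mtx,features.tsv,
    barcodes.tsv}, <out>/truth_genes.tsv, <out>/truth_cells.tsv and
    <out>/manifest.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes = gene_truth(config)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
        },
        "seed": config.seed,
        "replicates": [],
    }
    cell_truths = []
    for aid in config.analysis_ids:
        for rid in config.replicate_ids:
            m, t = simulate_replicate(config, aid, rid, genes=genes)
            write_tenx_triplet(m, out_dir / aid / rid)
            cell_truths.append(t.cells)
            manifest["replicates"].append(
                {
                    "analysis_id": aid,
                    "replicate_id": rid,
                    "seed": replicate_seed(config.seed, aid, rid),
                    "n_cells": m.n_cells,
                }
            )
    truth_genes = genes.drop(columns=["base_mean"])
    truth_genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
    pd.concat(cell_truths, ignore_index=True).to_csv(
        out_dir / "truth_cells.tsv", sep="\t", index=False
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def synthetic_annotation(
    truth_genes: pd.DataFrame,
    n_terms: int = 30,
    term_size_low: int = 15,
    term_size_high: int = 120,
    seed: int = 0,
) -> dict[str, tuple[str, set[str]]]:
    """Toy gene->GO map over the simulated universe.

    Term GO:SYN0000 collects the truly enriched genes (a "germline
    program" term that a correct candidate list should flag); the rest are
    random draws from the whole universe.
    """
    rng = np.random.default_rng([seed, 0x60A]) if seed is not None else np.random.default_rng()
    universe = truth_genes["gene_id"].to_numpy()
    annot: dict[str, tuple[str, set[str]]] = {
        "GO:SYN0000": (
            "germline program (simulated)",
            set(truth_genes.loc[truth_genes["is_enriched"], "gene_id"]),
        )
    }
    for i in range(1, n_terms + 1):
        size = int(rng.integers(term_size_low, term_size_high + 1))
        members = rng.choice(universe, size=size, replace=False)
        annot[f"GO:SYN{i:04d}"] = (f"simulated term {i}", set(members))
    return annot
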