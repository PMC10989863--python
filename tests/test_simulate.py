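"""Simulator contracts: config validation, determinism, NB moments, and
exact 10x-triplet round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from germscreen.errors import ConfigError
from germscreen.io_qc import read_tenx
from germscreen.simulate import (
    SimConfig,
    gene_truth,
    replicate_seed,
    simulate_replicate,
    write_run,
    write_tenx_triplet,
)

from conftest import make_count_matrix


@pytest.mark.parametrize(
    "kwargs",
    [
        {"germline_fraction": 0.0},
        {"germline_fraction": 1.0},
        {"n_genes": 10, "n_enriched": 20},
        {"nb_dispersion": 0.0},
        {"lnfc_low": 1.0, "lnfc_high": 0.5},
        {"marker_gene_ids": ("vas", "cona")},
        {"cells_per_replicate": 0},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigError):
        SimConfig(**kwargs)


def test_germline_count_is_floor_of_fraction():
    cfg = SimConfig(
        n_analyses=1, replicates_per_analysis=1, cells_per_replicate=800,
        germline_fraction=0.25, n_genes=100, n_enriched=5, n_mito_genes=2, seed=3,
    )
    _, truth = simulate_replicate(cfg, "a", "r")
    assert (truth.cells["lineage"] == "germline").sum() == 200


def test_truth_table_structure(tiny_config):
    _, truth = simulate_replicate(tiny_config, "analysis1", "rep1")
    g = truth.genes
    assert g["is_marker"].sum() == 4
    assert (g.loc[g["is_enriched"], "true_lnfc"] > 0).all()
    assert (g.loc[~g["is_enriched"], "true_lnfc"] == 0).all()
    assert set(truth.cells["lineage"]) == {"germline", "soma"}
    assert len(truth.cells) == tiny_config.cells_per_replicate


def test_same_seed_reproduces_counts_exactly(tiny_config):
    m1, _ = simulate_replicate(tiny_config, "analysis1", "rep1")
    m2, _ = simulate_replicate(tiny_config, "analysis1", "rep1")
    assert (m1.counts != m2.counts).nnz == 0
    m3, _ = simulate_replicate(tiny_config, "analysis1", "rep2")
    assert (m1.counts != m3.counts).nnz > 0  # replicates differ


def test_replicate_seed_stable_and_distinct():
    s = replicate_seed(1, "analysis1", "rep1")
    assert s == replicate_seed(1, "analysis1", "rep1")
    assert s != replicate_seed(1, "analysis1", "rep2")
    assert 0 <= s < 2**31


def test_null_config_has_no_group_difference():
    """With no enriched genes and equal base means, germline and soma
    per-gene sample means agree within 4 standard errors for >=99% of genes."""
    cfg = SimConfig(
        n_analyses=1, replicates_per_analysis=1, cells_per_replicate=2000,
        germline_fraction=0.5, n_genes=200, n_enriched=0,
        lnfc_low=0.0, lnfc_high=0.0, base_mean_low=2.0, base_mean_high=2.0,
        n_mito_genes=0, culled_class_fraction=0.0, seed=11,
    )
    m, truth = simulate_replicate(cfg, "a", "r")
    x = np.asarray(m.counts.todense(), dtype=float)
    germ = (truth.cells["lineage"] == "germline").to_numpy()
    d = x[:, germ].mean(axis=1) - x[:, ~germ].mean(axis=1)
    se = np.sqrt(x[:, germ].var(axis=1) / germ.sum() + x[:, ~germ].var(axis=1) / (~germ).sum())
    assert (np.abs(d) < 4 * se).mean() >= 0.99


def test_poisson_limit_variance():
    """At theta = 1e6 the NB degenerates to Poisson: for mu = 5 the sample
    variance over 1000 cells falls inside the chi-square 99.9% interval
    [4.0, 6.0] derived for Var = 5."""
    n, mu = 1000, 5.0
    # chi-square interval oracle: Var_hat ~ sigma^2 * chi2(n-1)/(n-1) approx
    lo = mu * chi2.ppf(0.0005, n - 1) / (n - 1)
    hi = mu * chi2.ppf(0.9995, n - 1) / (n - 1)
    assert 4.0 < lo and hi < 6.0  # the stated bounds contain the interval
    cfg = SimConfig(
        n_analyses=1, replicates_per_analysis=1, cells_per_replicate=n,
        germline_fraction=0.001, n_genes=10, n_enriched=0,
        lnfc_low=0.0, lnfc_high=0.0, base_mean_low=mu, base_mean_high=mu,
        nb_dispersion=1e6, n_mito_genes=0, culled_class_fraction=0.0, seed=5,
    )
    m, truth = simulate_replicate(cfg, "a", "r")
    soma = (truth.cells["lineage"] == "soma").to_numpy()
    x = np.asarray(m.counts.todense(), dtype=float)[:, soma]
    v = x.var(axis=1, ddof=1)
    assert ((v > 4.0) & (v < 6.0)).all()


def test_soma_moment_recovery():
    """Per-gene soma sample means recover the base means within 5%
    relative error at 5,000 cells for mu >= 1 (20 genes)."""
    cfg = SimConfig(
        n_analyses=1, replicates_per_analysis=1, cells_per_replicate=5000,
        germline_fraction=0.01, n_genes=20, n_enriched=0,
        lnfc_low=0.0, lnfc_high=0.0, base_mean_low=1.0, base_mean_high=10.0,
        n_mito_genes=0, culled_class_fraction=0.0, seed=2,
    )
    genes = gene_truth(cfg)
    m, truth = simulate_replicate(cfg, "a", "r", genes=genes)
    soma = (truth.cells["lineage"] == "soma").to_numpy()
    means = np.asarray(m.counts[:, soma].todense()).mean(axis=1)
    rel = np.abs(means - genes["base_mean"].to_numpy()) / genes["base_mean"].to_numpy()
    assert (rel < 0.05).all()


def test_marker_genes_strongest_enriched(tiny_config):
    g = gene_truth(tiny_config)
    markers = g.loc[g["is_marker"]]
    assert set(markers["gene_id"]) == set(tiny_config.marker_gene_ids)
    assert (markers["true_lnfc"] == tiny_config.lnfc_high).all()


def test_culled_class_tagging(tiny_config):
    g = gene_truth(tiny_config)
    culled = g.loc[g["is_culled_class"]]
    assert len(culled) == int(np.floor(tiny_config.culled_class_fraction * tiny_config.n_genes))
    assert not (culled["is_marker"] | culled["is_enriched"] | culled["is_mito"]).any()
    assert culled["symbol"].str.match(r"^(CR|RpL|RpS|asRNA:|snoRNA:|lncRNA:|snRNA:|sisRNA:)").all()


class TestTripletRoundTrip:
    def test_two_by_two(self, tmp_path):
        m = make_count_matrix([[0, 3], [1, 0]])
        write_tenx_triplet(m, tmp_path)
        body = [
            line for line in (tmp_path / "matrix.mtx").read_text().splitlines()
            if not line.startswith("%")
        ]
        assert len(body) == 1 + 2  # size line + 2 nonzeros
        back = read_tenx(tmp_path)
        assert (back.counts.todense() == m.counts.todense()).all()
        pd.testing.assert_frame_equal(back.genes, m.genes)
        pd.testing.assert_frame_equal(back.cells, m.cells)

    def test_empty_matrix(self, tmp_path):
        m = make_count_matrix(np.zeros((3, 2), dtype=int))
        write_tenx_triplet(m, tmp_path)
        back = read_tenx(tmp_path)
        assert back.counts.nnz == 0
        assert back.counts.shape == (3, 2)

    def test_random_matrix_bit_identical(self, tmp_path):
        rng = np.random.default_rng(7)
        dense = rng.poisson(1.0, size=(50, 100))
        m = make_count_matrix(dense, mito=[i < 3 for i in range(50)])
        write_tenx_triplet(m, tmp_path)
        back = read_tenx(tmp_path)
        assert (back.counts.todense() == dense).all()
        pd.testing.assert_frame_equal(back.genes, m.genes)
        pd.testing.assert_frame_equal(back.cells, m.cells)

    def test_simulated_replicate_round_trips(self, tiny_config, tmp_path):
        m, _ = simulate_replicate(tiny_config, "analysis1", "rep1")
        write_tenx_triplet(m, tmp_path)
        back = read_tenx(tmp_path)
        assert (back.counts != m.counts).nnz == 0
        pd.testing.assert_frame_equal(back.genes, m.genes)


def test_write_run_layout_and_manifest(tiny_config, tmp_path):
    manifest = write_run(tiny_config, tmp_path)
    assert len(manifest["replicates"]) == 4
    for aid in ("analysis1", "analysis2"):
        for rid in ("rep1", "rep2"):
            assert (tmp_path / aid / rid / "matrix.mtx").exists()
    truth_genes = pd.read_csv(tmp_path / "truth_genes.tsv", sep="\t")
    assert truth_genes["is_marker"].sum() == 4
    assert (tmp_path / "manifest.json").exists()
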