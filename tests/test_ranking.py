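"""Per-analysis ranking, intersection, mean-rank aggregation with the
lnFC tie-break, gene-class culling, and top-N selection."""

import numpy as np
import pandas as pd
import pytest

from germscreen.de import DEResult
from germscreen.errors import ConfigError, EmptyResultError
from germscreen.ranking import (
    GeneClassRules,
    aggregate_rank,
    cull_genes,
    intersect_analyses,
    rank_within_analysis,
    top_n,
)


def de_from(genes, p_adj, lnfc, analysis_id="a1", significant=None):
    n = len(genes)
    return DEResult(
        analysis_id=analysis_id,
        table=pd.DataFrame(
            {
                "gene_id": genes,
                "U": 0.0,
                "z": 0.0,
                "p": p_adj,
                "p_adj": p_adj,
                "lnfc": lnfc,
                "n_in": 10,
                "n_out": 20,
                "significant": significant if significant is not None else [True] * n,
            }
        ),
    )


class TestRankWithinAnalysis:
    def test_ascending_p_adj(self):
        r = rank_within_analysis(de_from(["A", "B", "C"], [0.01, 0.001, 0.04], [1, 1, 1]))
        assert dict(zip(r.table["gene_id"], r.table["rank"])) == {"A": 2, "B": 1, "C": 3}

    def test_average_rank_for_ties(self):
        r = rank_within_analysis(de_from(["A", "B", "C"], [0.01, 0.01, 0.04], [1, 1, 1]))
        assert list(r.table["rank"]) == [1.5, 1.5, 3.0]

    def test_single_gene(self):
        r = rank_within_analysis(de_from(["A"], [0.01], [1.0]))
        assert list(r.table["rank"]) == [1.0]

    def test_only_significant_ranked(self):
        r = rank_within_analysis(
            de_from(["A", "B", "C"], [0.01, 0.2, 0.03], [1, 1, 1],
                    significant=[True, False, True])
        )
        assert set(r.table["gene_id"]) == {"A", "C"}

    def test_no_significant_genes_raises(self):
        with pytest.raises(EmptyResultError, match="a1"):
            rank_within_analysis(de_from(["A"], [0.9], [1.0], significant=[False]))


class TestIntersect:
    def _ranks(self, *gene_sets):
        return [
            rank_within_analysis(
                de_from(list(gs), [0.01] * len(gs), [1.0] * len(gs), analysis_id=f"a{i}")
            )
            for i, gs in enumerate(gene_sets)
        ]

    def test_three_way(self):
        assert intersect_analyses(self._ranks("ABC", "BC", "BCD")) == {"B", "C"}

    def test_single_analysis(self):
        assert intersect_analyses(self._ranks("ABC")) == {"A", "B", "C"}

    def test_disjoint_is_empty_not_error(self):
        assert intersect_analyses(self._ranks("AB", "CD")) == set()


class TestAggregate:
    def test_lnfc_rank_breaks_mean_rank_tie(self):
        """A and B both have mean rank 2; A's larger lnFC gives it lnFC
        rank 1 in both analyses, so A precedes B."""
        r1 = rank_within_analysis(
            de_from(["A", "B", "C"], [0.02, 0.01, 0.03], [1.5, 0.5, 0.1], "a1")
        )
        r2 = rank_within_analysis(
            de_from(["A", "B", "C"], [0.02, 0.03, 0.01], [1.5, 0.5, 0.1], "a2")
        )
        agg = aggregate_rank([r1, r2], {"A", "B", "C"})
        assert list(agg.table["gene_id"][:2]) == ["A", "B"]
        a = agg.table.set_index("gene_id")
        assert a.at["A", "mean_rank"] == a.at["B", "mean_rank"] == 2.0
        assert a.at["A", "mean_lnfc_rank"] == 1.0
        assert a.at["B", "mean_lnfc_rank"] == 2.0

    def test_single_analysis_preserves_order(self):
        r = rank_within_analysis(
            de_from(["A", "B", "C"], [0.03, 0.01, 0.02], [1, 2, 3], "a1")
        )
        agg = aggregate_rank([r], {"A", "B", "C"})
        assert list(agg.table["gene_id"]) == ["B", "C", "A"]

    def test_mean_rank_order_vs_hand_computation(self):
        r1 = rank_within_analysis(de_from(["X", "Y", "Z"], [0.001, 0.01, 0.02], [3, 2, 1], "a1"))
        r2 = rank_within_analysis(de_from(["X", "Y", "Z"], [0.03, 0.001, 0.01], [1, 3, 2], "a2"))
        # hand: X ranks (1,3) mean 2; Y (2,1) mean 1.5; Z (3,2) mean 2.5
        agg = aggregate_rank([r1, r2], {"X", "Y", "Z"})
        assert list(agg.table["gene_id"]) == ["Y", "X", "Z"]
        assert list(agg.table["mean_rank"]) == [1.5, 2.0, 2.5]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(20)]
        rs = [
            rank_within_analysis(
                de_from(genes, rng.uniform(0, 0.04, 20), rng.uniform(0.1, 3, 20), f"a{k}")
            )
            for k in range(4)
        ]
        inter = intersect_analyses(rs)
        fwd = aggregate_rank(rs, inter).table["gene_id"]
        rev = aggregate_rank(rs[::-1], inter).table["gene_id"]
        assert list(fwd) == list(rev)

    def test_missing_gene_in_one_analysis_is_internal_error(self):
        r1 = rank_within_analysis(de_from(["A", "B"], [0.01, 0.02], [1, 1], "a1"))
        r2 = rank_within_analysis(de_from(["A"], [0.01], [1.0], "a2"))
        with pytest.raises(ConfigError, match="a2"):
            aggregate_rank([r1, r2], {"A", "B"})

    def test_empty_intersection_raises(self):
        r = rank_within_analysis(de_from(["A"], [0.01], [1.0]))
        with pytest.raises(EmptyResultError):
            aggregate_rank([r], set())


class TestCulling:
    @pytest.fixture
    def rules(self):
        return GeneClassRules.from_yaml()

    @pytest.mark.parametrize(
        "symbol,gene_class,reason",
        [
            ("CR43242", "pseudogene", "CR_pseudogene"),
            ("CR43242", "", "CR_pseudogene"),  # regex fallback without class
            ("mt:CoI", "", "mitochondrial"),
            ("RpL3", "", "ribosomal_structural"),
            ("snoRNA:Psi28S", "snoRNA", "snoRNA"),
            ("lncRNA:roX1", "", "lncRNA"),
            ("CG8142", "protein_coding", ""),
            ("vas", "protein_coding", ""),
        ],
    )
    def test_rule_matching(self, rules, symbol, gene_class, reason):
        assert rules.cull_reason(symbol, gene_class) == reason

    def test_cull_flags_and_renumbering(self, rules):
        r = rank_within_analysis(
            de_from(["CG1", "CR9000", "mt:sim1", "CG2"], [0.001, 0.002, 0.003, 0.004],
                    [1, 1, 1, 1])
        )
        agg = aggregate_rank([r], {"CG1", "CR9000", "mt:sim1", "CG2"})
        gene_table = pd.DataFrame(
            {
                "gene_id": ["CG1", "CR9000", "mt:sim1", "CG2"],
                "symbol": ["CG1", "CR9000", "mt:sim1", "CG2"],
                "gene_class": ["protein_coding", "pseudogene", "mitochondrial", "protein_coding"],
                "is_mito": [False, False, True, False],
            }
        )
        culled = cull_genes(agg, rules, gene_table)
        t = culled.table.set_index("gene_id")
        assert t.at["CR9000", "cull_reason"] == "CR_pseudogene"
        assert t.at["mt:sim1", "cull_reason"] == "mitochondrial"
        retained = culled.retained()
        assert list(retained["gene_id"]) == ["CG1", "CG2"]
        assert list(retained["position"]) == [1.0, 2.0]


class TestTopN:
    def _ranking(self, n):
        genes = [f"g{i:03d}" for i in range(n)]
        r = rank_within_analysis(
            de_from(genes, np.linspace(1e-6, 0.04, n), np.ones(n))
        )
        agg = aggregate_rank([r], set(genes))
        agg.table["cull_reason"] = ""
        return agg

    def test_short_list_returned_whole(self):
        assert len(top_n(self._ranking(3), 500)) == 3

    def test_n_zero_empty(self):
        assert len(top_n(self._ranking(3), 0)) == 0

    def test_truncation(self):
        agg = self._ranking(600)
        top = top_n(agg, 500)
        assert len(top) == 500
        tail = set(agg.table["gene_id"][500:])
        assert not (set(top["gene_id"]) & tail)


def test_ranking_deterministic_byte_identical(tmp_path):
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(50)]
    rs = [
        rank_within_analysis(
            de_from(genes, rng.uniform(0, 0.04, 50).round(3), rng.uniform(0, 2, 50), f"a{k}")
        )
        for k in range(3)
    ]
    outs = []
    for trial in range(2):
        agg = aggregate_rank(rs, intersect_analyses(rs))
        path = tmp_path / f"rank{trial}.tsv"
        agg.table.to_csv(path, sep="\t", index=False)
        outs.append(path.read_bytes())
    assert outs[0] == outs[1]
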