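# germscreen

Marker-anchored candidate-gene prioritization for *Drosophila* ovary
single-cell RNA-seq, plus rule-based tallying of a downstream RNAi
cytology screen.

## The problem

Early oogenesis in the fly germarium — 16-cell cyst formation, meiotic
entry, synaptonemal complex (SC) assembly and maintenance, double-strand
break (DSB) induction and repair, oocyte specification — is driven by
genes expressed in a small germline population that is heavily
outnumbered by somatic cells in whole-ovary dissociations.  A productive
way to nominate new players is co-expression: find the genes that are
consistently and specifically elevated in the cells expressing the
germline marker *vasa* and the SC central-region genes *c(3)G*, *cona*
and *corolla*, across several independent datasets, and screen the top of
that list with germline RNAi.

`germscreen` implements that prioritization as a tested, reusable
pipeline, and ships a synthetic-data generator with known ground truth so
the whole method can be exercised and validated without any downloads.

## The method

For each analysis (dataset) with its replicates pooled:

1. **QC** — keep cells whose genes-detected count lies in a per-replicate
   window and whose mitochondrial UMI fraction is below a cap
   (defaults: median ± 3 MAD of log1p genes-detected; mito ≤ 0.2).
2. **Normalization** — log-CP10K: `x = ln(1 + 1e4 · c / total)`.
3. **Germline labeling** — per-cell marker score = mean normalized
   expression of the 4 markers; cells split germline/soma at the Otsu
   threshold (exhaustive between-class-variance search over observed
   scores).
4. **Differential expression** — per gene, germline vs all other cells,
   two-sided Wilcoxon rank-sum with midranks, tie-corrected variance and
   continuity correction (exact enumeration for small groups); Bonferroni
   adjustment over the genes tested; "positive genes" = adjusted
   p < 0.05 **and** lnFC > 0, with
   `lnFC = ln[(mean(expm1 x_in)+1) / (mean(expm1 x_out)+1)]`.
5. **Aggregation** — rank significant genes per analysis by ascending
   adjusted p (average rank for ties); keep only genes significant in
   *every* analysis; order by mean rank, break ties by mean lnFC rank
   (rank 1 = largest lnFC), then gene id.
6. **Culling and top-N** — remove gene classes untestable by RNAi
   (mitochondrial, CR-designated pseudogenes, asRNA/hpRNA/snRNA/snRNP/
   snmRNA/snoRNA/lncRNA/sisRNA/pre-rRNA) and ribosomal structural
   proteins; take the top 500 as candidates.
7. **Enrichment** — hypergeometric GO Biological Process
   over-representation of the candidates against all expressed genes,
   with Benjamini–Hochberg control.

A separate module (`germscreen.screen`) encodes the phenotype rules of
the downstream RNAi screen: per-germarium defect flags (SC assembly /
maintenance, polycomplexes, DSB initiation / repair with the ≥ 2
γH2AV-foci region-3 rule, Orb-based developmental states), line calls at
the inclusive ≥ 50% defect fraction over ≥ 10 germaria, and
Table-style line/gene tallies.

## Worked example

```python
from germscreen.pipeline import RunConfig, run_all
from germscreen.simulate import SimConfig

manifest = run_all(RunConfig(out_dir="out", sim=SimConfig(seed=1), seed=1))
print(manifest["stages"]["rank"])
```

On the reference synthetic scenario (4 analyses × 3 replicates × 800
cells, 25% germline, 3,000 genes, 150 truly enriched genes with lnFC in
[ln 2, ln 4], seed 1) this prints

```
{'full': 'ranking_full.tsv', 'top': 'top_candidates.tsv',
 'n_intersection': 144, 'n_culled': 0, 'n_top': 144}
```

meaning 144 genes were Bonferroni-significant positive genes in all four
analyses (out of 154 truly enriched, the rest being too weakly expressed
to clear Bonferroni everywhere), none of them belonged to a culled class,
and all survive into the candidate list.  The four marker genes take
aggregate positions 1–4 (`vas` 1, `cona` 2, `c(3)G` 3, `corolla` 4):
they were simulated as the strongest enriched genes, and the ranking
recovers that.  `out/enrichment.tsv` flags the simulated "germline
program" annotation term as the most enriched.

The same pipeline runs stage-by-stage from the shell:

```bash
germscreen simulate --out data --seed 1
germscreen label --in data/analysis1/rep1 --markers 'vas,cona,corolla,c(3)G' \
    --out labels.tsv
germscreen run --config run.yaml
germscreen screen-tally --scores scores.csv --genes genes.tsv \
    --line-genes line_genes.tsv --out tally/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch: the full
prioritization pipeline on the reference synthetic scenario (seeded by
`--seed`) and the screen-tally rule engine on a 526-line fixture, then
writes the results JSON to `--out`.  Progress summaries go to stderr.

## Layout

| module | contents |
| --- | --- |
| `germscreen.simulate` | `SimConfig`, NB count simulator, 10x-triplet writer, truth tables |
| `germscreen.io_qc` | `CountMatrix`/`NormMatrix`, triplet reader, QC filters, log-CP10K |
| `germscreen.labeling` | marker score, Otsu germline assignment, dot-plot statistics |
| `germscreen.de` | Wilcoxon rank-sum (exact + asymptotic), lnFC, Bonferroni, DE tables |
| `germscreen.ranking` | per-analysis ranks, intersection, mean-rank aggregation, culling, top-N |
| `germscreen.enrichment` | hypergeometric upper tail, BH, over-representation tables |
| `germscreen.screen` | germarium/line phenotype rule engine and tallies |
| `germscreen.pipeline` / `germscreen.cli` | end-to-end orchestration, YAML config, `germscreen` CLI |

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
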