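# Methods

## Scope and design

`germscreen` reimplements, at desk scale, a marker-anchored
candidate-gene prioritization for ovary single-cell RNA-seq and the rule
engine of the downstream RNAi screen.  Two upstream stages of the
original workflow are deliberately replaced by simpler stand-ins, because
the downstream statistics depend only on properties both share:

* **Normalization.**  Regularized NB regression (sctransform-style) is
  replaced by log-CP10K, `x = ln(1 + 1e4 c / total)`.  The DE test is
  rank-based and lnFC compares group means of `expm1(x)`, so any monotone
  per-cell normalization yields the same test decisions and the same sign
  of enrichment.
* **Clustering.**  Graph clustering followed by marker-based cluster
  labeling is replaced by direct per-cell marker-score thresholding
  (Otsu).  The aggregation pipeline needs only a germline/soma partition,
  and the marker criterion *is* the labeling rule; externally computed
  partitions can be injected via `CellLabeling.from_labels`.

Dataset integration is likewise replaced by per-analysis pooling of
replicates: the cross-dataset robustness the original work obtained from
integration is carried here by the all-analyses intersection and
mean-rank aggregation, which are implemented faithfully.

## The count model

Counts are negative binomial in the mean/dispersion parameterization
`Var = μ + μ²/θ`, drawn as a gamma–Poisson mixture.  One dispersion
θ applies to all genes (default θ = 2, a typical UMI-level
overdispersion; θ → ∞ recovers Poisson and is tested against a
chi-square variance interval).

Gene-level structure is drawn once per master seed and shared by every
replicate and analysis; cell-level sampling uses a per-replicate seed
`seed + crc32("analysis|replicate") mod 2³¹`, so replicates differ but
every run is reproducible and any single replicate can be regenerated in
isolation.

Defaults of the reference scenario (all configurable via `SimConfig`):

| parameter | default | rationale |
| --- | --- | --- |
| analyses × replicates × cells | 4 × 3 × 800 | multi-dataset, multi-replicate shape of the real analyses |
| germline fraction | 0.25 | germline is the minority population; `floor(fraction · cells)` cells, deterministic |
| genes | 3,000 | desk-scale transcriptome |
| enriched genes | 150 | truly germline-elevated genes, lnFC ~ U[ln 2, ln 4] |
| baseline means | log-uniform [0.1, 10] | top of range ≈ 0.25% of a cell's UMIs, the abundance of vasa-class transcripts |
| markers | lnFC = ln 4 at baseline 10 | simulated as the strongest enriched genes so rank recovery is meaningful |
| dispersion θ | 2 | UMI overdispersion |
| mito genes | 13 at mean 20 | ≈ 6% mitochondrial UMI load in a healthy cell |
| culled-class genes | 5% of genes | symbols/classes (CR…, Rp[LS]…, snoRNA:… etc.) that exercise the culling stage |

What the generator does **not** emulate: ambient RNA, doublets, batch
effects beyond sampling noise, per-gene dispersions, dropout beyond NB
zeros, and any correlation structure between genes.  A green recovery
test therefore establishes that the pipeline's inference machinery is
correct under its own model assumptions — not that the thresholds are
robust to artifacts of real dissociations.

## Statistical components

**Wilcoxon rank-sum.**  Midranks throughout.  When
`n_in · n_out ≤ 64` and `C(n, n_in) ≤ 1e5`, the two-sided p is exact:
all assignments of the pooled midranks to the in-group are enumerated and
`p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))` — valid under ties, and equal to
symmetric tail doubling without them.  Otherwise the normal approximation
with tie-corrected variance
`σ² = n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))]` and a 0.5 continuity
correction is used (numerically identical to the standard asymptotic
Mann–Whitney p).  p-values are floored at 1e-300 so downstream ranking
stays finite.

A measured property worth knowing: for tie-free groups with
3 ≤ n₁, n₂ ≤ 8, the two-sided asymptotic p deviates from the exact p by
up to 0.0375 (worst at n₁ = n₂ = 3); one-sided deviations stay below
0.019.  This is a property of the approximation itself, not of this
implementation — the exact path covers that entire size range in
production, so the approximation is only ever used where it is accurate.

**lnFC.**  `ln[(mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)]` on the
natural-log scale — the expm1-mean convention with pseudocount 1, i.e. a
ratio of pseudocounted mean CP10K abundances.  Antisymmetric under group
swap.

**Multiplicity.**  DE uses Bonferroni with m = number of genes tested in
the analysis (no detection pre-filter is applied by default; the original
tooling may have pre-filtered, which is noted as unknowable).  The
enrichment table uses Benjamini–Hochberg (step-up with monotonicity
enforcement, via statsmodels) — the original publication names the ORA
tool but not its multiplicity method; BH with term-size bounds [10, 500]
is the tool-family convention and all three are configurable.

**Hypergeometric upper tail.**  `P(X ≥ k)` summed in log space
(log-gamma binomials + log-sum-exp); exactness is checked against integer
combinatorics for every configuration with N ≤ 30.  Term sets are used
as given — no ontology-graph (true-path) propagation is performed, so
results depend on the annotation release supplied.

**Otsu thresholding.**  Exhaustive search over observed unique scores for
the cut maximizing between-class variance; cells strictly above the
threshold are germline (ties at the threshold go to soma, for
determinism).  Degenerate (constant) score vectors and thresholds that
empty a class raise instead of guessing.

Measured on the reference scenario (seed 1): Otsu labeling accuracy
against the simulated truth is 0.93–0.95 per analysis, while the
oracle-best threshold on the same scores reaches only ≈ 0.95–0.96.
With markers elevated 4-fold at θ = 2 the germline and soma score
distributions genuinely overlap; the labeling-accuracy regression test
is set at 0.90 accordingly.  Label contamination at this level does not
disturb the end-to-end outcome: all four markers still aggregate to
positions 1–4 and every sufficiently expressed enriched gene clears
Bonferroni in all analyses.

## Aggregation conventions

Within an analysis, only significant positive genes are ranked
(ascending adjusted p, average rank for ties).  Cross-analysis ordering:
mean rank, then mean lnFC rank (computed descending in lnFC, so rank 1 is
the strongest enrichment), then gene id — a total, deterministic order.
Culling happens after aggregation and before the top-N cut, preserving
the full ranked audit trail with per-gene cull reasons; rules are ordered
(first match wins) and matched on gene-class label or symbol regex, with
the default rule file shipped at `germscreen/data/cull_rules.yaml`.
Markers are not exempt from ranking or culling — they compete normally.

## Screen rule engine

Per germarium, defect flags follow the scoring scheme: developmental =
any non-normal Orb state; SC assembly = no full-length SC (or too few
nuclei with it) in region 2A; SC maintenance = fragmented/absent SC in
the region-3 oocyte; polycomplex = SC aggregates; DSB initiation = no
γH2AV in region 2A; DSB repair = **≥ 2** γH2AV foci in the region-3
oocyte.  Line calls require an inclusive ≥ 50% defect fraction over
≥ 10 germaria; lines with any underdeveloped ovary are called
underdeveloped outright (such ovaries yield no scorable germaria, so no
minimum-n applies), and developmental calls take precedence over SC/DSB
calls because staging cannot be read reliably in developmentally abnormal
germaria.  With fewer than 10 germaria and defects present the call is
withheld as `insufficient_germaria`.

Gene-level tallies roll up as "at least one line": a gene is wild-type
only if all of its lines are, and genes with both an underdeveloped line
and a germaria-phenotype line are reported as an explicit overlap count
rather than forced into one bucket.  Percentages round half away from
zero.

## Numerical and degenerate-input choices

* Genes silent in every cell get p = 1, lnFC = 0, never significant.
* Genes are never removed by QC; an all-cells-removed QC result is an
  error naming the replicate, as is a zero-total cell reaching
  normalization.
* Mito fraction of a zero-total cell is reported as 0 with a warning.
* MTX round-trips are exact (coordinate integer format, 1-based indices,
  genes as rows).
* End-to-end reruns with the same seed are byte-identical.

## Known limitations

* One global NB dispersion; no gene-level mean–variance trend.
* The intersect-then-rank procedure is faithful, but the synthetic world
  cannot reproduce the published candidate list itself — that would
  require the original raw sequencing runs, alignment, and the
  replicate-specific QC cutoffs published only in supplementary form.
* Otsu on a 4-gene score assumes an (approximately) bimodal score
  distribution; datasets where the germline is vanishingly rare or
  markers are weakly captured should inject an external clustering.
* The enrichment module treats annotation term sets as flat; without
  ontology propagation, parent terms are only as complete as the input
  annotation makes them.
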