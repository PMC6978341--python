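# famvar

Gene-family expression variance scoring for bulk tumor transcriptomes,
with the analysis pipeline used to connect that score to cancer stem-cell
biology: cohort stratification and association tests, five-year survival
modeling, qPCR enrichment profiling of sorted cell populations, and
single-hit limiting-dilution estimation of cancer-initiating-cell (CIC)
frequency.

## The score

The aldehyde dehydrogenase (ALDH) superfamily has 19 human isoforms, and
high ALDH activity marks cancer-initiating cells. Which isoform carries
that activity varies by tumor. The **ALDH variance score (AVS)**
quantifies, per sample, how concentrated family expression is in a single
isoform. Each sample's RSEM-like expression over the n = 19 isoforms is
converted to percent of the family total,

    x_i = 100 * v_i / sum_j v_j,

and the score is the population variance of the percent vector:

    AVS = sum_i (x_i - mean(x))^2 / n.

AVS = 0 when all isoforms contribute equally and reaches
100² (n−1)/n² ≈ 498.6 (for n = 19) when a single isoform carries all
expression. The score is invariant to library size and to isoform order.
The same machinery applies to any gene family; a 37-member cytokeratin
family ships as a negative-control definition.

Around the score, the package implements: median and top-75%/bottom-25%
cohort stratification; Fisher exact, Spearman and Wilcoxon association
tests (AVS group vs tumor class, AVS vs the mRNAsi stemness index);
five-year Kaplan-Meier/log-rank and per-isoform univariate Cox models;
2^−ΔΔCt fold-enrichment profiles of sorted ALDH-high vs ALDH-low
populations; and the single-hit Poisson model for limiting-dilution
assays, under which a graft of d cells forms a tumor with probability
1 − exp(−d·f), yielding a maximum-likelihood CIC frequency f with a
log-scale Wald CI. A seeded synthetic-cohort generator
(`famvar.simulate`) provides a two-class cohort — one class with a
dominant isoform, one with diverse isoforms — so every stage can be
exercised without external downloads.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on a
synthetic 400-sample cohort (200 per tumor class) and write tables under
`results/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_score_avs.py
python analysis/03_cohort_associations.py
python analysis/04_survival_analysis.py
python analysis/05_qpcr_enrichment.py
python analysis/06_limiting_dilution.py
```

Output from a run (seed 42):

```
median AVS threshold: 47.27
AVS range: 2.57 .. 367.05
Fisher exact: p = 1.94e-119
Spearman AVS~mRNAsi: rho = 0.243, p = 8.94e-07 (n = 400)
combined cohort: log-rank high vs low AVS chi2 = 70.18, p = 5.42e-17
dominant isoform: ALDH1A3 (11.3 +/- 1.3-fold, unique)
published frequencies 1/9205 -> 1/590453: 64.14-fold depletion (> 60-fold)
```

Reading: the dominant-isoform class separates cleanly from the diverse
class at the cohort median AVS (Fisher p), the score correlates
positively with stemness (rho = 0.24), the high-AVS group has better
five-year survival under the generator's protective hazard, the ΔΔCt
profile recovers the engineered 12-fold dominant-isoform enrichment, and
dividing the two published CIC frequencies reproduces the >60-fold
depletion. Fitted frequencies from a simulated four-dose assay land near
their truths (e.g. control 1/8314 vs true 1/9205).

The same operations are scriptable via the `famvar` CLI
(`validate`, `score`, `associate`, `survival`, `ddct`, `lda`, `simulate`).

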