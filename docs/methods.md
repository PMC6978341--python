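# Methods

## The family variance score

For a sample with non-negative expression v over an n-member gene family,
the percent profile is x_i = 100·v_i/Σv and the score is the population
variance AVS = Σ(x_i − mean(x))²/n. Choices that matter:

- **Percent (0–100) scale, not proportions.** On the 0–1 scale the
  maximum for n = 19 would be ≈0.05; observed scores in the hundreds are
  only consistent with percent units. The attainable range is
  [0, 100²(n−1)/n²] = [0, ≈498.6] for n = 19.
- **Divisor n, not n−1.** The score is the population variance of a
  complete composition, not an estimate from a sample of isoforms; n is
  always the full family size, counting members with zero expression,
  and (under the "zero" missing policy) members absent from the matrix.
- **Linear input scale.** Percent-of-family is taken on RSEM-like linear
  values; log-transformed matrices must be back-transformed by the user.
- **Degenerate samples.** A sample whose family total is zero has no
  defined profile; it is excluded from scoring and reported separately
  rather than scored 0 (which would mean "perfectly even").

Stratification rules: the median split assigns samples exactly at the
median to "low" (a deterministic tie-break; either convention is
defensible, this one is fixed and documented). The quartile25 split puts
samples strictly below the 25th percentile (linear-interpolation
definition) in "low", i.e. "high" is the top 75%. All-identical scores
trigger a degenerate all-"low" assignment with a warning instead of an
arbitrary split.

## Association tests

Fisher's exact test is two-sided by the probability-mass rule; the table
orientation (which margin is rows) does not affect p. Spearman uses
average ranks and the t-approximation with n−2 df (adequate at cohort
sizes; an exact permutation p is available for n ≤ 10). Wilcoxon
rank-sum switches from exact enumeration (combined n ≤ 12, tie-free) to
the tie- and continuity-corrected normal approximation. Missing stemness
values are removed pairwise, never imputed. These are scipy.stats
implementations behind a validating surface; the exact conventions are
what the surrounding analyses assume.

## Survival

Follow-up is administratively truncated at 60 months ("five-year"
horizon, with survival times in months) before both Kaplan-Meier and Cox
fitting. KM and Cox use lifelines; Cox ties are handled by the Efron
approximation (better than Breslow for heavily tied month-resolution
data; switchable). The two-group log-rank statistic (O₁−E₁)²/V is
computed directly from per-event-time hypergeometric tables so each
group's observed and expected event counts are reported; it agrees with
lifelines' test and, at β = 0 with a tie-free binary covariate, with the
Cox score test (classical identity, verified in the suite to 1e-6).
Confidence intervals are Wald on the log hazard ratio. The family scan
fits each isoform as a continuous covariate on log2(expression + 1) —
per-unit hazard ratios on raw RSEM scales are nearly meaningless for
highly expressed genes — and the transform is recorded in the output and
configurable. Class cohorts with fewer than two events are skipped.

## ΔΔCt enrichment

fold = 2^−[(Ct_t,high − Ct_ref,high) − (Ct_t,low − Ct_ref,low)] with
amplification efficiency fixed at 2. Replicates are paired by index and
summarized as mean ± s.e.m. of replicate folds (mean-of-folds rather
than fold-of-means; with triplicate Ct noise of ~0.2 cycles the two
differ by far less than the s.e.m.). The dominant isoform is the maximal
mean fold, with exact ties flagged; the count of isoforms above a
configurable 5-fold threshold summarizes profile diversity.

## Limiting dilution

The single-hit Poisson likelihood is maximized over θ = log f by a
bracketed root find of the score equation on θ ∈ [log 1e−15, 0]
(tolerance 1e-12; the likelihood is unimodal in θ for non-degenerate
data). The single-dose closed form f = −ln(1−k/n)/d is reproduced to
1e-10 relative. The default CI is Wald on log f from observed
information — the convention of classical limiting-dilution calculators —
with a profile-likelihood CI by flag, since Wald degrades near
boundaries. All-negative assays return f = 0 with an exact one-sided
upper bound from P(no graft responds) = 0.05; all-positive assays are
flagged at the upper boundary with f capped at 1 (the model's MLE can
exceed 1 cell⁻¹, which is biologically vacuous). Arms are compared by a
df = 1 likelihood ratio test of shared-f versus per-arm f, and fold
depletion is the ratio of MLEs.

## Synthetic cohorts

The generator emulates a two-class bulk-RNA cohort in which the quantity
the score measures — percent-of-family diversity — differs by class:

| parameter | default | meaning |
|---|---|---|
| n_per_class | 200 | samples per tumor class |
| alpha_dominant | (8, 0.3×18) | Dirichlet concentrations, dominant-isoform class |
| alpha_diverse | 3 (symmetric) | concentrations, diverse class |
| total_mu, total_sigma | 8, 1 | log-normal family total (median ≈ 3000, RSEM-like) |
| stemness a, b, tau | 0.4, 0.04, 0.13 | mrnasi = clamp₀₁(a + b·z(AVS) + N(0, τ)) |
| hazard_per_class | 0.010, 0.022 /month | exponential baselines (median ≈ 69 vs 31 months) |
| beta_avs | −0.7 | log-hazard for the cohort-median high-AVS group |
| censor_max | 120 months | uniform administrative censoring |

The Dirichlet parameterization directly controls the evenness AVS
measures: the dominant class scores in the hundreds and the diverse
class near 10, bracketing the observed cell-line range (≈28–313).
The stemness slope/noise pair targets a cohort Spearman rho near 0.3.
Survival is exponential (the simplest hazard adequate for univariate Cox
recovery), with the protective effect attached to the cohort-level
high-AVS group. All draws come from per-component child streams spawned
from one seed, so generation is bit-reproducible and adding a component
leaves the others unchanged.

Deliberately not modeled: batch/GC effects, aneuploidy, intra-tumor
heterogeneity, any transcriptome outside the family, and per-class
within-class AVS–hazard coupling. Passing tests on these cohorts
demonstrate that the pipeline's statistics behave as designed, not that
the biological claims hold in real tumors.

## Problem sizes and tolerances

The verification suite uses: 1,000 random profiles for AVS invariances
(1e-9 absolute) and oracle agreement (1e-12 relative); the full
1 ≤ k < n ≤ 50 grid for the single-dose closed form (1e-10 relative);
1,000 seeded assays (f = 1e-4, doses 10³–10⁵, 10 animals/dose) for
nominal-95% CI coverage, accepted in [93%, 97%]; 100 replicates at
n = 500 per true hazard ratio in {0.5, 1, 2} for Cox recovery (mean
log-HR within 0.1 of truth); and 50 seeded cohorts at 200 samples/class
for the end-to-end pattern, with pass-rate thresholds of 80% (Fisher),
90% (positive Spearman) and 70% (log-rank) fixed in advance. Cox
iteration runs to a 1e-12 step tolerance; the dilution root find to
1e-12 in log f.
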