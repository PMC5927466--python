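# Methods

## Model and procedure

All three layers share one testing kernel applied to per-feature log2
changes versus the day-0 group mean. For a feature with observations
`x_gs` over samples `s` grouped by day `t ∈ {0, 3, 6, 9}`:

* **log2 change**: `y_gs = log2((x_gs + c) / mean_{s ∈ day0}(x_gs + c))`
  with an additive floor `c` (default 0.01 in the measurement's units)
  so zero measurements stay finite. Because the baseline is a
  per-feature constant on the log scale, the omnibus F statistic is
  identical on `y` and on `log2(x + c)`; the transform matters for the
  reported per-day effect sizes, not for significance.
* **Omnibus test**: fixed-effects one-way ANOVA across days — the
  per-feature slice of a feature × time cell-means model —
  `F = (SSB/(T−1)) / (SSE/(N−T))`, with Benjamini–Hochberg adjustment
  across features; features pass at `p_adj ≤ 0.05`.
* **Post hoc**: equal-variance two-sample Student t tests of each
  non-baseline day versus day 0 at `p < 0.05`, defining per-day
  membership and direction (sign of the mean difference).

Degenerate features (no variation at all) get p = 1 by convention;
features with exact group differences and zero replicate scatter get
p = 0.

### Gene weights

Expression adds a per-gene weight derived from sequencing
representation. Gene-wise RPKM is modelled with an exponential
distribution; the maximum-likelihood rate is `λ̂_g = 1/mean_g` (with an
inverse link the fitted linear predictor is the rate itself). Each gene
is scored by `score_g = 1 − exp(−λ_pool · mean_g)`, the probability
that an exponential variable at the transcriptome-wide pooled rate
falls below the gene's mean — a representation score in [0, 1). The
weight is the cumulative hazard of the empirical score distribution,
`w_g = −ln(1 − F̂(score_g))` with `F̂ = rank/(G+1)` (average ranks on
ties), clipped at `ln(G+1)` (the top rank's exact value). The published
description of this weighting is one sentence; the construction above
is this package's documented interpretation, and `weighting="none"`
disables it.

A constant per-gene weight cancels from a per-gene F ratio, so under
the default `error_pooling="per_gene"` the weights are bookkeeping
only. They become consequential under `error_pooling="global"`, where
the residual variance is pooled across genes as `Σ_g w_g·SSE_g /
(G·(N−T))` and each gene's weighted between-group mean square is tested
against it on `G·(N−T)` denominator df. Both options are exposed
because the original analysis does not state which was used.

### Effect-size gates

* Genes: with `σ_SSR² = SST/(N−1)` (scatter about the gene's grand
  mean) and `σ_within² = SSE/(N−1)`, the gate `0.3·σ_SSR > 0.3·σ_within`
  reduces algebraically to `SST > SSE`, i.e. SSB > 0 — it excludes only
  genes whose day means are exactly equal. This near-vacuity is a
  property of the rule as published; the stricter `between_vs_within`
  mode (SSB > SSE) is provided as an alternative and both are tested.
* Metabolites: the per-metabolite effect is the largest per-day
  |group-mean log2RC| (the summary statistic is not pinned down by the
  source; the max-over-days reading matches "minimum effect size" for a
  time course). The threshold is `0.3 × σ_log2RC`, where `σ_log2RC² =
  SSE/(N−1)` pools within-cell scatter over the entire metabolite × day
  matrix, and the smallest estimate across the supplied cell lines
  wins. `2^0.20 ≈ 1.149`, so a 0.20 threshold is about a 1.15-fold
  change. Noise-free input makes the threshold degenerate (zero); this
  raises unless `allow_zero=True`.

### Methylation QC and imputation

β = mCG/(mCG+CG) × 100 per probe and sample; cells with zero total
intensity are undefined and treated as failed reads. No background
subtraction or normalisation stage exists, matching the upstream
processing choice.

QC operates on probe × cell × day replicate blocks (N = 3):

* **Fence.** Outliers are replicates whose residual around the block
  sample mean crosses a 1.5-IQR fence. Per-block quartile fences are
  degenerate at N = 3 — with linear-interpolation quartiles the extreme
  residual can *never* cross `Q3 + 1.5·IQR` (provable algebraically),
  and median-centred per-block fences flag ~46% of clean Gaussian
  triples. The fence is therefore estimated **array-wise**: residuals
  around block means are pooled over all blocks and the Tukey fence
  `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` of that pooled distribution (linear
  interpolation quartiles) is applied to every cell. This restores a
  calibrated rule (<1% false flags on clean data). A lone block QC'd
  without array context falls back to a median-centred block fence.
* **Multi-crossing blocks.** A single aberrant replicate drags the
  block mean, and can push honest replicates over the fence too; a
  symmetric wide block would otherwise lose both tails. When several
  residuals cross the fence, the most aberrant replicate is removed and
  the survivors are re-tested around their own mean; only a
  still-aberrant remainder counts as a second outlier.
* **Verdicts.** More than one failed read or more than one outlier
  discards the block; otherwise the single bad replicate is dropped and
  the block (now N = 2) is imputed back to N = 3.
* **Imputation.** The imputed value is the trimmed mean of the two
  survivors (their midpoint) plus a residual estimate borrowed from the
  probe's other day groups: `r̂ = Σ_k ρ(t,k)·resid_k / Σ_k |ρ(t,k)|`,
  where `resid_k` is the same-replicate-index residual in group k (zero
  — the survivors' mean residual — when that replicate did not survive)
  and ρ is the Pearson correlation of group mean-β profiles over
  fully-clean probes. Absolute-value weights prevent sign cancellation;
  results are clipped to [0, 100]. With no context the unadjusted mean
  is used.
* **Degrees of freedom.** An imputed value contributes to group means
  and Δ%mCG but carries no information about replicate error; counting
  it as a free observation measurably inflates the false discovery rate
  (the substituted value sits near the survivor midpoint and shrinks
  the error estimate). Each imputed cell therefore removes one
  denominator df from the omnibus F and the post hoc t — the classic
  missing-plot correction. This restores planted-run FDR to the 0.05–
  0.08 range without touching sensitivity.

Probes whose baseline (day 0) block is discarded, or with fewer than
two surviving day groups, are excluded and logged.

## Synthetic data

The generators emulate the default study layout: days 0/3/6/9 with 3
replicates for expression and methylation and 4 for metabolomics, one
cell line per study. Planted effects are placed on a contiguous random
run of the non-baseline days (progressive time-course shape; a fixed
day set can be requested via `effect_days`), with magnitude `effect_sd`
and a random sign shared across the feature's days.

Default conditions (chosen once as the exercised study conditions):

| layer | features | planted | effect | replicate noise |
|---|---|---|---|---|
| expression | 500 genes | 20% | 2.0 log2 | 0.25 log2 |
| metabolomics | 200 metabolites | 25% | 0.6 log2 | 0.15 log2 |
| methylation | 1000 probes | 10% | 20 β-points | 2 β-points |

Expression baselines are log2-normal (mean 3, SD 2, truncated at
RPKM ≥ 0.01) — a stand-in for an unreported distribution, spanning the
dynamic range where the weighting scheme differentiates genes.
Metabolite baselines are log2-normal in arbitrary units. Methylation
baselines are a bimodal mixture (Beta(2,10) and Beta(8,2), scaled to
[0,100]); planted signs are flipped when the shift would leave [1, 99]
so the planted truth stays realisable within β bounds. Intensities are
constructed so that mCG/(mCG+CG)×100 reproduces the noisy β at a
log-normal total intensity. QC hazards: failed-read cells at 2%
(modest, realistic array failure) and replicate displacement
(≥ 3× the noise scale) at 2%; outliers are injected before the failed
mask, so a cell can be both. All randomness flows from one integer seed
through a single `numpy.random.Generator`.

What the generator does **not** emulate: probe-type chemistry
differences, spatial array artefacts, batch or replicate main effects,
count overdispersion at low RPKM, correlated features (pathways), or
missing-not-at-random failures. Passing tests therefore demonstrate the
machinery's correctness and calibration under idealised independent
Gaussian noise, not performance on real arrays.

## Integration

Gene-level summaries average per-day Δ%mCG over a gene's significant
probes by scope: promoter = {TSS1500, TSS200} (the array's own promoter
classes; configurable), body = {Body, 1stExon}, overall = promoter ∪
body ∪ UTRs. A day-d DMEG is a day-d DEG with at least one significant
promoter probe that day; percentages are rounded to the nearest integer
(half away from zero). The 2×2 association uses the full annotated gene
universe, `OR = (a·d)/(b·c)` with +0.5 per cell when any cell is zero,
and Pearson chi-squared (no continuity correction, df = 1). Concordance
classifies eligible genes (a direction and a nonzero scope Δ) into sign
quadrants; the default `promoter_inverse` convention counts hypo+up and
hyper+down as concordant (the repressive-promoter expectation), with
`same_sign` selectable, since the source does not state its convention.

## Numerical choices and edge cases

* Additive floor 0.01 before log2 (configurable); avoids dropping
  zero-measurement features.
* Degeneracy tolerances are relative (1e-12 of the feature's scale).
* Strictness: omnibus `p_adj ≤ 0.05`; post hoc `p < 0.05`; gene effect
  gate strict `>`; metabolite effect gate `≥`.
* Empirical-CDF ties: average ranks.
* BH adjustment delegates to `statsmodels.stats.multitest`.
* Pipeline stage seeds derive from the run seed by hashing the stage
  name (blake2s, reduced below 2^31), so stages re-run in isolation.

## Problem sizes

Tests and the acceptance script exercise the defaults above plus
2000-gene global-null calibration runs; these sizes give stable
sensitivity/FDR estimates (binomial SE on the null fraction ≈ 0.005)
while keeping the full suite to a few seconds of compute.

## Known limitations

* The weighting construction and the imputation residual formula are
  documented interpretations of one-sentence descriptions; alternatives
  (e.g. other score definitions) would change individual weights but
  not the unit-weight path, which is oracle-checked against textbook
  ANOVA.
* The literal gene effect gate (SST > SSE) excludes almost nothing; use
  `between_vs_within` for a consequential gate.
* Imputation is approximately mean-unbiased but not variance-faithful;
  the df correction compensates on average, not per-probe.
* With N = 3 replicates, two same-direction displaced replicates in one
  block are indistinguishable from a shifted pair with one low outlier;
  QC resolves such blocks in favour of the majority pair.
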