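# Methods

This note records the modeling choices behind `vepbench`: the evaluation
procedure itself, the conventions adopted where the procedure is genuinely
underdetermined, the synthetic-cohort generator and its defaults, and the
limits of what the synthetic tests demonstrate.

## Evaluation model

The unit of benchmarking is a **gene–trait combination**: a gene with a
previously reported rare-variant burden association and a phenotype. Only
rare missense variants (folded MAF < 0.1% in both the study cohort and a
reference population) enter the evaluation, because common variants are
shaped by selection and LD in ways that confound per-variant effect
prediction, and because burden associations are established on rare
variation.

**Binary traits.** After orientation (low-is-damaging predictors are
negated so that higher always means more damaging), each predictor's scores
for the gene's post-QC rare variants are winsorized at the 5th/95th
percentiles and affinely mapped to [0, 1]. A carrier's participant-centric
score is the dosage-weighted sum of normalized scores over carried, scored
variants — an additive model; homozygous carriage counts twice. The
performance measure is the area under the balanced precision–recall curve
(AUBPRC). At threshold `s`, with TPR = TP/P and FPR = FP/N, balanced
precision is TPR/(TPR + FPR): the precision that would be observed at a 50%
prior on positives, making combinations with different prevalences
comparable. When P = N it reduces to raw precision exactly.

**Quantitative traits.** Trait values are averaged across each variant's
carriers (each carrier counted once, regardless of dosage), and performance
is PCC², the squared Pearson correlation between oriented raw scores and
variant-mean trait values. Raw rather than winsorized scores are used:
Pearson correlation is affine-invariant, so normalization could matter only
through clipping, and clipping would discard tail information the
correlation can use. Squaring weights positive and negative correlations of
equal strength equally; consequently PCC² is orientation-*insensitive*,
which is why orientation errors can only be detected on binary
combinations.

### Curve construction

Thresholds are the distinct observed participant scores in descending
order; participants with equal scores cross a threshold together. Every
achieved threshold has TP + FP ≥ 1, so balanced precision is defined at
every achieved point; the 0/0 case never enters the integral. The curve is
anchored at recall 0 by constant extension of the most stringent achieved
point's balanced precision, always reaches recall 1 at the minimal
threshold, and is integrated by the trapezoidal rule over recall. This
construction is exactly invariant under strictly increasing transforms of
the scores, and degenerates correctly: all-equal scores give the single
point (recall 1, balanced precision 0.5) and area 0.5.

## Uncertainty and comparison

**Paired bootstrap.** Default 10,000 iterations. For each combination, the
evaluation set (carriers with a defined label, or measured carriers for
quantitative traits) is resampled with replacement; the identical index
multiset is applied to every predictor in an iteration, so per-iteration
differences reflect predictor differences, not resampling noise. For
quantitative combinations variant-mean trait values are recomputed on every
resample. Iterations where any included predictor's metric is undefined
(single-class resample, < 3 scored variants drawn, zero variance) are
dropped for the whole combination to preserve pairing; the drop count is
reported and a combination losing more than half its iterations is flagged
unreliable rather than silently summarized. Each distribution is summarized
by its mean and percentile 95% CI (2.5th/97.5th).

**Empirical p-values.** For predictors a (better by mean) and b,
p = #{iterations : value_a − value_b ≤ 0} / retained iterations. Ties count
against a, so p(a, a) = 1 and p(a, b) + p(b, a) − 1 equals the tie fraction
exactly. Zero p-values are legitimate under this formula and are kept; a
(k+1)/(i+1) correction is available by option for users who need strictly
positive p-values.

**FDR.** Storey q-values are computed over one pooled family per analysis
stage: all per-combination pairwise p-values form one family (tie-calling
stage), and the overall Wilcoxon matrix forms a second, separate family.
π0 is estimated by the smoother method — π0(λ) = #{p > λ}/(m(1−λ)) on
λ = 0.05, …, 0.95, smoothed by a least-squares cubic (three effective
degrees of freedom; scipy's default smoothing spline degenerates to exactly
this on a 19-point grid) and read off at λ = 0.95, clipped to (0, 1]. For
families under 100 p-values π0 is fixed at 1, where the estimator is too
unstable; q-values then reduce exactly to the Benjamini–Hochberg step-up.
The smoother is noisy on any single family (its λ-wise inputs share tail
counts), which is why the test suite checks its calibration in aggregate
across seeds rather than draw by draw.

**Tie rule.** Per combination, the top predictor is the one with the
highest bootstrap-mean metric; every predictor whose comparison against the
top yields q ≥ 10% is tied for best. Tie membership is tested against the
top only, not within the tied set.

**Wilcoxon signed-rank.** The overall stage compares per-combination means
for every predictor pair on the combinations both participated in (at least
2 required). Zero differences are dropped; up to 25 nonzero pairs the exact
two-sided null is built by convolution over doubled midranks (ties
included), beyond that a normal approximation with tie-corrected variance
and continuity correction is used.

**Kendall tau-b** (cross-cohort rank agreement) is computed by direct pair
counting with tie correction; the p-value is exact by permutation
enumeration up to 8 items and asymptotic beyond.

## Ranking and tie-breaks

Predictors are ranked by the number of combinations where they are
best-or-tied. A predictor coverage-excluded from a gene cannot be counted
in that gene's combinations, and pairs skip combinations either member
missed; per-pair denominators are reported. Equal counts are broken first
by the number of rivals a predictor significantly outperforms (q < 10% with
favorable direction) in the overall matrix.

Remaining ties are broken by q-value comparison. A two-sided q is small
whenever the evidence is strong *in either direction*, so comparing raw
q-values would credit a predictor for comparisons it convincingly loses —
with near-duplicate predictors in the panel this demonstrably inverts
rankings. The tie-break therefore compares *directional evidence*: for each
comparison, evidence = (1 − q) signed by whether the comparison's direction
favors the predictor; within a tied group, a predictor is credited for each
matched comparison (the tied pair's own, plus each common rival) where its
evidence is strictly stronger than its rival's. Predictors still tied after
all three stages share a rank (competition ranking), flagged explicitly
rather than broken arbitrarily.

## Quality control conventions

The filter wording is applied literally: site Phred quality **strictly
greater than** 20 and genotype missingness **strictly below** 10%; carrier
read depth ≥ 7 and allele balance ≥ threshold (inclusive, as "minimum of"
/ "threshold passed"). The allele-balance rule is site-level by default: a
site survives if at least one depth-passing carrier meets the AB threshold
(homozygous-alt carriers auto-pass; AB is alt reads over total reads), and
sub-threshold carriers at surviving sites are retained. A call-level
variant of the rule is available by configuration. Cohort MAF is the
allele-count frequency over passing calls, folded at 0.5 (a site fixed for
the alternate allele folds to 0); a missing reference frequency is treated
as 0 (absent from the reference implies at most extremely rare). Absent
DP/AD fields auto-pass their filters with a logged warning. Filters are
pure predicates on populated fields, so QC and rarity filtering commute.

The binary-trait evaluation set is the gene's carriers (participants with
at least one scored post-QC rare variant for the predictor in question);
non-carriers carry no predictor information under the additive model. A
configuration switch instead includes all phenotyped participants at
aggregated score 0.

## Synthetic cohort generator

The generator produces the statistical regime the analysis assumes, with
every parameter exposed in `SimulationConfig`:

| parameter | default | meaning |
|---|---|---|
| `n_participants` | 2000 | cohort size |
| `n_genes`, `variants_per_gene` | 2, 200 (int or per-gene tuple) | gene count and rare-variant count per gene |
| `maf_range` | (1e-4, 9e-4) | log-uniform MAF support, all < 0.1% |
| `null_fraction` | 0.1 | share of variants with β = 0 (exact, rounded) |
| `effect_scale` | 0.75 | mean of exponential |β|, trait-SD units per allele |
| `effect_sign_prob` | 1.0 | probability a nonzero β is trait-increasing |
| `trait_noise_sd` | 0.5 | environmental SD of quantitative traits |
| `prevalence` | 0.25 | binary-trait target prevalence |
| `predictor_specs` | noise 0.1/0.5/2.0 | panel of `PredictorFidelity` |

Genotypes are dosage ~ Binomial(2, MAF) per participant. Traits share one
additive genetic component g = Σ dosage·β; quantitative traits add
independent Gaussian noise, and each binary trait thresholds an independent
liability g + N(0, 1) at Φ⁻¹(1 − prevalence) — independent rather than a
thresholded copy of the quantitative trait, so the two trait kinds are not
redundant in tests. Predictor scores are |β| + N(0, noise²), negated for
low-is-damaging orientation, with a per-variant missingness probability; a
`copy_of` spec reuses another predictor's realized raw scores, so
sign-flipped or down-sampled copies are literal copies. Carrier calls get
simulated depth (92/8 mixture of Poisson(30)/Poisson(5), floored at 1) and
allele-supporting reads (Binomial(depth, 0.5) het with a 5% skewed slice at
0.10; 0.98 hom-alt); ~10% of sites draw failing Phred quality, per-variant
genotype missingness is Beta(2, 38), and ~5% of variants are common in the
reference despite cohort rarity — each filter has something real to remove.

Default rationale. The per-gene allele rate at defaults is λ ≈ 0.15, so
~14% of participants carry a rare variant in a gene and ~1% carry two or
more — the multi-carrier sparsity reported for large burden-associated
genes in biobank-scale cohorts, and (at n = 2000) enough carriers per gene
(~200 after QC for a 200-variant gene) for per-combination comparisons to
have discriminating power at all. `effect_scale` = 0.75 trait-SD units
puts |β| in the same range as the mid predictor's score noise (0.5), the
regime where fidelity differences are visible; much larger effects make all
predictors' orderings agree, much smaller ones drown every predictor in
label noise. `effect_sign_prob` = 1 reflects that a burden-associated
gene–trait pair has a dominant effect direction; mixed signs within a gene
would make PCC² uninformative for every predictor alike. Prevalence 0.25 is
typical of the categorical phenotypes (e.g. medication use) used as binary
traits, and keeps case counts among carriers above the minimum-support
exclusion.

The demo conditions (`demo_config`) add a sign-flipped and a 60%-missing
copy of the best predictor and use gene sizes (200, 30): real burden genes
vary greatly in size, and the small gene is where the 10-prediction
coverage rule binds for the thinned copy. The demo's three traits are all
binary because orientation errors are invisible to PCC² (see above);
quantitative combinations are exercised throughout the rest of the suite.

What the generator does **not** emulate: linkage disequilibrium, population
structure and relatedness, covariates (age, sex, ancestry), X-chromosome
dosage, per-transcript annotation ambiguity, genotype-calling artifacts
beyond the simulated per-call fields, and correlated traits. Tests passing
on this cohort show the pipeline's statistical machinery is correct and
powerful under its own assumptions — not that any particular real predictor
ranking would be recovered in a real cohort, where these confounders exist.

## Numerical conventions

- Percentiles (winsorization, bootstrap CIs) use linear interpolation
  between order statistics (numpy default, "type 7").
- Degenerate score scales (all values identical, or coinciding 5th/95th
  percentiles) map every variant to 0.5 with a logged warning.
- Participants with equal aggregated scores move across thresholds
  together; no intra-tie ordering exists anywhere in the curve.
- All randomness flows from one root seed; per-combination bootstrap
  streams are derived from (seed, sha256(combo id)), so results are
  independent of combo processing order and safe to parallelize. Reruns
  with the same seed are byte-identical in every result and fixture file;
  the run manifest is the one exception, since it records wall-clock
  timings alongside the config digest and row-count bookkeeping.
- PCC² is computed per bootstrap iteration and the distribution of squared
  values is summarized (square first, then average); the alternative
  (squaring a summarized mean) is not used, and the choice is recorded in
  the output metadata column `metric = PCC2`.

## Problem sizes used by the test suite

Unit and property tests run on toys (tens of sites, hundreds of
participants). The analysis-level recovery tests run the full pipeline at
the demo conditions — 2000 participants, 2 genes × 3 binary traits, five
predictors, 1000 bootstrap iterations, 20 seeded replicates — a scale
chosen so the whole suite completes comfortably on a single CPU while the
recovery claims (fidelity ordering, orientation handling, coverage
exclusion) hold with high per-replicate probability. Qualitative
single-run claims are asserted as high-probability events across the
replicate set, not on one lucky seed.

## Known limitations

- The FDR ≥ 10% tie rule rewards uncertainty: a noisy predictor ties the
  top more easily than a precise one slightly behind it. With few
  combinations this is a real source of ranking instability; the paper-scale
  setting (140 combinations) suppresses it by aggregation.
- With 6 combinations the overall Wilcoxon matrix's smallest possible
  p-value is 2/2⁶ ≈ 0.031, which after family-wide FDR correction sits near
  the 10% significance line; pairwise "wins" are therefore rare at demo
  scale and the directional q tie-break does most of the ordering work.
- Storey's π0 smoother is biased-low on a noticeable fraction of single
  families even for uniform nulls; families under 100 p-values use π0 = 1
  (pure Benjamini–Hochberg) for this reason.
- Binary-trait evaluation is carrier-only by default; whether real analyses
  should include non-carriers at score 0 is a genuine modeling choice,
  exposed as a switch.
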