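# vepbench

Benchmarking computational variant effect predictors against population
cohort genotype–phenotype data.

Dozens of computational predictors assign each missense variant a score for
how damaging it is, and they disagree. Clinical-assay benchmarks are small
and circular (predictors train on them); sequenced population cohorts offer
an independent test: if a gene is burden-associated with a trait, a good
predictor's scores for that gene's **rare** (MAF < 0.1%) missense variants
should track which carriers actually have the trait. `vepbench` implements
that evaluation end to end for researchers comparing predictors — from VCF
quality control through statistically tie-aware ranking — and ships a
synthetic cohort generator with the same statistical structure, so the whole
pipeline is testable without controlled-access data.

## The method

For each gene–trait combination and each predictor:

- **Binary traits.** Oriented scores are winsorized at the gene's 5th/95th
  percentiles and rescaled to [0, 1] (0 = neutral, 1 = damaging). Each
  carrier gets a participant-centric score `s_p = Σ_v d_pv · s̃_v` (additive
  over carried variants; two variants at 0.5 aggregate to 1). Performance is
  the area under the **balanced precision**–recall curve (AUBPRC), where
  balanced precision = TPR/(TPR + FPR) — the precision expected at a 50%
  prior on positives, so prevalence differences between traits cancel.
- **Quantitative traits.** Trait values are averaged over each variant's
  carriers, and performance is **PCC²**, the squared Pearson correlation of
  oriented raw scores with variant-mean trait values (squared so positive
  and negative correlations of equal strength weigh equally).

Uncertainty comes from a paired bootstrap (default 10,000 iterations):
participants are resampled with replacement, the *same* resample is applied
to every predictor, and for an ordered pair (a better than b by mean)

    p(a, b) = #{iterations : metric_a − metric_b ≤ 0} / iterations.

Storey q-values over the pooled family of pairwise p-values calibrate the
FDR; a predictor with q ≥ 10% against the top performer is **tied for
best**. Overall, predictors are ranked by the number of combinations where
they were best-or-tied, with ties broken by significant pairwise wins in a
two-tailed Wilcoxon signed-rank matrix over per-combo means, then by
directional q-value comparisons. Cross-cohort agreement of two rankings is
measured with Kendall's tau-b.

Data-hygiene rules from sequenced-cohort practice are built in: site Phred
quality > 20, genotype missingness < 10%, carrier depth ≥ 7, an
allele-balance rule (0.15 or 0.20 depending on cohort profile), rarity
(folded MAF < 0.1%) required in both the cohort and a reference population,
predictors excluded from genes where they score fewer than 10 variants, and
combinations with fewer than 10 supporting phenotypes dropped.

## Worked example

`examples/03_benchmark_metrics.py` builds a 120-participant toy with two
predictors of different fidelity and prints:

```
AUBPRC good predictor: 0.869
AUBPRC poor predictor: 0.695
PCC² informative scores: 0.610
good: mean 0.868  95% CI [0.790, 0.934]
poor: mean 0.692  95% CI [0.568, 0.801]
empirical p (good outperformed by poor): 0.0065
```

An AUBPRC of 0.5 is chance and 1.0 is perfect separation of carriers with
the trait; the low-noise predictor scores 0.869 versus 0.695. The paired
bootstrap puts a 95% CI around each mean, and the empirical p of 0.0065
says the poor predictor overtook the good one in only 0.65% of shared
resamples — after FDR correction these two would *not* be called tied.

The other examples cover cohort simulation (`01`), VCF quality control
(`02`), and the full pipeline with tie-aware overall ranking (`04`). The
same pipeline runs from the shell:

```bash
vepbench simulate --out fixture/ --seed 42
vepbench all --config run.yaml --out results/ --seed 42
```

where `run.yaml` points either at real inputs (VCF, phenotype TSV, score
TSVs, orientation metadata, combination list) or at a `simulate:` block.

## Layout

- `src/vepbench/synthetic_cohort.py` — cohort generator and fixture writer
- `src/vepbench/variant_qc.py` — VCF/TSV ingest, QC and rarity filters
- `src/vepbench/score_prep.py` — orientation, coverage, normalization,
  participant aggregation, variant means, sparse-trait exclusion
- `src/vepbench/perf_metrics.py` — AUBPRC and PCC²
- `src/vepbench/inference.py` — paired bootstrap, empirical p, Storey q,
  Wilcoxon signed-rank, Kendall tau-b
- `src/vepbench/ranking.py` — tie-calling, tie-broken overall ranking,
  cross-cohort agreement
- `src/vepbench/pipeline.py`, `src/vepbench/cli.py` — orchestration and the
  thin CLI

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
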