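"""Pipeline orchestration: simulate -> qc -> prepare -> benchmark -> rank -> report.

Every stage is a pure function of its inputs plus the run configuration;
all randomness flows from the single root seed (per-combo bootstrap streams
are derived from it), so a run is reproducible byte-for-byte given the same
inputs — the manifest records row counts, drop counts and timings per stage.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import score_prep, variant_qc
from ._util import ConfigurationError, UndefinedMetricError, atomic_write_text, logger
from .inference import (
    BinaryComboData,
    BootstrapPlan,
    PerformanceDistribution,
    QuantComboData,
    bootstrap_performance,
    empirical_pvalue,
    point_estimates,
    storey_qvalues,
)
from .ranking import (
    ComboRanking,
    count_best_or_tied,
    final_ranking,
    overall_pairwise_matrix,
    rank_combo,
)
from .synthetic_cohort import Cohort, SimulationConfig, simulate_cohort, write_fixture
from .variant_qc import QcThresholds

__version__ = "0.1.0"

__all__ = [
    "RunConfig",
    "InputBundle",
    "PipelineResult",
    "bundle_from_cohort",
    "bundle_from_files",
    "run_qc_stage",
    "prepare_combos",
    "benchmark_combos",
    "rank_predictors",
    "render_report",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Everything a run needs: inputs (files or a simulation), thresholds, plan."""

    simulate: SimulationConfig | None = None
    vcf: str | None = None
    genotype_tsv: str | None = None
    sites_tsv: str | None = None
    phenotypes: str | None = None
    scores_dir: str | None = None
    meta: str | None = None
    combos: str | None = None
    profile: str = "discovery"
    maf_cutoff: float = 0.001
    ab_rule: str = "site"
    iterations: int = 10_000
    seed: int = 0
    fdr: float = 0.10
    min_predictions: int = 10
    min_trait_count: int = 10
    include_noncarriers: bool = False
    ignore_orientation: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ConfigurationError("fdr must be in (0, 1)")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")

    @property
    def thresholds(self) -> QcThresholds:
        return QcThresholds.for_profile(
            self.profile, maf_cutoff=self.maf_cutoff, ab_rule=self.ab_rule
        )

    @property
    def plan(self) -> BootstrapPlan:
        return BootstrapPlan(iterations=self.iterations, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if "seed" not in sim:
                sim["seed"] = cfg.seed
            cfg.simulate = SimulationConfig.from_dict(sim)
        return cfg

    def digest(self) -> str:
        def default(o):
            if isinstance(o, SimulationConfig):
                d = dict(o.__dict__)
                d["predictor_specs"] = [vars(s) for s in o.predictor_specs]
                return d
            return str(o)

        payload = json.dumps(vars(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class InputBundle:
    """Stage-0 inputs in memory, whether simulated or read from disk."""

    sites: pd.DataFrame
    calls: pd.DataFrame
    participant_ids: list[str]
    phenotypes: pd.DataFrame  # participants x traits, wide
    trait_kinds: dict[str, str]
    scores: pd.DataFrame  # predictor_id, variant_id, score
    meta: dict[str, str]
    combos: pd.DataFrame  # gene_id, trait_id, trait_kind


def bundle_from_cohort(cohort: Cohort) -> InputBundle:
    """In-memory path from a simulated cohort (no file round-trip)."""
    n = cohort.carriers.n_participants
    miss_frac = (
        cohort.carriers.missing.groupby("variant_id").size() / n
        if len(cohort.carriers.missing)
        else pd.Series(dtype=float)
    )
    sites = cohort.variants.rename(columns={"ref": "ref", "alt": "alt"}).copy()
    sites["call_missingness"] = sites["variant_id"].map(miss_frac).fillna(0.0)
    sites = sites[variant_qc.SITE_COLUMNS]
    calls = cohort.carriers.calls[variant_qc.CALL_COLUMNS].copy()
    return InputBundle(
        sites, calls, list(cohort.carriers.participant_ids), cohort.phenotypes,
        dict(cohort.trait_kinds), cohort.scores, dict(cohort.meta), cohort.combos,
    )


def bundle_from_files(config: RunConfig) -> InputBundle:
    """Read all pipeline inputs from their on-disk formats."""
    if config.vcf:
        geno = variant_qc.read_genotypes(config.vcf, format="vcf")
    elif config.genotype_tsv:
        geno = variant_qc.read_genotypes(
            config.genotype_tsv, format="tsv", sites_path=config.sites_tsv
        )
    else:
        raise ConfigurationError("either vcf or genotype_tsv input is required")
    pheno_long = pd.read_csv(config.phenotypes, sep="\t")
    phenotypes = pheno_long.pivot(
        index="participant_id", columns="trait_id", values="value"
    )
    combos = pd.read_csv(config.combos, sep="\t")
    trait_kinds = dict(zip(combos["trait_id"], combos["trait_kind"]))
    frames = [
        pd.read_csv(f, sep="\t") for f in sorted(Path(config.scores_dir).glob("*.tsv"))
    ]
    if not frames:
        raise ConfigurationError(f"no score tables found in {config.scores_dir}")
    scores = pd.concat(frames, ignore_index=True)
    meta_df = pd.read_csv(config.meta, sep="\t")
    meta = dict(zip(meta_df["predictor_id"], meta_df["orientation"]))
    return InputBundle(
        geno.sites, geno.calls, geno.participant_ids, phenotypes, trait_kinds,
        scores, meta, combos,
    )


def run_qc_stage(
    bundle: InputBundle, thresholds: QcThresholds
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality + dual-rarity filtering; returns (rare sites with MAF, their calls)."""
    sites_pass, calls_pass = variant_qc.apply_qc(bundle.sites, bundle.calls, thresholds)
    sites_maf = variant_qc.attach_cohort_maf(
        sites_pass, calls_pass, len(bundle.participant_ids)
    )
    rare = variant_qc.filter_rare(sites_maf, thresholds)
    calls_rare = calls_pass[
        calls_pass["variant_id"].isin(set(rare["variant_id"]))
    ].reset_index(drop=True)
    return rare, calls_rare


@dataclass
class PreparedData:
    """Post-QC, oriented, coverage-checked evaluation data per combo."""

    combo_data: list[BinaryComboData | QuantComboData]
    coverage: pd.DataFrame
    combos: pd.DataFrame  # with n_support / retained columns
    eval_participants: dict[str, list[str]]
    skipped: list[tuple[str, str]] = field(default_factory=list)


def prepare_combos(
    bundle: InputBundle,
    rare_sites: pd.DataFrame,
    rare_calls: pd.DataFrame,
    config: RunConfig,
) -> PreparedData:
    """Orient scores, enforce coverage, normalize, and build per-combo data."""
    meta = bundle.meta
    if config.ignore_orientation:
        meta = {p: score_prep.HIGH for p in bundle.scores["predictor_id"].unique()}
    oriented = score_prep.orient_scores(bundle.scores, meta)
    rare_ids = set(rare_sites["variant_id"])
    oriented = oriented[oriented["variant_id"].isin(rare_ids)]

    gene_variants = {
        g: set(grp["variant_id"]) for g, grp in rare_sites.groupby("gene_id")
    }
    coverage = score_prep.check_coverage(
        oriented, gene_variants, config.min_predictions
    )
    gene_calls = {
        g: rare_calls[rare_calls["variant_id"].isin(vs)]
        for g, vs in gene_variants.items()
    }
    eval_participants = {
        g: sorted(gc.loc[gc["dosage"] >= 1, "participant_id"].unique())
        for g, gc in gene_calls.items()
    }
    combos = score_prep.exclude_sparse_traits(
        bundle.phenotypes, bundle.combos, eval_participants, config.min_trait_count
    )

    # per-gene per-predictor oriented score Series over the gene's rare set
    pred_gene_scores: dict[tuple[str, str], pd.Series] = {}
    for (pred, gene), grp in oriented.merge(
        rare_sites[["variant_id", "gene_id"]], on="variant_id"
    ).groupby(["predictor_id", "gene_id"]):
        pred_gene_scores[(pred, gene)] = grp.set_index("variant_id")["score"]

    combo_data: list[BinaryComboData | QuantComboData] = []
    skipped: list[tuple[str, str]] = []
    for c in combos.itertuples():
        combo_id = f"{c.gene_id}|{c.trait_id}"
        if not c.retained:
            skipped.append((combo_id, "sparse-trait exclusion"))
            continue
        included = sorted(
            coverage[(coverage["gene_id"] == c.gene_id) & coverage["included"]][
                "predictor_id"
            ]
        )
        if not included:
            skipped.append((combo_id, "no predictor meets gene coverage"))
            logger.info("combo %s skipped: no predictor meets coverage", combo_id)
            continue
        gc = gene_calls[c.gene_id]
        trait_vals = bundle.phenotypes[c.trait_id]
        if c.trait_kind == "binary":
            pids = [
                p for p in eval_participants[c.gene_id]
                if p in trait_vals.index and pd.notna(trait_vals.get(p))
            ]
            if config.include_noncarriers:
                pids = sorted(
                    p for p in bundle.participant_ids
                    if p in trait_vals.index and pd.notna(trait_vals.get(p))
                )
            labels = trait_vals.loc[pids].to_numpy() == 1
            score_mat = np.full((len(included), len(pids)), np.nan)
            for k, pred in enumerate(included):
                norm = score_prep.normalize_gene_scores(
                    pred_gene_scores[(pred, c.gene_id)]
                )
                agg = score_prep.aggregate_participant_scores(
                    gc, norm,
                    include_noncarriers=config.include_noncarriers,
                    participant_ids=pids if config.include_noncarriers else None,
                )
                score_mat[k] = agg.reindex(pids).to_numpy()
            combo_data.append(BinaryComboData(combo_id, included, score_mat,
                                              np.asarray(labels)))
        else:
            carriers = gc.loc[gc["dosage"] >= 1, ["participant_id", "variant_id"]]
            carriers = carriers.drop_duplicates()
            measured = carriers["participant_id"].map(trait_vals).notna()
            carriers = carriers[measured]
            cpids = sorted(carriers["participant_id"].unique())
            vids = sorted(carriers["variant_id"].unique())
            cpos = {p: i for i, p in enumerate(cpids)}
            vpos = {v: i for i, v in enumerate(vids)}
            score_mat = np.full((len(included), len(vids)), np.nan)
            for k, pred in enumerate(included):
                s = pred_gene_scores[(pred, c.gene_id)]
                for v in vids:
                    if v in s.index:
                        score_mat[k, vpos[v]] = s[v]
            combo_data.append(
                QuantComboData(
                    combo_id,
                    included,
                    carrier_traits=trait_vals.loc[cpids].to_numpy(dtype=float),
                    carrier_idx=carriers["participant_id"].map(cpos).to_numpy(),
                    variant_idx=carriers["variant_id"].map(vpos).to_numpy(),
                    n_variants=len(vids),
                    variant_scores=score_mat,
                )
            )
    return PreparedData(combo_data, coverage, combos, eval_participants, skipped)


@dataclass
class BenchmarkResult:
    distributions: dict[str, dict[str, PerformanceDistribution]]  # combo -> pred -> dist
    summary: pd.DataFrame
    pairwise: pd.DataFrame


def benchmark_combos(
    prepared: PreparedData, plan: BootstrapPlan, fdr: float = 0.10
) -> BenchmarkResult:
    """Paired bootstrap per combo, then the pooled per-combo pairwise q family."""
    distributions: dict[str, dict[str, PerformanceDistribution]] = {}
    summary_rows = []
    pair_rows = []
    for data in prepared.combo_data:
        try:
            dists = bootstrap_performance(data, plan)
        except UndefinedMetricError as exc:
            logger.warning("combo %s skipped in bootstrap: %s", data.combo_id, exc)
            prepared.skipped.append((data.combo_id, str(exc)))
            continue
        points = point_estimates(data)
        distributions[data.combo_id] = dists
        for pred in data.predictors:
            d = dists[pred]
            summary_rows.append(
                (data.combo_id, pred, d.metric, d.mean, d.ci_low, d.ci_high,
                 points[pred], d.n_dropped, d.unreliable)
            )
        order = sorted(data.predictors, key=lambda p: (-dists[p].mean, p))
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                p = empirical_pvalue(dists[a], dists[b])
                pair_rows.append((data.combo_id, a, b, p))
    summary = pd.DataFrame(
        summary_rows,
        columns=["combo_id", "predictor_id", "metric", "mean", "ci_low", "ci_high",
                 "point_estimate", "n_dropped", "unreliable"],
    )
    pairwise = pd.DataFrame(
        pair_rows, columns=["combo_id", "predictor_a", "predictor_b", "p"]
    )
    if len(pairwise):
        pairwise["q"] = storey_qvalues(pairwise["p"].to_numpy())
    else:
        pairwise["q"] = np.nan
    pairwise["significant"] = pairwise["q"] < fdr
    return BenchmarkResult(distributions, summary, pairwise)


@dataclass
class RankingResult:
    combo_rankings: list[ComboRanking]
    combo_table: pd.DataFrame
    counts: pd.Series
    matrix: pd.DataFrame
    overall: pd.DataFrame


def rank_predictors(
    bench: BenchmarkResult, fdr: float = 0.10, predictors: list[str] | None = None
) -> RankingResult:
    """Per-combo winners/tied sets, best-or-tied counts, Wilcoxon matrix, final ranks."""
    combo_rankings = []
    for combo_id in sorted(bench.distributions):
        means = {p: d.mean for p, d in bench.distributions[combo_id].items()}
        pw = bench.pairwise[bench.pairwise["combo_id"] == combo_id]
        combo_rankings.append(rank_combo(combo_id, means, pw, fdr))
    combo_table = pd.DataFrame(
        [
            (r.combo_id, r.top, ",".join(sorted(r.tied)), ",".join(r.order))
            for r in combo_rankings
        ],
        columns=["combo_id", "top", "tied_set", "order"],
    )
    counts = count_best_or_tied(combo_rankings)
    combo_means = bench.summary.pivot(
        index="combo_id", columns="predictor_id", values="mean"
    )
    matrix = overall_pairwise_matrix(combo_means, fdr)
    # a predictor coverage-excluded from every combo still appears, with count 0
    universe = sorted(set(predictors or []) | set(combo_means.columns))
    counts = counts.reindex(universe, fill_value=0)
    overall = final_ranking(counts, matrix)
    return RankingResult(combo_rankings, combo_table, counts, matrix, overall)


@dataclass
class PipelineResult:
    config: RunConfig
    bundle: InputBundle
    rare_sites: pd.DataFrame
    rare_calls: pd.DataFrame
    prepared: PreparedData
    bench: BenchmarkResult
    ranks: RankingResult
    manifest: dict
    report: str


def render_report(ranks: RankingResult, bench: BenchmarkResult) -> str:
    """Human-readable summary: per-combo tables with CIs and tie markers, the
    overall best-or-tied/wins/rank table, and the pairwise significance grid."""
    lines = ["# Predictor benchmarking report", ""]
    for r in ranks.combo_rankings:
        dists = bench.distributions[r.combo_id]
        metric = next(iter(dists.values())).metric
        lines.append(f"## {r.combo_id}  [{metric}]")
        lines.append("predictor            mean   [95% CI]          tied")
        for p in r.order:
            d = dists[p]
            mark = "*" if p in r.tied else " "
            lines.append(
                f"{p:<20} {d.mean:.4f} [{d.ci_low:.4f}, {d.ci_high:.4f}]  {mark}"
            )
        lines.append("")
    lines.append("## Overall ranking")
    lines.append("rank  predictor            best_or_tied  wins  shared")
    for row in ranks.overall.itertuples():
        lines.append(
            f"{row.final_rank:<5} {row.predictor_id:<20} {row.n_best_or_tied:<13}"
            f" {row.pairwise_wins:<5} {'yes' if row.shared_rank else 'no'}"
        )
    lines.append("")
    lines.append("## Pairwise significance grid (overall Wilcoxon, q < fdr)")
    preds = list(ranks.counts.index)
    lut = {
        frozenset((m.predictor_a, m.predictor_b)): m for m in ranks.matrix.itertuples()
    }
    header = "          " + " ".join(f"{p[:9]:>9}" for p in preds)
    lines.append(header)
    for a in preds:
        cells = []
        for b in preds:
            if a == b:
                cells.append(f"{'.':>9}")
                continue
            m = lut.get(frozenset((a, b)))
            if m is None or not m.significant:
                cells.append(f"{'-':>9}")
            else:
                cells.append(f"{('^' if m.direction == a else 'v'):>9}")
        lines.append(f"{a[:9]:<10}" + " ".join(cells))
    lines.append("")
    return "\n".join(lines)


def _write_outputs(out_dir: Path, result: PipelineResult) -> None:
    def tsv(df: pd.DataFrame, name: str) -> None:
        atomic_write_text(
            out_dir / name, df.to_csv(sep="\t", index=False, float_format="%.10g")
        )

    tsv(result.rare_sites, "qc_sites.tsv")
    tsv(result.prepared.coverage, "coverage.tsv")
    tsv(result.prepared.combos, "combos_retained.tsv")
    tsv(result.bench.summary, "distributions.tsv")
    tsv(result.bench.pairwise, "pairwise.tsv")
    tsv(result.ranks.combo_table, "combo_rankings.tsv")
    tsv(result.ranks.matrix, "overall_matrix.tsv")
    tsv(result.ranks.overall, "overall_ranking.tsv")
    atomic_write_text(out_dir / "report.txt", result.report)
    atomic_write_text(
        out_dir / "manifest.json", json.dumps(result.manifest, indent=2, sort_keys=True)
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full stage graph; write result files when out_dir is set."""
    manifest: dict = {
        "config_digest": config.digest(),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = {"wall_seconds": round(time.time() - t0, 3), **counts}

    t0 = time.time()
    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate)
        if config.out_dir:
            write_fixture(cohort, Path(config.out_dir) / "fixture")
        bundle = bundle_from_cohort(cohort)
        record("simulate", t0, variants=len(bundle.sites), calls=len(bundle.calls))
    else:
        bundle = bundle_from_files(config)
        record("load", t0, variants=len(bundle.sites), calls=len(bundle.calls))

    t0 = time.time()
    rare_sites, rare_calls = run_qc_stage(bundle, config.thresholds)
    record(
        "qc", t0,
        sites_in=len(bundle.sites), sites_out=len(rare_sites),
        sites_dropped=len(bundle.sites) - len(rare_sites),
        calls_in=len(bundle.calls), calls_out=len(rare_calls),
        calls_dropped=len(bundle.calls) - len(rare_calls),
    )

    t0 = time.time()
    prepared = prepare_combos(bundle, rare_sites, rare_calls, config)
    record(
        "prepare", t0,
        combos_in=len(bundle.combos), combos_out=len(prepared.combo_data),
        combos_dropped=len(bundle.combos) - len(prepared.combo_data),
    )

    t0 = time.time()
    bench = benchmark_combos(prepared, config.plan, config.fdr)
    record(
        "benchmark", t0,
        combos_in=len(prepared.combo_data), combos_out=len(bench.distributions),
        combos_dropped=len(prepared.combo_data) - len(bench.distributions),
        pairwise_tests=len(bench.pairwise),
    )

    t0 = time.time()
    ranks = rank_predictors(
        bench, config.fdr, sorted(bundle.scores["predictor_id"].unique())
    )
    record("rank", t0, predictors=len(ranks.counts), combos=len(ranks.combo_rankings))

    report = render_report(ranks, bench)
    manifest["skipped_combos"] = sorted(prepared.skipped)
    result = PipelineResult(
        config, bundle, rare_sites, rare_calls, prepared, bench, ranks, manifest, report
    )
    if config.out_dir:
        _write_outputs(Path(config.out_dir), result)
    return result
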