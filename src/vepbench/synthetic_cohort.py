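"""Synthetic population-cohort generator.

Emulates the statistical structure the benchmarking pipeline assumes without
any controlled-access data: rare (MAF < 0.1%) missense variants with sparse
carriers, additive per-variant effects on quantitative traits, a
liability-threshold binary trait, and a panel of predictors whose scores are
noisy monotone transforms of the true effect magnitudes with configurable
noise, missingness and sign orientation.  Per-call sequencing fields (depth,
allele balance, site quality, genotype missingness) are simulated so the QC
filters have something real to act on.

The generative choices (log-uniform MAFs, exponential effect magnitudes,
independent liabilities for binary traits) are documented in
``docs/methods.md``; all are exposed through :class:`SimulationConfig`.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._util import (
    ConfigurationError,
    DataConsistencyError,
    atomic_write_text,
    derive_rng,
)

__all__ = [
    "PredictorFidelity",
    "SimulationConfig",
    "CarrierMatrix",
    "Cohort",
    "simulate_variants",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_predictor_scores",
    "simulate_cohort",
    "write_fixture",
]

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class PredictorFidelity:
    """Fidelity of one synthetic predictor.

    ``noise_sd`` is the SD of Gaussian noise added to the true effect
    magnitude |β| before orientation; ``missingness`` is the per-variant
    probability of leaving a variant unscored.  ``copy_of`` reuses another
    predictor's realized raw scores (before orientation and missingness), so
    sign-flipped or down-sampled copies are literal copies, not re-draws.
    """

    predictor_id: str
    noise_sd: float = 0.0
    orientation: str = "high_is_damaging"
    missingness: float = 0.0
    copy_of: str | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError(f"{self.predictor_id}: noise_sd must be >= 0")
        if not (0 <= self.missingness < 1):
            raise ConfigurationError(f"{self.predictor_id}: missingness must be in [0, 1)")
        if self.orientation not in ("high_is_damaging", "low_is_damaging"):
            raise ConfigurationError(f"{self.predictor_id}: unknown orientation")


def _default_panel() -> list[PredictorFidelity]:
    return [
        PredictorFidelity("pred_hi", noise_sd=0.1),
        PredictorFidelity("pred_mid", noise_sd=0.5),
        PredictorFidelity("pred_lo", noise_sd=2.0),
    ]


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults are the conditions the pipeline's analysis-level tests run at:
    2000 participants, 2 genes of 200 rare variants each (log-uniform MAF in
    (1e-4, 9e-4), per-gene allele rate ~0.15 so ~1% of participants carry
    multiple variants in a gene), 10% null variants, exponential effect
    magnitudes of mean 0.75 trait-SD units, and three predictors of
    decreasing fidelity.  ``variants_per_gene`` may be a single count or one
    count per gene (real burden genes vary greatly in rare-variant count).
    """

    n_participants: int = 2000
    n_genes: int = 2
    variants_per_gene: int | tuple[int, ...] = 200
    maf_range: tuple[float, float] = (1e-4, 9e-4)
    null_fraction: float = 0.1
    effect_scale: float = 0.75
    trait_noise_sd: float = 0.5
    prevalence: float = 0.25
    n_quantitative_traits: int = 1
    n_binary_traits: int = 1
    effect_sign_prob: float = 1.0
    predictor_specs: list[PredictorFidelity] = field(default_factory=_default_panel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        sizes = self.gene_sizes
        if len(sizes) != self.n_genes or any(s < 1 for s in sizes):
            raise ConfigurationError(
                "variants_per_gene must be a count >= 1, or one count per gene"
            )
        lo, hi = self.maf_range
        if not (0 < lo <= hi):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high")
        if hi >= 0.001:
            raise ConfigurationError(
                "maf_range upper bound must be < 0.001 (simulated variants are rare)"
            )
        if not (0 <= self.null_fraction <= 1):
            raise ConfigurationError("null_fraction must be in [0, 1]")
        if self.effect_scale <= 0:
            raise ConfigurationError("effect_scale must be positive")
        if self.trait_noise_sd < 0:
            raise ConfigurationError("trait_noise_sd must be >= 0")
        if not (0 < self.prevalence < 1):
            raise ConfigurationError("prevalence must be in (0, 1)")
        if not (0 <= self.effect_sign_prob <= 1):
            raise ConfigurationError("effect_sign_prob must be in [0, 1]")
        if self.n_quantitative_traits < 0 or self.n_binary_traits < 0:
            raise ConfigurationError("trait counts must be >= 0")
        if self.n_quantitative_traits + self.n_binary_traits < 1:
            raise ConfigurationError("at least one trait is required")
        if not self.predictor_specs:
            raise ConfigurationError("predictor_specs must be non-empty")

    @property
    def gene_sizes(self) -> list[int]:
        if isinstance(self.variants_per_gene, int):
            return [self.variants_per_gene] * self.n_genes
        return [int(s) for s in self.variants_per_gene]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        specs = [
            s if isinstance(s, PredictorFidelity) else PredictorFidelity(**s)
            for s in d.pop("predictor_specs", _default_panel())
        ]
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        cfg = cls(predictor_specs=specs, **d)
        cfg.validate()
        return cfg


@dataclass
class CarrierMatrix:
    """Sparse participant x variant dosage table with per-call QC fields.

    Only carriers (dosage >= 1) are materialized; ``missing`` lists the
    no-call (./.) entries that drive the site-missingness filter.
    """

    participant_ids: list[str]
    calls: pd.DataFrame  # participant_id, variant_id, dosage, depth, alt_reads, allele_balance
    missing: pd.DataFrame  # participant_id, variant_id

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)


@dataclass
class Cohort:
    """A fully simulated cohort: the substrate for every downstream stage."""

    config: SimulationConfig
    variants: pd.DataFrame
    effects: pd.Series  # variant_id -> beta
    carriers: CarrierMatrix
    phenotypes: pd.DataFrame  # participants x traits (wide)
    trait_kinds: dict[str, str]
    scores: pd.DataFrame  # predictor_id, variant_id, score (long)
    meta: dict[str, str]  # predictor_id -> orientation
    combos: pd.DataFrame  # gene_id, trait_id, trait_kind


def demo_predictor_panel() -> list[PredictorFidelity]:
    """Five-predictor panel: three fidelity levels plus a sign-flipped and a
    60%-missing literal copy of the best."""
    return [
        PredictorFidelity("pred_hi", noise_sd=0.1),
        PredictorFidelity("pred_mid", noise_sd=0.5),
        PredictorFidelity("pred_lo", noise_sd=2.0),
        PredictorFidelity(
            "pred_flip", noise_sd=0.1, orientation="low_is_damaging", copy_of="pred_hi"
        ),
        PredictorFidelity("pred_sparse", noise_sd=0.1, missingness=0.6, copy_of="pred_hi"),
    ]


def demo_config(seed: int = 0) -> SimulationConfig:
    """Demo study conditions: 2000 participants, 2 genes x 3 binary traits,
    the five-predictor demo panel.  Binary traits throughout because AUBPRC
    is orientation-sensitive while PCC² is not: the sign-flipped copy can
    only be distinguished from its parent on binary combos.  Gene sizes
    (200, 30) mimic a large and a small burden gene; the small gene is where
    the >=10-predictions coverage rule binds for the 60%-missing copy."""
    return SimulationConfig(
        variants_per_gene=(200, 30),
        n_binary_traits=3,
        n_quantitative_traits=0,
        predictor_specs=demo_predictor_panel(),
        seed=seed,
    )


def simulate_variants(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the variant catalogue and true per-variant effects.

    MAFs are log-uniform on ``maf_range``; a rounded ``null_fraction`` share
    of variants get β = 0, the rest |β| ~ Exponential(mean ``effect_scale``)
    with sign +1 with probability ``effect_sign_prob``.  Site quality,
    genotype missingness and a gnomAD-like reference MAF are attached so the
    QC filters are exercised: ~10% of sites fail the Phred>20 rule, a small
    tail fails missingness<10%, and ~5% of variants are common in the
    reference despite being rare in the cohort.
    """
    config.validate()
    sizes = config.gene_sizes
    n = sum(sizes)
    genes = [f"GENE{g + 1}" for g in range(config.n_genes)]
    gene_col = np.repeat(genes, sizes)
    vids = [
        f"{gene}_v{j + 1:03d}" for gene, size in zip(genes, sizes) for j in range(size)
    ]
    lo, hi = config.maf_range
    maf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    beta = np.zeros(n)
    n_null = int(round(config.null_fraction * n))
    null_idx = rng.choice(n, size=n_null, replace=False)
    nonnull = np.setdiff1d(np.arange(n), null_idx)
    mag = rng.exponential(scale=config.effect_scale, size=nonnull.size)
    sign = np.where(rng.random(nonnull.size) < config.effect_sign_prob, 1.0, -1.0)
    beta[nonnull] = mag * sign

    low_qual = rng.random(n) < 0.10
    site_quality = np.where(
        low_qual, rng.uniform(5, 20, size=n), rng.uniform(25, 60, size=n)
    )
    target_missingness = rng.beta(2, 38, size=n)
    common_in_ref = rng.random(n) < 0.05
    reference_maf = np.where(
        common_in_ref,
        rng.uniform(1.1e-3, 5e-3, size=n),
        rng.uniform(0, 8e-4, size=n),
    )
    ref = _NUCS[rng.integers(0, 4, size=n)]
    alt = _NUCS[
        (np.char.index("ACGT", ref) + rng.integers(1, 4, size=n)) % 4
    ]
    pos = np.concatenate(
        [
            1_000_000 * (g + 1) + 100 + 37 * np.arange(size)
            for g, size in enumerate(sizes)
        ]
    )
    variants = pd.DataFrame(
        {
            "variant_id": vids,
            "gene_id": gene_col,
            "chrom": "1",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": maf,
            "site_quality": site_quality,
            "target_missingness": target_missingness,
            "reference_maf": reference_maf,
        }
    )
    effects = pd.Series(beta, index=pd.Index(vids, name="variant_id"), name="beta")
    return variants, effects


def _participant_ids(n: int) -> list[str]:
    return [f"P{i + 1:06d}" for i in range(n)]


def simulate_genotypes(
    variants: pd.DataFrame, n_participants: int, rng: np.random.Generator
) -> CarrierMatrix:
    """Draw sparse genotypes: dosage ~ Binomial(2, MAF) per participant.

    Carrier calls receive simulated read depth (a 92/8 mixture of
    Poisson(30)/Poisson(5), floored at 1), allele-supporting read counts
    (Binomial(depth, 0.5) for het, 0.98 for hom-alt, with a 5% slice of
    skewed het calls at rate 0.10 that fail the allele-balance filter), and
    each variant's no-call set realizes its target genotype missingness among
    non-carriers.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    if (variants["maf"] > 0.5).any():
        raise ConfigurationError("variant MAFs must be <= 0.5")
    rows: list[tuple] = []
    miss_rows: list[tuple] = []
    pids = np.array(_participant_ids(n_participants))
    for v in variants.itertuples():
        p = v.maf
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
        n_ref, n_het, n_hom = rng.multinomial(n_participants, probs)
        n_carriers = int(n_het + n_hom)
        order = rng.permutation(n_participants)
        carrier_pos = order[:n_carriers]
        dosages = np.r_[np.ones(n_het, int), np.full(n_hom, 2)]
        for pi, dos in zip(carrier_pos, dosages):
            low = rng.random() < 0.08
            depth = max(1, int(rng.poisson(5 if low else 30)))
            if dos == 2:
                alt_reads = int(rng.binomial(depth, 0.98))
            else:
                skew = rng.random() < 0.05
                alt_reads = int(rng.binomial(depth, 0.10 if skew else 0.5))
            rows.append(
                (pids[pi], v.variant_id, int(dos), depth, alt_reads, alt_reads / depth)
            )
        non_carrier_pos = order[n_carriers:]
        n_miss = int(rng.binomial(non_carrier_pos.size, v.target_missingness))
        for pi in non_carrier_pos[:n_miss]:
            miss_rows.append((pids[pi], v.variant_id))
    calls = pd.DataFrame(
        rows,
        columns=["participant_id", "variant_id", "dosage", "depth", "alt_reads",
                 "allele_balance"],
    )
    missing = pd.DataFrame(miss_rows, columns=["participant_id", "variant_id"])
    return CarrierMatrix(list(pids), calls, missing)


def simulate_traits(
    carriers: CarrierMatrix,
    effects: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Quantitative and binary traits from the additive genetic component.

    Every trait shares the genetic component g_p = Σ_v dosage·β_v.
    Quantitative traits add independent Normal(0, trait_noise_sd²) noise.
    Binary traits threshold an independent liability g_p + Normal(0, 1) at
    Φ⁻¹(1 − prevalence), so each realizes the target prevalence in
    expectation with rare carriers.
    """
    n = carriers.n_participants
    pid_index = pd.Index(carriers.participant_ids)
    g = np.zeros(n)
    if len(carriers.calls):
        unknown = set(carriers.calls["variant_id"]) - set(effects.index)
        if unknown:
            raise DataConsistencyError(
                f"carried variants without a true effect: {sorted(unknown)[:5]}"
            )
        ppos = pid_index.get_indexer(carriers.calls["participant_id"])
        contrib = (
            carriers.calls["dosage"].to_numpy()
            * effects.loc[carriers.calls["variant_id"]].to_numpy()
        )
        np.add.at(g, ppos, contrib)
    cols: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for j in range(config.n_quantitative_traits):
        tid = f"qt{j + 1}"
        cols[tid] = g + rng.normal(0.0, config.trait_noise_sd, size=n)
        kinds[tid] = "quantitative"
    thr = norm.ppf(1 - config.prevalence)
    for j in range(config.n_binary_traits):
        tid = f"bt{j + 1}"
        liability = g + rng.normal(0.0, 1.0, size=n)
        cols[tid] = (liability > thr).astype(float)
        kinds[tid] = "binary"
    phenotypes = pd.DataFrame(cols, index=pid_index)
    phenotypes.index.name = "participant_id"
    return phenotypes, kinds


def simulate_predictor_scores(
    effects: pd.Series,
    specs: list[PredictorFidelity],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-predictor variant scores: |β| + noise, oriented, with missingness.

    Raw scores are |β_v| + Normal(0, noise_sd²); ``low_is_damaging``
    predictors emit the negation.  A ``copy_of`` spec reuses the parent's raw
    scores (same noise realization) before applying its own orientation and
    missingness, so flipped or thinned copies stay comparable variant-wise.
    """
    if not specs:
        raise ConfigurationError("predictor_specs must be non-empty")
    vids = effects.index.to_numpy()
    n = vids.size
    raw_store: dict[str, np.ndarray] = {}
    frames = []
    meta: dict[str, str] = {}
    for spec in specs:
        if spec.copy_of is not None:
            if spec.copy_of not in raw_store:
                raise ConfigurationError(
                    f"{spec.predictor_id}: copy_of '{spec.copy_of}' must be listed earlier"
                )
            raw = raw_store[spec.copy_of]
        else:
            raw = np.abs(effects.to_numpy()) + rng.normal(0.0, spec.noise_sd, size=n)
        raw_store[spec.predictor_id] = raw
        emitted = -raw if spec.orientation == "low_is_damaging" else raw
        keep = rng.random(n) >= spec.missingness
        frames.append(
            pd.DataFrame(
                {
                    "predictor_id": spec.predictor_id,
                    "variant_id": vids[keep],
                    "score": emitted[keep],
                }
            )
        )
        meta[spec.predictor_id] = spec.orientation
    scores = pd.concat(frames, ignore_index=True)
    return scores, meta


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run the full generator from one seed; every stage uses its own stream."""
    config.validate()
    variants, effects = simulate_variants(config, derive_rng(config.seed, "variants"))
    carriers = simulate_genotypes(
        variants, config.n_participants, derive_rng(config.seed, "genotypes")
    )
    phenotypes, kinds = simulate_traits(
        carriers, effects, config, derive_rng(config.seed, "traits")
    )
    scores, meta = simulate_predictor_scores(
        effects, config.predictor_specs, derive_rng(config.seed, "scores")
    )
    combos = pd.DataFrame(
        [
            (g, t, kinds[t])
            for g in variants["gene_id"].unique()
            for t in phenotypes.columns
        ],
        columns=["gene_id", "trait_id", "trait_kind"],
    )
    return Cohort(config, variants, effects, carriers, phenotypes, kinds, scores,
                  meta, combos)


def _vcf_text(cohort: Cohort) -> str:
    """Render the cohort as a VCF v4.2 string (GT:DP:AD, QUAL = site Phred)."""
    pids = cohort.carriers.participant_ids
    n = len(pids)
    pid_pos = {p: i for i, p in enumerate(pids)}
    lines = [
        "##fileformat=VCFv4.2",
        "##source=vepbench-synthetic-cohort",
        "##contig=<ID=1>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=RAF,Number=1,Type=Float,Description="Reference population allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pids),
    ]
    calls_by_variant = {
        vid: grp for vid, grp in cohort.carriers.calls.groupby("variant_id")
    }
    miss_by_variant = {
        vid: grp["participant_id"] for vid, grp in cohort.carriers.missing.groupby("variant_id")
    }
    variants = cohort.variants.sort_values(["chrom", "pos"], kind="stable")
    for v in variants.itertuples():
        entries = np.full(n, "0/0", dtype=object)
        for p in miss_by_variant.get(v.variant_id, []):
            entries[pid_pos[p]] = "./."
        if v.variant_id in calls_by_variant:
            for c in calls_by_variant[v.variant_id].itertuples():
                gt = "0/1" if c.dosage == 1 else "1/1"
                ref_reads = c.depth - c.alt_reads
                entries[pid_pos[c.participant_id]] = (
                    f"{gt}:{c.depth}:{ref_reads},{c.alt_reads}"
                )
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t"
            f"{v.site_quality:.2f}\t.\tGENE={v.gene_id};RAF={v.reference_maf:.6g}\t"
            "GT:DP:AD\t" + "\t".join(entries)
        )
    return "\n".join(lines) + "\n"


def write_fixture(cohort: Cohort, output_directory: str | Path) -> dict[str, Path]:
    """Write the cohort in the standard on-disk formats the pipeline ingests.

    Produces cohort.vcf, phenotypes.tsv (long), per-predictor score TSVs,
    predictor metadata, the gene-trait combination list, and truth tables for
    test assertions.  Byte-identical for identical configs (fixed float
    formatting, deterministic ordering).
    """
    out = Path(output_directory)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["vcf"] = out / "cohort.vcf"
    atomic_write_text(paths["vcf"], _vcf_text(cohort))

    pheno_lines = ["participant_id\ttrait_id\tvalue"]
    for trait in cohort.phenotypes.columns:
        kind = cohort.trait_kinds[trait]
        for pid, val in cohort.phenotypes[trait].items():
            txt = f"{int(val)}" if kind == "binary" else f"{val:.10g}"
            pheno_lines.append(f"{pid}\t{trait}\t{txt}")
    paths["phenotypes"] = out / "phenotypes.tsv"
    atomic_write_text(paths["phenotypes"], "\n".join(pheno_lines) + "\n")

    scores_dir = out / "scores"
    scores_dir.mkdir(exist_ok=True)
    for pred, grp in cohort.scores.groupby("predictor_id", sort=True):
        lines = ["predictor_id\tvariant_id\tscore"] + [
            f"{pred}\t{r.variant_id}\t{r.score:.10g}" for r in grp.itertuples()
        ]
        paths[f"scores/{pred}"] = scores_dir / f"{pred}.tsv"
        atomic_write_text(paths[f"scores/{pred}"], "\n".join(lines) + "\n")

    meta_lines = ["predictor_id\torientation"] + [
        f"{p}\t{o}" for p, o in sorted(cohort.meta.items())
    ]
    paths["meta"] = out / "predictor_meta.tsv"
    atomic_write_text(paths["meta"], "\n".join(meta_lines) + "\n")

    combo_lines = ["gene_id\ttrait_id\ttrait_kind"] + [
        f"{r.gene_id}\t{r.trait_id}\t{r.trait_kind}" for r in cohort.combos.itertuples()
    ]
    paths["combos"] = out / "combos.tsv"
    atomic_write_text(paths["combos"], "\n".join(combo_lines) + "\n")

    truth_lines = ["variant_id\tgene_id\tmaf\tbeta"] + [
        f"{v.variant_id}\t{v.gene_id}\t{v.maf:.10g}\t{cohort.effects[v.variant_id]:.10g}"
        for v in cohort.variants.itertuples()
    ]
    paths["truth"] = out / "truth_variants.tsv"
    atomic_write_text(paths["truth"], "\n".join(truth_lines) + "\n")

    fid_lines = ["predictor_id\tnoise_sd\torientation\tmissingness\tcopy_of"] + [
        f"{s.predictor_id}\t{s.noise_sd:.10g}\t{s.orientation}\t{s.missingness:.10g}\t"
        f"{s.copy_of or '.'}"
        for s in cohort.config.predictor_specs
    ]
    paths["truth_predictors"] = out / "truth_predictors.tsv"
    atomic_write_text(paths["truth_predictors"], "\n".join(fid_lines) + "\n")
    return paths


def fixture_digest(output_directory: str | Path) -> str:
    """SHA-256 over all fixture files (sorted), for determinism checks."""
    out = Path(output_directory)
    h = hashlib.sha256()
    for f in sorted(p for p in out.rglob("*") if p.is_file()):
        h.update(f.relative_to(out).as_posix().encode())
        h.update(f.read_bytes())
    return h.hexdigest()
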