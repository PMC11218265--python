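"""Genotype ingest and quality control.

Reads genotype calls from VCF (via cyvcf2) or long-format TSV and applies
the site/call filters used for cohort exome data: site Phred quality > 20,
genotype missingness < 10%, carrier read depth >= 7, and an allele-balance
rule requiring at least one carrier at or above the AB threshold (0.15 for
the discovery-cohort profile, 0.20 for the validation profile).  Rarity is
enforced in *both* the cohort and a gnomAD-like reference: folded MAF must
be < 0.1% in each.

Inequality conventions (literal reading of the filter wording): quality and
missingness are strict, depth and allele balance are inclusive.  Homozygous-
alt calls auto-pass the AB rule; a missing reference frequency is treated as
0 (absent from the reference implies at most extremely rare).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ConfigurationError, DataConsistencyError, VepbenchError, logger

__all__ = [
    "QcThresholds",
    "GenotypeData",
    "read_genotypes",
    "apply_qc",
    "compute_cohort_maf",
    "attach_cohort_maf",
    "filter_rare",
]

SITE_COLUMNS = [
    "variant_id", "gene_id", "chrom", "pos", "ref", "alt",
    "site_quality", "call_missingness", "reference_maf",
]
CALL_COLUMNS = ["participant_id", "variant_id", "dosage", "depth", "allele_balance"]


@dataclass(frozen=True)
class QcThresholds:
    """QC cutoffs; ``for_profile`` selects the cohort-specific AB threshold."""

    min_quality: float = 20.0       # exclusive: quality must be > this
    max_missingness: float = 0.10   # exclusive: missingness must be < this
    min_depth: float = 7.0          # inclusive
    min_allele_balance: float = 0.15  # inclusive
    maf_cutoff: float = 0.001       # exclusive, applied to cohort and reference
    ab_rule: str = "site"           # "site": >=1 qualifying carrier keeps the site
                                    # "call": also drop individual sub-threshold het calls

    def __post_init__(self) -> None:
        if not (0 <= self.max_missingness <= 1):
            raise ConfigurationError("max_missingness must be in [0, 1]")
        if not (0 <= self.min_allele_balance <= 1):
            raise ConfigurationError("min_allele_balance must be in [0, 1]")
        if self.min_depth < 0 or self.maf_cutoff <= 0:
            raise ConfigurationError("min_depth must be >= 0 and maf_cutoff > 0")
        if self.ab_rule not in ("site", "call"):
            raise ConfigurationError("ab_rule must be 'site' or 'call'")

    @classmethod
    def for_profile(cls, profile: str, **overrides) -> "QcThresholds":
        ab = {"discovery": 0.15, "validation": 0.20}.get(profile)
        if ab is None:
            raise ConfigurationError(f"unknown cohort profile '{profile}'")
        return replace(cls(min_allele_balance=ab), **overrides)


@dataclass
class GenotypeData:
    """Parsed genotype input: site table, carrier calls, and the sample list."""

    sites: pd.DataFrame
    calls: pd.DataFrame
    participant_ids: list[str]


def _read_vcf(path: str | Path) -> GenotypeData:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)
    sample_arr = np.array(samples)
    site_rows = []
    call_frames = []
    for rec in vcf:
        alts = rec.ALT
        gt_types = rec.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        missing = gt_types == 3
        miss_frac = float(missing.sum()) / n if n else 0.0
        qual = rec.QUAL
        if qual is None:
            logger.warning("%s:%s has no QUAL; quality filter auto-passes", rec.CHROM, rec.POS)
            qual = np.nan
        gene = rec.INFO.get("GENE")
        raf = rec.INFO.get("RAF")
        raf = 0.0 if raf is None else float(raf)
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        genotypes = None
        if len(alts) > 1:
            genotypes = np.array([g[:2] for g in rec.genotypes])
        for ai, alt in enumerate(alts):
            if genotypes is None:
                dosage = np.where(missing, 0, gt_types).astype(int)
            else:  # decompose multi-allelic record: count this alternate allele
                dosage = (genotypes == ai + 1).sum(axis=1)
            vid = rec.ID if (rec.ID and len(alts) == 1) else (
                f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            )
            carrier = dosage >= 1
            if carrier.any():
                idx = np.flatnonzero(carrier)
                if dp is not None:
                    depth = dp.reshape(n, -1)[idx, 0].astype(float)
                    depth[depth < 0] = np.nan
                else:
                    depth = np.full(idx.size, np.nan)
                if ad is not None:
                    ad_arr = ad.reshape(n, -1).astype(float)
                    ad_arr[ad_arr < 0] = np.nan
                    alt_reads = ad_arr[idx, ai + 1]
                    total = np.nansum(ad_arr[idx], axis=1)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        ab = np.where(total > 0, alt_reads / total, np.nan)
                else:
                    ab = np.full(idx.size, np.nan)
                call_frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": sample_arr[idx],
                            "variant_id": vid,
                            "dosage": dosage[idx],
                            "depth": depth,
                            "allele_balance": ab,
                        }
                    )
                )
            site_rows.append(
                (vid, gene, rec.CHROM, rec.POS, rec.REF, alt, qual, miss_frac, raf)
            )
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    calls = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else pd.DataFrame(columns=CALL_COLUMNS)
    )
    return GenotypeData(sites, calls, samples)


def _read_tsv(calls_path: str | Path, sites_path: str | Path) -> GenotypeData:
    calls = pd.read_csv(calls_path, sep="\t")
    missing_cols = set(CALL_COLUMNS) - set(calls.columns)
    if missing_cols:
        raise VepbenchError(f"genotype TSV lacks columns: {sorted(missing_cols)}")
    sites = pd.read_csv(sites_path, sep="\t")
    if "reference_maf" not in sites.columns:
        sites["reference_maf"] = 0.0
    if "call_missingness" not in sites.columns:
        sites["call_missingness"] = 0.0
    participants = sorted(calls["participant_id"].unique())
    return GenotypeData(sites, calls, participants)


def read_genotypes(
    path: str | Path, format: str = "vcf", sites_path: str | Path | None = None
) -> GenotypeData:
    """Parse genotype input into (sites, carrier calls, sample list).

    ``format='vcf'`` parses a VCF v4.2 file: one site per alternate allele
    (multi-allelic records decomposed), site quality from QUAL, genotype
    missingness as the ./. fraction, allele balance from AD when present.
    Absent DP/AD fields yield NaN, which auto-passes the corresponding
    filters with a logged warning.  ``format='tsv'`` reads a long call table
    plus a site table (``sites_path``).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        if sites_path is None:
            raise ConfigurationError("tsv format requires sites_path")
        return _read_tsv(path, sites_path)
    raise ConfigurationError(f"unknown genotype format '{format}'")


def apply_qc(
    sites: pd.DataFrame, calls: pd.DataFrame, thresholds: QcThresholds
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply site and call quality filters; returns (passing sites, passing calls).

    A site passes iff quality > min_quality, missingness < max_missingness,
    and at least one carrier call surviving the depth filter qualifies under
    the allele-balance rule (AB >= threshold, hom-alt auto-pass, NaN AB
    auto-pass).  Carrier calls below the depth cutoff are dropped everywhere;
    with ``ab_rule='site'`` sub-threshold het calls at passing sites are
    retained, with ``ab_rule='call'`` they are dropped too.  Per-filter drop
    counts are logged.
    """
    n_sites = len(sites)
    qual_ok = sites["site_quality"].isna() | (sites["site_quality"] > thresholds.min_quality)
    miss_ok = sites["call_missingness"] < thresholds.max_missingness

    depth_ok = calls["depth"].isna() | (calls["depth"] >= thresholds.min_depth)
    calls_d = calls[depth_ok]
    ab_qualifies = (
        (calls_d["dosage"] >= 2)
        | calls_d["allele_balance"].isna()
        | (calls_d["allele_balance"] >= thresholds.min_allele_balance)
    )
    sites_with_qualifying_carrier = set(calls_d.loc[ab_qualifies, "variant_id"])
    ab_ok = sites["variant_id"].isin(sites_with_qualifying_carrier)

    keep = qual_ok & miss_ok & ab_ok
    passing_sites = sites[keep].reset_index(drop=True)
    logger.info(
        "QC sites: %d in, %d fail quality, %d fail missingness, %d fail AB/carrier, %d pass",
        n_sites, int((~qual_ok).sum()), int((~miss_ok).sum()),
        int((qual_ok & miss_ok & ~ab_ok).sum()), len(passing_sites),
    )
    out_calls = calls_d[calls_d["variant_id"].isin(set(passing_sites["variant_id"]))]
    if thresholds.ab_rule == "call":
        keep_call = (
            (out_calls["dosage"] >= 2)
            | out_calls["allele_balance"].isna()
            | (out_calls["allele_balance"] >= thresholds.min_allele_balance)
        )
        out_calls = out_calls[keep_call]
    logger.info(
        "QC calls: %d in, %d dropped for depth, %d retained",
        len(calls), int((~depth_ok).sum()), len(out_calls),
    )
    return passing_sites, out_calls.reset_index(drop=True)


def compute_cohort_maf(calls: pd.DataFrame, n_participants: int) -> pd.Series:
    """Folded cohort minor-allele frequency per variant from passing calls.

    AF = Σ dosage / (2·n_participants), folded to min(AF, 1−AF) so a variant
    fixed for the alternate allele folds to 0.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    dose = calls.groupby("variant_id")["dosage"].sum()
    if (dose > 2 * n_participants).any():
        bad = dose[dose > 2 * n_participants].index[0]
        raise DataConsistencyError(
            f"variant {bad}: allele count exceeds 2 x {n_participants} participants"
        )
    af = dose / (2.0 * n_participants)
    return np.minimum(af, 1.0 - af).rename("cohort_maf")


def attach_cohort_maf(
    sites: pd.DataFrame, calls: pd.DataFrame, n_participants: int
) -> pd.DataFrame:
    """Sites with a ``cohort_maf`` column (0 for variants with no passing call)."""
    maf = compute_cohort_maf(calls, n_participants)
    out = sites.copy()
    out["cohort_maf"] = out["variant_id"].map(maf).fillna(0.0)
    return out


def filter_rare(sites: pd.DataFrame, thresholds: QcThresholds) -> pd.DataFrame:
    """Keep sites rare in BOTH the cohort and the reference (strict < cutoff)."""
    if "cohort_maf" not in sites.columns:
        raise VepbenchError("filter_rare requires cohort_maf (see attach_cohort_maf)")
    ref = sites["reference_maf"].fillna(0.0)
    keep = (sites["cohort_maf"] < thresholds.maf_cutoff) & (ref < thresholds.maf_cutoff)
    logger.info("rarity filter: %d in, %d pass (MAF < %g in cohort and reference)",
                len(sites), int(keep.sum()), thresholds.maf_cutoff)
    return sites[keep].reset_index(drop=True)
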