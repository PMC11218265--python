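"""Predictor score preparation.

Orientation (so higher always means more damaging), the >=10-predictions
per-gene coverage rule, 5th/95th-percentile winsorized 0-1 normalization,
additive participant-centric aggregation for binary traits, variant-mean
trait values for quantitative traits, and the minimum-count trait
exclusions.

Normalization scope is per predictor per gene, over that gene's post-QC
rare-variant score set: the percentiles are then well defined for every
comparison.  Quantitative traits correlate *raw oriented* scores with
variant-mean trait values (Pearson correlation is affine-invariant, so
winsorized rescaling would matter only through clipping).
"""
from __future__ import annotations

import pandas as pd

import numpy as np

from ._util import ConfigurationError, VepbenchError, logger

__all__ = [
    "DegenerateScaleError",
    "orient_scores",
    "check_coverage",
    "winsorize_normalize",
    "normalize_gene_scores",
    "aggregate_participant_scores",
    "variant_mean_traits",
    "exclude_sparse_traits",
]

HIGH = "high_is_damaging"
LOW = "low_is_damaging"


class DegenerateScaleError(VepbenchError):
    """All scores identical: the 5th/95th percentile scale has zero width."""


def orient_scores(table: pd.DataFrame, meta: dict[str, str]) -> pd.DataFrame:
    """Negate scores of low-is-damaging predictors; output is uniformly high-is-damaging."""
    preds = set(table["predictor_id"].unique())
    missing = preds - set(meta)
    if missing:
        raise ConfigurationError(f"predictors without orientation metadata: {sorted(missing)}")
    bad = [p for p in preds if meta[p] not in (HIGH, LOW)]
    if bad:
        raise ConfigurationError(f"unknown orientation for: {bad}")
    out = table.copy()
    flip = out["predictor_id"].map(meta) == LOW
    out.loc[flip, "score"] = -out.loc[flip, "score"]
    return out


def check_coverage(
    table: pd.DataFrame,
    gene_variants: dict[str, set[str]],
    min_predictions: int = 10,
) -> pd.DataFrame:
    """Per (gene, predictor): how many of the gene's variants are scored, and inclusion.

    A predictor is included for a gene iff it scores >= ``min_predictions``
    of the gene's post-QC rare variants; excluded predictors take no part in
    any comparison for combos involving that gene.
    """
    rows = []
    preds = sorted(table["predictor_id"].unique())
    scored = {
        p: set(grp["variant_id"]) for p, grp in table.groupby("predictor_id")
    }
    for gene, vset in sorted(gene_variants.items()):
        for p in preds:
            n = len(scored[p] & vset)
            rows.append((gene, p, n, n >= min_predictions))
    cov = pd.DataFrame(rows, columns=["gene_id", "predictor_id", "n_scored", "included"])
    for r in cov[~cov["included"]].itertuples():
        logger.info("coverage: %s excluded for %s (%d < %d predictions)",
                    r.predictor_id, r.gene_id, r.n_scored, min_predictions)
    return cov


def winsorize_normalize(gene_scores: pd.Series) -> tuple[pd.Series, float, float]:
    """Clip a gene's oriented scores at the 5th/95th percentiles, rescale to [0, 1].

    Percentiles use the linear-interpolation convention.  After orientation,
    0 corresponds to most-neutral and 1 to most-damaging.  Raises
    :class:`DegenerateScaleError` when the percentile interval has zero
    width (e.g. all scores identical); callers map such genes to 0.5.
    """
    vals = gene_scores.astype(float)
    if len(vals) < 2 or vals.nunique() < 2:
        raise DegenerateScaleError("need >= 2 distinct scores to normalize")
    floor, ceil = np.percentile(vals.to_numpy(), [5, 95])
    if ceil <= floor:
        raise DegenerateScaleError("5th and 95th percentiles coincide")
    clipped = vals.clip(floor, ceil)
    return (clipped - floor) / (ceil - floor), float(floor), float(ceil)


def normalize_gene_scores(gene_scores: pd.Series) -> pd.Series:
    """winsorize_normalize with the degenerate fallback: everything to 0.5."""
    try:
        norm, _, _ = winsorize_normalize(gene_scores)
        return norm
    except DegenerateScaleError:
        logger.warning("degenerate score scale; mapping %d variants to 0.5", len(gene_scores))
        return pd.Series(0.5, index=gene_scores.index)


def aggregate_participant_scores(
    calls: pd.DataFrame,
    normalized: pd.Series,
    include_noncarriers: bool = False,
    participant_ids: list[str] | None = None,
) -> pd.Series:
    """Participant-centric score: Σ over carried scored variants of dosage x score.

    Under the additive model two variants scored 0.5 aggregate to 1.0;
    homozygous carriage counts a variant's score twice.  Participants
    carrying no scored variant are absent from the result unless
    ``include_noncarriers`` adds the remaining ``participant_ids`` at 0.
    """
    scored = calls[calls["variant_id"].isin(normalized.index)]
    contrib = scored["dosage"].to_numpy() * normalized.loc[scored["variant_id"]].to_numpy()
    agg = pd.Series(contrib, index=scored["participant_id"]).groupby(level=0).sum()
    agg.index.name = "participant_id"
    if include_noncarriers:
        if participant_ids is None:
            raise ConfigurationError("include_noncarriers requires participant_ids")
        agg = agg.reindex(participant_ids, fill_value=0.0)
        agg.index.name = "participant_id"
    return agg.rename("participant_score")


def variant_mean_traits(calls: pd.DataFrame, trait_values: pd.Series) -> pd.Series:
    """Mean trait value of each variant's carriers (non-missing measurements only).

    Each carrier contributes once regardless of dosage; variants with no
    measured carrier are omitted.
    """
    carriers = calls.loc[calls["dosage"] >= 1, ["participant_id", "variant_id"]]
    carriers = carriers.drop_duplicates()
    vals = carriers["participant_id"].map(trait_values)
    ok = vals.notna()
    means = vals[ok].groupby(carriers.loc[ok, "variant_id"]).mean()
    means.index.name = "variant_id"
    return means.rename("mean_trait")


def exclude_sparse_traits(
    phenotypes: pd.DataFrame,
    combos: pd.DataFrame,
    eval_participants: dict[str, list[str]],
    min_count: int = 10,
) -> pd.DataFrame:
    """Drop gene-trait combos with too little phenotype support among carriers.

    Binary combos need >= ``min_count`` evaluation-set carriers with the
    trait; quantitative combos need >= ``min_count`` non-missing
    measurements among carriers.  Returns the combos table with ``retained``
    and ``n_support`` columns.
    """
    rows = []
    for c in combos.itertuples():
        pids = [p for p in eval_participants.get(c.gene_id, []) if p in phenotypes.index]
        vals = phenotypes.loc[pids, c.trait_id] if pids else pd.Series(dtype=float)
        if c.trait_kind == "binary":
            n_support = int((vals == 1).sum())
        else:
            n_support = int(vals.notna().sum())
        retained = n_support >= min_count
        if not retained:
            logger.info("combo %s/%s dropped: %d < %d phenotype support",
                        c.gene_id, c.trait_id, n_support, min_count)
        rows.append((c.gene_id, c.trait_id, c.trait_kind, n_support, retained))
    return pd.DataFrame(
        rows, columns=["gene_id", "trait_id", "trait_kind", "n_support", "retained"]
    )
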