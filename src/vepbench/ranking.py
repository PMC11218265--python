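"""Per-combination tie-calling and the overall tie-broken predictor ranking.

For each gene-trait combination the top predictor is the one with the
highest bootstrap-mean metric; any predictor whose comparison against the
top yields q >= 0.10 is *tied for best*.  Overall, predictors are ranked by
the number of combinations where they were best-or-tied, with ties broken
(1) by the number of rivals they statistically outperform in the
all-combination Wilcoxon matrix and (2) by head-to-head per-rival q-value
counts; residual full ties share a rank.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import VepbenchError, logger
from .inference import kendall_tau, storey_qvalues, wilcoxon_signed_rank

__all__ = [
    "ComboRanking",
    "rank_combo",
    "count_best_or_tied",
    "overall_pairwise_matrix",
    "final_ranking",
    "cross_cohort_agreement",
]


@dataclass
class ComboRanking:
    """Winner and statistically-tied set for one gene-trait combination."""

    combo_id: str
    order: list[str]  # predictors by mean metric, descending
    means: dict[str, float]
    top: str
    tied: set[str]  # {top} plus predictors with q >= fdr vs the top


def rank_combo(
    combo_id: str,
    means: dict[str, float],
    pairwise: pd.DataFrame,
    fdr: float = 0.10,
) -> ComboRanking:
    """Build the combo's ranking from means and top-vs-other q-values.

    ``pairwise`` rows carry (predictor_a, predictor_b, p, q) with a the
    numerically better predictor; only rows involving the top predictor
    decide tie membership.
    """
    if not means:
        raise VepbenchError(f"combo {combo_id}: no included predictors")
    order = sorted(means, key=lambda p: (-means[p], p))
    top = order[0]
    tied = {top}
    for other in order[1:]:
        rows = pairwise[
            ((pairwise["predictor_a"] == top) & (pairwise["predictor_b"] == other))
            | ((pairwise["predictor_a"] == other) & (pairwise["predictor_b"] == top))
        ]
        if len(rows) and float(rows.iloc[0]["q"]) >= fdr:
            tied.add(other)
    return ComboRanking(combo_id, order, dict(means), top, tied)


def count_best_or_tied(combo_rankings: list[ComboRanking]) -> pd.Series:
    """Per predictor, the number of combinations whose tied set contains it."""
    preds = sorted({p for r in combo_rankings for p in r.order})
    counts = pd.Series(0, index=pd.Index(preds, name="predictor_id"), dtype=int)
    for r in combo_rankings:
        for p in r.tied:
            counts[p] += 1
    return counts.rename("n_best_or_tied")


def overall_pairwise_matrix(
    combo_means: pd.DataFrame, fdr: float = 0.10, min_shared: int = 2
) -> pd.DataFrame:
    """Wilcoxon signed-rank comparison of per-combo means for every predictor pair.

    ``combo_means``: combos x predictors, NaN where a predictor did not
    participate.  Each pair is compared on the combos where both
    participated; q-values are computed over the whole matrix family and a
    pair is significant at q < ``fdr``.  ``direction`` names the predictor
    with the larger paired-mean tendency.  Pairs sharing fewer than
    ``min_shared`` combos are marked incomparable (NaN p, excluded from the
    q family).
    """
    preds = list(combo_means.columns)
    rows = []
    for a, b in itertools.combinations(preds, 2):
        paired = combo_means[[a, b]].dropna()
        n = len(paired)
        if n < min_shared:
            rows.append((a, b, n, np.nan, None))
            logger.info("overall matrix: %s vs %s incomparable (%d shared combos)", a, b, n)
            continue
        p = wilcoxon_signed_rank(paired[a], paired[b])
        diff = float((paired[a] - paired[b]).mean())
        direction = a if diff > 0 else (b if diff < 0 else None)
        rows.append((a, b, n, p, direction))
    mat = pd.DataFrame(rows, columns=["predictor_a", "predictor_b", "n_combos", "p",
                                      "direction"])
    mat["q"] = np.nan
    valid = mat["p"].notna()
    if valid.any():
        mat.loc[valid, "q"] = storey_qvalues(mat.loc[valid, "p"].to_numpy())
    mat["significant"] = valid & (mat["q"] < fdr)
    return mat


def _pair_lookup(matrix: pd.DataFrame) -> dict[frozenset, pd.Series]:
    return {
        frozenset((r.predictor_a, r.predictor_b)): r
        for r in matrix.itertuples()
    }


def _wins(pred: str, matrix: pd.DataFrame) -> int:
    """Number of rivals this predictor statistically outperforms (q < fdr, favorable direction)."""
    m = matrix[matrix["significant"] & (matrix["direction"] == pred)]
    return int(((m["predictor_a"] == pred) | (m["predictor_b"] == pred)).sum())


def _directional_evidence(pred: str, row) -> float:
    """Signed strength of a pairwise comparison from ``pred``'s point of view.

    1 - q when the direction favors pred, -(1 - q) when it favors the rival,
    0 when q is 1 or the pair has no tendency.  A small two-sided q means
    strong evidence in *some* direction; being convincingly beaten must not
    count in a predictor's favor.
    """
    if row is None or np.isnan(row.q) or row.direction is None:
        return 0.0
    strength = 1.0 - float(row.q)
    return strength if row.direction == pred else -strength


def _lower_q_count(pred: str, rival: str, matrix: pd.DataFrame) -> int:
    """Head-to-head tie-break 2 between two tied predictors.

    Over the pair's own comparison and matched third parties r, count the
    comparisons where ``pred``'s evidence is strictly stronger than
    ``rival``'s: a lower q in a favorable-direction comparison wins;
    evidence of being outperformed counts negatively.
    """
    lut = _pair_lookup(matrix)
    others = sorted(
        {p for r in matrix.itertuples() for p in (r.predictor_a, r.predictor_b)}
        - {pred, rival}
    )
    count = 0
    direct = lut.get(frozenset((pred, rival)))
    if _directional_evidence(pred, direct) > _directional_evidence(rival, direct):
        count += 1
    for r in others:
        ea = _directional_evidence(pred, lut.get(frozenset((pred, r))))
        eb = _directional_evidence(rival, lut.get(frozenset((rival, r))))
        if ea > eb:
            count += 1
    return count


def final_ranking(counts: pd.Series, matrix: pd.DataFrame) -> pd.DataFrame:
    """Tie-broken overall ranking.

    Sort by best-or-tied count, then by significant pairwise wins, then by
    head-to-head lower-q counts within the remaining tie group; predictors
    still tied after all three share a rank (competition ranking).
    """
    preds = list(counts.index)
    wins = {p: _wins(p, matrix) for p in preds}

    def group_sort(group: list[str]) -> list[list[str]]:
        # within a (count, wins) tie group, order by pairwise lower-q counts
        if len(group) == 1:
            return [group]
        lq = {
            p: sum(_lower_q_count(p, r, matrix) for r in group if r != p)
            for p in group
        }
        ordered = sorted(group, key=lambda p: (-lq[p], p))
        out: list[list[str]] = []
        for p in ordered:
            if out and lq[out[-1][0]] == lq[p]:
                out[-1].append(p)
            else:
                out.append([p])
        return out

    primary = sorted(preds, key=lambda p: (-counts[p], -wins[p], p))
    tiers: list[list[str]] = []
    for p in primary:
        if tiers and counts[tiers[-1][0]] == counts[p] and wins[tiers[-1][0]] == wins[p]:
            tiers[-1].append(p)
        else:
            tiers.append([p])
    rows = []
    rank = 1
    for tier in tiers:
        for subgroup in group_sort(tier):
            shared = len(subgroup) > 1
            if shared:
                logger.info("shared rank %d: %s", rank, subgroup)
            for p in subgroup:
                rows.append((p, int(counts[p]), wins[p], rank, shared))
            rank += len(subgroup)
    out = pd.DataFrame(
        rows,
        columns=["predictor_id", "n_best_or_tied", "pairwise_wins", "final_rank",
                 "shared_rank"],
    )
    return out.reset_index(drop=True)


def cross_cohort_agreement(
    ranking_1: pd.DataFrame | pd.Series, ranking_2: pd.DataFrame | pd.Series
) -> tuple[float, float, int]:
    """Kendall tau-b between two cohorts' final ranks on the shared predictor set."""

    def as_series(r):
        if isinstance(r, pd.DataFrame):
            return r.set_index("predictor_id")["final_rank"]
        return r

    r1, r2 = as_series(ranking_1), as_series(ranking_2)
    shared = sorted(set(r1.index) & set(r2.index))
    if len(shared) < 2:
        raise VepbenchError("cross-cohort agreement needs >= 2 shared predictors")
    tau, p = kendall_tau(r1.loc[shared].to_numpy(), r2.loc[shared].to_numpy())
    return tau, p, len(shared)
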