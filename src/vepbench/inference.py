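"""Statistical machinery of the predictor comparisons.

Paired bootstrap over participants, empirical pairwise p-values, Storey
q-values, the exact/approximate Wilcoxon signed-rank test, and Kendall's
tau-b.  The pairing contract is central: within a gene-trait combination,
every predictor is evaluated on the *same* resampled participant multiset in
every iteration, so per-iteration differences between predictors are
meaningful and the empirical p-value

    p(a, b) = #{iterations : value_a - value_b <= 0} / retained iterations

is a direct tail probability of the paired difference (ties count against
the nominally better predictor a).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._util import (
    PairingContractError,
    UndefinedMetricError,
    VepbenchError,
    derive_rng,
    logger,
)
from .perf_metrics import aubprc, squared_pearson

__all__ = [
    "BootstrapPlan",
    "BinaryComboData",
    "QuantComboData",
    "PerformanceDistribution",
    "bootstrap_performance",
    "point_estimates",
    "empirical_pvalue",
    "storey_pi0",
    "storey_qvalues",
    "wilcoxon_signed_rank",
    "kendall_tau",
]


@dataclass(frozen=True)
class BootstrapPlan:
    """Resampling plan: iteration count and the root seed for index streams.

    Indices for a combo are drawn from a stream keyed on (seed, combo_id),
    so results are independent of the order combos are processed in.
    """

    iterations: int = 10_000
    seed: int = 0

    def rng_for(self, combo_id: str) -> np.random.Generator:
        return derive_rng(self.seed, "bootstrap", combo_id)


@dataclass
class BinaryComboData:
    """Evaluation data for one binary gene-trait combination.

    ``scores[k, p]`` is predictor k's aggregated participant-centric score for
    evaluation-set participant p, NaN where the participant carries no variant
    scored by that predictor (such participants are excluded for k only).
    """

    combo_id: str
    predictors: list[str]
    scores: np.ndarray  # (n_predictors, n_participants), NaN = undefined
    labels: np.ndarray  # (n_participants,) bool

    metric = "AUBPRC"

    @property
    def n(self) -> int:
        return self.labels.size

    def evaluate(self, idx: np.ndarray) -> np.ndarray:
        out = np.full(len(self.predictors), np.nan)
        lab = self.labels[idx]
        for k in range(len(self.predictors)):
            s = self.scores[k, idx]
            m = ~np.isnan(s)
            try:
                out[k] = aubprc(s[m], lab[m])
            except UndefinedMetricError:
                pass
        return out


@dataclass
class QuantComboData:
    """Evaluation data for one quantitative gene-trait combination.

    Carriers are participants with >=1 post-QC rare variant in the gene and a
    non-missing trait measurement.  ``carrier_idx``/``variant_idx`` list the
    carrier-variant incidences; variant-mean trait values are recomputed on
    every resample of carriers.  ``variant_scores[k, v]`` is predictor k's
    oriented raw score for variant v (NaN = unscored).
    """

    combo_id: str
    predictors: list[str]
    carrier_traits: np.ndarray  # (n_carriers,)
    carrier_idx: np.ndarray  # incidence: carrier index
    variant_idx: np.ndarray  # incidence: variant index
    n_variants: int
    variant_scores: np.ndarray  # (n_predictors, n_variants), NaN = unscored

    metric = "PCC2"

    @property
    def n(self) -> int:
        return self.carrier_traits.size

    def evaluate(self, idx: np.ndarray) -> np.ndarray:
        mult = np.bincount(idx, minlength=self.n).astype(float)
        w = mult[self.carrier_idx]
        den = np.bincount(self.variant_idx, weights=w, minlength=self.n_variants)
        num = np.bincount(
            self.variant_idx,
            weights=w * self.carrier_traits[self.carrier_idx],
            minlength=self.n_variants,
        )
        seen = den > 0
        means = np.full(self.n_variants, np.nan)
        means[seen] = num[seen] / den[seen]
        out = np.full(len(self.predictors), np.nan)
        for k in range(len(self.predictors)):
            s = self.variant_scores[k]
            m = seen & ~np.isnan(s)
            try:
                out[k] = squared_pearson(s[m], means[m])
            except UndefinedMetricError:
                pass
        return out


@dataclass
class PerformanceDistribution:
    """Bootstrap distribution of AUBPRC or PCC² for one (predictor, combo)."""

    predictor_id: str
    combo_id: str
    metric: str
    values: np.ndarray
    n_dropped: int
    unreliable: bool = False
    mean: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        if self.values.size:
            self.mean = float(np.mean(self.values))
            self.ci_low = float(np.percentile(self.values, 2.5))
            self.ci_high = float(np.percentile(self.values, 97.5))
        else:
            self.mean = self.ci_low = self.ci_high = float("nan")


def bootstrap_performance(
    data: BinaryComboData | QuantComboData, plan: BootstrapPlan
) -> dict[str, PerformanceDistribution]:
    """Paired bootstrap of the combo's performance metric for every predictor.

    Participants (binary) or measured carriers (quantitative) are resampled
    with replacement; the same index multiset is applied to every predictor in
    an iteration.  Iterations where the metric is undefined for *any* included
    predictor (e.g. a single-class resample) are dropped combo-wide so the
    distributions stay element-wise paired; the drop count is reported, and a
    combo losing more than half its iterations is flagged unreliable.
    """
    if data.n == 0 or not data.predictors:
        raise UndefinedMetricError(f"combo {data.combo_id}: empty evaluation set")
    rng = plan.rng_for(data.combo_id)
    vals = np.empty((plan.iterations, len(data.predictors)))
    for t in range(plan.iterations):
        idx = rng.integers(0, data.n, size=data.n)
        vals[t] = data.evaluate(idx)
    keep = ~np.isnan(vals).any(axis=1)
    n_dropped = int(plan.iterations - keep.sum())
    unreliable = n_dropped > plan.iterations / 2
    if unreliable:
        logger.warning(
            "combo %s: %d/%d bootstrap iterations undefined; flagged unreliable",
            data.combo_id, n_dropped, plan.iterations,
        )
    vals = vals[keep]
    return {
        pred: PerformanceDistribution(pred, data.combo_id, data.metric, vals[:, k],
                                      n_dropped, unreliable)
        for k, pred in enumerate(data.predictors)
    }


def point_estimates(data: BinaryComboData | QuantComboData) -> dict[str, float]:
    """Metric on the un-resampled evaluation set (NaN where undefined)."""
    vals = data.evaluate(np.arange(data.n))
    return dict(zip(data.predictors, (float(v) for v in vals)))


def empirical_pvalue(dist_a, dist_b, add_one_correction: bool = False) -> float:
    """Fraction of paired iterations where predictor a is outperformed by b.

    Ties count in the numerator, so p(a, a) = 1 exactly.  With
    ``add_one_correction`` the (k+1)/(i+1) estimator is used instead, for
    users who need strictly positive p-values.
    """
    a = np.asarray(getattr(dist_a, "values", dist_a), dtype=float)
    b = np.asarray(getattr(dist_b, "values", dist_b), dtype=float)
    if a.shape != b.shape:
        raise PairingContractError(
            f"paired distributions differ in length: {a.shape} vs {b.shape}"
        )
    if a.size == 0:
        raise UndefinedMetricError("no retained iterations")
    k = int(np.sum((a - b) <= 0))
    if add_one_correction:
        return (k + 1) / (a.size + 1)
    return k / a.size


_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


def storey_pi0(pvalues, min_family_size: int = 100) -> float:
    """Estimate the null proportion π0 by the smoother method.

    π0(λ) = #{p > λ} / (m(1−λ)) is evaluated on λ = 0.05..0.95, smoothed with
    a cubic smoothing spline and read off at λ = 0.95, clipped to (0, 1].
    Families smaller than ``min_family_size`` get π0 = 1 (the estimate is too
    unstable; q-values then reduce to the Benjamini-Hochberg step-up).
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise VepbenchError("p-values must lie in [0, 1]")
    if m < min_family_size:
        return 1.0
    pi0_lam = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in _LAMBDA_GRID])
    # cubic least-squares smoothing (3 effective df), read off at the largest lambda
    pi0 = float(np.polyval(np.polyfit(_LAMBDA_GRID, pi0_lam, 3), _LAMBDA_GRID[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a family of p-values, in input order.

    q(p_(k)) = min_{j >= k} π0·m·p_(j)/j.  With π0 = 1 this is exactly the
    Benjamini-Hochberg adjustment; π0 < 1 tightens it by the estimated
    fraction of true nulls.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise VepbenchError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of positive midranks) and the midranks of |d|."""
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by dynamic programming over all 2^n sign patterns.

    Midranks are doubled to integers; the distribution of 2·W+ under the null
    (each sign pattern equiprobable) is built by convolution.
    """
    weights = np.rint(2 * ranks).astype(np.int64)
    total = int(weights.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for wt in weights:
        dist[wt:] = dist[wt:] + dist[:-wt]
    dist /= 2.0 ** len(weights)
    w2 = int(round(2 * w_plus))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(x, y, exact_limit: int = 25) -> float:
    """Two-tailed Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped before ranking (all-zero pairs give the
    degenerate p = 1).  Up to ``exact_limit`` nonzero pairs the null
    distribution is enumerated exactly (ties handled via midranks); beyond
    that a normal approximation with tie-corrected variance and continuity
    correction is used.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("wilcoxon_signed_rank: all differences zero; p = 1")
        return 1.0
    w_plus, ranks = _signed_rank_statistic(d)
    if n <= exact_limit:
        return _exact_signed_rank_p(w_plus, ranks)
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return 1.0
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-b by direct pair counting with tie correction."""
    n = x.size
    i, j = np.triu_indices(n, k=1)
    sx = np.sign(x[j] - x[i])
    sy = np.sign(y[j] - y[i])
    conc_minus_disc = float(np.sum(sx * sy))
    n0 = n * (n - 1) / 2.0
    n1 = n0 - float(np.sum(sx != 0))  # tied pairs in x
    n2 = n0 - float(np.sum(sy != 0))
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        raise UndefinedMetricError("tau-b undefined: one ranking is entirely tied")
    return conc_minus_disc / denom


def kendall_tau(rank_1, rank_2, exact_limit: int = 8) -> tuple[float, float]:
    """Kendall tau-b with its two-sided p-value.

    For up to ``exact_limit`` items the p-value is exact, by enumerating all
    permutations of one ranking; beyond that the standard normal
    approximation is used.
    """
    x = np.asarray(rank_1, dtype=float)
    y = np.asarray(rank_2, dtype=float)
    if x.shape != y.shape:
        raise VepbenchError("rankings must cover the same item set")
    n = x.size
    if n < 2:
        raise VepbenchError("kendall_tau needs at least 2 items")
    tau = _tau_b(x, y)
    if n <= exact_limit:
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            try:
                t = _tau_b(x, y[list(perm)])
            except UndefinedMetricError:  # pragma: no cover - y fully tied caught above
                continue
            total += 1
            if abs(t) >= abs(tau) - 1e-12:
                hits += 1
        return tau, hits / total
    p = float(stats.kendalltau(x, y, variant="b", method="asymptotic").pvalue)
    return tau, p
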