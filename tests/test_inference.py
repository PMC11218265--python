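"""Bootstrap pairing, empirical p identities, Storey q-values vs BH,
exact Wilcoxon enumeration, and Kendall tau-b."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vepbench._util import PairingContractError, VepbenchError
from vepbench.inference import (
    BinaryComboData,
    BootstrapPlan,
    QuantComboData,
    bootstrap_performance,
    empirical_pvalue,
    kendall_tau,
    point_estimates,
    storey_pi0,
    storey_qvalues,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------- empirical p


class TestEmpiricalPvalue:
    def test_self_comparison_is_one(self):
        d = np.array([0.1, 0.5, 0.9])
        assert empirical_pvalue(d, d) == 1.0

    def test_strictly_better_is_zero(self):
        assert empirical_pvalue(np.array([2.0, 3.0]), np.array([1.0, 2.0])) == 0.0

    def test_direct_count(self):
        a = np.array([1.0, 0.0, 1.0, 3.0])
        b = np.array([0.0, 1.0, 1.0, 1.0])  # diffs 1, -1, 0, 2
        assert empirical_pvalue(a, b) == 0.5

    def test_pairing_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, size=50).astype(float)
            b = rng.integers(0, 4, size=50).astype(float)
            n = a.size
            k_ab = round(empirical_pvalue(a, b) * n)
            k_ba = round(empirical_pvalue(b, a) * n)
            assert k_ab + k_ba == n + int(np.sum(a == b))

    def test_length_mismatch(self):
        with pytest.raises(PairingContractError):
            empirical_pvalue(np.zeros(3), np.zeros(4))

    def test_add_one_correction(self):
        a, b = np.array([2.0, 2.0]), np.array([1.0, 1.0])
        assert empirical_pvalue(a, b, add_one_correction=True) == pytest.approx(1 / 3)


# ---------------------------------------------------------------- Storey q


def bh_stepup(p):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for k in range(m - 1, -1, -1):
        prev = min(prev, m * p[order[k]] / (k + 1))
        adj[order[k]] = prev
    return adj


class TestStoreyQvalues:
    def test_single_zero(self):
        assert storey_qvalues([0.0]).tolist() == [0.0]

    def test_equals_bh_with_pi0_one(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(2, 40))
            assert np.allclose(storey_qvalues(p, pi0=1.0), bh_stepup(p), atol=1e-15)

    def test_pi0_near_one_for_uniform_nulls(self):
        # the smoother is noisy on any single draw (its lambda-wise inputs are
        # correlated), but across seeds it concentrates just below 1
        estimates = [
            storey_pi0(np.random.default_rng(seed).uniform(size=1000))
            for seed in range(20)
        ]
        assert all(e <= 1.0 for e in estimates)
        assert 0.8 <= np.mean(estimates) <= 1.0

    def test_small_family_pi0_fixed_at_one(self):
        p = np.linspace(0.01, 0.5, 50)
        assert storey_pi0(p) == 1.0

    def test_qvalues_preserve_p_order_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=500) ** 2
        q = storey_qvalues(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q <= 1.0).all() and (q >= 0.0).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(VepbenchError):
            storey_qvalues([0.5, 1.2])


# ---------------------------------------------------------------- Wilcoxon


def brute_force_wilcoxon(x, y):
    """Exact two-sided signed-rank p by explicit enumeration of sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(
            wilcoxon_signed_rank(y, x), abs=1e-12
        )

    def test_six_pair_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            x = rng.integers(0, 5, size=6).astype(float)
            y = rng.integers(0, 5, size=6).astype(float)
            assert wilcoxon_signed_rank(x, y) == pytest.approx(
                brute_force_wilcoxon(x, y), abs=1e-12
            )

    def test_one_sided_sweep_doubles_tail(self):
        # 9 positive differences of distinct magnitude: p = 2 / 2^9
        x = np.arange(1.0, 10.0)
        assert wilcoxon_signed_rank(x * 2, x) == pytest.approx(2 / 512)

    def test_large_sample_close_to_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.3, 1, size=60)
        y = rng.normal(0.0, 1, size=60)
        ours = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert ours == pytest.approx(ref, rel=0.05)


# ---------------------------------------------------------------- Kendall


def pair_count_tau_b(x, y):
    """Independent tau-b oracle: explicit loop over all pairs."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[j] - x[i])
            dy = np.sign(y[j] - y[i])
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


class TestKendallTau:
    def test_identity(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [1, 2, 3, 4])
        assert tau == pytest.approx(1.0)

    def test_reversal(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_four_item_pair_counting(self):
        x, y = np.array([1, 2, 3, 4]), np.array([2, 1, 4, 3])
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(pair_count_tau_b(x, y))

    def test_ties_handled_like_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            x = rng.integers(0, 4, size=7).astype(float)
            y = rng.integers(0, 4, size=7).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            tau, p = kendall_tau(x, y)
            assert tau == pytest.approx(pair_count_tau_b(x, y), abs=1e-12)
            assert 0.0 <= p <= 1.0

    def test_exact_p_matches_explicit_permutation(self):
        x, y = np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 3.0, 2.0, 4.0])
        tau, p = kendall_tau(x, y)
        taus = [
            pair_count_tau_b(x, y[list(perm)])
            for perm in itertools.permutations(range(4))
        ]
        expected = np.mean([abs(t) >= abs(tau) - 1e-12 for t in taus])
        assert p == pytest.approx(expected)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=25), rng.normal(size=25)
        tau, p = kendall_tau(x, y)
        ref = stats.kendalltau(x, y, variant="b", method="asymptotic")
        assert tau == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_too_few_items(self):
        with pytest.raises(VepbenchError):
            kendall_tau([1], [1])


# ---------------------------------------------------------------- bootstrap


def _binary_combo(rng, n=60, informative=True, predictors=("a", "b")):
    labels = rng.integers(0, 2, size=n).astype(bool)
    base = labels + rng.normal(0, 1.0, size=n) if informative else rng.normal(size=n)
    scores = np.vstack([base for _ in predictors])
    return BinaryComboData("G|t", list(predictors), scores, labels)


class TestBootstrap:
    def test_identical_predictors_identical_distributions(self):
        rng = np.random.default_rng(8)
        data = _binary_combo(rng)
        dists = bootstrap_performance(data, BootstrapPlan(iterations=200, seed=1))
        assert np.array_equal(dists["a"].values, dists["b"].values)

    def test_same_plan_reproducible(self):
        rng = np.random.default_rng(9)
        data = _binary_combo(rng)
        d1 = bootstrap_performance(data, BootstrapPlan(iterations=100, seed=2))
        d2 = bootstrap_performance(data, BootstrapPlan(iterations=100, seed=2))
        assert np.array_equal(d1["a"].values, d2["a"].values)

    def test_noiseless_quantitative_predictor_is_perfect(self):
        rng = np.random.default_rng(10)
        beta = rng.exponential(1.0, size=20)
        data = QuantComboData(
            "G|q", ["perfect"],
            carrier_traits=2.0 * beta + 1.0,  # exact affine function of scores
            carrier_idx=np.arange(20),
            variant_idx=np.arange(20),
            n_variants=20,
            variant_scores=beta[None, :],
        )
        dists = bootstrap_performance(data, BootstrapPlan(iterations=300, seed=3))
        assert np.allclose(dists["perfect"].values, 1.0, atol=1e-12)

    def test_dropped_iterations_bookkeeping(self):
        rng = np.random.default_rng(11)
        labels = np.zeros(6, dtype=bool)
        labels[0] = True  # single-class resamples are common -> drops
        data = BinaryComboData("G|t", ["a"], rng.normal(size=(1, 6)), labels)
        plan = BootstrapPlan(iterations=400, seed=4)
        dists = bootstrap_performance(data, plan)
        d = dists["a"]
        assert d.n_dropped == plan.iterations - d.values.size
        assert d.n_dropped > 0

    def test_all_undefined_flags_unreliable(self):
        data = BinaryComboData(
            "G|t", ["a"], np.zeros((1, 5)), np.ones(5, dtype=bool)
        )
        dists = bootstrap_performance(data, BootstrapPlan(iterations=50, seed=5))
        assert dists["a"].unreliable and dists["a"].values.size == 0

    def test_ci_contains_point_estimate_usually(self):
        rng = np.random.default_rng(12)
        hits = 0
        for rep in range(20):
            data = _binary_combo(rng, n=80)
            point = point_estimates(data)["a"]
            d = bootstrap_performance(data, BootstrapPlan(iterations=200, seed=rep))
            hits += d["a"].ci_low <= point <= d["a"].ci_high
        assert hits >= 18

    def test_mean_stable_under_doubling(self):
        rng = np.random.default_rng(13)
        data = _binary_combo(rng, n=100)
        d1 = bootstrap_performance(data, BootstrapPlan(iterations=500, seed=6))["a"]
        d2 = bootstrap_performance(data, BootstrapPlan(iterations=1000, seed=6))["a"]
        halfwidth = (d1.ci_high - d1.ci_low) / 2
        assert abs(d1.mean - d2.mean) < halfwidth
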