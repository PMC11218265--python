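"""QC filter semantics: strict/inclusive boundaries, folding, dual rarity,
order independence, and agreement with a brute-force per-rule oracle."""

import numpy as np
import pandas as pd
import pytest

from vepbench._util import ConfigurationError, DataConsistencyError
from vepbench.variant_qc import (
    QcThresholds,
    apply_qc,
    attach_cohort_maf,
    compute_cohort_maf,
    filter_rare,
    read_genotypes,
)


def _site(vid, qual=30.0, miss=0.05, ref_maf=0.0, gene="G1"):
    return {
        "variant_id": vid, "gene_id": gene, "chrom": "1", "pos": 100,
        "ref": "A", "alt": "T", "site_quality": qual, "call_missingness": miss,
        "reference_maf": ref_maf,
    }


def _call(pid, vid, dosage=1, depth=10, ab=0.5):
    return {"participant_id": pid, "variant_id": vid, "dosage": dosage,
            "depth": depth, "allele_balance": ab}


class TestReadGenotypes:
    def test_fixture_roundtrip_site_count(self, fixture_dir, small_cohort):
        geno = read_genotypes(fixture_dir / "cohort.vcf")
        assert len(geno.sites) == len(small_cohort.variants)
        assert len(geno.participant_ids) == small_cohort.carriers.n_participants

    def test_fixture_roundtrip_calls_exact(self, fixture_dir, small_cohort):
        geno = read_genotypes(fixture_dir / "cohort.vcf")
        cols = ["participant_id", "variant_id", "dosage", "depth", "allele_balance"]
        want = (small_cohort.carriers.calls[cols]
                .sort_values(["variant_id", "participant_id"]).reset_index(drop=True))
        got = (geno.calls[cols].sort_values(["variant_id", "participant_id"])
               .reset_index(drop=True).astype(want.dtypes))
        pd.testing.assert_frame_equal(got, want)

    def test_missing_genotype_fraction(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\tv1\tA\tT\t50\t.\tGENE=G1\tGT\t0/1\t0/0\t./.\n"
        )
        geno = read_genotypes(vcf)
        assert geno.sites.loc[0, "call_missingness"] == pytest.approx(1 / 3)
        # no DP/AD fields: depth and allele balance auto-pass as NaN
        assert np.isnan(geno.calls.loc[0, "depth"])

    def test_missingness_matches_simulated_nocall_fractions(self, fixture_dir,
                                                            small_cohort):
        geno = read_genotypes(fixture_dir / "cohort.vcf")
        n = small_cohort.carriers.n_participants
        want = (small_cohort.carriers.missing.groupby("variant_id").size() / n)
        got = geno.sites.set_index("variant_id")["call_missingness"]
        assert np.allclose(got.reindex(want.index), want)


class TestApplyQc:
    def test_five_site_toy(self):
        # {qual, miss, best carrier (depth, AB)}; defaults pass only the first
        spec = [
            ("s1", 30, 0.05, 10, 0.5),
            ("s2", 30, 0.05, 6, 0.5),   # depth below 7
            ("s3", 30, 0.20, 10, 0.5),  # missingness at/above 10%
            ("s4", 15, 0.05, 10, 0.5),  # quality at/below 20
            ("s5", 30, 0.05, 10, 0.1),  # AB below 0.15
        ]
        sites = pd.DataFrame([_site(v, qual=q, miss=m) for v, q, m, _, _ in spec])
        calls = pd.DataFrame([_call("P1", v, depth=d, ab=a) for v, _, _, d, a in spec])
        passing, _ = apply_qc(sites, calls, QcThresholds())
        assert list(passing["variant_id"]) == ["s1"]

    def test_quality_strictly_greater(self):
        sites = pd.DataFrame([_site("s", qual=20.0)])
        calls = pd.DataFrame([_call("P1", "s")])
        passing, _ = apply_qc(sites, calls, QcThresholds())
        assert len(passing) == 0

    def test_quality_19_dropped_regardless(self):
        sites = pd.DataFrame([_site("s", qual=19.0)])
        calls = pd.DataFrame([_call("P1", "s", depth=100, ab=0.5)])
        passing, _ = apply_qc(sites, calls, QcThresholds())
        assert len(passing) == 0

    def test_vacuous_thresholds_keep_every_carried_site(self):
        sites = pd.DataFrame([_site(f"s{i}", qual=5, miss=0.5) for i in range(4)])
        calls = pd.DataFrame([_call("P1", f"s{i}", depth=1, ab=0.01) for i in range(3)])
        thr = QcThresholds(min_quality=0, max_missingness=1.0, min_depth=0,
                           min_allele_balance=0)
        passing, _ = apply_qc(sites, calls, thr)
        assert set(passing["variant_id"]) == {"s0", "s1", "s2"}  # s3 has no carrier

    def test_hom_alt_auto_passes_allele_balance(self):
        sites = pd.DataFrame([_site("s")])
        calls = pd.DataFrame([_call("P1", "s", dosage=2, ab=0.05)])
        passing, _ = apply_qc(sites, calls, QcThresholds())
        assert len(passing) == 1

    def test_site_rule_retains_subthreshold_carriers(self):
        sites = pd.DataFrame([_site("s")])
        calls = pd.DataFrame([_call("P1", "s", ab=0.5), _call("P2", "s", ab=0.05)])
        _, kept = apply_qc(sites, calls, QcThresholds(ab_rule="site"))
        assert len(kept) == 2
        _, kept = apply_qc(sites, calls, QcThresholds(ab_rule="call"))
        assert list(kept["participant_id"]) == ["P1"]


class TestCohortMaf:
    def test_single_het_among_1000(self):
        maf = compute_cohort_maf(pd.DataFrame([_call("P1", "v")]), 1000)
        assert maf["v"] == pytest.approx(5e-4)

    def test_no_carriers_zero(self):
        sites = pd.DataFrame([_site("v")])
        out = attach_cohort_maf(sites, pd.DataFrame(columns=["participant_id",
                                                             "variant_id", "dosage"]),
                                100)
        assert out.loc[0, "cohort_maf"] == 0.0

    def test_fixed_alt_folds_to_zero(self):
        maf = compute_cohort_maf(pd.DataFrame([_call("P1", "v", dosage=2)]), 1)
        assert maf["v"] == 0.0

    def test_overflow_raises(self):
        with pytest.raises(DataConsistencyError):
            compute_cohort_maf(
                pd.DataFrame([_call("P1", "v", dosage=2), _call("P2", "v", dosage=2)]),
                1,
            )


class TestFilterRare:
    def _sites(self, cohort_maf, ref_maf):
        s = pd.DataFrame([_site("v", ref_maf=ref_maf)])
        s["cohort_maf"] = cohort_maf
        return s

    def test_boundary_exactly_at_cutoff_dropped(self):
        assert len(filter_rare(self._sites(0.001, 0.0), QcThresholds())) == 0

    def test_common_in_reference_dropped(self):
        # rare in cohort but common in the reference population: fails dual rule
        assert len(filter_rare(self._sites(5e-4, 0.002), QcThresholds())) == 0

    def test_rare_in_both_retained(self):
        assert len(filter_rare(self._sites(0.0, 0.0), QcThresholds())) == 1

    def test_missing_reference_maf_treated_as_zero(self):
        s = self._sites(5e-4, np.nan)
        assert len(filter_rare(s, QcThresholds())) == 1


def _random_toy(rng, n_sites=50):
    sites = pd.DataFrame(
        [
            _site(
                f"s{i}",
                qual=rng.uniform(10, 40),
                miss=rng.uniform(0, 0.2),
                ref_maf=rng.choice([0.0, 5e-4, 2e-3]),
            )
            for i in range(n_sites)
        ]
    )
    calls = []
    for i in range(n_sites):
        for j in range(rng.integers(0, 4)):
            calls.append(
                _call(
                    f"P{j}", f"s{i}",
                    dosage=int(rng.choice([1, 1, 2])),
                    depth=int(rng.integers(1, 30)),
                    ab=float(rng.uniform(0, 1)),
                )
            )
    return sites, pd.DataFrame(calls)


def brute_force_passing(sites, calls, thr, n_participants):
    """Independent per-rule evaluation of every site, one site at a time."""
    out = []
    for s in sites.itertuples():
        if not (np.isnan(s.site_quality) or s.site_quality > thr.min_quality):
            continue
        if not s.call_missingness < thr.max_missingness:
            continue
        mine = calls[calls["variant_id"] == s.variant_id]
        ok = False
        allele_count = 0
        for c in mine.itertuples():
            if not (np.isnan(c.depth) or c.depth >= thr.min_depth):
                continue
            allele_count += c.dosage
            if (c.dosage >= 2 or np.isnan(c.allele_balance)
                    or c.allele_balance >= thr.min_allele_balance):
                ok = True
        if not ok:
            continue
        af = allele_count / (2 * n_participants)
        maf = min(af, 1 - af)
        ref = 0.0 if np.isnan(s.reference_maf) else s.reference_maf
        if maf < thr.maf_cutoff and ref < thr.maf_cutoff:
            out.append(s.variant_id)
    return set(out)


class TestFilterProperties:
    @pytest.mark.parametrize("profile", ["discovery", "validation"])
    def test_matches_brute_force_oracle(self, profile):
        rng = np.random.default_rng(42)
        thr = QcThresholds.for_profile(profile, maf_cutoff=0.3)
        for _ in range(5):
            sites, calls = _random_toy(rng)
            passing, kept_calls = apply_qc(sites, calls, thr)
            withmaf = attach_cohort_maf(passing, kept_calls, 10)
            rare = filter_rare(withmaf, thr)
            assert set(rare["variant_id"]) == brute_force_passing(sites, calls, thr, 10)

    def test_qc_and_rarity_filters_commute(self):
        rng = np.random.default_rng(3)
        thr = QcThresholds(maf_cutoff=0.3)
        sites, calls = _random_toy(rng)
        sites = attach_cohort_maf(sites, calls, 10)
        a, _ = apply_qc(filter_rare(sites, thr), calls, thr)
        b = filter_rare(apply_qc(sites, calls, thr)[0], thr)
        assert set(a["variant_id"]) == set(b["variant_id"])

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(9)
        sites, calls = _random_toy(rng)
        tight = QcThresholds()
        n_tight = len(apply_qc(sites, calls, tight)[0])
        for relaxed in [
            QcThresholds(min_quality=10),
            QcThresholds(max_missingness=0.5),
            QcThresholds(min_depth=2),
            QcThresholds(min_allele_balance=0.01),
        ]:
            assert len(apply_qc(sites, calls, relaxed)[0]) >= n_tight


def test_unknown_profile_rejected():
    with pytest.raises(ConfigurationError):
        QcThresholds.for_profile("ukb")
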