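"""Apply the cohort QC and dual-rarity filters to a VCF.

Reads genotypes back from a simulated fixture VCF, then applies the site and
call filters (Phred quality > 20, genotype missingness < 10%, carrier depth
>= 7, allele balance >= 0.15) and keeps only variants with folded MAF < 0.1%
in both the cohort and the gnomAD-like reference column.
"""
from pathlib import Path

from vepbench import (
    QcThresholds,
    SimulationConfig,
    apply_qc,
    read_genotypes,
    simulate_cohort,
    write_fixture,
)
from vepbench.variant_qc import attach_cohort_maf, filter_rare

fixture = Path("scratch/example_fixture")
if not (fixture / "cohort.vcf").exists():
    write_fixture(simulate_cohort(SimulationConfig(seed=42)), fixture)

geno = read_genotypes(fixture / "cohort.vcf")
thresholds = QcThresholds.for_profile("discovery")  # allele balance 0.15

sites, calls = apply_qc(geno.sites, geno.calls, thresholds)
sites = attach_cohort_maf(sites, calls, len(geno.participant_ids))
rare = filter_rare(sites, thresholds)

print(f"sites read:            {len(geno.sites)}")
print(f"pass quality/AB/depth: {len(sites)}")
print(f"rare in cohort+ref:    {len(rare)}")
print(f"carrier calls kept:    {len(calls)}")
# Dropped sites are low-quality (Phred <= 20), high-missingness, carrier-less
# after the depth filter, or common in the reference despite cohort rarity.
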