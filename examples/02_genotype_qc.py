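"""From a HipSTR-dialect VCF to a QC'd dosage matrix.

Simulates a small family cohort with call-level noise, writes its VCF,
re-reads it, applies the three call filters (posterior >= 0.90, flank-indel
and stutter read fractions <= 0.15), and reports locus-level QC: presence
rate, PIC and the polymorphism class mix.
"""

import tempfile
from pathlib import Path

from strdose import SimConfig, simulate_cohort, simulate_str_vcf
from strdose.genotypes import dosage_matrix, filter_calls, filter_loci, hwe_test, genotype_counts, locus_qc, read_str_vcf

cfg = SimConfig(seed=8, n_families=20, offspring_per_family=4, n_loci=120)
cohort = simulate_cohort(cfg)

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "calls.vcf"
    simulate_str_vcf(cohort, vcf)
    raw = read_str_vcf(vcf)
    kept = filter_calls(raw)
    print(f"calls: {len(raw.calls)} raw -> {len(kept.calls)} after QC "
          f"({1 - len(kept.calls) / len(raw.calls):.1%} removed)")

    dm = dosage_matrix(kept)
    gwas_ready = filter_loci(dm, purpose="gwas")     # presence rate > 0.2
    grm_ready = filter_loci(dm, purpose="grm")       # missing rate < 0.1
    print(f"loci: {len(dm.locus_ids)} called, {len(gwas_ready.locus_ids)} usable for "
          f"association, {len(grm_ready.locus_ids)} for the relationship matrix")

    qc = locus_qc(dm)
    mix = qc["polymorphism_class"].value_counts(normalize=True)
    print("polymorphism classes (PIC<0.25 low, 0.25-0.5 medium, >0.5 high):")
    print(mix.round(3).to_string())

    locus = dm.locus_ids[0]
    res = hwe_test(genotype_counts(dm, locus), n_perm=2000, seed=1)
    print(f"HWE Monte-Carlo p at {locus}: {res.p_value:.3f} "
          "(large p: genotype frequencies consistent with random mating)")
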