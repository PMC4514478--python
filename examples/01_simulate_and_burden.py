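"""Simulate a case/control cohort and compare minor-allele burden (MAC).

Builds a cohort in which 20% of SNPs carry small positive minor-allele
effects — a diffuse polygenic burden — then orients minor alleles from the
control sample, computes each individual's minor allele content (minor-allele
copies / assayed allele slots), and compares the case and control
distributions with a one-way ANOVA.
"""

import maburden as mb

cfg = mb.SimulationConfig(n_cases=500, n_controls=500, n_snps=5000,
                          n_risk_snps=1000, effect_mean=0.1, effect_sd=0.02,
                          missing_rate=0.01, seed=8)
matrix, truth = mb.simulate_cohort(cfg)
print(f"cohort: {matrix.is_case.sum()} cases, {matrix.is_control.sum()} controls, "
      f"{matrix.n_variants} SNPs ({truth.table['is_risk'].sum()} with true effects)")

ma_set = mb.compute_control_maf(matrix, maf_ceiling=0.4)
print(f"informative SNPs with control MAF < 0.4: {ma_set.informative.sum()}")

mac = mb.compute_mac(matrix, ma_set).table
case_mac = mac.loc[mac["phenotype"] == 1, "mac"]
ctrl_mac = mac.loc[mac["phenotype"] == 0, "mac"]
f_stat, p = mb.compare_group_means({"case": case_mac, "control": ctrl_mac})

print(f"mean MAC cases    {case_mac.mean():.5f}")
print(f"mean MAC controls {ctrl_mac.mean():.5f}")
print(f"one-way ANOVA     F = {f_stat:.2f}, p = {p:.3g}")
print("A small upward shift of case MAC with a significant ANOVA p is the")
print("burden signature: cases carry slightly more minor alleles per assayed")
print("allele slot than controls.")
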