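"""External cross-validation through a partially shared SNP panel.

Two cohorts drawn from one generative truth are genotyped on panels sharing
only 24% of their SNPs (as happens across genotyping platforms).  The risk
model is trained wholly on the first cohort, reduced to the shared SNPs,
and evaluated on the second with AUC and the true positive rate at 100%
specificity (fraction of cases scoring above every control).
"""

import maburden as mb

cfg = mb.SimulationConfig(n_cases=500, n_controls=500, n_snps=5000,
                          n_risk_snps=50, effect_mean=0.4, effect_sd=0.05,
                          missing_rate=0.01, seed=3)
train, test, _ = mb.simulate_cohort_pair(cfg, cfg, snp_overlap_fraction=0.24)
shared = set(train.variants["snp_id"]) & set(test.variants["snp_id"])
print(f"panels: {train.n_variants} vs {test.n_variants} SNPs, {len(shared)} shared")

report = mb.external_validate(train, test, mb.ModelSpec(maf_ceiling=0.4,
                                                        p_threshold=0.05))
lo, hi = report.auc_ci
tlo, thi = report.tpr_ci
print(f"model SNPs usable on the test panel: {report.model_size}")
print(f"external AUC  {report.auc:.3f} (95% CI {lo:.3f}-{hi:.3f}, DeLong)")
print(f"TPR@100%spec  {100 * report.tpr_full_spec:.2f}% "
      f"(95% CI {100 * tlo:.2f}%-{100 * thi:.2f}%, Clopper-Pearson) "
      f"at threshold {report.threshold_full_spec:.3f}")
print("With 76% of the model SNPs lost to the panel intersection, little of")
print("the weak polygenic signal survives: held-out AUC sits near chance and")
print("the zero-false-positive TPR is small or zero.  Rerunning with")
print("snp_overlap_fraction=1.0 keeps the full model and lifts the AUC.")
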