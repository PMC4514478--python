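"""Round-trip PLINK text files and run the QC battery.

Writes a simulated cohort to PED/MAP, reads it back, then applies the QC
filters in their fixed order: duplicate removal, ancestry-outlier exclusion
on GRM principal components, missingness/MAF floors, and the exact
Hardy-Weinberg test in controls.
"""

import tempfile
from pathlib import Path

import maburden as mb

cfg = mb.SimulationConfig(n_cases=200, n_controls=200, n_snps=1000,
                          n_risk_snps=0, missing_rate=0.03, seed=12)
matrix, _ = mb.simulate_cohort(cfg)

with tempfile.TemporaryDirectory() as tmp:
    prefix = Path(tmp) / "cohort"
    mb.write_ped_map(matrix, prefix)
    ped_kb = (prefix.with_suffix(".ped")).stat().st_size / 1024
    print(f"wrote {prefix}.ped ({ped_kb:.0f} KiB) and {prefix}.map")
    back = mb.read_ped_map(f"{prefix}.ped", f"{prefix}.map")
    print(f"read back {back.n_samples} samples x {back.n_variants} SNPs")

filtered, report = mb.run_qc(matrix)
print("\nQC report (filters applied in order):")
print(report.to_frame().to_string(index=False))
print(f"\n{filtered.n_samples} samples x {filtered.n_variants} SNPs survive QC.")
print("On clean simulated data only the exact HWE test removes anything, and")
print("only at roughly its nominal false-positive rate.")
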