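import numpy as np
import pandas as pd
import pytest

from maburden import (GenotypeMatrix, SimulationConfig, simulate_cohort)


def make_matrix(calls, phenotypes, chrom=None, pos=None, alleles=None):
    """Hand-build a small GenotypeMatrix for targeted unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if alleles is None:
        alleles = [("A", "G")] * m
    variants = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else list(range(1000, 1000 + 1000 * m, 1000)),
        "snp_id": [f"snp{j}" for j in range(m)],
        "allele1": [a for a, _ in alleles],
        "allele2": [b for _, b in alleles],
        "counted_allele": [a for a, _ in alleles],
    })
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "phenotype": phenotypes,
        "sex": [1] * n,
    })
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no risk SNPs: the null hypothesis holds exactly."""
    cfg = SimulationConfig(n_cases=150, n_controls=150, n_snps=400,
                           n_risk_snps=0, missing_rate=0.01, seed=42)
    matrix, truth = simulate_cohort(cfg)
    return matrix, truth


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with strong positive minor-allele effects for direction checks."""
    cfg = SimulationConfig(n_cases=300, n_controls=300, n_snps=600,
                           n_risk_snps=60, effect_mean=1.2, effect_sd=0.1,
                           missing_rate=0.01, seed=7)
    matrix, truth = simulate_cohort(cfg)
    return matrix, truth
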