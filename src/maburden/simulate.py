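"""Synthetic case/control cohort generator.

Produces genotype cohorts with the statistical structure the burden analysis
assumes: population minor-allele frequencies drawn from a configurable
spectrum, genotypes in Hardy-Weinberg proportions given those frequencies,
an additive minor-allele disease model on the logit scale, and independent
per-genotype missingness.  Ground truth (population MAF, risk flags, true
log-odds effects) is returned alongside the cohort so parameter-recovery
tests can compare estimates against it.

The disease model scores an individual as ``sum over risk SNPs of
(copies / 2) * effect`` so that the generative effect scale matches the
downstream scoring rule in which a heterozygote contributes half a
coefficient.  Case/control status is then Bernoulli with probability
``sigmoid(baseline + score)``, and the requested numbers of cases and
controls are filled by rejection from a stream of simulated individuals.

Linkage disequilibrium beyond HWE is off by default.  An optional block
copula mode ties adjacent SNPs together: within blocks of ``ld_block_size``
consecutive SNPs, each haplotype draws one latent uniform shared by all
member SNPs, and each SNP's allele is re-drawn independently with
probability ``ld_flip_prob``.  Marginal allele frequencies are preserved
exactly while adjacent SNPs become positively correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING, CASE, CONTROL

#: allele pairs that survive strand reconciliation (no A/T or C/G)
_UNAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                      ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults give a desk-scale analogue of a GWAS case/control cohort:
    a Beta-shaped MAF spectrum bounded away from 0 and 0.5, a small core of
    risk SNPs with positive log-odds effects of realistic polygenic size,
    and 1% genotype missingness.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_snps: int = 5000
    #: Beta(a, b) shape of the population MAF spectrum, truncated to
    #: [maf_floor, maf_ceiling]; Beta(0.8, 2.2) skews toward low frequencies
    maf_shape_a: float = 0.8
    maf_shape_b: float = 2.2
    maf_floor: float = 0.01
    maf_ceiling: float = 0.5
    n_risk_snps: int = 50
    #: per-risk-SNP log-odds effect ~ Normal(mean, sd), optionally sign-forced
    effect_mean: float = 0.2
    effect_sd: float = 0.05
    effect_sign_positive: bool = True
    baseline_log_odds: float = -1.0
    missing_rate: float = 0.01
    n_chromosomes: int = 4
    bp_spacing: int = 20_000
    #: rejection-sampling attempt cap, as a multiple of n_cases + n_controls
    max_attempt_factor: int = 100
    #: block-copula LD: block size 1 disables; flip probability controls decay
    ld_block_size: int = 1
    ld_flip_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_floor <= self.maf_ceiling <= 0.5):
            raise ValueError("need 0 < maf_floor <= maf_ceiling <= 0.5")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_risk_snps > self.n_snps:
            raise ValueError("n_risk_snps cannot exceed n_snps")
        if min(self.n_cases, self.n_controls, self.n_snps) < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


class QuotaError(RuntimeError):
    """Case/control quota unreachable within the attempt cap."""


@dataclass
class Truth:
    """Generative ground truth for one simulated SNP universe."""

    table: pd.DataFrame  # snp_id, true_maf, is_risk, true_effect
    config: SimulationConfig

    def __post_init__(self) -> None:
        t = self.table
        off_risk = t.loc[~t["is_risk"], "true_effect"]
        assert (off_risk == 0).all(), "non-risk SNPs must have zero effect"


def _draw_truth(cfg: SimulationConfig, rng: np.random.Generator,
                n_snps: int | None = None, prefix: str = "rs") -> pd.DataFrame:
    """Draw per-SNP population MAFs, risk flags and effects."""
    m = cfg.n_snps if n_snps is None else n_snps
    maf = rng.beta(cfg.maf_shape_a, cfg.maf_shape_b, size=m)
    maf = cfg.maf_floor + maf * (cfg.maf_ceiling - cfg.maf_floor)
    is_risk = np.zeros(m, dtype=bool)
    n_risk = min(cfg.n_risk_snps, m)
    is_risk[rng.choice(m, size=n_risk, replace=False)] = True
    effect = np.zeros(m)
    eff = rng.normal(cfg.effect_mean, cfg.effect_sd, size=n_risk)
    if cfg.effect_sign_positive:
        eff = np.abs(eff)
    effect[is_risk] = eff
    return pd.DataFrame({
        "snp_id": [f"{prefix}{k}" for k in range(m)],
        "true_maf": maf,
        "is_risk": is_risk,
        "true_effect": effect,
    })


def _make_variants(truth: pd.DataFrame, cfg: SimulationConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Lay variants down on synthetic autosomes with ~uniform spacing."""
    m = len(truth)
    per_chrom = np.array_split(np.arange(m), cfg.n_chromosomes)
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    for c, idx in enumerate(per_chrom, start=1):
        gaps = rng.integers(1, 2 * cfg.bp_spacing, size=len(idx))
        chrom[idx] = str(c)
        pos[idx] = np.cumsum(gaps)
    pair_idx = rng.integers(0, len(_UNAMBIGUOUS_PAIRS), size=m)
    a_major = [_UNAMBIGUOUS_PAIRS[k][0] for k in pair_idx]
    a_minor = [_UNAMBIGUOUS_PAIRS[k][1] for k in pair_idx]
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "snp_id": truth["snp_id"].to_numpy(),
        "allele1": a_major, "allele2": a_minor, "counted_allele": a_minor,
    })


def _draw_haplotypes(maf: np.ndarray, n: int, cfg: SimulationConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw one haploid allele layer (n x m of 0/1 minor-allele indicators)."""
    m = len(maf)
    if cfg.ld_block_size <= 1:
        return (rng.random((n, m)) < maf).astype(np.int8)
    # block copula: one latent uniform per (individual, block), shared by
    # member SNPs; per-SNP independent re-draw with ld_flip_prob
    block_of = np.arange(m) // cfg.ld_block_size
    n_blocks = block_of[-1] + 1
    latent = rng.random((n, n_blocks))
    hap = (latent[:, block_of] < maf).astype(np.int8)
    redraw = rng.random((n, m)) < cfg.ld_flip_prob
    indep = (rng.random((n, m)) < maf).astype(np.int8)
    hap[redraw] = indep[redraw]
    return hap


def _simulate_batch(truth: pd.DataFrame, cfg: SimulationConfig, n: int,
                    rng: np.random.Generator):
    """Simulate n individuals over the full SNP universe; returns (geno, is_case)."""
    maf = truth["true_maf"].to_numpy()
    effect = truth["true_effect"].to_numpy()
    geno = _draw_haplotypes(maf, n, cfg, rng) + _draw_haplotypes(maf, n, cfg, rng)
    dosage = geno.astype(np.float64) / 2.0
    # centre the genetic score at its population mean so baseline_log_odds
    # sets the prevalence irrespective of the risk architecture
    logit = cfg.baseline_log_odds + (dosage - maf) @ effect
    p_case = 1.0 / (1.0 + np.exp(-logit))
    is_case = rng.random(n) < p_case
    return geno, is_case


def _fill_quotas(truth: pd.DataFrame, cfg: SimulationConfig,
                 rng: np.random.Generator):
    """Rejection-sample until case/control quotas are met (bounded attempts)."""
    want = cfg.n_cases + cfg.n_controls
    cap = cfg.max_attempt_factor * want
    cases, controls, drawn = [], [], 0
    batch = max(want, 256)
    while True:
        n_case_have = sum(x.shape[0] for x in cases)
        n_ctrl_have = sum(x.shape[0] for x in controls)
        if n_case_have >= cfg.n_cases and n_ctrl_have >= cfg.n_controls:
            break
        if drawn >= cap:
            raise QuotaError(
                f"drew {drawn} individuals without filling quotas "
                f"({n_case_have}/{cfg.n_cases} cases, {n_ctrl_have}/{cfg.n_controls} controls); "
                "disease prevalence too extreme for the requested cohort"
            )
        geno, is_case = _simulate_batch(truth, cfg, batch, rng)
        drawn += batch
        if n_case_have < cfg.n_cases:
            cases.append(geno[is_case][: cfg.n_cases - n_case_have])
        if n_ctrl_have < cfg.n_controls:
            controls.append(geno[~is_case][: cfg.n_controls - n_ctrl_have])
    geno = np.vstack([np.vstack(cases), np.vstack(controls)])
    pheno = np.r_[np.full(cfg.n_cases, CASE), np.full(cfg.n_controls, CONTROL)]
    return geno.astype(np.int8), pheno


def _mask_missing(geno: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        geno = geno.copy()
        geno[rng.random(geno.shape) < rate] = MISSING
    return geno


def _assemble(geno: np.ndarray, pheno: np.ndarray, variants: pd.DataFrame,
              cfg: SimulationConfig, rng: np.random.Generator,
              id_prefix: str = "ind") -> GenotypeMatrix:
    n = len(pheno)
    samples = pd.DataFrame({
        "sample_id": [f"{id_prefix}{i}" for i in range(n)],
        "phenotype": pheno,
        "sex": rng.integers(1, 3, size=n),
    })
    return GenotypeMatrix(samples=samples, variants=variants.copy(), calls=geno)


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, Truth]:
    """Simulate one case/control cohort plus its generative ground truth.

    Fully deterministic given ``config.seed``: every stochastic draw flows
    from a single root generator.

    Raises
    ------
    QuotaError
        If the case/control quotas cannot be filled within
        ``max_attempt_factor * (n_cases + n_controls)`` simulated individuals.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    variants = _make_variants(truth, config, rng)
    geno, pheno = _fill_quotas(truth, config, rng)
    geno = _mask_missing(geno, config.missing_rate, rng)
    matrix = _assemble(geno, pheno, variants, config, rng)
    return matrix, Truth(table=truth, config=config)


def simulate_cohort_pair(config_a: SimulationConfig, config_b: SimulationConfig,
                         snp_overlap_fraction: float
                         ) -> tuple[GenotypeMatrix, GenotypeMatrix, Truth]:
    """Simulate two cohorts from one generative truth with partly shared panels.

    A SNP universe of ``n_a + n_b - n_shared`` variants is drawn once, where
    ``n_shared = round(snp_overlap_fraction * n_snps(config_a))``.  Both
    cohorts' individuals are simulated over the full universe (so disease
    status reflects every risk SNP, observed or not) and each cohort's
    delivered panel is then restricted: cohort A sees the shared SNPs plus
    its own private ones, cohort B likewise.  Shared SNPs therefore have
    identical population frequencies and effects in both cohorts.

    Randomness derives from ``config_a.seed``; ``config_b.seed`` is ignored.
    """
    if not (0 <= snp_overlap_fraction <= 1):
        raise ValueError("snp_overlap_fraction must be in [0, 1]")
    n_a, n_b = config_a.n_snps, config_b.n_snps
    n_shared = round(snp_overlap_fraction * n_a)
    if n_shared > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller panel")
    rng = np.random.default_rng(config_a.seed)

    n_universe = n_a + n_b - n_shared
    # risk SNPs drawn over the whole universe, scaled so the union carries
    # config_a's risk architecture
    cfg_u = SimulationConfig(**{**config_a.to_dict(),
                                "n_snps": n_universe,
                                "n_risk_snps": min(config_a.n_risk_snps, n_universe)})
    truth = _draw_truth(cfg_u, rng, n_snps=n_universe)
    variants = _make_variants(truth, cfg_u, rng)

    idx_a = np.arange(n_a)                                # shared block first
    idx_b = np.r_[np.arange(n_shared), np.arange(n_a, n_universe)]

    geno_a, pheno_a = _fill_quotas(truth, replace_counts(cfg_u, config_a), rng)
    geno_b, pheno_b = _fill_quotas(truth, replace_counts(cfg_u, config_b), rng)
    geno_a = _mask_missing(geno_a[:, idx_a], config_a.missing_rate, rng)
    geno_b = _mask_missing(geno_b[:, idx_b], config_b.missing_rate, rng)

    mat_a = _assemble(geno_a, pheno_a, variants.iloc[idx_a], config_a, rng, id_prefix="A")
    mat_b = _assemble(geno_b, pheno_b, variants.iloc[idx_b], config_b, rng, id_prefix="B")
    return mat_a, mat_b, Truth(table=truth, config=cfg_u)


def replace_counts(universe_cfg: SimulationConfig,
                   cohort_cfg: SimulationConfig) -> SimulationConfig:
    """Universe-wide config with one cohort's sample quotas and baseline."""
    d = universe_cfg.to_dict()
    d.update(n_cases=cohort_cfg.n_cases, n_controls=cohort_cfg.n_controls,
             baseline_log_odds=cohort_cfg.baseline_log_odds,
             max_attempt_factor=cohort_cfg.max_attempt_factor)
    return SimulationConfig(**d)


def write_truth_table(truth: Truth, path) -> None:
    """Write the ground-truth table as tab-separated text with a header."""
    truth.table.to_csv(path, sep="\t", index=False)
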