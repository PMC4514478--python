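"""Sample- and SNP-level quality control.

Implements the standard GWAS QC battery applied before burden analysis:
exact Hardy-Weinberg filtering (controls only by default), per-SNP
missingness and MAF floors, ancestry-outlier exclusion on the top principal
components of the standardized genetic relationship matrix (GRM), and
removal of duplicated individuals by genotype concordance.

The recommended filter order (applied by :func:`run_qc`) is
duplicates -> PC outliers -> missingness/MAF -> HWE, and the order actually
applied is recorded in the :class:`QCReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING


@dataclass
class FilterRecord:
    name: str
    tested: int
    removed: int
    threshold: float

    def __post_init__(self) -> None:
        assert 0 <= self.removed <= self.tested


@dataclass
class QCReport:
    """Ordered record of QC filters applied to a cohort."""

    filters: list[FilterRecord] = field(default_factory=list)

    def add(self, name: str, tested: int, removed: int, threshold: float) -> None:
        self.filters.append(FilterRecord(name, tested, removed, threshold))

    def extend(self, other: "QCReport") -> None:
        self.filters.extend(other.filters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.name, f.tested, f.removed, f.threshold) for f in self.filters],
            columns=["filter", "tested", "removed", "threshold"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---- Hardy-Weinberg exact test ----------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value for one biallelic SNP.

    Conditions on the observed allele counts and sums, over all possible
    heterozygote counts of matching parity, the probabilities of tables no
    more probable than the observed one.  Probabilities are built by the
    usual two-sided recurrence from the modal heterozygote count, which is
    numerically stable for large samples.

    Returns a p-value in (0, 1]; monomorphic SNPs (only one table possible)
    return exactly 1.0.
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # copies of the rarer allele
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # possible het counts share the parity of n_rare and are <= n_rare
    probs = _hwe_het_distribution(n, n_rare)
    p_obs = probs[n_Aa // 2 if n_rare % 2 == 0 else (n_Aa - 1) // 2]
    # sum over het counts with probability <= observed (with slack for fp noise)
    include = probs <= p_obs * (1.0 + 1e-12)
    if include.all():
        return 1.0  # observed table is modal: every table counted
    return float(min(1.0, probs[include].sum()))


def _hwe_het_distribution(n: int, n_rare: int) -> np.ndarray:
    """Conditional probabilities of each feasible heterozygote count.

    Feasible het counts run over {parity(n_rare), parity+2, ..., n_rare};
    entry k corresponds to het count ``2k + parity``.
    """
    parity = n_rare % 2
    hets = np.arange(parity, n_rare + 1, 2)
    # start from the modal het count and apply the ratio recurrence both ways
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mid % 2 != parity:
        mid += 1 if mid < n_rare else -1
    mid_idx = (mid - parity) // 2
    logp = np.empty(len(hets), dtype=np.float64)
    logp[mid_idx] = 0.0
    # P(h-2)/P(h) = h(h-1) / ((rare_hom+1)(common_hom+1) * 4)
    for i in range(mid_idx, 0, -1):
        h = hets[i]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[i - 1] = logp[i] + np.log(h * (h - 1.0)) \
            - np.log(4.0 * (rare_hom + 1.0) * (common_hom + 1.0))
    # P(h+2)/P(h) = 4*rare_hom*common_hom / ((h+2)(h+1))
    for i in range(mid_idx, len(hets) - 1):
        h = hets[i]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[i + 1] = logp[i] + np.log(4.0 * rare_hom * common_hom) \
            - np.log((h + 2.0) * (h + 1.0))
    probs = np.exp(logp - logp.max())
    return probs / probs.sum()


def _genotype_counts(matrix: GenotypeMatrix, sample_mask: np.ndarray) -> np.ndarray:
    """Per-SNP genotype counts (n_variants x 3) over the masked samples."""
    calls = matrix.calls[sample_mask, :]
    return np.stack([(calls == g).sum(axis=0) for g in (0, 1, 2)], axis=1)


def filter_hwe(matrix: GenotypeMatrix, alpha: float = 0.01,
               population: str = "controls") -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs whose exact HWE p-value is <= alpha.

    The test population defaults to controls, the usual case/control
    convention (cases may deviate from HWE at true risk loci).
    """
    if population not in ("controls", "all"):
        raise ValueError("population must be 'controls' or 'all'")
    mask = matrix.is_control if population == "controls" else np.ones(matrix.n_samples, bool)
    counts = _genotype_counts(matrix, mask)
    keep = np.ones(matrix.n_variants, dtype=bool)
    for j in range(matrix.n_variants):
        c = counts[j]
        if c.sum() == 0:
            continue  # untestable; retained
        keep[j] = hwe_exact_test(c[0], c[1], c[2]) > alpha
    report = QCReport()
    report.add(f"hwe_{population}", matrix.n_variants, int((~keep).sum()), alpha)
    return matrix.take_variants(np.flatnonzero(keep)), report


def filter_missing_and_maf(matrix: GenotypeMatrix, max_missing: float = 0.05,
                           min_maf: float = 1e-4) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with missingness strictly above ``max_missing`` or control
    MAF strictly below ``min_maf``.

    Boundary convention is strict on both sides: a SNP at exactly 5%
    missingness or exactly the MAF floor is retained.
    """
    miss_frac = matrix.missing_mask.mean(axis=0) if matrix.n_samples else \
        np.zeros(matrix.n_variants)
    ctrl = matrix.calls[matrix.is_control, :]
    called = (ctrl != MISSING).sum(axis=0)
    copies = np.where(ctrl == MISSING, 0, ctrl).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, copies / (2.0 * called), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    with np.errstate(invalid="ignore"):
        remove = (miss_frac > max_missing) | (maf < min_maf)  # nan MAF -> not removed here
    report = QCReport()
    report.add("missingness", matrix.n_variants,
               int((miss_frac > max_missing).sum()), max_missing)
    report.add("maf_floor", matrix.n_variants,
               int(((maf < min_maf) & ~np.isnan(maf)).sum()), min_maf)
    return matrix.take_variants(np.flatnonzero(~remove)), report


# ---- GRM / PCA ---------------------------------------------------------------

def genetic_relationship_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Standardized GRM: per-SNP (g - 2p)/sqrt(2p(1-p)), averaged pairwise
    over SNPs where both samples are called."""
    calls = matrix.calls.astype(np.float64)
    called = matrix.calls != MISSING
    calls[~called] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic SNPs to build a GRM")
    z = (calls[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    z[np.isnan(z)] = 0.0  # missing contributes 0 to numerator
    counts = called[:, poly].astype(np.float64)
    denom = counts @ counts.T
    denom[denom == 0] = np.nan
    return (z @ z.T) / denom


def genetic_relationship_pca(matrix: GenotypeMatrix, n_components: int = 3
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Top principal components of the GRM, for ancestry outlier screening.

    Returns ``(pcs, eigenvalues)``: ``pcs`` is samples x n_components
    (eigenvectors ordered by non-increasing eigenvalue).
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples for PCA")
    grm = genetic_relationship_matrix(matrix)
    grm = np.nan_to_num(grm, nan=0.0)
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1][:n_components]
    return vecs[:, order], vals[order]


def exclude_pc_outliers(pcs: np.ndarray, sample_ids, sd_multiplier: float = 6.0
                        ) -> tuple[list, QCReport]:
    """Single-pass outlier exclusion: a sample is removed if any of the first
    three components is more than ``sd_multiplier`` SDs from that component's
    mean.  Returns the kept sample ids."""
    pcs = np.asarray(pcs, dtype=np.float64)
    use = pcs[:, : min(3, pcs.shape[1])]
    mean = use.mean(axis=0)
    sd = use.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf  # constant component cannot flag anyone
    outlier = (np.abs(use - mean) > sd_multiplier * sd).any(axis=1)
    kept = [sid for sid, out in zip(sample_ids, outlier) if not out]
    report = QCReport()
    report.add("pc_outliers", len(pcs), int(outlier.sum()), sd_multiplier)
    return kept, report


# ---- duplicates --------------------------------------------------------------

def remove_duplicates(matrix: GenotypeMatrix, concordance_threshold: float = 0.99,
                      max_snps: int = 10_000) -> tuple[GenotypeMatrix, QCReport]:
    """Drop the later member of any sample pair whose non-missing genotype
    concordance reaches the threshold (computed on up to ``max_snps`` SNPs).

    Which member survives is deterministic: the sample that appears first in
    the cohort is kept.
    """
    if not (0.5 < concordance_threshold <= 1.0):
        raise ValueError("concordance_threshold must be in (0.5, 1]")
    calls = matrix.calls[:, : min(max_snps, matrix.n_variants)]
    called = (calls != MISSING).astype(np.float64)
    matches = np.zeros((matrix.n_samples, matrix.n_samples))
    for g in (0, 1, 2):
        ind = ((calls == g).astype(np.float64))
        matches += ind @ ind.T
    both = called @ called.T
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(both > 0, matches / both, 0.0)
    drop = np.zeros(matrix.n_samples, dtype=bool)
    dup_i, dup_j = np.nonzero(np.triu(conc >= concordance_threshold, k=1))
    for i, j in zip(dup_i, dup_j):
        if not drop[i]:
            drop[j] = True
    report = QCReport()
    report.add("duplicates", matrix.n_samples, int(drop.sum()), concordance_threshold)
    return matrix.take_samples(np.flatnonzero(~drop)), report


# ---- composite ---------------------------------------------------------------

def run_qc(matrix: GenotypeMatrix, *, hwe_alpha: float = 0.01,
           hwe_population: str = "controls", max_missing: float = 0.05,
           min_maf: float = 1e-4, pc_sd_multiplier: float = 6.0,
           concordance_threshold: float = 0.99,
           skip_pca: bool = False) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC battery in the fixed order duplicates -> PC outliers ->
    missingness/MAF -> HWE; the order is recorded in the returned report."""
    report = QCReport()
    matrix, r = remove_duplicates(matrix, concordance_threshold)
    report.extend(r)
    if not skip_pca:
        pcs, _ = genetic_relationship_pca(matrix, n_components=3)
        kept, r = exclude_pc_outliers(pcs, matrix.samples["sample_id"], pc_sd_multiplier)
        report.extend(r)
        keep_idx = np.flatnonzero(matrix.samples["sample_id"].isin(kept).to_numpy())
        matrix = matrix.take_samples(keep_idx)
    matrix, r = filter_missing_and_maf(matrix, max_missing, min_maf)
    report.extend(r)
    matrix, r = filter_hwe(matrix, hwe_alpha, hwe_population)
    report.extend(r)
    return matrix, report
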