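"""Minor-allele statistics: MA determination, MAC burden, per-SNP logistic fits.

The burden statistic here is the minor allele content (MAC): for each
individual, the number of minor-allele copies carried across informative
SNPs divided by the total number of assayed allele slots (2 x called SNPs),
giving a per-allele proportion in [0, 1].  Minor alleles are oriented from
the *control* sample's allele frequencies, and SNPs that cannot be oriented
(control MAF exactly 0.5, or MAF 0 in both groups) are flagged
non-informative and excluded from burdens and models.

Per-SNP association weights come from a univariate logistic regression of
case status on minor-allele copy count (0/1/2) with intercept.  Because a
genotype takes only three values, each SNP's likelihood depends on the data
only through six counts (genotype x phenotype), so all SNPs are fitted
simultaneously with a Newton/IRLS iteration vectorized across SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeMatrix, MISSING

#: |log-odds| beyond which a univariate fit is treated as separated
_SEPARATION_BOUND = 15.0


@dataclass
class MinorAlleleSet:
    """Per-SNP minor-allele orientation derived from control frequencies.

    ``table`` columns: ``snp_id``, ``minor_allele``, ``control_maf``,
    ``case_maf``, ``informative``.  ``minor_is_counted`` marks whether the
    matrix's counted allele already is the minor allele (otherwise calls are
    flipped g -> 2-g when counting minor copies).
    """

    table: pd.DataFrame
    maf_ceiling: float | None = None

    @property
    def informative(self) -> np.ndarray:
        return self.table["informative"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class MacProfile:
    """Per-individual minor-allele content over informative SNPs.

    ``table`` columns: ``sample_id``, ``phenotype``, ``minor_copies``,
    ``called_snps``, ``mac``.  ``mac`` is NaN for a sample with zero called
    informative SNPs.
    """

    table: pd.DataFrame

    @property
    def mac(self) -> np.ndarray:
        return self.table["mac"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class AssociationTable:
    """Per-SNP logistic association results, minor-allele oriented.

    ``table`` columns: ``snp_id``, ``coef`` (log-odds per minor-allele copy),
    ``se``, ``p_value``, ``case_maf``, ``control_maf``, ``converged``.
    Non-converged or separated SNPs carry NaN coefficients and are excluded
    from risk models downstream.
    """

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---- allele frequencies and MA orientation -----------------------------------

def _allele_freq(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counted-allele frequency and called-sample count per SNP (missing excluded)."""
    called = (calls != MISSING).sum(axis=0)
    copies = np.where(calls == MISSING, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, copies / (2.0 * called), np.nan)
    return freq, called


def compute_control_maf(matrix: GenotypeMatrix,
                        maf_ceiling: float | None = None) -> MinorAlleleSet:
    """Determine each SNP's minor allele from the control sample.

    The minor allele is the less frequent of the two alleles among control
    calls (missing genotypes excluded from denominators).  Non-informative
    SNPs are flagged rather than dropped: control MAF exactly 0.5 (no minor
    allele), MAF 0 in both cases and controls (monomorphic everywhere), and
    SNPs with no control calls at all.  If ``maf_ceiling`` is given, SNPs at
    or above it are additionally flagged uninformative (the ceiling used is
    recorded on the result).
    """
    ctrl_freq, ctrl_called = _allele_freq(matrix.calls[matrix.is_control, :])
    case_freq, _ = _allele_freq(matrix.calls[matrix.is_case, :])

    counted = matrix.variants["counted_allele"].to_numpy()
    a1 = matrix.variants["allele1"].to_numpy()
    a2 = matrix.variants["allele2"].to_numpy()
    other = np.where(counted == a1, a2, a1)

    with np.errstate(invalid="ignore"):
        counted_is_minor = ctrl_freq < 0.5
        tie = ctrl_freq == 0.5
    minor_allele = np.where(counted_is_minor, counted, other)
    with np.errstate(invalid="ignore"):
        control_maf = np.where(counted_is_minor, ctrl_freq, 1.0 - ctrl_freq)
        case_maf_minor = np.where(counted_is_minor, case_freq, 1.0 - case_freq)

    no_ctrl = ctrl_called == 0
    with np.errstate(invalid="ignore"):
        zero_both = (control_maf == 0) & ((case_maf_minor == 0) | np.isnan(case_maf_minor))
    informative = ~(tie | no_ctrl | zero_both)
    informative &= ~np.isnan(ctrl_freq)
    if maf_ceiling is not None:
        with np.errstate(invalid="ignore"):
            informative &= control_maf < maf_ceiling

    table = pd.DataFrame({
        "snp_id": matrix.variants["snp_id"].to_numpy(),
        "minor_allele": np.where(no_ctrl, "?", minor_allele),
        "control_maf": control_maf,
        "case_maf": case_maf_minor,
        "informative": informative,
        "minor_is_counted": counted_is_minor | no_ctrl,
    })
    return MinorAlleleSet(table=table, maf_ceiling=maf_ceiling)


def minor_allele_calls(matrix: GenotypeMatrix, ma_set: MinorAlleleSet) -> np.ndarray:
    """Calls re-expressed as minor-allele copy counts (missing stays -1)."""
    if len(ma_set.table) != matrix.n_variants or \
            not (ma_set.table["snp_id"].to_numpy() == matrix.variants["snp_id"].to_numpy()).all():
        raise ValueError("minor-allele set does not match the matrix variant panel")
    calls = matrix.calls.copy()
    flip = ~ma_set.table["minor_is_counted"].to_numpy()
    sub = calls[:, flip]
    nonmiss = sub != MISSING
    sub[nonmiss] = 2 - sub[nonmiss]
    calls[:, flip] = sub
    return calls


# ---- MAC burden --------------------------------------------------------------

def compute_mac(matrix: GenotypeMatrix, ma_set: MinorAlleleSet) -> MacProfile:
    """Per-individual minor allele content over informative SNPs.

    MAC = minor-allele copies / (2 x called informative SNPs); missing
    genotypes drop out of both numerator and denominator.  A sample with no
    called informative SNP gets NaN (flagged, not zero).
    """
    mac_calls = minor_allele_calls(matrix, ma_set)[:, ma_set.informative]
    called = (mac_calls != MISSING).sum(axis=1)
    copies = np.where(mac_calls == MISSING, 0, mac_calls).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mac = np.where(called > 0, copies / (2.0 * called), np.nan)
    return MacProfile(table=pd.DataFrame({
        "sample_id": matrix.samples["sample_id"].to_numpy(),
        "phenotype": matrix.samples["phenotype"].to_numpy(),
        "minor_copies": copies,
        "called_snps": called,
        "mac": mac,
    }))


def compare_group_means(values_by_group: dict) -> tuple[float, float]:
    """One-way ANOVA across groups (e.g. case vs control MAC distributions).

    Returns ``(F, p)``.  Degenerate input with zero within-group variance and
    equal means returns ``(0.0, 1.0)`` by convention.
    """
    groups = [np.asarray(v, dtype=np.float64) for v in values_by_group.values()]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    means = [g.mean() for g in groups]
    if all(g.var() == 0 for g in groups) and len(set(means)) == 1:
        return 0.0, 1.0
    f, p = sps.f_oneway(*groups)
    if np.isnan(f):
        return 0.0, 1.0
    return float(f), float(p)


# ---- per-SNP logistic association --------------------------------------------

def _logistic_irls_grouped(counts: np.ndarray, tol: float = 1e-8,
                           max_iter: int = 50):
    """Newton/IRLS logistic fits vectorized across SNPs via sufficient stats.

    ``counts``: (m, 3, 2) array of sample counts by genotype (0/1/2 minor
    copies) and phenotype (control, case).  Fits logit P(case) = b0 + b1*g
    per SNP.  Returns (b0, b1, se1, converged).
    """
    counts = counts.astype(np.float64)
    m = counts.shape[0]
    g = np.array([0.0, 1.0, 2.0])
    n_tot = counts.sum(axis=2)            # (m, 3) samples per genotype
    n_case = counts[:, :, 1]              # (m, 3) cases per genotype

    b0 = np.zeros(m)
    b1 = np.zeros(m)
    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = b0[:, None] + b1[:, None] * g[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n_tot * mu * (1.0 - mu)
        r = n_case - n_tot * mu
        # gradient and 2x2 Hessian of the log-likelihood
        g0 = r.sum(axis=1)
        g1 = (r * g).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * g).sum(axis=1)
        h11 = (w * g * g).sum(axis=1)
        det = h00 * h11 - h01 * h01
        bad = ~(det > 1e-12)
        det_safe = np.where(bad, 1.0, det)
        d0 = (h11 * g0 - h01 * g1) / det_safe
        d1 = (h00 * g1 - h01 * g0) / det_safe
        d0[bad] = 0.0
        d1[bad] = 0.0
        step = np.maximum(np.abs(d0), np.abs(d1))
        upd = active.copy()
        b0[upd] += d0[upd]
        b1[upd] += d1[upd]
        newly = active & (step < tol) & ~bad
        converged |= newly
        active &= ~newly
        active &= ~bad
        active &= np.abs(b1) < _SEPARATION_BOUND  # runaway => separation

    separated = np.abs(b1) >= _SEPARATION_BOUND
    converged &= ~separated
    # Wald SE of b1 from the inverse Hessian at the optimum
    eta = b0[:, None] + b1[:, None] * g[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = n_tot * mu * (1.0 - mu)
    h00 = w.sum(axis=1)
    h01 = (w * g).sum(axis=1)
    h11 = (w * g * g).sum(axis=1)
    det = h00 * h11 - h01 * h01
    with np.errstate(invalid="ignore", divide="ignore"):
        se1 = np.sqrt(np.where(det > 0, h00 / det, np.nan))
    return b0, b1, se1, converged


def fit_snp_logistic(genotypes: np.ndarray, phenotype: np.ndarray,
                     tol: float = 1e-8, max_iter: int = 50
                     ) -> tuple[float, float, float, bool]:
    """Univariate logistic fit of case status on one SNP's copy counts.

    ``genotypes``: per-sample minor-allele copies with -1 for missing;
    ``phenotype``: 1=case, 0=control.  Returns
    ``(coefficient, se, p_value, converged)``; a constant genotype or a
    separated fit comes back non-converged with NaN coefficient.
    """
    tab = fit_association(np.asarray(genotypes).reshape(-1, 1),
                          np.asarray(phenotype), tol=tol, max_iter=max_iter)
    row = tab.iloc[0]
    return float(row["coef"]), float(row["se"]), float(row["p_value"]), bool(row["converged"])


def fit_association(geno: np.ndarray, phenotype: np.ndarray,
                    tol: float = 1e-8, max_iter: int = 50) -> pd.DataFrame:
    """Fit every SNP column of ``geno`` (minor-copy counts, -1 missing).

    Returns a frame with coef / se / p_value / converged per column; SNPs
    with a constant genotype among called samples, fewer than one case or
    one control called, or a separated likelihood are flagged non-converged.
    """
    geno = np.asarray(geno)
    pheno = np.asarray(phenotype)
    m = geno.shape[1]
    counts = np.zeros((m, 3, 2), dtype=np.int64)
    for gval in (0, 1, 2):
        mask = geno == gval
        counts[:, gval, 0] = (mask & (pheno == 0)[:, None]).sum(axis=0)
        counts[:, gval, 1] = (mask & (pheno == 1)[:, None]).sum(axis=0)

    n_by_geno = counts.sum(axis=2)
    n_case = counts[:, :, 1].sum(axis=1)
    n_ctrl = counts[:, :, 0].sum(axis=1)
    nonconstant = (n_by_geno > 0).sum(axis=1) >= 2
    fitable = nonconstant & (n_case >= 1) & (n_ctrl >= 1)

    b0 = np.full(m, np.nan)
    b1 = np.full(m, np.nan)
    se1 = np.full(m, np.nan)
    conv = np.zeros(m, dtype=bool)
    if fitable.any():
        r0, r1, rse, rconv = _logistic_irls_grouped(counts[fitable], tol, max_iter)
        b0[fitable], b1[fitable], se1[fitable], conv[fitable] = r0, r1, rse, rconv
    conv &= np.isfinite(b1) & np.isfinite(se1) & (se1 > 0)
    b1[~conv] = np.nan
    se1[~conv] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        z = b1 / se1
        p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.where(conv, np.clip(p, np.nextafter(0, 1), 1.0), np.nan)
    return pd.DataFrame({"coef": b1, "se": se1, "p_value": p, "converged": conv,
                         "intercept": b0})


def fit_all_snps(matrix: GenotypeMatrix, ma_set: MinorAlleleSet,
                 tol: float = 1e-8, max_iter: int = 50) -> AssociationTable:
    """Per-SNP logistic association of case status on minor-allele copies.

    Only informative SNPs are fitted; others carry NaN rows.  Coefficients
    are log-odds per minor-allele copy, so a positive coefficient means the
    minor allele is enriched in cases.
    """
    mac_calls = minor_allele_calls(matrix, ma_set)
    pheno = matrix.samples["phenotype"].to_numpy()
    use = np.isin(pheno, (0, 1))
    fits = fit_association(mac_calls[use][:, ma_set.informative],
                           pheno[use], tol=tol, max_iter=max_iter)
    m = matrix.n_variants
    out = pd.DataFrame({
        "snp_id": matrix.variants["snp_id"].to_numpy(),
        "coef": np.full(m, np.nan),
        "se": np.full(m, np.nan),
        "p_value": np.full(m, np.nan),
        "case_maf": ma_set.table["case_maf"].to_numpy(),
        "control_maf": ma_set.table["control_maf"].to_numpy(),
        "converged": np.zeros(m, dtype=bool),
    })
    idx = np.flatnonzero(ma_set.informative)
    out.loc[idx, "coef"] = fits["coef"].to_numpy()
    out.loc[idx, "se"] = fits["se"].to_numpy()
    out.loc[idx, "p_value"] = fits["p_value"].to_numpy()
    out.loc[idx, "converged"] = fits["converged"].to_numpy()
    return AssociationTable(table=out)


# ---- MAF-binned average risk -------------------------------------------------

def maf_binned_average_risk(association: AssociationTable, ma_set: MinorAlleleSet,
                            matrix: GenotypeMatrix, bins: int = 5,
                            maf_ceiling: float = 0.4) -> pd.DataFrame:
    """Average per-SNP weighted risk score within equal-width MAF bins.

    SNPs are partitioned by control MAF into ``bins`` equal-width intervals
    over (0, maf_ceiling].  Within each bin, every sample's weighted score
    restricted to the bin's SNPs (coefficient x copies/2) is summed, the
    cohort mean taken, and divided by the bin's SNP count: the mean per-SNP
    contribution of that frequency class.  Empty bins are absent from the
    output rather than zero.
    """
    edges = np.linspace(0.0, maf_ceiling, bins + 1)
    tab = association.table
    usable = tab["converged"].to_numpy() & ma_set.informative
    maf = tab["control_maf"].to_numpy()
    coef = np.where(usable, tab["coef"].to_numpy(), 0.0)
    dosage = minor_allele_calls(matrix, ma_set).astype(np.float64)
    dosage[dosage == MISSING] = 0.0
    dosage /= 2.0

    rows = []
    for b in range(bins):
        lo, hi = edges[b], edges[b + 1]
        with np.errstate(invalid="ignore"):
            in_bin = usable & (maf > lo) & (maf <= hi)
        n_snps = int(in_bin.sum())
        if n_snps == 0:
            continue
        per_sample = dosage[:, in_bin] @ coef[in_bin]
        rows.append((lo, hi, n_snps, per_sample.mean() / n_snps))
    return pd.DataFrame(rows, columns=["maf_low", "maf_high", "n_snps",
                                       "mean_score_per_snp"])
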