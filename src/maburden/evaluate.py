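"""Model evaluation: ROC/AUC, TPR at 100% specificity, sweeps, cross-validation.

The two headline metrics of the risk models are the area under the ROC
curve (probability that a random case outscores a random control, ties
half-credit) and the true positive rate at 100% specificity: the fraction
of cases scoring strictly above the highest control score, i.e. detectable
with zero false positives.  AUC confidence intervals use the DeLong
variance estimator; the TPR, being a binomial proportion, gets an exact
Clopper-Pearson interval.

Validation designs mirror the standard two-cohort workflow: an external
validation (train on one cohort, score a second through the shared SNP
panel), a stratified k-fold internal cross-validation in which the minor
allele set and all coefficients are re-derived inside each training split
(no leakage into the held-out fold), and a model sweep over MAF ceilings
and p-value thresholds plus a haplotype-representative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .io import GenotypeMatrix, intersect_panels
from .stats import (AssociationTable, MinorAlleleSet, compute_control_maf,
                    fit_all_snps)
from .scoring import (RiskModel, ScoreProfile, EmptyModelError,
                      train_risk_model, score_individuals, reduce_model_to_panel)
from .haplotype import build_blocks, select_representatives


# ---- ROC primitives ----------------------------------------------------------

def _check_groups(case_scores, control_scores):
    case_scores = np.asarray(case_scores, dtype=np.float64)
    control_scores = np.asarray(control_scores, dtype=np.float64)
    if len(case_scores) == 0 or len(control_scores) == 0:
        raise ValueError("need at least one case and one control score")
    return case_scores, control_scores


def auc(case_scores, control_scores) -> tuple[float, tuple[float, float]]:
    """Rank-sum (pair-counting) AUC with a DeLong 95% confidence interval.

    AUC is the fraction of (case, control) pairs where the case scores
    higher, ties counted half.  The DeLong variance comes from the sample
    variances of the per-observation placement values; the normal-theory
    interval is clipped to [0, 1].
    """
    cs, ks = _check_groups(case_scores, control_scores)
    m, n = len(cs), len(ks)
    all_scores = np.concatenate([cs, ks])
    ranks = sps.rankdata(all_scores)
    auc_val = (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)

    # DeLong placement values: V10_i = P(case_i > random control) with ties half
    ranks_cases = sps.rankdata(cs)
    ranks_controls = sps.rankdata(ks)
    v10 = (ranks[:m] - ranks_cases) / n
    v01 = 1.0 - (ranks[m:] - ranks_controls) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (float(np.clip(auc_val - half, 0.0, 1.0)),
          float(np.clip(auc_val + half, 0.0, 1.0)))
    return float(auc_val), ci


def tpr_full_specificity(case_scores, control_scores
                         ) -> tuple[float, tuple[float, float], float]:
    """TPR at 100% specificity with an exact binomial 95% CI.

    The operating threshold is the maximum control score; a case counts as
    detected only if it scores *strictly* above it (a case tied with the
    best control is not detected).  Returns ``(tpr, (lo, hi), threshold)``.
    """
    cs, ks = _check_groups(case_scores, control_scores)
    threshold = float(ks.max())
    detected = int((cs > threshold).sum())
    n = len(cs)
    tpr = detected / n
    lo = 0.0 if detected == 0 else float(sps.beta.ppf(0.025, detected, n - detected + 1))
    hi = 1.0 if detected == n else float(sps.beta.ppf(0.975, detected + 1, n - detected))
    return tpr, (lo, hi), threshold


def roc_curve(case_scores, control_scores) -> pd.DataFrame:
    """ROC points, one per distinct threshold, from (0,0) to (1,1).

    Point k gives the FPR and TPR of the classifier "score >= t_k" over the
    distinct observed scores t_k in descending order.  The trapezoid area
    under the polyline equals the rank-sum AUC exactly (ties walk a diagonal
    segment, which the trapezoid rule scores as half-credit).
    """
    cs, ks = _check_groups(case_scores, control_scores)
    thresholds = np.unique(np.concatenate([cs, ks]))[::-1]
    tpr = [(cs >= t).mean() for t in thresholds]
    fpr = [(ks >= t).mean() for t in thresholds]
    return pd.DataFrame({
        "fpr": np.concatenate([[0.0], fpr]),
        "tpr": np.concatenate([[0.0], tpr]),
    })


def trapezoid_auc(roc: pd.DataFrame) -> float:
    return float(np.trapezoid(roc["tpr"].to_numpy(), roc["fpr"].to_numpy()))


@dataclass
class EvaluationReport:
    """Discrimination summary of one scored case/control cohort."""

    auc: float
    auc_ci: tuple[float, float]
    tpr_full_spec: float
    tpr_ci: tuple[float, float]
    threshold_full_spec: float
    n_cases: int
    n_controls: int
    roc: pd.DataFrame = field(repr=False)
    scores: ScoreProfile | None = field(default=None, repr=False)
    model_size: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "auc": self.auc, "auc_lo": self.auc_ci[0], "auc_hi": self.auc_ci[1],
            "tpr_full_spec": self.tpr_full_spec,
            "tpr_lo": self.tpr_ci[0], "tpr_hi": self.tpr_ci[1],
            "threshold_full_spec": self.threshold_full_spec,
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "model_size": self.model_size,
        }])


def evaluate_scores(scores: ScoreProfile, model_size: int | None = None
                    ) -> EvaluationReport:
    """Full discrimination report from a scored case/control cohort."""
    cs, ks = scores.case_control_scores()
    a, a_ci = auc(cs, ks)
    t, t_ci, thr = tpr_full_specificity(cs, ks)
    return EvaluationReport(
        auc=a, auc_ci=a_ci, tpr_full_spec=t, tpr_ci=t_ci,
        threshold_full_spec=thr, n_cases=len(cs), n_controls=len(ks),
        roc=roc_curve(cs, ks), scores=scores, model_size=model_size,
    )


# ---- model specification -----------------------------------------------------

@dataclass
class ModelSpec:
    """Selection rule for one risk model in a sweep or validation run."""

    maf_ceiling: float = 0.4
    p_threshold: float = 0.05
    direction: str = "cases_enriched"
    use_haplotype: bool = False
    #: LD-block parameters, used only when use_haplotype is set
    window_bp: int = 200_000
    r2_min: float = 0.5

    def label(self) -> str:
        base = "haplotype" if self.use_haplotype else f"maf<{self.maf_ceiling:g}"
        return f"{base}, p<{self.p_threshold:g}"


def _train_on(matrix: GenotypeMatrix, spec: ModelSpec,
              training_id: str = "train") -> tuple[RiskModel, MinorAlleleSet]:
    """Derive the MA set, association table and risk model from one cohort."""
    ma_set = compute_control_maf(matrix)
    assoc = fit_all_snps(matrix, ma_set)
    model = train_risk_model(assoc, ma_set, maf_ceiling=spec.maf_ceiling,
                             p_threshold=spec.p_threshold,
                             direction=spec.direction, training_id=training_id)
    if spec.use_haplotype:
        blocks = build_blocks(matrix, window_bp=spec.window_bp, r2_min=spec.r2_min)
        reps = set(select_representatives(blocks, assoc, ma_set,
                                          maf_ceiling=spec.maf_ceiling,
                                          p_threshold=spec.p_threshold))
        keep = model.table["snp_id"].isin(reps)
        if not keep.any():
            raise EmptyModelError("no haplotype representative met the criteria")
        model = RiskModel(table=model.table.loc[keep].reset_index(drop=True),
                          criteria=dict(model.criteria, haplotype=True))
    return model, ma_set


# ---- external validation -----------------------------------------------------

def external_validate(train: GenotypeMatrix, test: GenotypeMatrix,
                      spec: ModelSpec | None = None) -> EvaluationReport:
    """Train wholly on one cohort, score an independent cohort.

    Panels are harmonized by :func:`intersect_panels` (matching the training
    orientation), the model reduced to the shared SNPs, and the held-out
    cohort scored and summarized.  Minor-allele orientation comes from the
    *training* controls throughout.
    """
    spec = spec or ModelSpec()
    model, _ = _train_on(train, spec)  # full training panel, no peeking at test
    _, test_h = intersect_panels(train, test)
    model = reduce_model_to_panel(model, test_h.variants["snp_id"])
    scores = score_individuals(model, test_h)
    return evaluate_scores(scores, model_size=model.n_snps)


def control_only_validation(model: RiskModel, control_matrix: GenotypeMatrix,
                            case_scores: np.ndarray) -> tuple[float, float]:
    """Fraction of cases scoring above every control in an external control bank.

    The model is reduced to the control panel, all controls scored, and the
    given case scores compared against the pooled control maximum with the
    strict-inequality rule.  Returns ``(case_fraction, threshold)``.
    """
    reduced = reduce_model_to_panel(model, control_matrix.variants["snp_id"])
    ctrl_scores = score_individuals(reduced, control_matrix).scores
    threshold = float(ctrl_scores.max())
    case_scores = np.asarray(case_scores, dtype=np.float64)
    return float((case_scores > threshold).mean()), threshold


# ---- sweep -------------------------------------------------------------------

@dataclass
class SweepResult:
    """Long-format grid of (model, p-threshold) evaluation cells."""

    table: pd.DataFrame

    def best(self) -> pd.Series:
        return self.table.loc[self.table["auc"].idxmax()]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


DEFAULT_MAF_CEILINGS = (0.1, 0.2, 0.3, 0.4, 0.5)
DEFAULT_P_GRID = (1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5)


def model_sweep(train: GenotypeMatrix, test: GenotypeMatrix,
                maf_ceilings=DEFAULT_MAF_CEILINGS, p_grid=DEFAULT_P_GRID,
                include_haplotype: bool = True,
                direction: str = "cases_enriched",
                window_bp: int = 200_000, r2_min: float = 0.5) -> SweepResult:
    """Evaluate every (model family, p threshold) cell on the held-out cohort.

    Model families are the MAF-ceiling models (five by default) plus
    optionally the haplotype-representative model (fixed at the 0.4 ceiling).
    The association table is computed once on the harmonized training cohort
    and reused across cells.  A cell whose selection is empty is recorded
    with NaN metrics and size 0, not dropped.
    """
    train_h, test_h = intersect_panels(train, test)
    ma_set = compute_control_maf(train_h)
    assoc = fit_all_snps(train_h, ma_set)
    blocks = build_blocks(train_h, window_bp=window_bp, r2_min=r2_min) \
        if include_haplotype else None

    rows = []
    families: list[tuple[str, float, bool]] = \
        [(f"maf<{c:g}", c, False) for c in maf_ceilings]
    if include_haplotype:
        families.append(("haplotype", 0.4, True))
    for label, ceiling, is_hap in families:
        for p_thr in p_grid:
            cell = {"model": label, "maf_ceiling": ceiling, "p_threshold": p_thr,
                    "model_size": 0, "auc": np.nan, "tpr_full_spec": np.nan}
            try:
                model = train_risk_model(assoc, ma_set, maf_ceiling=ceiling,
                                         p_threshold=p_thr, direction=direction)
                if is_hap:
                    reps = set(select_representatives(blocks, assoc, ma_set,
                                                      maf_ceiling=ceiling,
                                                      p_threshold=p_thr))
                    keep = model.table["snp_id"].isin(reps)
                    if not keep.any():
                        raise EmptyModelError("no representative qualified")
                    model = RiskModel(model.table.loc[keep].reset_index(drop=True),
                                      dict(model.criteria, haplotype=True))
                model = reduce_model_to_panel(model, test_h.variants["snp_id"])
                scores = score_individuals(model, test_h)
                report = evaluate_scores(scores, model_size=model.n_snps)
                cell.update(model_size=model.n_snps, auc=report.auc,
                            tpr_full_spec=report.tpr_full_spec)
            except (EmptyModelError, ValueError):
                pass  # empty cell: absent metrics, not zero
            rows.append(cell)
    return SweepResult(table=pd.DataFrame(rows))


# ---- k-fold cross-validation -------------------------------------------------

@dataclass
class CrossValResult:
    """Per-fold and averaged discrimination metrics."""

    folds: pd.DataFrame  # fold, n_test, model_size, auc, tpr_full_spec
    mean_auc: float
    mean_tpr: float
    seed: int

    def to_tsv(self, path) -> None:
        self.folds.to_csv(path, sep="\t", index=False)


def kfold_cross_validate(matrix: GenotypeMatrix, k: int = 10,
                         spec: ModelSpec | None = None,
                         seed: int = 0) -> CrossValResult:
    """Stratified k-fold internal cross-validation.

    Samples are partitioned into k folds stratified by case status, so each
    fold holds both classes; every sample is validated exactly once.  Within
    each split, the minor-allele set and the per-SNP logistic weights are
    re-derived from the training folds only — the held-out fold contributes
    nothing to MA orientation or coefficients — and the held-out fold is
    scored and summarized.  Deterministic given ``seed``.
    """
    spec = spec or ModelSpec()
    if matrix.n_samples < k:
        raise ValueError(f"need at least k={k} samples")
    pheno = matrix.samples["phenotype"].to_numpy()
    use = np.flatnonzero(np.isin(pheno, (0, 1)))
    y = pheno[use]
    if min((y == 0).sum(), (y == 1).sum()) < k:
        raise ValueError("need >= k cases and >= k controls for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(use)), y)):
        train_m = matrix.take_samples(use[tr])
        test_m = matrix.take_samples(use[te])
        model, _ = _train_on(train_m, spec, training_id=f"fold{fold}")
        scores = score_individuals(model, test_m)
        report = evaluate_scores(scores, model_size=model.n_snps)
        rows.append((fold, len(te), model.n_snps, report.auc,
                     report.tpr_full_spec))
    folds = pd.DataFrame(rows, columns=["fold", "n_test", "model_size",
                                        "auc", "tpr_full_spec"])
    return CrossValResult(folds=folds, mean_auc=float(folds["auc"].mean()),
                          mean_tpr=float(folds["tpr_full_spec"].mean()),
                          seed=seed)
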