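"""Weighted minor-allele risk models: training, scoring, panel reduction.

A risk model is a set of SNPs selected from a training cohort's association
table — control MAF below a ceiling, association p below a threshold, and
(by default) minor allele more frequent in cases than controls — each
carrying its logistic coefficient as a weight.  An individual's total
weighted risk score sums, over model SNPs, the coefficient for a
homozygous-minor genotype and half the coefficient for a heterozygote;
missing genotypes contribute nothing and are excluded from the used-SNP
count.  No per-sample renormalization is applied when a model is reduced to
a smaller shared panel: the raw sum is the score, and an optional
per-used-SNP normalized column is provided for users who want one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING
from .stats import AssociationTable, MinorAlleleSet, minor_allele_calls, compute_control_maf

log = logging.getLogger(__name__)


@dataclass
class RiskModel:
    """Selected SNPs with minor-allele orientation and coefficient weights.

    ``table`` columns: ``snp_id``, ``minor_allele``, ``weight``,
    ``control_maf``, ``p_value``.  ``criteria`` records the selection rule
    that produced the model.
    """

    table: pd.DataFrame
    criteria: dict

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ScoreProfile:
    """Per-sample total weighted risk scores.

    ``table`` columns: ``sample_id``, ``phenotype``, ``score``,
    ``snps_used`` (model SNPs with a called genotype), ``score_per_snp``
    (score / snps_used, NaN when no SNP was usable).
    """

    table: pd.DataFrame

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    def case_control_scores(self) -> tuple[np.ndarray, np.ndarray]:
        s = self.table
        return (s.loc[s["phenotype"] == 1, "score"].to_numpy(),
                s.loc[s["phenotype"] == 0, "score"].to_numpy())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class EmptyModelError(ValueError):
    """No SNP satisfied the model selection criteria."""


def train_risk_model(association: AssociationTable, ma_set: MinorAlleleSet,
                     maf_ceiling: float = 0.4, p_threshold: float = 0.05,
                     direction: str = "cases_enriched",
                     training_id: str = "train") -> RiskModel:
    """Select model SNPs: control MAF < ceiling, p < threshold (strict),
    converged fits only, and under the default direction rule the minor
    allele must be more frequent in cases than in controls.
    """
    if direction not in ("cases_enriched", "any"):
        raise ValueError("direction must be 'cases_enriched' or 'any'")
    tab = association.table
    with np.errstate(invalid="ignore"):
        sel = (
            tab["converged"].to_numpy()
            & ma_set.informative
            & (tab["control_maf"].to_numpy() < maf_ceiling)
            & (tab["p_value"].to_numpy() < p_threshold)
        )
        if direction == "cases_enriched":
            sel &= tab["case_maf"].to_numpy() > tab["control_maf"].to_numpy()
    criteria = {"maf_ceiling": maf_ceiling, "p_threshold": p_threshold,
                "direction": direction, "training_cohort": training_id}
    if not sel.any():
        raise EmptyModelError(f"no SNP met the selection criteria {criteria}")
    chosen = tab.loc[sel]
    model = pd.DataFrame({
        "snp_id": chosen["snp_id"].to_numpy(),
        "minor_allele": ma_set.table.loc[sel, "minor_allele"].to_numpy(),
        "weight": chosen["coef"].to_numpy(),
        "control_maf": chosen["control_maf"].to_numpy(),
        "p_value": chosen["p_value"].to_numpy(),
    })
    return RiskModel(table=model, criteria=criteria)


def score_individuals(model: RiskModel, matrix: GenotypeMatrix) -> ScoreProfile:
    """Total weighted risk score of every individual in the cohort.

    Contribution of a model SNP: 0 for no minor-allele copy, 0.5x the
    coefficient for a heterozygote, the full coefficient for
    homozygous-minor.  Missing genotypes contribute zero and decrement the
    used-SNP count.  The scored matrix must contain at least one model SNP;
    minor-allele orientation is taken from the model, not re-derived from
    the scored cohort's controls.
    """
    panel = {s: j for j, s in enumerate(matrix.variants["snp_id"])}
    present = [sid in panel for sid in model.table["snp_id"]]
    if not any(present):
        raise ValueError("no model SNP present in the scored panel")
    sub = model.table.loc[present]
    cols = [panel[s] for s in sub["snp_id"]]
    calls = matrix.calls[:, cols].astype(np.float64)

    # orient calls to count the model's minor allele
    counted = matrix.variants["counted_allele"].to_numpy()[cols]
    need_flip = counted != sub["minor_allele"].to_numpy()
    flip_cols = np.flatnonzero(need_flip)
    for j in flip_cols:
        col = calls[:, j]
        nonmiss = col != MISSING
        col[nonmiss] = 2 - col[nonmiss]

    weights = sub["weight"].to_numpy()
    missing = calls == MISSING
    dosage = np.where(missing, 0.0, calls) / 2.0
    score = dosage @ weights
    used = (~missing).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(used > 0, score / used, np.nan)
    return ScoreProfile(table=pd.DataFrame({
        "sample_id": matrix.samples["sample_id"].to_numpy(),
        "phenotype": matrix.samples["phenotype"].to_numpy(),
        "score": score,
        "snps_used": used,
        "score_per_snp": per_snp,
    }))


def reduce_model_to_panel(model: RiskModel, panel_snp_ids) -> RiskModel:
    """Restrict a model to the SNPs present in another cohort's panel."""
    panel = set(panel_snp_ids)
    keep = model.table["snp_id"].isin(panel)
    if not keep.any():
        raise ValueError("model shares no SNP with the target panel")
    frac = keep.mean()
    log.info("reduce_model_to_panel: kept %d/%d SNPs (%.1f%%)",
             int(keep.sum()), len(model.table), 100 * frac)
    criteria = dict(model.criteria, reduced_to=int(keep.sum()),
                    reduction_fraction=float(frac))
    return RiskModel(table=model.table.loc[keep].reset_index(drop=True),
                     criteria=criteria)


def threshold_classify(scores: ScoreProfile, threshold: float) -> np.ndarray:
    """Predicted-case labels: score strictly greater than the threshold."""
    if not np.isfinite(threshold):
        if np.isnan(threshold):
            raise ValueError("threshold must not be NaN")
    return scores.scores > threshold
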