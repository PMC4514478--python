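"""End-to-end orchestration: config, staged runs, artifact output.

A :class:`RunConfig` captures every knob of the workflow — simulation
parameters or input paths, QC thresholds, model criteria, sweep grids, the
cross-validation k and all seeds — and is echoed verbatim (as YAML, with a
content hash) into the output directory so a run is reproducible from its
artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as gio
from .simulate import SimulationConfig, simulate_cohort, simulate_cohort_pair, write_truth_table
from .qc import run_qc
from .stats import compute_control_maf, compute_mac, compare_group_means, fit_all_snps
from .scoring import train_risk_model, score_individuals
from .evaluate import (ModelSpec, external_validate, model_sweep,
                       kfold_cross_validate, evaluate_scores,
                       DEFAULT_MAF_CEILINGS, DEFAULT_P_GRID)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    # input: either PED/MAP prefixes or a simulation request
    train_prefix: str | None = None
    test_prefix: str | None = None
    simulate: dict | None = None          # SimulationConfig fields
    simulate_test: dict | None = None     # overrides for the test cohort
    snp_overlap_fraction: float = 1.0
    # QC
    run_qc: bool = True
    hwe_alpha: float = 0.01
    max_missing: float = 0.05
    min_maf: float = 1e-4
    pc_sd_multiplier: float = 6.0
    skip_pca: bool = False
    # model
    maf_ceiling: float = 0.4
    p_threshold: float = 0.05
    direction: str = "cases_enriched"
    # evaluation
    do_sweep: bool = False
    maf_ceilings: tuple = tuple(DEFAULT_MAF_CEILINGS)
    p_grid: tuple = tuple(DEFAULT_P_GRID)
    do_crossval: bool = False
    k_folds: int = 10
    seed: int = 0
    out_dir: str = "maburden_run"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        # YAML round-trips tuples as lists; normalize
        cfg.maf_ceilings = tuple(cfg.maf_ceilings)
        cfg.p_grid = tuple(cfg.p_grid)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_or_simulate(cfg: RunConfig, out: Path):
    if cfg.simulate is not None:
        sim_a = SimulationConfig(**{**cfg.simulate, "seed": cfg.seed})
        if cfg.simulate_test is not None or cfg.snp_overlap_fraction < 1.0:
            sim_b = SimulationConfig(**{**cfg.simulate, **(cfg.simulate_test or {}),
                                        "seed": cfg.seed})
            train, test, truth = simulate_cohort_pair(sim_a, sim_b,
                                                      cfg.snp_overlap_fraction)
        else:
            train, truth = simulate_cohort(sim_a)
            test = None
        write_truth_table(truth, out / "truth.tsv")
        return train, test
    if cfg.train_prefix is None:
        raise ValueError("config must give train_prefix or a simulate block")
    train = gio.read_ped_map(f"{cfg.train_prefix}.ped", f"{cfg.train_prefix}.map")
    test = None
    if cfg.test_prefix:
        test = gio.read_ped_map(f"{cfg.test_prefix}.ped", f"{cfg.test_prefix}.map")
    return train, test


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages, writing every artifact as TSV.

    Stage order: load/simulate -> QC -> MA statistics (MAC + group ANOVA +
    per-SNP association) -> train -> in-sample evaluation, then optionally
    external validation, the model sweep and k-fold cross-validation.  Any
    stage failure raises :class:`StageError` naming the stage; artifacts
    written before the failure are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    log.info("run %s (config hash %s, seed %d)", out, config.config_hash(), config.seed)

    stage = "load"
    try:
        train, test = _load_or_simulate(config, out)
        if config.run_qc:
            stage = "qc"
            train, report = run_qc(train, hwe_alpha=config.hwe_alpha,
                                   max_missing=config.max_missing,
                                   min_maf=config.min_maf,
                                   pc_sd_multiplier=config.pc_sd_multiplier,
                                   skip_pca=config.skip_pca)
            report.to_tsv(out / "qc_train.tsv")
            if test is not None:
                test, report_t = run_qc(test, hwe_alpha=config.hwe_alpha,
                                        max_missing=config.max_missing,
                                        min_maf=config.min_maf,
                                        pc_sd_multiplier=config.pc_sd_multiplier,
                                        skip_pca=config.skip_pca)
                report_t.to_tsv(out / "qc_test.tsv")

        stage = "ma_statistics"
        ma_set = compute_control_maf(train, maf_ceiling=config.maf_ceiling)
        ma_set.to_tsv(out / "minor_alleles.tsv")
        mac = compute_mac(train, ma_set)
        mac.to_tsv(out / "mac_train.tsv")
        t = mac.table
        f_stat, p_anova = compare_group_means({
            "case": t.loc[t["phenotype"] == 1, "mac"],
            "control": t.loc[t["phenotype"] == 0, "mac"],
        })
        assoc = fit_all_snps(train, ma_set)
        assoc.to_tsv(out / "association.tsv")

        stage = "train"
        spec = ModelSpec(maf_ceiling=config.maf_ceiling,
                         p_threshold=config.p_threshold,
                         direction=config.direction)
        model = train_risk_model(assoc, ma_set, maf_ceiling=config.maf_ceiling,
                                 p_threshold=config.p_threshold,
                                 direction=config.direction)
        model.to_tsv(out / "risk_model.tsv")

        stage = "evaluate"
        in_scores = score_individuals(model, train)
        in_scores.to_tsv(out / "scores_train.tsv")
        in_report = evaluate_scores(in_scores, model_size=model.n_snps)
        in_report.to_frame().to_csv(out / "evaluation_insample.tsv", sep="\t", index=False)
        summary = {
            "config_hash": config.config_hash(), "seed": config.seed,
            "n_train_samples": train.n_samples, "n_train_snps": train.n_variants,
            "mac_anova_F": f_stat, "mac_anova_p": p_anova,
            "model_size": model.n_snps, "insample_auc": in_report.auc,
        }

        if test is not None:
            stage = "external_validation"
            ext = external_validate(train, test, spec)
            ext.to_frame().to_csv(out / "evaluation_external.tsv", sep="\t", index=False)
            ext.roc.to_csv(out / "roc_external.tsv", sep="\t", index=False)
            summary.update(external_auc=ext.auc, external_tpr=ext.tpr_full_spec,
                           external_model_size=ext.model_size)
            if config.do_sweep:
                stage = "sweep"
                sweep = model_sweep(train, test, maf_ceilings=config.maf_ceilings,
                                    p_grid=config.p_grid, direction=config.direction)
                sweep.to_tsv(out / "sweep.tsv")

        if config.do_crossval:
            stage = "crossval"
            cv = kfold_cross_validate(train, k=config.k_folds, spec=spec,
                                      seed=config.seed)
            cv.to_tsv(out / "crossval.tsv")
            summary.update(cv_mean_auc=cv.mean_auc, cv_mean_tpr=cv.mean_tpr)

        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc
    return out
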