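import numpy as np
import pytest

import maburden as mb


class TestAuc:
    def test_constant_scores_exactly_half(self):
        a, ci = mb.auc([1.0] * 20, [1.0] * 30)
        assert a == 0.5
        assert ci[0] <= 0.5 <= ci[1]

    def test_full_separation_exactly_one(self):
        a, _ = mb.auc([2.0, 3.0, 4.0], [0.0, 1.0])
        assert a == 1.0

    def test_pair_counting_example(self):
        # cases {2, 0} vs control {1}: one win, one loss -> 0.5
        a, _ = mb.auc([2.0, 0.0], [1.0])
        assert a == 0.5

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        cs, ks = rng.normal(0.3, 1, 40), rng.normal(0, 1, 50)
        assert mb.auc(cs, ks)[0] == pytest.approx(1 - mb.auc(ks, cs)[0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        cs, ks = rng.normal(0.5, 1, 30), rng.normal(0, 1, 30)
        a1 = mb.auc(cs, ks)[0]
        a2 = mb.auc(np.exp(cs), np.exp(ks))[0]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_delong_ci_matches_r_proc_reference(self):
        """Frozen oracle: DeLong CI computed by R's pROC::ci.auc for this
        exact score set."""
        cases = [1.2, 0.8, 2.5, 0.3, 1.9, 1.1, 0.7, 2.2]
        controls = [0.4, 0.9, 0.1, 1.3, 0.2, 0.6, 0.5, 1.0, 0.35, 0.8]
        a, ci = mb.auc(cases, controls)
        assert a == pytest.approx(0.78125, abs=1e-10)
        assert ci[0] == pytest.approx(0.5499878, abs=1e-6)
        assert ci[1] == pytest.approx(1.0, abs=1e-6)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mb.auc([], [1.0])


class TestTprFullSpecificity:
    def test_definition_example(self):
        tpr, _, thr = mb.tpr_full_specificity([3.0, 2.0, 1.0], [2.0, 1.0])
        assert tpr == pytest.approx(1 / 3)
        assert thr == 2.0

    def test_no_case_above_controls(self):
        tpr, _, _ = mb.tpr_full_specificity([1.0, 2.0], [2.5, 3.0])
        assert tpr == 0.0

    def test_tie_with_max_control_not_detected(self):
        tpr, _, _ = mb.tpr_full_specificity([5.0, 5.0], [5.0])
        assert tpr == 0.0

    def test_clopper_pearson_interval(self):
        from scipy.stats import binomtest
        cases = [3.0] * 4 + [0.0] * 16
        tpr, (lo, hi), _ = mb.tpr_full_specificity(cases, [1.0, 2.0])
        ref = binomtest(4, 20).proportion_ci(method="exact")
        assert tpr == pytest.approx(0.2)
        assert lo == pytest.approx(ref.low, abs=1e-10)
        assert hi == pytest.approx(ref.high, abs=1e-10)

    def test_equals_roc_tpr_at_zero_fpr(self):
        rng = np.random.default_rng(3)
        cs, ks = rng.normal(1, 1, 50), rng.normal(0, 1, 60)
        tpr, _, _ = mb.tpr_full_specificity(cs, ks)
        roc = mb.roc_curve(cs, ks)
        at_zero = roc.loc[roc["fpr"] == 0, "tpr"].max()
        assert tpr == pytest.approx(at_zero)


class TestRocCurve:
    def test_perfect_separation_passes_through_corner(self):
        roc = mb.roc_curve([2.0, 3.0], [0.0, 1.0])
        assert ((roc["fpr"] == 0) & (roc["tpr"] == 1)).any()

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(4)
        roc = mb.roc_curve(rng.normal(1, 1, 30), rng.normal(0, 1, 30))
        assert roc.iloc[0].tolist() == [0.0, 0.0]
        assert roc.iloc[-1].tolist() == [1.0, 1.0]
        assert (np.diff(roc["fpr"]) >= 0).all()
        assert (np.diff(roc["tpr"]) >= 0).all()

    def test_trapezoid_equals_ranksum_with_ties(self):
        """Identity between the two AUC routes, heavy ties included."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            cs = rng.choice([0, 1, 2, 3, 4], size=rng.integers(2, 40)).astype(float)
            ks = rng.choice([0, 1, 2, 3], size=rng.integers(2, 40)).astype(float)
            a = mb.auc(cs, ks)[0]
            t = mb.trapezoid_auc(mb.roc_curve(cs, ks))
            assert t == pytest.approx(a, abs=1e-12)

    def test_constant_scores_diagonal(self):
        roc = mb.roc_curve([1.0, 1.0], [1.0, 1.0, 1.0])
        assert roc.values.tolist() == [[0.0, 0.0], [1.0, 1.0]]


@pytest.fixture(scope="module")
def sweep_result(effect_cohort):
    matrix, _ = effect_cohort
    half = matrix.n_samples // 2
    rng = np.random.default_rng(0)
    perm = rng.permutation(matrix.n_samples)
    train = matrix.take_samples(perm[:half])
    test = matrix.take_samples(perm[half:])
    return mb.model_sweep(train, test, p_grid=(0.01, 0.05, 1.0))


class TestModelSweep:
    def test_six_model_families(self, sweep_result):
        models = sweep_result.table["model"].unique()
        assert len(models) == 6
        assert "haplotype" in models

    def test_grid_dimensions(self, sweep_result):
        assert len(sweep_result.table) == 6 * 3

    def test_vacuous_p_selects_all_qualifying(self, sweep_result, effect_cohort):
        row = sweep_result.table.query(
            "model == 'maf<0.5' and p_threshold == 1.0").iloc[0]
        # every informative converged case-enriched SNP qualifies
        assert row["model_size"] > 0
        sizes = sweep_result.table.query("model == 'maf<0.5'")["model_size"]
        assert row["model_size"] == sizes.max()

    def test_model_size_monotone_in_p(self, sweep_result):
        for fam, sub in sweep_result.table.groupby("model"):
            s = sub.sort_values("p_threshold")["model_size"].to_numpy()
            assert (np.diff(s) >= 0).all()


class TestKfoldCrossValidation:
    def test_folds_partition_samples(self, effect_cohort):
        matrix, _ = effect_cohort
        cv = mb.kfold_cross_validate(matrix, k=5, seed=3)
        assert cv.folds["n_test"].sum() == matrix.n_samples
        assert len(cv.folds) == 5
        assert cv.mean_auc == pytest.approx(cv.folds["auc"].mean())

    def test_deterministic_given_seed(self, effect_cohort):
        matrix, _ = effect_cohort
        a = mb.kfold_cross_validate(matrix, k=4, seed=9)
        b = mb.kfold_cross_validate(matrix, k=4, seed=9)
        assert a.folds.equals(b.folds)

    def test_signal_detected_out_of_fold(self, effect_cohort):
        """Strong-effect cohort: held-out AUC is clearly above chance."""
        matrix, _ = effect_cohort
        cv = mb.kfold_cross_validate(matrix, k=5, seed=1)
        assert cv.mean_auc > 0.6

    def test_too_few_per_class_rejected(self, effect_cohort):
        matrix, _ = effect_cohort
        few = matrix.take_samples(range(12))  # all cases
        with pytest.raises(ValueError):
            mb.kfold_cross_validate(few, k=10)


class TestExternalValidation:
    def test_recovery_above_chance(self):
        cfg = mb.SimulationConfig(n_cases=250, n_controls=250, n_snps=800,
                                  n_risk_snps=80, effect_mean=1.2,
                                  effect_sd=0.05, seed=19)
        train, test, _ = mb.simulate_cohort_pair(cfg, cfg, 1.0)
        rep = mb.external_validate(train, test)
        assert rep.auc > 0.55

    def test_full_overlap_equals_direct_scoring(self, effect_cohort):
        matrix, _ = effect_cohort
        rep1 = mb.external_validate(matrix, matrix)
        ma = mb.compute_control_maf(matrix)
        assoc = mb.fit_all_snps(matrix, ma)
        model = mb.train_risk_model(assoc, ma)
        rep2 = mb.evaluate_scores(mb.score_individuals(model, matrix))
        assert rep1.auc == pytest.approx(rep2.auc, abs=1e-12)

    def test_insample_exceeds_external(self):
        cfg = mb.SimulationConfig(n_cases=150, n_controls=150, n_snps=2000,
                                  n_risk_snps=40, effect_mean=0.3, seed=23)
        train, test, _ = mb.simulate_cohort_pair(cfg, cfg, 1.0)
        ext = mb.external_validate(train, test)
        ins = mb.external_validate(train, train)
        assert ins.auc > ext.auc

    def test_reduced_panel_still_above_chance(self):
        cfg = mb.SimulationConfig(n_cases=250, n_controls=250, n_snps=1000,
                                  n_risk_snps=100, effect_mean=0.5, seed=29)
        train, test, _ = mb.simulate_cohort_pair(cfg, cfg, 0.5)
        rep = mb.external_validate(train, test)
        assert rep.model_size > 0
        assert rep.auc > 0.5


class TestControlOnlyValidation:
    def test_monotone_in_control_pool(self, effect_cohort):
        matrix, _ = effect_cohort
        ma = mb.compute_control_maf(matrix)
        assoc = mb.fit_all_snps(matrix, ma)
        model = mb.train_risk_model(assoc, ma)
        prof = mb.score_individuals(model, matrix)
        cs, _ = prof.case_control_scores()
        ctrl_idx = np.flatnonzero(matrix.is_control)
        small = matrix.take_samples(ctrl_idx[:50])
        large = matrix.take_samples(ctrl_idx)
        frac_small, _ = mb.control_only_validation(model, small, cs)
        frac_large, _ = mb.control_only_validation(model, large, cs)
        assert frac_large <= frac_small

    def test_no_shared_snps_errors(self, effect_cohort):
        matrix, _ = effect_cohort
        ma = mb.compute_control_maf(matrix)
        assoc = mb.fit_all_snps(matrix, ma)
        model = mb.train_risk_model(assoc, ma)
        stranger = matrix.take_variants(range(3))
        stranger.variants["snp_id"] = ["x0", "x1", "x2"]
        with pytest.raises(ValueError):
            mb.control_only_validation(model, stranger, np.array([1.0]))


def test_null_tpr_matches_exchangeability():
    """Pure-null pairs: mean TPR@100%spec ~ 1/(n_controls+1)."""
    rng = np.random.default_rng(6)
    n_cases, n_controls = 80, 120
    tprs = []
    for _ in range(400):
        cs = rng.normal(size=n_cases)
        ks = rng.normal(size=n_controls)
        tprs.append(mb.tpr_full_specificity(cs, ks)[0])
    expect = 1 / (n_controls + 1)
    se = np.std(tprs) / np.sqrt(len(tprs))
    assert abs(np.mean(tprs) - expect) < 3 * se + 1e-4
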