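import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import maburden as mb
from conftest import make_matrix


class TestControlMaf:
    def test_controls_monomorphic_major(self):
        """Controls all hom for allele1: MAF 0, minor allele is allele2,
        informative only because cases carry it."""
        calls = np.array([[2], [2], [1], [2]], dtype=np.int8)
        m = make_matrix(calls, [0, 0, 1, 1], alleles=[("A", "G")])
        ma = mb.compute_control_maf(m)
        row = ma.table.iloc[0]
        assert row["control_maf"] == 0
        assert row["minor_allele"] == "G"
        assert row["informative"]  # case MAF > 0

    def test_monomorphic_everywhere_non_informative(self):
        calls = np.full((4, 1), 2, dtype=np.int8)
        m = make_matrix(calls, [0, 0, 1, 1])
        ma = mb.compute_control_maf(m)
        assert not ma.table["informative"].iloc[0]

    def test_simple_count(self):
        # 10 controls, 4 copies of allele2 in 20 slots -> MAF 0.2
        calls = np.array([1, 1, 1, 1] + [0] * 6, dtype=np.int8).reshape(-1, 1)
        calls = 2 - calls  # counted allele = allele1 = major
        m = make_matrix(calls, [0] * 10)
        ma = mb.compute_control_maf(m)
        assert ma.table["control_maf"].iloc[0] == pytest.approx(0.2)
        assert ma.table["minor_allele"].iloc[0] == "G"

    def test_exact_half_non_informative(self):
        calls = np.array([[0], [2], [1], [1]], dtype=np.int8)
        m = make_matrix(calls, [0, 0, 0, 0])
        ma = mb.compute_control_maf(m)
        assert ma.table["control_maf"].iloc[0] == 0.5
        assert not ma.table["informative"].iloc[0]

    def test_no_control_calls_flagged(self):
        calls = np.array([[mb.MISSING], [mb.MISSING], [1]], dtype=np.int8)
        m = make_matrix(calls, [0, 0, 1])
        ma = mb.compute_control_maf(m)
        assert not ma.table["informative"].iloc[0]

    def test_maf_ceiling_applied(self, null_cohort):
        matrix, _ = null_cohort
        ma = mb.compute_control_maf(matrix, maf_ceiling=0.2)
        inf = ma.table.loc[ma.table["informative"]]
        assert (inf["control_maf"] < 0.2).all()
        assert ma.maf_ceiling == 0.2


class TestMac:
    def _two_snp(self):
        # counted allele == minor allele in both columns
        calls = np.array([[1, 0],   # het at snp0, hom-major at snp1 -> MAC 1/4
                          [2, 2],   # hom-minor everywhere -> MAC 1
                          [1, mb.MISSING]],  # missing drops denominator
                         dtype=np.int8)
        # minor == counted allele: pad with all-major controls
        return make_matrix(np.vstack([calls, np.zeros((6, 2), dtype=np.int8)]),
                           [1, 1, 0] + [0] * 6)

    def test_worked_examples(self):
        m = self._two_snp()
        ma = mb.compute_control_maf(m)
        assert ma.informative.all()
        mac = mb.compute_mac(m, ma).table
        assert mac["mac"].iloc[0] == pytest.approx(1 / 4)
        assert mac["mac"].iloc[1] == pytest.approx(1.0)
        # missing genotype: 1 copy / 2 slots at the one called SNP
        assert mac["mac"].iloc[2] == pytest.approx(1 / 2)
        assert mac["called_snps"].iloc[2] == 1

    def test_zero_called_snps_flagged_nan(self):
        calls = np.array([[mb.MISSING], [1], [0]], dtype=np.int8)
        m = make_matrix(calls, [1, 0, 0])
        ma = mb.compute_control_maf(m)
        mac = mb.compute_mac(m, ma).table
        assert np.isnan(mac["mac"].iloc[0])

    def test_invariant_to_snp_order_and_noninformative(self, null_cohort):
        matrix, _ = null_cohort
        ma = mb.compute_control_maf(matrix)
        base = mb.compute_mac(matrix, ma).table["mac"].to_numpy()
        # permute SNPs
        rng = np.random.default_rng(1)
        perm = rng.permutation(matrix.n_variants)
        m2 = matrix.take_variants(perm)
        mac2 = mb.compute_mac(m2, mb.compute_control_maf(m2)).table["mac"].to_numpy()
        np.testing.assert_allclose(base, mac2)
        # append a non-informative (monomorphic) SNP
        mono = np.full((matrix.n_samples, 1), 0, dtype=np.int8)
        m3 = make_matrix(np.hstack([matrix.calls, mono]),
                         matrix.samples["phenotype"])
        mac3 = mb.compute_mac(m3, mb.compute_control_maf(m3)).table["mac"].to_numpy()
        np.testing.assert_allclose(base, mac3)

    def test_invariant_to_counted_allele_orientation(self, null_cohort):
        """Flipping a SNP's counted allele cannot change anyone's MAC."""
        matrix, _ = null_cohort
        base = mb.compute_mac(matrix, mb.compute_control_maf(matrix)).table["mac"]
        flipped = matrix.flip_counted_allele([0, 1, 2])
        after = mb.compute_mac(flipped, mb.compute_control_maf(flipped)).table["mac"]
        np.testing.assert_allclose(base, after)


class TestAnova:
    def test_identical_groups(self):
        f, p = mb.compare_group_means({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert f == 0.0 and p == 1.0

    def test_f_equals_t_squared_two_groups(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(size=30), rng.normal(0.3, 1, size=25)
            f, p = mb.compare_group_means({"a": a, "b": b})
            t, pt = sps.ttest_ind(a, b)  # pooled-variance t
            assert f == pytest.approx(t ** 2, rel=1e-10)
            assert p == pytest.approx(pt, rel=1e-10)

    def test_burden_simulation_direction(self, effect_cohort):
        matrix, _ = effect_cohort
        ma = mb.compute_control_maf(matrix)
        mac = mb.compute_mac(matrix, ma).table
        case = mac.loc[mac["phenotype"] == 1, "mac"]
        ctrl = mac.loc[mac["phenotype"] == 0, "mac"]
        f, p = mb.compare_group_means({"case": case, "control": ctrl})
        assert case.mean() > ctrl.mean()
        assert p < 0.01


class TestSnpLogistic:
    def test_null_distribution_flat(self):
        g = np.tile([0, 1, 2, 1], 50)
        y = np.tile([0, 0, 1, 1], 50)  # same genotype mix in both classes
        coef, se, p, conv = mb.fit_snp_logistic(
            np.r_[g, g], np.r_[y, 1 - y])
        assert conv
        assert coef == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_binary_genotype_matches_2x2_log_odds_ratio(self):
        """With genotypes 0/1 only, the fitted slope is the table log OR."""
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = 200
            g = rng.integers(0, 2, n)
            y = (rng.random(n) < 0.3 + 0.3 * g).astype(int)
            tab = np.array([[(1 - y)[g == 0].sum(), y[g == 0].sum()],
                            [(1 - y)[g == 1].sum(), y[g == 1].sum()]], float)
            if (tab == 0).any():
                continue
            expect = np.log(tab[1, 1] * tab[0, 0] / (tab[1, 0] * tab[0, 1]))
            coef, _, _, conv = mb.fit_snp_logistic(g, y)
            assert conv
            assert coef == pytest.approx(expect, abs=1e-7)

    def test_matches_statsmodels_on_random_snps(self):
        """Coefficient and Wald p agree with an independent fit to 1e-6."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 100:
            n = 300
            g = rng.choice([0, 1, 2], size=n, p=[0.5, 0.35, 0.15])
            eta = -0.4 + rng.normal(0, 0.3) * g
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            if y.sum() in (0, n) or len(np.unique(g)) < 2:
                continue
            coef, se, p, conv = mb.fit_snp_logistic(g, y)
            if not conv:
                continue
            ref = sm.Logit(y, sm.add_constant(g.astype(float))).fit(disp=0)
            assert coef == pytest.approx(ref.params[1], abs=1e-6)
            assert p == pytest.approx(ref.pvalues[1], abs=1e-6)
            checked += 1

    def test_constant_genotype_flagged(self):
        coef, se, p, conv = mb.fit_snp_logistic(np.ones(50, int),
                                                np.r_[np.ones(25, int),
                                                      np.zeros(25, int)])
        assert not conv and np.isnan(coef)

    def test_complete_separation_flagged(self):
        g = np.r_[np.zeros(30, int), np.full(30, 2)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        _, _, _, conv = mb.fit_snp_logistic(g, y)
        assert not conv

    def test_missing_genotypes_excluded(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, 200)
        y = rng.integers(0, 2, 200)
        gm = g.copy()
        gm[:50] = mb.MISSING
        ref = mb.fit_snp_logistic(g[50:], y[50:])
        got = mb.fit_snp_logistic(gm, y)
        assert got[0] == pytest.approx(ref[0], abs=1e-10)

    def test_coefficient_sign_flips_with_allele_flip(self, effect_cohort):
        matrix, _ = effect_cohort
        ma = mb.compute_control_maf(matrix)
        assoc = mb.fit_all_snps(matrix, ma)
        j = int(assoc.table["p_value"].idxmin())
        g = mb.minor_allele_calls(matrix, ma)[:, j]
        y = matrix.samples["phenotype"].to_numpy()
        c1, *_ = mb.fit_snp_logistic(g, y)
        gf = np.where(g == mb.MISSING, mb.MISSING, 2 - g)
        c2, *_ = mb.fit_snp_logistic(gf, y)
        assert c1 == pytest.approx(-c2, abs=1e-6)

    def test_type_one_error_calibrated_on_null(self):
        """Fraction of p < 0.05 on a null cohort is ~5% (binomial band)."""
        cfg = mb.SimulationConfig(n_cases=300, n_controls=300, n_snps=2500,
                                  n_risk_snps=0, missing_rate=0.0, seed=21)
        matrix, _ = mb.simulate_cohort(cfg)
        ma = mb.compute_control_maf(matrix)
        assoc = mb.fit_all_snps(matrix, ma)
        p = assoc.table.loc[assoc.table["converged"], "p_value"]
        frac = (p < 0.05).mean()
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / len(p))


class TestMafBinnedRisk:
    def test_single_bin_equals_overall_mean_per_snp(self, effect_cohort):
        matrix, _ = effect_cohort
        ma = mb.compute_control_maf(matrix)
        assoc = mb.fit_all_snps(matrix, ma)
        one = mb.maf_binned_average_risk(assoc, ma, matrix, bins=1,
                                         maf_ceiling=0.5)
        assert len(one) == 1
        usable = assoc.table["converged"].to_numpy() & ma.informative
        coef = np.where(usable, assoc.table["coef"].to_numpy(), 0.0)
        dosage = mb.minor_allele_calls(matrix, ma).astype(float)
        dosage[dosage == mb.MISSING] = 0
        total = (dosage / 2)[:, usable] @ coef[usable]
        expect = total.mean() / usable.sum()
        assert one["mean_score_per_snp"].iloc[0] == pytest.approx(expect)

    def test_bins_partition_included_snps(self, effect_cohort):
        matrix, _ = effect_cohort
        ma = mb.compute_control_maf(matrix)
        assoc = mb.fit_all_snps(matrix, ma)
        binned = mb.maf_binned_average_risk(assoc, ma, matrix, bins=5,
                                            maf_ceiling=0.5)
        usable = assoc.table["converged"].to_numpy() & ma.informative
        maf = assoc.table["control_maf"].to_numpy()
        in_range = usable & (maf > 0) & (maf <= 0.5)
        assert binned["n_snps"].sum() == in_range.sum()

    def test_low_maf_bins_carry_higher_average_risk(self):
        """Constructed cohort whose low-MAF SNPs carry larger coefficients:
        per-SNP bin averages then fall with MAF (direction only).

        A SNP's bin contribution scales like coefficient x MAF (the mean
        dosage), so the generative per-dosage effect is set proportional to
        MAF^-1.5, making the recovered coefficient x MAF product decrease
        with frequency.
        """
        rng = np.random.default_rng(17)
        n, m = 1500, 600
        maf = rng.uniform(0.05, 0.5, size=m)
        geno = ((rng.random((n, m)) < maf).astype(np.int8)
                + (rng.random((n, m)) < maf).astype(np.int8))
        effect = 0.004 * maf ** -1.5  # dosage-scale log-odds
        logit = -0.5 + (geno / 2.0) @ effect
        pheno = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        matrix = make_matrix(geno, pheno)
        ma = mb.compute_control_maf(matrix)
        assoc = mb.fit_all_snps(matrix, ma)
        binned = mb.maf_binned_average_risk(assoc, ma, matrix, bins=3,
                                            maf_ceiling=0.5)
        vals = binned["mean_score_per_snp"].to_numpy()
        assert vals[0] > vals[-1]
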