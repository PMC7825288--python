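import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirsnp_rewire import lmm
from mirsnp_rewire.datagen import TraitSpec, pedigree_kinship, simulate_phenotype

from oracles import dense_lmm_loglik


def _eig(kinship):
    return lmm.KinshipEigen.from_kinship(kinship)


class TestGrm:
    def test_identical_individuals_get_identical_rows(self, rng):
        g = rng.integers(0, 3, (5, 200)).astype(float)
        g[3] = g[1]
        k = lmm.grm(g)
        assert np.allclose(k[1], k[3])
        assert np.allclose(k, k.T)

    def test_grm_is_psd(self, rng):
        k = lmm.grm(rng.integers(0, 3, (20, 300)))
        assert np.linalg.eigvalsh(k).min() > -1e-10

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError):
            lmm.grm(np.ones((10, 5)))

    def test_exclusion_list_removes_markers(self, rng):
        g = rng.integers(0, 3, (10, 50)).astype(float)
        k_all = lmm.grm(g)
        k_ex = lmm.grm(g, exclude=[0, 1])
        assert not np.allclose(k_all, k_ex)
        assert np.allclose(k_ex, lmm.grm(g[:, 2:]))


class TestFitLmm:
    def test_identity_kinship_collapses_to_ols(self, rng):
        n = 40
        w = np.column_stack([np.ones(n), rng.normal(size=n)])
        x = rng.integers(0, 3, n).astype(float)
        y = w @ [1.0, 0.5] + 0.3 * x + rng.normal(size=n)
        fit = lmm.fit_lmm(y, w, _eig(np.eye(n)), x=x)
        beta_ols = np.linalg.lstsq(np.column_stack([w, x]), y, rcond=None)[0]
        assert fit.beta == pytest.approx(beta_ols[-1], abs=1e-5)

    def test_loglik_matches_dense_grid_oracle(self):
        """On an 8-animal fixture the spectral profile likelihood maximum must
        match a 10^4-point dense-inversion grid search."""
        rng = np.random.default_rng(2)
        kin = pedigree_kinship(np.array([0, 0, 0, 1, 1, 1, 2, 2]))
        w = np.ones((8, 1))
        x = np.array([0, 1, 2, 0, 1, 0, 2, 1], float)
        y = simulate_phenotype(
            x, kin, TraitSpec(beta_true=0.5, var_polygenic=0.5, var_residual=0.5),
            np.zeros(8, int), rng,
        )
        design = np.column_stack([w, x])
        grid = np.linspace(-5, 5, 10_000)
        oracle = max(dense_lmm_loglik(y, design, kin, 10.0**g) for g in grid)
        fit = lmm.fit_lmm(y, w, _eig(kin), x=x)
        assert fit.loglik == pytest.approx(oracle, abs=1e-5)

    @pytest.mark.parametrize("log_lam", [-3.0, 0.0, 2.0])
    def test_spectral_equals_dense_likelihood_at_fixed_lambda(self, log_lam, rng):
        n = 12
        kin = pedigree_kinship(np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]))
        w = np.ones((n, 1))
        x = rng.integers(0, 3, n).astype(float)
        y = rng.normal(size=n) + 0.4 * x
        design = np.column_stack([w, x])
        eig = _eig(kin)
        from mirsnp_rewire.lmm import _profile_loglik

        ll_spec = _profile_loglik(log_lam, eig.rotate(y), eig.rotate(design), eig.values)[0]
        ll_dense = dense_lmm_loglik(y, design, kin, 10.0**log_lam)
        assert ll_spec == pytest.approx(ll_dense, abs=1e-8)

    def test_rotation_leaves_beta_and_lrt_unchanged(self, rng):
        n = 30
        kin = pedigree_kinship(np.repeat(np.arange(5), 6))
        w = np.ones((n, 1))
        x = rng.integers(0, 3, n).astype(float)
        y = rng.normal(size=n) + 0.5 * x
        q, _ = np.linalg.qr(rng.normal(size=(n, n)))
        f0 = lmm.fit_lmm(y, w, _eig(kin), x=x)
        n0 = lmm.fit_lmm(y, w, _eig(kin))
        fr = lmm.fit_lmm(q @ y, q @ w, _eig(q @ kin @ q.T), x=q @ x)
        nr = lmm.fit_lmm(q @ y, q @ w, _eig(q @ kin @ q.T))
        assert fr.beta == pytest.approx(f0.beta, abs=1e-4)
        lrt0 = lmm.lrt_test(n0.loglik, f0.loglik)[0]
        lrtr = lmm.lrt_test(nr.loglik, fr.loglik)[0]
        assert lrtr == pytest.approx(lrt0, abs=1e-3)

    def test_constant_shift_moves_only_intercept(self, rng):
        n = 25
        kin = pedigree_kinship(np.repeat(np.arange(5), 5))
        w = np.ones((n, 1))
        x = rng.integers(0, 3, n).astype(float)
        y = rng.normal(size=n)
        f0 = lmm.fit_lmm(y, w, _eig(kin), x=x)
        f1 = lmm.fit_lmm(y + 10.0, w, _eig(kin), x=x)
        assert f1.beta == pytest.approx(f0.beta, abs=1e-5)
        assert f1.coefficients[0] == pytest.approx(f0.coefficients[0] + 10.0, abs=1e-4)

    def test_reml_flag_gives_similar_beta(self, rng):
        n = 40
        kin = pedigree_kinship(np.repeat(np.arange(8), 5))
        w = np.ones((n, 1))
        x = rng.integers(0, 3, n).astype(float)
        y = rng.normal(size=n) + 0.6 * x
        ml = lmm.fit_lmm(y, w, _eig(kin), x=x)
        reml = lmm.fit_lmm(y, w, _eig(kin), x=x, reml=True)
        assert np.isfinite(reml.loglik)
        assert reml.beta == pytest.approx(ml.beta, abs=5 * ml.se)

    def test_lambda_recovery_in_simulated_cohorts(self, small_cohort):
        """Data generated at lambda = 1 (equal variance components) yields
        median lambda-hat of the right order."""
        eig = _eig(small_cohort.kinship)
        rng = np.random.default_rng(3)
        lams = []
        for _ in range(30):
            y = simulate_phenotype(
                np.zeros(150), small_cohort.kinship,
                TraitSpec(var_polygenic=0.5, var_residual=0.5),
                np.zeros(150, int), rng,
            )
            lams.append(lmm.fit_lmm(y, np.ones((150, 1)), eig).lambda_hat)
        assert 0.3 < np.median(lams) < 3.0


class TestLrtAndBonferroni:
    def test_equal_likelihoods_give_null_result(self):
        assert lmm.lrt_test(-10.0, -10.0) == (0.0, 1.0)

    def test_chi2_quantile(self):
        lrt, p = lmm.lrt_test(0.0, 3.841 / 2)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_small_negative_noise_clipped(self):
        lrt, p = lmm.lrt_test(-10.0, -10.0 - 1e-9)
        assert lrt == 0.0 and p == 1.0

    def test_bonferroni_study_threshold(self):
        assert lmm.bonferroni_threshold(0.10, 5) == pytest.approx(0.02)

    @pytest.mark.parametrize("fwer,n,expected", [(0.07, 1, 0.07), (0.05, 20, 0.0025)])
    def test_bonferroni_arithmetic(self, fwer, n, expected):
        assert lmm.bonferroni_threshold(fwer, n) == pytest.approx(expected)

    def test_bonferroni_invalid_inputs(self):
        with pytest.raises(ValueError):
            lmm.bonferroni_threshold(0.1, 0)
        with pytest.raises(ValueError):
            lmm.bonferroni_threshold(1.5, 5)


class TestAssociateAll:
    def _tables(self, cohort, rng, beta=0.0, snp=0):
        n = cohort.kinship.shape[0]
        samples = [f"s{i}" for i in range(n)]
        y = simulate_phenotype(
            cohort.genotypes[:, snp], cohort.kinship,
            TraitSpec(beta_true=beta, var_polygenic=0.3, var_residual=0.7),
            np.zeros(n, int), rng,
        )
        dosages = pd.DataFrame(
            cohort.genotypes.T, columns=samples,
            index=[f"rs{j}" for j in range(cohort.genotypes.shape[1])],
        )
        pheno = pd.DataFrame({"trait": y}, index=samples)
        return dosages, pheno

    def test_planted_effect_detected_null_snps_not(self, small_cohort, rng):
        dosages, pheno = self._tables(small_cohort, rng, beta=0.8, snp=1)
        res = lmm.associate_all(dosages, pheno, None, small_cohort.kinship, fwer=0.10)
        res = res.set_index("snp")
        assert res.loc["rs1", "significant"].item()
        assert res.loc["rs1", "beta"] == pytest.approx(0.8, abs=3 * res.loc["rs1", "se"])

    def test_zero_variance_phenotype_skipped_with_warning(self, small_cohort):
        n = 150
        samples = [f"s{i}" for i in range(n)]
        dosages = pd.DataFrame(
            small_cohort.genotypes.T[:1], columns=samples, index=["rs0"]
        )
        pheno = pd.DataFrame({"flat": np.ones(n)}, index=samples)
        with pytest.warns(UserWarning, match="zero variance"):
            res = lmm.associate_all(dosages, pheno, None, small_cohort.kinship)
        assert res.empty

    def test_reference_coding_matches_cell_means_beta(self, small_cohort, rng):
        """beta-hat is invariant to the categorical covariate parameterization."""
        dosages, pheno = self._tables(small_cohort, rng, beta=0.5, snp=0)
        n = len(pheno)
        cov = pd.DataFrame(
            {"batch": rng.integers(0, 3, n).astype(str)}, index=pheno.index
        )
        res_ref = lmm.associate_all(dosages[:1], pheno, cov, small_cohort.kinship)
        # cell-means: one indicator per level, no intercept -> same fitted span
        w_cell = pd.get_dummies(cov["batch"]).to_numpy(float)
        eig = _eig(small_cohort.kinship)
        fit = lmm.fit_lmm(
            pheno["trait"].to_numpy(), w_cell, eig,
            x=dosages.iloc[0].to_numpy(float),
        )
        assert fit.beta == pytest.approx(res_ref["beta"].iloc[0], abs=1e-4)
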