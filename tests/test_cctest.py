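"""Case-control score tests: null model, burden, SKAT, SKAT-O."""

import warnings

import numpy as np
import pytest
from scipy.stats import chi2, ncx2

from rarewin.casecontrol import (
    CCTestConfig,
    SeparationError,
    SmallSampleWarning,
    build_design,
    burden_test,
    fit_null,
    mixture_chi2_sf,
    skat_test,
    skato_test,
)

pytestmark = pytest.mark.filterwarnings("ignore::rarewin.casecontrol.SmallSampleWarning")


def intercept_null(y):
    return fit_null(np.asarray(y, float), np.ones((len(y), 1)), ["intercept"])


class TestFitNull:
    def test_intercept_only_mle(self):
        null = intercept_null([1, 1, 0, 0])
        np.testing.assert_allclose(null.mu, 0.5, atol=1e-8)

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            intercept_null([1, 1, 1, 1])

    def test_rank_deficiency_rejected(self):
        X = np.ones((6, 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank"):
            fit_null(np.array([1, 0, 1, 0, 1, 0.0]), X)

    def test_perfect_separation_names_covariate(self):
        y = np.array([1, 1, 1, 0, 0, 0.0])
        X = np.column_stack([np.ones(6), y * 2 - 1])
        with pytest.raises(SeparationError, match="x1"):
            fit_null(y, X)

    def test_small_sample_warning(self):
        with pytest.warns(SmallSampleWarning):
            warnings.simplefilter("always")
            fit_null(
                np.array([1, 0, 1, 0.0]), np.ones((4, 1))
            )

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(21)
        n = 5000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
        beta = np.array([-0.5, 0.8, -0.6])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        null = fit_null(y, X)
        # the null model reproduces the MLE means; coefficients near truth
        np.testing.assert_allclose(null.mu, res.fittedvalues, atol=1e-6)
        assert np.all(np.abs(res.params - beta) < 3 * res.bse)


class TestBurden:
    def test_hand_worked_score_test(self):
        null = intercept_null([1, 1, 0, 0])
        g = np.array([[2.0], [2.0], [0.0], [0.0]])
        # U = 2, Var = 1, statistic 4 → χ²₁ tail ≈ 0.0455
        assert burden_test(null, g) == pytest.approx(chi2.sf(4, 1))

    def test_all_zero_genotypes(self):
        null = intercept_null([1, 0, 1, 0])
        assert burden_test(null, np.zeros((4, 3))) == 1.0

    def test_matches_label_permutation_oracle(self):
        rng = np.random.default_rng(33)
        n = 600
        G = rng.binomial(2, 0.08, size=(n, 5)).astype(float)
        # mild association so the p-value is in a regime where the χ²
        # approximation and the permutation law should agree
        risk = 0.45 + 0.12 * (G.sum(axis=1) > 0)
        y = (rng.random(n) < risk).astype(float)
        null = intercept_null(y)
        p = burden_test(null, G)
        # permutation oracle: intercept-only model ⇒ permute labels
        c = G.sum(axis=1)
        U_obs = abs(c @ (y - y.mean()))
        n_perm = 100_000
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        U_null = np.abs((y - y.mean())[perms] @ c)
        p_perm = (1 + (U_null >= U_obs - 1e-12).sum()) / (1 + n_perm)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < 3 * se + 0.005


class TestSkat:
    def test_single_variant_equals_burden(self):
        rng = np.random.default_rng(4)
        n = 150
        y = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        null = fit_null(y, X)
        g = rng.binomial(2, 0.1, size=(n, 1)).astype(float)
        assert skat_test(null, g) == pytest.approx(burden_test(null, g), rel=1e-9)

    def test_all_zero_genotypes(self):
        null = intercept_null([1, 0, 1, 0])
        assert skat_test(null, np.zeros((4, 2))) == 1.0

    def test_liu_and_imhof_tails_agree(self):
        lam = np.array([3.0, 1.2, 0.4, 0.1])
        for q in (2.0, 6.0, 12.0, 20.0):
            p_liu = mixture_chi2_sf(q, lam, "liu")
            p_int = mixture_chi2_sf(q, lam, "integration")
            assert p_int == pytest.approx(p_liu, rel=0.15, abs=5e-4)

    def test_mixture_single_eigenvalue_exact(self):
        assert mixture_chi2_sf(7.2, np.array([1.8])) == pytest.approx(
            chi2.sf(4.0, 1)
        )


class TestSkatO:
    @pytest.fixture(scope="class")
    def fixture_data(self):
        rng = np.random.default_rng(42)
        n, V = 200, 8
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.normal(60, 8, n) / 10])
        y = (rng.random(n) < 0.4).astype(float)
        G = rng.binomial(2, 0.05, size=(n, V)).astype(float)
        y[(G[:, :3].sum(1) > 0) & (rng.random(n) < 0.35)] = 1.0
        return fit_null(y, X), G

    def test_rho_endpoints(self, fixture_data):
        null, G = fixture_data
        res = skato_test(null, G)
        assert res.p_rho[res.rho_grid.index(1.0)] == pytest.approx(res.p_burden)
        assert res.p_rho[res.rho_grid.index(0.0)] == pytest.approx(res.p_skat)

    def test_bonferroni_sandwich(self, fixture_data):
        null, G = fixture_data
        res = skato_test(null, G)
        assert min(res.p_rho) <= res.p_skato <= len(res.rho_grid) * min(res.p_rho)

    def test_matches_residual_permutation_oracle(self, fixture_data):
        null, G = fixture_data
        res = skato_test(null, G)
        rng = np.random.default_rng(77)
        V = G.shape[1]
        w = np.ones(V)
        Z1 = null.adjust(G * w)
        A = Z1.T @ Z1
        from rarewin.casecontrol import _liu_params, _rho_half

        n_perm = 100_000
        perms = np.argsort(rng.random((n_perm, len(null.resid))), axis=1)
        U = null.resid[perms] @ G  # (P, V)
        Qs, Qb = (U**2).sum(1), U.sum(1) ** 2
        minp = np.ones(n_perm)
        for rho in res.rho_grid:
            Rh = _rho_half(rho, V)
            lam = np.linalg.eigvalsh(Rh @ A @ Rh)
            mu_q, s_q, mu_x, s_x, df, d = _liu_params(lam[lam > 1e-10])
            qn = ((1 - rho) * Qs + rho * Qb - mu_q) / s_q * s_x + mu_x
            p = ncx2.sf(qn, df, d) if d > 0 else chi2.sf(qn, df)
            minp = np.minimum(minp, p)
        p_perm = (1 + (minp <= min(res.p_rho) + 1e-12).sum()) / (1 + n_perm)
        assert res.p_skato == pytest.approx(p_perm, rel=0.10)

    def test_single_variant_window_collapses(self):
        null = intercept_null([1, 0, 1, 0, 1, 0])
        g = np.array([[1.0], [0], [2], [0], [0], [1]])
        res = skato_test(null, g)
        assert res.p_skato == pytest.approx(res.p_skat)
        assert res.p_skat == pytest.approx(res.p_burden)


class TestInvariances:
    @pytest.fixture(scope="class")
    def data(self):
        rng = np.random.default_rng(8)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.35).astype(float)
        G = rng.binomial(2, 0.06, size=(n, 6)).astype(float)
        return y, X, G

    def test_orthogonal_covariate_changes_nothing(self, data):
        y, X, G = data
        rng = np.random.default_rng(9)
        v = rng.normal(size=len(y))
        basis = np.column_stack([X, y, G])
        v -= basis @ np.linalg.lstsq(basis, v, rcond=None)[0]  # orthogonalize
        p0 = skat_test(fit_null(y, X), G)
        p1 = skat_test(fit_null(y, np.column_stack([X, v])), G)
        assert p1 == pytest.approx(p0, abs=1e-6)
        b0 = burden_test(fit_null(y, X), G)
        b1 = burden_test(fit_null(y, np.column_stack([X, v])), G)
        assert b1 == pytest.approx(b0, abs=1e-6)

    def test_weight_scaling_invariance(self, data):
        y, X, G = data
        null = fit_null(y, X)
        w = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 3.0])
        assert burden_test(null, G, 3 * w) == pytest.approx(
            burden_test(null, G, w), rel=1e-9
        )
        assert skat_test(null, G, 3 * w) == pytest.approx(
            skat_test(null, G, w), rel=1e-9
        )
        r0 = skato_test(null, G, w)
        r1 = skato_test(null, G, 3 * w)
        assert r1.p_skato == pytest.approx(r0.p_skato, rel=1e-6)


class TestStratification:
    def test_jaccard_pcs_restore_calibration_under_confounding(self):
        """Two subpopulations with different disease rates and partially
        private variants: the unadjusted SKAT type-I error is inflated,
        while including the Jaccard PCs brings it back inside the exact
        binomial band."""
        from scipy.stats import binom

        from rarewin.popstruct import jaccard_matrix, jaccard_pca
        from rarewin.simulate import (
            SimConfig, simulate_case_control, simulate_founder_panel,
        )

        cfg = SimConfig(
            n_cases=300, n_controls=300, n_chrom=1, variants_per_chrom=10_000,
            af_low=0.009, n_subpops=2, fst_like_divergence=0.5,
            n_panel_haplotypes=3000, seed=2,
        )
        panel = simulate_founder_panel(cfg)
        G, _, _, truth = simulate_case_control(cfg, panel)
        labels = np.array([truth.subpop_of_sample[s] for s in G.samples])
        rng = np.random.default_rng(2)
        # phenotype depends on subpopulation only — any association with
        # the (subpopulation-structured) genotypes is pure confounding
        y = (rng.random(len(labels)) < np.where(labels == 0, 0.25, 0.55)).astype(float)
        coords, _ = jaccard_pca(jaccard_matrix(G.dosage), 4)
        n = len(y)
        null_plain = fit_null(y, np.ones((n, 1)))
        null_pcs = fit_null(y, np.column_stack([np.ones(n), coords]))
        hits_plain = hits_pcs = tested = 0
        for start in range(0, 3000, 10):
            Gw = G.dosage[:, start : start + 10]
            if np.ptp(Gw) == 0:
                continue
            tested += 1
            hits_plain += skat_test(null_plain, Gw) <= 0.05
            hits_pcs += skat_test(null_pcs, Gw) <= 0.05
        lo = binom.ppf(0.025, tested, 0.05)
        hi = binom.ppf(0.975, tested, 0.05)
        assert hits_plain > hi, (hits_plain, hi)
        assert lo <= hits_pcs <= hi, (hits_pcs, lo, hi)


class TestDesign:
    def test_center_dummies_age_sex_pcs(self):
        import pandas as pd

        cov = pd.DataFrame(
            {
                "center": ["C1", "C2", "C1"],
                "age": [70, 65, 80],
                "sex": [1, 2, 1],
                "PC1": [0.1, -0.2, 0.0],
                "PC2": [0.3, 0.1, -0.1],
            },
            index=pd.Index(["a", "b", "c"], name="iid"),
        )
        X, names = build_design(cov, ["b", "a"], n_pcs=1)
        assert names == ["intercept", "center_C2", "age", "sex", "PC1"]
        np.testing.assert_allclose(X[0], [1, 1, 65, 2, -0.2])
        assert X.shape == (2, 5)
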