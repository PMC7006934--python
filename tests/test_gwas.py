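"""Association scan: OLS oracle, permutation threshold, inflation, marker H2."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from diallelgp import (GwasConfig, fit_null_varcomp, build_null, scan,
                       permutation_threshold, inflation_factor, select_model,
                       ase, marker_h2, significant_marker_h2,
                       grm_additive, pca_covariates)
from diallelgp.gwas import NullModel
from conftest import toy_genotypes


@pytest.fixture(scope="module")
def iid_panel():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.1, 0.5, 300)
    dos = rng.binomial(2, p, size=(120, 300)).astype(float)
    return toy_genotypes(dos, role="hybrids")


class TestScanOlsOracle:
    def test_matches_statsmodels_without_kinship(self, iid_panel):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(iid_panel.n_samples)
        cfg = GwasConfig(coding="A", kinship=(), n_pc=0, n_perm=100)
        null = fit_null_varcomp(y, None, {})
        res = scan(y, iid_panel, cfg, null)
        for j in [0, 7, 150, 299]:
            x = iid_panel.dosages[:, j] - 1.0
            X = sm.add_constant(x)
            ols = sm.OLS(y, X).fit()
            assert res.table["beta_A"].iloc[j] == pytest.approx(
                ols.params[1], abs=1e-8)
            assert res.table["p_A"].iloc[j] == pytest.approx(
                ols.pvalues[1], abs=1e-8)

    def test_matches_statsmodels_with_pcs(self, iid_panel):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(iid_panel.n_samples)
        cfg = GwasConfig(coding="A", kinship=(), n_pc=2, n_perm=100)
        pcs = pca_covariates(iid_panel, 2)
        null = fit_null_varcomp(y, pcs, {})
        res = scan(y, iid_panel, cfg, null)
        j = 42
        X = sm.add_constant(np.column_stack(
            [pcs, iid_panel.dosages[:, j] - 1.0]))
        ols = sm.OLS(y, X).fit()
        assert res.table["p_A"].iloc[j] == pytest.approx(ols.pvalues[-1],
                                                         abs=1e-8)

    def test_ad_marginal_tests_match_joint_ols(self, iid_panel):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(iid_panel.n_samples)
        cfg = GwasConfig(coding="AD", kinship=(), n_pc=0, n_perm=100)
        null = fit_null_varcomp(y, None, {})
        res = scan(y, iid_panel, cfg, null)
        j = 11
        a = iid_panel.dosages[:, j] - 1.0
        d = (iid_panel.dosages[:, j] == 1.0).astype(float)
        ols = sm.OLS(y, sm.add_constant(np.column_stack([a, d]))).fit()
        assert res.table["beta_A"].iloc[j] == pytest.approx(ols.params[1],
                                                            abs=1e-8)
        assert res.table["p_D"].iloc[j] == pytest.approx(ols.pvalues[2],
                                                         abs=1e-8)


class TestNullModel:
    def test_pure_noise_gives_small_polygenic_share(self, iid_panel):
        shares = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(iid_panel.n_samples)
            G = grm_additive(iid_panel)
            null = fit_null_varcomp(y, None, {"sigma2_a": G})
            s2a = null.varcomps["sigma2_a"]
            shares.append(s2a / (s2a + null.varcomps["sigma2_e"]))
        assert np.mean(shares) < 0.15

    def test_duplicate_kinship_warns(self, iid_panel):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(iid_panel.n_samples)
        G = grm_additive(iid_panel)
        with pytest.warns(UserWarning, match="identical kinships"):
            fit_null_varcomp(y, None, {"k1": G, "k2": G})

    def test_whitener_inverts_covariance(self, iid_panel):
        rng = np.random.default_rng(5)
        G = grm_additive(iid_panel)
        h = np.linalg.cholesky(G.values + 1e-6 * np.eye(G.n)) \
            @ rng.standard_normal(G.n)
        y = h + rng.standard_normal(G.n)
        null = fit_null_varcomp(y, None, {"sigma2_a": G})
        s2a, s2e = null.varcomps["sigma2_a"], null.varcomps["sigma2_e"]
        Sigma = s2a * G.values + s2e * np.eye(G.n)
        W = null.whitener
        np.testing.assert_allclose(W @ Sigma @ W.T, np.eye(G.n), atol=1e-6)


class TestScanBehaviour:
    def test_planted_qtl_detected(self):
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            p = rng.uniform(0.2, 0.5, 150)
            dos = rng.binomial(2, p, size=(300, 150)).astype(float)
            g = toy_genotypes(dos, role="hybrids")
            x = dos[:, 50] - 1.0
            beta = np.sqrt(0.20 / 0.80) / x.std()  # ~20% of variance
            y = beta * x + rng.standard_normal(300)
            cfg = GwasConfig(coding="A", kinship=(), n_pc=0, n_perm=400,
                             seed=seed)
            null = fit_null_varcomp(y, None, {})
            res = scan(y, g, cfg, null)
            thr = permutation_threshold(y, g, cfg, null)
            if res.table["p_A"].iloc[50] <= thr:
                hits += 1
        assert hits >= 0.9 * n_seeds - 1

    def test_no_heterozygote_marker_skipped_under_d(self):
        rng = np.random.default_rng(6)
        dos = rng.choice([0.0, 1.0, 2.0], size=(60, 5))
        dos[:, 2] = np.where(dos[:, 2] == 1.0, 0.0, dos[:, 2])
        g = toy_genotypes(dos, role="hybrids")
        y = rng.standard_normal(60)
        cfg = GwasConfig(coding="D", kinship=(), n_pc=0, n_perm=100)
        res = scan(y, g, cfg, fit_null_varcomp(y, None, {}))
        assert np.isnan(res.table["p_D"].iloc[2])
        assert res.table["skip_reason"].iloc[2] != ""

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.5, 1000)
        dos = rng.binomial(2, p, size=(200, 1000)).astype(float)
        g = toy_genotypes(dos, role="hybrids")
        y = rng.standard_normal(200)
        cfg = GwasConfig(coding="A", kinship=(), n_pc=0, n_perm=100)
        res = scan(y, g, cfg, fit_null_varcomp(y, None, {}))
        pv = res.table["p_A"].dropna()
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_ad_additive_matches_a_scan_without_dominance(self, iid_panel):
        rng = np.random.default_rng(8)
        x = iid_panel.dosages[:, 10] - 1.0
        y = 0.8 * x + rng.standard_normal(iid_panel.n_samples)
        null = fit_null_varcomp(y, None, {})
        resA = scan(y, iid_panel, GwasConfig(coding="A", kinship=(),
                                             n_perm=100), null)
        resAD = scan(y, iid_panel, GwasConfig(coding="AD", kinship=(),
                                              n_perm=100), null)
        assert resAD.table["beta_A"].iloc[10] == pytest.approx(
            resA.table["beta_A"].iloc[10], rel=0.15)


class TestPermutationThreshold:
    def test_order_statistic_definition(self, iid_panel):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(iid_panel.n_samples)
        cfg = GwasConfig(coding="A", kinship=(), n_pc=0, n_perm=100,
                         alpha=0.05, seed=1)
        null = fit_null_varcomp(y, None, {})
        thr, minp = permutation_threshold(y, iid_panel, cfg, null,
                                          return_minp=True)
        assert thr == np.sort(minp)[4]  # ceil(0.05*100) = 5th smallest

    def test_monotone_in_alpha(self, iid_panel):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(iid_panel.n_samples)
        null = fit_null_varcomp(y, None, {})
        thrs = []
        for alpha in (0.01, 0.05, 0.10):
            cfg = GwasConfig(coding="A", kinship=(), n_pc=0, n_perm=200,
                             alpha=alpha, seed=2)
            thrs.append(permutation_threshold(y, iid_panel, cfg, null))
        assert thrs[0] <= thrs[1] <= thrs[2]

    def test_insufficient_permutations_rejected(self, iid_panel):
        y = np.random.default_rng(11).standard_normal(iid_panel.n_samples)
        cfg = GwasConfig(coding="A", kinship=(), n_perm=30, alpha=0.01)
        with pytest.raises(ValueError):
            permutation_threshold(y, iid_panel, cfg)


class TestModelSelection:
    def test_single_candidate_returned(self, iid_panel):
        y = np.random.default_rng(12).standard_normal(iid_panel.n_samples)
        res = scan(y, iid_panel, GwasConfig(coding="A", kinship=(),
                                            n_perm=100),
                   fit_null_varcomp(y, None, {}))
        assert select_model([res]) is res

    def test_calibrated_null_lambda_near_one(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.1, 0.5, 1000)
        dos = rng.binomial(2, p, size=(150, 1000)).astype(float)
        g = toy_genotypes(dos, role="hybrids")
        y = rng.standard_normal(150)
        res = scan(y, g, GwasConfig(coding="A", kinship=(), n_perm=100),
                   fit_null_varcomp(y, None, {}))
        assert res.lambda_gc == pytest.approx(1.0, abs=0.12)

    def test_structure_inflates_and_pc_corrects(self):
        """Two diverged groups with a group-shifted phenotype inflate the
        naive scan; one PC restores calibration."""
        from diallelgp import SimConfig, simulate_parents, make_diallel, \
            make_hybrid_genotypes
        cfg = SimConfig(n_parents_group1=20, n_parents_group2=20,
                        n_markers=800, n_hybrids=150, group_divergence=0.35,
                        seed=14, allow_intragroup=True)
        parents = simulate_parents(cfg)
        des = make_diallel(parents, 150, seed=14, allow_intragroup=True)
        hyb = make_hybrid_genotypes(parents, des)
        pc1 = pca_covariates(hyb, 1)[:, 0]
        rng = np.random.default_rng(15)
        y = pc1 / pc1.std() + rng.standard_normal(150)
        res0 = scan(y, hyb, GwasConfig(coding="A", kinship=(), n_pc=0,
                                       n_perm=100),
                    fit_null_varcomp(y, None, {}))
        res1 = scan(y, hyb, GwasConfig(coding="A", kinship=(), n_pc=1,
                                       n_perm=100),
                    fit_null_varcomp(y, pca_covariates(hyb, 1), {}))
        assert res0.lambda_gc > 1.15
        assert abs(res1.lambda_gc - 1) < abs(res0.lambda_gc - 1)
        assert select_model([res0, res1]) is res1


class TestEffectDecomposition:
    def test_ase_reference_values(self):
        assert ase(-9.56, 10.60, 0.08) == pytest.approx(-0.656, abs=1e-10)
        assert ase(3.0, 0.0, 0.2) == 3.0
        assert ase(3.0, 1.7, 0.5) == 3.0

    def test_marker_h2_reference_value(self):
        # MAF 0.10, alpha -2.30 against a phenotypic variance of 37.79
        mh = marker_h2(0.10, 37.79, "additive", alpha=-2.30)
        assert mh.h2 == pytest.approx(0.0252, abs=1e-4)

    def test_zero_effect_zero_h2(self):
        assert marker_h2(0.3, 10.0, "additive", alpha=0.0).h2 == 0.0

    def test_ad_reduces_to_additive_when_d_zero(self):
        add = marker_h2(0.2, 5.0, "additive", alpha=1.3)
        ada = marker_h2(0.2, 5.0, "AD-additive", a=1.3, d=0.0)
        dom = marker_h2(0.2, 5.0, "AD-dominance", d=0.0)
        assert ada.h2 == pytest.approx(add.h2, abs=1e-14)
        assert dom.h2 == 0.0
        assert ada.alpha == pytest.approx(1.3)

    def test_input_guards(self):
        with pytest.raises(ValueError):
            marker_h2(0.0, 1.0, "additive", alpha=1.0)
        with pytest.raises(ValueError):
            marker_h2(0.5, 0.0, "additive", alpha=1.0)
        with pytest.raises(ValueError):
            ase(1.0, 1.0, 1.0)

    def test_h2_matches_realized_variance_fraction(self):
        """Evaluated at the true effects, the formulas track the realized
        share of phenotypic variance at large n."""
        rng = np.random.default_rng(16)
        n = 1000
        p = 0.3
        dos = rng.binomial(2, p, n).astype(float)
        a_eff, d_eff = 0.9, 0.5
        g_val = a_eff * (dos - 1.0) + d_eff * (dos == 1.0)
        y = g_val + rng.standard_normal(n)
        var_g = float(np.var(y, ddof=1))
        p_hat = dos.mean() / 2.0
        mh_a = marker_h2(p_hat, var_g, "AD-additive", a=a_eff, d=d_eff)
        mh_d = marker_h2(p_hat, var_g, "AD-dominance", d=d_eff)
        realized = np.var(g_val) / np.var(y)
        assert (mh_a.h2 + mh_d.h2) == pytest.approx(realized, rel=0.2)


def test_significant_marker_h2_table(iid_panel):
    rng = np.random.default_rng(17)
    x = iid_panel.dosages[:, 5] - 1.0
    y = 1.2 * x + rng.standard_normal(iid_panel.n_samples)
    cfg = GwasConfig(coding="AD", kinship=(), n_pc=0, n_perm=100, seed=3)
    null = fit_null_varcomp(y, None, {})
    res = scan(y, iid_panel, cfg, null)
    res.threshold = permutation_threshold(y, iid_panel, cfg, null)
    tab = significant_marker_h2(res, y)
    assert "m5" in set(tab["marker_id"])
    row = tab.set_index("marker_id").loc["m5"]
    assert 0.0 < row["h2_additive"] < 1.0
    assert row["var_g"] == pytest.approx(np.var(y, ddof=1))
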