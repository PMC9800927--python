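import numpy as np
import pytest

import clonegs as cg
from clonegs.bayes import McmcConfig, _run, run_bayesB, run_bayesCpi


@pytest.fixture(scope="module")
def marker_panel():
    cfg = cg.SimConfig(n_clones=200, m_markers=500, seed=21, family_size=1)
    g = cg.simulate_genotypes(cfg)
    return cg.build_designs(cg.impute_mean(g))


class TestConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(pi=1.0)
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)


class TestBayesB:
    def test_seed_determinism(self, marker_panel):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 200)
        mc = McmcConfig(n_iter=600, burn_in=100, thin=2, seed=9, pi=0.9)
        a = run_bayesB(y, marker_panel, mc)
        b = run_bayesB(y, marker_panel, mc)
        np.testing.assert_array_equal(a.chains.to_numpy(), b.chains.to_numpy())
        np.testing.assert_array_equal(a.effects_a, b.effects_a)

    def test_null_inclusion_low(self, marker_panel):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 200)
        post = run_bayesB(y, marker_panel,
                          McmcConfig(n_iter=2000, burn_in=500, thin=5,
                                     seed=2, pi=0.99))
        assert post.inclusion_a.mean() < 0.05

    def test_large_effect_markers_recovered(self):
        # 20 equal large effects among 1000 markers, h2 = 0.5
        cfg = cg.SimConfig(n_clones=500, m_markers=1000, seed=22,
                           family_size=1)
        g = cg.simulate_genotypes(cfg)
        d = cg.build_designs(cg.impute_mean(g))
        rng = np.random.default_rng(3)
        causal = rng.choice(d.Z_add.shape[1], 20, replace=False)
        alpha = np.zeros(d.Z_add.shape[1])
        alpha[causal] = rng.choice([-1.0, 1.0], 20)
        gv = d.Z_add @ alpha
        gv = gv / gv.std()
        y = gv + rng.normal(0, 1, cfg.n_clones)
        post = run_bayesB(y, d, McmcConfig(n_iter=3000, burn_in=800, thin=5,
                                           seed=4, pi=0.98))
        top = np.argsort(-post.inclusion_a)[:20]
        assert len(set(top) & set(causal)) >= 10

    def test_ridge_agreement_with_pi_zero(self, marker_panel):
        # no point mass + common variance: posterior means ~ SNP-BLUP
        rng = np.random.default_rng(5)
        Z = marker_panel.Z_add
        y = Z @ rng.normal(0, 0.05, Z.shape[1]) + rng.normal(0, 1, 200)
        post = _run(y, marker_panel,
                    McmcConfig(n_iter=4000, burn_in=800, thin=4, seed=6,
                               pi=0.0),
                    with_dominance=False, estimate_pi=False, common_var=True)
        s2m = post.sigma2_a / np.sum(np.var(Z, axis=0))
        lam = post.sigma2_e / s2m
        ridge = np.linalg.solve(Z.T @ Z + lam * np.eye(Z.shape[1]),
                                Z.T @ (y - y.mean()))
        assert np.corrcoef(ridge, post.effects_a)[0, 1] > 0.98

    def test_dominance_variance_accounting(self, marker_panel):
        # additive-only model: genetic variance equals additive variance
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 200)
        mc = McmcConfig(n_iter=600, burn_in=100, thin=2, seed=8, pi=0.9)
        post = run_bayesB(y, marker_panel, mc, with_dominance=False)
        np.testing.assert_allclose(post.chains["sigma2_g"],
                                   post.chains["sigma2_a"], rtol=1e-10)
        assert post.sigma2_d == pytest.approx(0.0, abs=1e-12)
        post_ad = run_bayesB(y, marker_panel, mc, with_dominance=True)
        assert post_ad.sigma2_d > 0

    def test_intercept_centering_on_null(self, marker_panel):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, 200)  # centered null
        post = run_bayesB(y - y.mean(), marker_panel,
                          McmcConfig(n_iter=1500, burn_in=400, thin=3,
                                     seed=10, pi=0.95))
        assert abs(post.mu) < 3 * post.chains["mu"].std() + 0.05


class TestBayesCpi:
    def test_null_pi_high(self, marker_panel):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, 200)
        post = run_bayesCpi(y, marker_panel,
                            McmcConfig(n_iter=6000, burn_in=1500, thin=5,
                                       seed=12))
        assert post.pi_a > 0.9

    def test_dense_architecture_pi_low(self, marker_panel):
        rng = np.random.default_rng(13)
        Z = marker_panel.Z_add
        gv = Z @ rng.normal(0, 1, Z.shape[1])
        gv = gv / gv.std()
        y = gv + rng.normal(0, 1, 200)
        post = run_bayesCpi(y, marker_panel,
                            McmcConfig(n_iter=6000, burn_in=1500, thin=5,
                                       seed=14))
        assert post.pi_a < 0.5

    def test_seed_determinism(self, marker_panel):
        rng = np.random.default_rng(15)
        y = rng.normal(0, 1, 200)
        mc = McmcConfig(n_iter=500, burn_in=100, thin=2, seed=16)
        a = run_bayesCpi(y, marker_panel, mc)
        b = run_bayesCpi(y, marker_panel, mc)
        np.testing.assert_array_equal(a.chains.to_numpy(), b.chains.to_numpy())


class TestPrediction:
    def test_predict_requires_dominance_design(self, marker_panel):
        rng = np.random.default_rng(17)
        y = rng.normal(0, 1, 200)
        post = run_bayesB(y, marker_panel,
                          McmcConfig(n_iter=400, burn_in=100, thin=2,
                                     seed=18, pi=0.9), with_dominance=True)
        with pytest.raises(ValueError, match="dominance"):
            post.predict(marker_panel.Z_add)
        out = post.predict(marker_panel.Z_add, marker_panel.H_classical)
        assert out["gegv"].shape == (200,)
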