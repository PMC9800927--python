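import numpy as np
import pytest

import clonegs as cg
from clonegs.gblup import (ModelSpec, fit_gblup, heritabilities,
                           heritability_ratios, predict_new)
from clonegs.genotypes import build_designs, from_dosages
from clonegs.kinship import RelationshipMatrix, condition_psd
from clonegs.mixed_model import RandomTerm, mme_solve


def small_instance(n=8, m=4, seed=3):
    rng = np.random.default_rng(seed)
    dos = rng.integers(0, 3, (n, m)).astype(float)
    g = from_dosages([f"c{i}" for i in range(n)],
                     [f"m{j}" for j in range(m)], dos, orient_major=False)
    d = build_designs(g)
    y = rng.normal(0, 2, n)
    return g, d, y


class TestHeritabilityRatios:
    # variance components published for this germplasm; ratios must
    # reproduce the reported heritabilities exactly
    @pytest.mark.parametrize("s2a, s2g, s2e, h2, H2", [
        (17.0, 17.0, 32.0, 0.347, None),   # yield, additive model
        (6.4, 17.9, 28.5, None, 0.386),    # yield, additive-dominant classical
        (2.6, 19.4, 29.1, None, 0.400),    # yield, additive-dominant genotypic
        (1.92, 2.10, 1.92, None, 0.522),   # dry matter, classical
        (2.61, 2.61, 2.57, None, 0.504),   # dry yield, kernel model
    ])
    def test_reported_ratios(self, s2a, s2g, s2e, h2, H2):
        got_h2, got_H2 = heritability_ratios(s2a, s2g, s2e)
        if h2 is not None:
            assert round(got_h2, 3) == h2
        if H2 is not None:
            assert round(got_H2, 3) == H2

    def test_zero_additive(self):
        h2, H2 = heritability_ratios(0.0, 2.0, 2.0)
        assert h2 == 0.0 and H2 == 0.5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            heritability_ratios(0.0, 0.0, 0.0)


class TestEquivalenceOracle:
    """G-BLUP solutions must equal marker-effect (SNP-BLUP) solutions at the
    matched variance ratio — the canonical sanity check for the MME path."""

    def test_additive_model(self):
        g, d, y = small_instance()
        Z = d.Z_add
        c = 2 * np.sum(d.p * (1 - d.p))
        G = Z @ Z.T / c + 1e-10 * np.eye(len(y))
        s2a, s2e = 1.7, 0.9
        X = np.ones((len(y), 1))
        gb = mme_solve(y, X, [RandomTerm("a", np.eye(len(y)), G)],
                       {"a": s2a, "residual": s2e})
        rr = mme_solve(y, X, [RandomTerm("m", Z)],
                       {"m": s2a / c, "residual": s2e})
        np.testing.assert_allclose(gb.u["a"], Z @ rr.u["m"], atol=1e-6)

    def test_additive_dominant_model(self):
        g, d, y = small_instance(seed=5)
        Z, H = d.Z_add, d.H_classical
        ca = 2 * np.sum(d.p * (1 - d.p))
        cd = np.sum((2 * d.p * (1 - d.p)) ** 2)
        n = len(y)
        G = Z @ Z.T / ca + 1e-10 * np.eye(n)
        D = H @ H.T / cd + 1e-10 * np.eye(n)
        comp = {"a": 1.3, "d": 0.8, "residual": 1.1}
        X = np.ones((n, 1))
        gb = mme_solve(y, X, [RandomTerm("a", np.eye(n), G),
                              RandomTerm("d", np.eye(n), D)], comp)
        rr = mme_solve(y, X, [RandomTerm("am", Z), RandomTerm("dm", H)],
                       {"am": 1.3 / ca, "dm": 0.8 / cd, "residual": 1.1})
        np.testing.assert_allclose(gb.u["a"] + gb.u["d"],
                                   Z @ rr.u["am"] + H @ rr.u["dm"], atol=1e-6)


def panel_fit(small_panel, panel_cvdata, terms):
    data = panel_cvdata
    spec = ModelSpec(data.dblup.astype(float), data.clone_ids,
                     [(data.kinships[k], lab) for k, lab in terms])
    return spec, fit_gblup(spec)


class TestFitGblup:
    def test_heritability_recovery_additive(self):
        # single additive term, true h2 = 0.5, direct clone phenotypes
        rng = np.random.default_rng(10)
        hits = 0
        for seed in range(8):
            cfg = cg.SimConfig(n_clones=400, m_markers=1200, seed=seed,
                               profile="custom", sigma2_a=1.0, sigma2_d=0.0,
                               sigma2_e=1.0)
            g = cg.simulate_genotypes(cfg)
            true = cg.simulate_effects(g, cfg)
            y = true.genotypic + rng.normal(0, 1.0, cfg.n_clones)
            G = condition_psd(cg.additive_G(cg.build_designs(g)))
            fit = fit_gblup(ModelSpec(y, g.clone_ids, [(G, "additive")]))
            h2, _ = heritabilities(fit)
            hits += 0.35 <= h2 <= 0.65
        assert hits >= 6

    def test_dominance_small_on_additive_data(self):
        rng = np.random.default_rng(11)
        fracs = []
        for seed in range(5):
            cfg = cg.SimConfig(n_clones=300, m_markers=1000, seed=100 + seed,
                               profile="custom", sigma2_a=1.0, sigma2_d=0.0,
                               sigma2_e=1.0)
            g = cg.simulate_genotypes(cfg)
            true = cg.simulate_effects(g, cfg)
            y = true.genotypic + rng.normal(0, 1.0, cfg.n_clones)
            d = cg.build_designs(g)
            G = condition_psd(cg.additive_G(d))
            D = condition_psd(cg.dominance_classical(d))
            fit = fit_gblup(ModelSpec(y, g.clone_ids,
                                      [(G, "additive"), (D, "dominance")]))
            fracs.append(fit.sigma2_d / fit.sigma2_g)
        assert np.mean(fracs) < 0.15

    def test_prediction_shift_invariance(self, small_panel, panel_cvdata):
        spec, fit = panel_fit(small_panel, panel_cvdata,
                              [("additive", "additive")])
        spec2 = ModelSpec(spec.y_d + 100.0, spec.clone_ids, spec.random_terms)
        fit2 = fit_gblup(spec2)
        np.testing.assert_allclose(fit2.gebv, fit.gebv, atol=1e-4)
        assert fit2.mu == pytest.approx(fit.mu + 100.0, abs=1e-3)

    def test_rkhs_is_gblup_with_kernel_covariance(self, small_panel,
                                                  panel_cvdata):
        # one code path: swapping in the kernel is the whole RKHS model
        data = panel_cvdata
        spec = ModelSpec(data.dblup.astype(float), data.clone_ids,
                         [(data.kinships["gaussian_kernel"], "genotypic")])
        fit = fit_gblup(spec)
        assert fit.sigma2_g == fit.variance_components["genotypic"]
        np.testing.assert_allclose(fit.gegv,
                                   fit.solutions["genotypic"], atol=1e-12)

    def test_masked_duplicate_clone_gets_same_prediction(self):
        rng = np.random.default_rng(12)
        cfg = cg.SimConfig(n_clones=60, m_markers=300, seed=13,
                           profile="custom", sigma2_a=1.0, sigma2_d=0.0,
                           sigma2_e=0.5)
        g = cg.simulate_genotypes(cfg)
        dos = g.dosages.copy()
        dos[1] = dos[0]  # clone 1 duplicates clone 0
        g2 = cg.from_dosages(g.clone_ids, g.marker_ids, dos,
                             orient_major=False)
        G = condition_psd(cg.additive_G(cg.build_designs(g2)))
        true = cg.simulate_effects(g2, cfg)
        y = true.genotypic + rng.normal(0, 0.7, 60)
        y_masked = y.copy()
        y_masked[1] = np.nan  # duplicate is unphenotyped
        fit = fit_gblup(ModelSpec(y_masked, g2.clone_ids, [(G, "additive")]))
        assert fit.gebv[1] == pytest.approx(fit.gebv[0], abs=1e-3)
        pred = predict_new(fit, None, [g2.clone_ids[1]])
        assert pred["gebv"][0] == pytest.approx(fit.gebv[1])

    def test_predict_unknown_clone_rejected(self, small_panel, panel_cvdata):
        _, fit = panel_fit(small_panel, panel_cvdata,
                           [("additive", "additive")])
        with pytest.raises(KeyError, match="ghost"):
            predict_new(fit, None, ["ghost"])
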