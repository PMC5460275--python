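import numpy as np
import pytest

from palmgs.containers import GenotypeMatrix
from palmgs.wgr import (
    BAYES_METHODS,
    BayesianWGR,
    RRBLUP,
    WGRConfig,
    fit_bayes,
    fit_rrblup,
    predict_gebv,
)

from conftest import unrelated_genotypes


def _sim(n, m, h2, n_qtl, seed):
    rng = np.random.default_rng(seed)
    G = unrelated_genotypes(n, m, seed=seed)
    qtl = rng.choice(m, n_qtl, replace=False)
    eff = rng.standard_normal(n_qtl)
    tbv = G.dosages[:, qtl].astype(float) @ eff
    noise = rng.normal(0, np.sqrt(tbv.var() * (1 - h2) / h2), n)
    return G, tbv + noise


class TestRRBLUP:
    def test_ridge_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        D = rng.integers(0, 3, (5, 3)).astype(float)
        y = rng.standard_normal(5)
        fit = RRBLUP(y, D).fit(lambda_=1.0)
        Mc = D - D.mean(axis=0)
        oracle = np.linalg.inv(Mc.T @ Mc + np.eye(3)) @ Mc.T @ (y - y.mean())
        np.testing.assert_allclose(fit.marker_effects, oracle, atol=1e-10)

    def test_gblup_equivalence(self):
        G, y = _sim(80, 150, h2=0.5, n_qtl=20, seed=1)
        fit = RRBLUP(y, G).fit()
        Mc = G.dosages.astype(float) - G.dosages.astype(float).mean(axis=0)
        K = Mc @ Mc.T
        V = fit.sigma2_u * K + fit.sigma2_e * np.eye(80)
        g_blup = fit.sigma2_u * K @ np.linalg.solve(V, y - y.mean())
        np.testing.assert_allclose(Mc @ fit.marker_effects, g_blup, atol=1e-8)

    def test_no_signal_shrinks_to_intercept(self):
        rng = np.random.default_rng(2)
        G = unrelated_genotypes(60, 100, seed=2)
        y = 5.0 + 1e-8 * rng.standard_normal(60)
        fit = RRBLUP(y, G).fit()
        assert np.abs(fit.marker_effects).max() < 1e-6
        assert fit.intercept == pytest.approx(5.0, abs=1e-6)

    def test_constant_phenotype_errors(self):
        G = unrelated_genotypes(20, 10, seed=3)
        with pytest.raises(ValueError, match="constant"):
            RRBLUP(np.ones(20), G)

    def test_marker_permutation_invariance(self):
        G, y = _sim(50, 40, h2=0.6, n_qtl=10, seed=4)
        fit = RRBLUP(y, G.dosages).fit()
        perm = np.random.default_rng(5).permutation(40)
        fit_p = RRBLUP(y, G.dosages[:, perm]).fit()
        np.testing.assert_allclose(fit_p.marker_effects, fit.marker_effects[perm],
                                   atol=1e-6)

    def test_huge_lambda_gives_intercept_only(self):
        G, y = _sim(50, 40, h2=0.6, n_qtl=10, seed=6)
        fit = RRBLUP(y, G).fit(lambda_=1e12)
        assert np.abs(fit.marker_effects).max() < 1e-6
        np.testing.assert_allclose(fit.predict(G), fit.intercept, atol=1e-4)

    def test_predict_contracts(self):
        G, y = _sim(40, 30, h2=0.6, n_qtl=5, seed=7)
        fit = RRBLUP(y, G).fit()
        # in-sample prediction equals fitted values
        np.testing.assert_allclose(fit.predict(G), fit.fittedvalues)
        # all-zero dosage row maps to the raw-scale intercept
        zero = np.zeros((1, 30))
        assert fit.predict(zero)[0] == pytest.approx(fit.intercept)
        # linearity: doubling one effect doubles its contribution
        one = np.zeros((1, 30))
        one[0, 4] = 2
        contrib = fit.predict(one)[0] - fit.intercept
        assert contrib == pytest.approx(2 * fit.marker_effects[4])

    def test_predict_marker_alignment(self):
        G, y = _sim(40, 30, h2=0.6, n_qtl=5, seed=8)
        fit = RRBLUP(y, G.subset_markers(np.arange(10))).fit()
        with pytest.warns(UserWarning, match="extra markers"):
            pred = fit.predict(G)
        assert len(pred) == 40
        with pytest.raises(ValueError, match="missing"):
            fit.predict(G.subset_markers(np.arange(12, 30)))


class TestBayesian:
    def test_near_zero_phenotype_gives_zero_effects(self):
        rng = np.random.default_rng(9)
        G = unrelated_genotypes(50, 60, seed=9)
        y = 1e-9 * rng.standard_normal(50)
        for method in BAYES_METHODS:
            cfg = WGRConfig(method=method, n_iter=1500, burn_in=500, seed=1)
            fit = BayesianWGR(y, G, config=cfg).fit()
            assert np.abs(fit.marker_effects).max() < 1e-4, method

    def test_brr_matches_rrblup(self):
        G, y = _sim(200, 400, h2=0.6, n_qtl=80, seed=10)
        rr = RRBLUP(y, G).fit()
        cfg = WGRConfig(method="BRR", n_iter=8000, burn_in=2000, seed=2)
        brr = BayesianWGR(y, G, config=cfg).fit()
        r = np.corrcoef(rr.marker_effects, brr.marker_effects)[0, 1]
        assert r > 0.98

    def test_chains_agree_across_seeds(self):
        G, y = _sim(150, 250, h2=0.6, n_qtl=40, seed=11)
        fits = []
        for seed in (1, 2):
            cfg = WGRConfig(method="BRR", n_iter=8000, burn_in=2000, seed=seed)
            fits.append(BayesianWGR(y, G, config=cfg).fit())
        r = np.corrcoef(fits[0].marker_effects, fits[1].marker_effects)[0, 1]
        assert r > 0.99

    def test_bayes_c_recovers_single_qtl(self):
        rng = np.random.default_rng(12)
        G = unrelated_genotypes(500, 300, seed=12)
        qtl = 123
        g = G.dosages[:, qtl].astype(float)
        y = 1.0 * g + rng.normal(0, np.sqrt(g.var() * 0.25 / 0.75), 500)
        cfg = WGRConfig(method="BC", n_iter=6000, burn_in=1500, seed=3)
        fit = BayesianWGR(y, G, config=cfg).fit()
        assert fit.pi_hat > 0.9
        assert fit.marker_effects[qtl] == pytest.approx(1.0, abs=0.25)

    def test_reproducible_under_seed(self):
        G, y = _sim(60, 80, h2=0.5, n_qtl=10, seed=13)
        cfg = WGRConfig(method="BL", n_iter=1200, burn_in=300, seed=7)
        f1 = BayesianWGR(y, G, config=cfg).fit()
        f2 = BayesianWGR(y, G, config=WGRConfig(**cfg.__dict__)).fit()
        np.testing.assert_array_equal(f1.marker_effects, f2.marker_effects)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            WGRConfig(method="BA", n_iter=100, burn_in=100).validate()
        with pytest.raises(ValueError, match="method"):
            WGRConfig(method="XX").validate()

    def test_all_methods_agree_on_gebv_direction(self):
        # on polygenic data all five models should give near-identical GEBVs
        G, y = _sim(200, 300, h2=0.6, n_qtl=100, seed=14)
        gebvs = [RRBLUP(y, G).fit().predict(G)]
        for method in BAYES_METHODS:
            cfg = WGRConfig(method=method, n_iter=4000, burn_in=1000, seed=4)
            gebvs.append(BayesianWGR(y, G, config=cfg).fit().predict(G))
        for i in range(len(gebvs)):
            for j in range(i + 1, len(gebvs)):
                assert np.corrcoef(gebvs[i], gebvs[j])[0, 1] > 0.9

    def test_summary_and_wrappers(self):
        G, y = _sim(40, 30, h2=0.6, n_qtl=5, seed=15)
        fit = fit_rrblup(G, y)
        text = fit.summary()
        assert "RRBLUP" in text and "sigma2_u" in text
        cfg = WGRConfig(method="BC", n_iter=800, burn_in=200, seed=5)
        fb = fit_bayes(G, y, cfg)
        assert "pi" in fb.summary()
        assert fb.ess_sigma2_e is not None and fb.ess_sigma2_e > 0
        np.testing.assert_allclose(predict_gebv(fit, G), fit.predict(G))
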