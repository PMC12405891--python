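import numpy as np
import pandas as pd
import pytest

import enbayes as eb
from enbayes.bayes import FittedBayesModel
from enbayes.errors import ValidationError
from enbayes.io import Dataset, GenotypeMatrix, PhenotypeVector
from conftest import make_dataset


class TestDefaultPrior:
    def _unit_dataset(self, p=10, n=40, seed=0):
        # all markers at allele frequency 0.5 -> sum 2f(1-f) = p/2
        rng = np.random.default_rng(seed)
        X = np.tile([0.0, 2.0], (n // 2, p)).reshape(n, p)
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std()  # var(y) = 1 exactly
        return make_dataset(X, y)

    def test_bayesrr_scale_matches_stated_target(self):
        ds = self._unit_dataset(p=10)
        prior = eb.default_prior("BayesRR", ds, h2_prior=0.5)
        target = 0.5 / (0.5 * 10)  # h2*var(y) / (pi_eff * sum 2f(1-f))
        assert prior.S == pytest.approx(target * (4.2 + 2) / 4.2)

    def test_bayesb_scale_inflated_by_pi0(self):
        ds = self._unit_dataset(p=10)
        rr = eb.default_prior("BayesRR", ds, h2_prior=0.5)
        bb = eb.default_prior("BayesB", ds, h2_prior=0.5)
        assert bb.S == pytest.approx(rr.S / 0.05)

    def test_h2_bounds_rejected(self):
        ds = self._unit_dataset()
        for bad in (0.0, 1.0):
            with pytest.raises(ValidationError):
                eb.default_prior("BayesA", ds, h2_prior=bad)

    def test_constant_phenotype_rejected(self):
        ds = self._unit_dataset()
        flat = Dataset(ds.genotypes,
                       PhenotypeVector(ds.phenotype.line_ids,
                                       np.ones(ds.n_lines)))
        with pytest.raises(ValidationError):
            eb.default_prior("BayesA", flat)

    def test_bayesr_mixture_defaults(self):
        ds = self._unit_dataset()
        prior = eb.default_prior("BayesR", ds)
        assert prior.mixture_scalers == (1e-3, 1e-2, 1e-1)
        assert prior.mixture_props == (1e-4, 1e-3, 1e-2)


class TestFitBayes:
    def test_fixed_variance_rr_matches_ridge_closed_form(self):
        rng = np.random.default_rng(2)
        n, p = 40, 12
        X = rng.integers(0, 3, size=(n, p)).astype(float)
        y = X @ (0.3 * rng.standard_normal(p)) + rng.standard_normal(n)
        ds = make_dataset(X, y)
        s2, s2e = 0.2, 1.0
        fit = eb.fit_bayes(ds, eb.default_prior("BayesRR", ds),
                           eb.MCMCConfig(2000, 500, 1, seed=0),
                           fixed_variances={"sigma2": s2, "sigma2_e": s2e})
        Zc = X - X.mean(0)
        ridge = np.linalg.solve(Zc.T @ Zc + (s2e / s2) * np.eye(p),
                                Zc.T @ (y - y.mean()))
        from enbayes.diagnostics import effective_sample_size
        for j in range(p):
            draws = fit.effect_samples[:, j]
            mcse = draws.std() / np.sqrt(max(effective_sample_size(draws), 1))
            assert abs(fit.u_hat[j] - ridge[j]) <= 3 * mcse + 1e-9

    def test_bit_identical_under_same_seed(self, tiny_ds, reduced_mcmc):
        ds, _ = tiny_ds
        prior = eb.default_prior("BayesR", ds)
        f1 = eb.fit_bayes(ds, prior, reduced_mcmc)
        f2 = eb.fit_bayes(ds, prior, reduced_mcmc)
        assert np.array_equal(f1.u_hat, f2.u_hat)
        assert f1.mu_hat == f2.mu_hat
        pd.testing.assert_frame_equal(f1.samples, f2.samples)

    def test_point_mass_shrinks_harder_than_ridge(self, tiny_ds):
        ds, _ = tiny_ds
        for seed in range(3):
            mcmc = eb.MCMCConfig.reduced(seed=seed)
            b = eb.fit_bayes(ds, eb.default_prior("BayesB", ds), mcmc)
            rr = eb.fit_bayes(ds, eb.default_prior("BayesRR", ds), mcmc)
            assert np.abs(b.u_hat).mean() <= np.abs(rr.u_hat).mean()

    def test_pi_stays_in_unit_interval_every_retained_draw(self, tiny_ds,
                                                           reduced_mcmc):
        ds, _ = tiny_ds
        for model in ("BayesBpi", "BayesCpi", "BayesR"):
            fit = eb.fit_bayes(ds, eb.default_prior(model, ds), reduced_mcmc)
            pi = fit.samples["pi"].to_numpy()
            assert pi.min() >= 0.0 and pi.max() <= 1.0

    def test_marker_permutation_equivariance_weak_form(self, tiny_ds):
        ds, _ = tiny_ds
        mcmc = eb.MCMCConfig.reduced(seed=4)
        fit1 = eb.fit_bayes(ds, eb.default_prior("BayesA", ds), mcmc)
        yhat1 = eb.predict_bayes(fit1, ds.genotypes).values
        perm = np.random.default_rng(0).permutation(ds.n_markers)
        g2 = GenotypeMatrix(ds.genotypes.line_ids,
                            ds.genotypes.marker_ids[perm],
                            ds.genotypes.dosages[:, perm])
        ds2 = Dataset(g2, ds.phenotype)
        fit2 = eb.fit_bayes(ds2, eb.default_prior("BayesA", ds2), mcmc)
        yhat2 = eb.predict_bayes(fit2, g2).values
        assert eb.pcc(yhat1, yhat2) > 0.98

    def test_too_few_lines_rejected(self):
        ds = make_dataset(np.zeros((5, 3)), np.arange(5.0))
        with pytest.raises(ValidationError):
            eb.fit_bayes(ds, eb.BayesPriorSpec(model="BayesA"),
                         eb.MCMCConfig.reduced())


class TestPredictBayes:
    def _manual_fit(self, u, mu=0.0, col_means=None):
        u = np.asarray(u, dtype=float)
        p = u.size
        nsave = 10
        return FittedBayesModel(
            model="BayesRR", mu_hat=mu, u_hat=u, sigma2_e_hat=1.0,
            pi_hat=1.0, inclusion_prob=np.ones(p),
            samples=pd.DataFrame(np.zeros((nsave, 3)),
                                 columns=["mu", "sigma2_e", "pi"]),
            marker_ids=np.array([f"M{j}" for j in range(p)], dtype=object),
            col_means=np.zeros(p) if col_means is None else
            np.asarray(col_means, float),
            effect_samples=np.zeros((nsave, p)),
        )

    def test_null_effects_give_intercept(self):
        fit = self._manual_fit([0.0, 0.0], mu=2.5)
        g = GenotypeMatrix(["A", "B"], ["M0", "M1"], [[0, 1], [2, 1]])
        np.testing.assert_allclose(eb.predict_bayes(fit, g).values, 2.5)

    def test_single_marker_hand_example_with_centering(self):
        fit = self._manual_fit([2.0], mu=0.0, col_means=[1.0])
        g = GenotypeMatrix(["A", "B", "C"], ["M0"], [[0], [1], [2]])
        np.testing.assert_allclose(eb.predict_bayes(fit, g).values,
                                   [-2.0, 0.0, 2.0])

    def test_in_sample_consistency(self, tiny_ds, reduced_mcmc):
        ds, _ = tiny_ds
        fit = eb.fit_bayes(ds, eb.default_prior("BayesL", ds), reduced_mcmc)
        yhat = eb.predict_bayes(fit, ds.genotypes).values
        manual = fit.mu_hat + (ds.genotypes.dosages - fit.col_means) @ fit.u_hat
        np.testing.assert_allclose(yhat, manual)

    def test_marker_reordering_by_id(self):
        fit = self._manual_fit([1.0, -1.0])
        g = GenotypeMatrix(["A"], ["M1", "M0"], [[2, 0]])  # swapped order
        out = eb.predict_bayes(fit, g)
        assert out.values[0] == pytest.approx(0 * 1.0 + 2 * -1.0)

    def test_missing_marker_rejected(self):
        fit = self._manual_fit([1.0, 2.0])
        g = GenotypeMatrix(["A"], ["M0"], [[1]])
        with pytest.raises(ValidationError, match="M1"):
            eb.predict_bayes(fit, g)


class TestRegressorInterface:
    def test_sklearn_contract(self, tiny_ds):
        from sklearn.base import clone
        ds, _ = tiny_ds
        est = eb.BayesAlphabetRegressor(model="BayesCpi", niter=400, nburn=200,
                                        thin=2, random_state=1)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        est.fit(ds.genotypes.dosages, ds.phenotype.values)
        assert est.coef_.shape == (ds.n_markers,)
        assert 0.0 <= est.pi_ <= 1.0
        preds = est.predict(ds.genotypes.dosages)
        assert preds.shape == (ds.n_lines,)
        assert eb.pcc(ds.phenotype.values, preds) > 0.0


class TestDiagnostics:
    def _fit_with_samples(self, frame):
        p = 2
        return FittedBayesModel(
            model="BayesRR", mu_hat=0.0, u_hat=np.zeros(p),
            sigma2_e_hat=1.0, pi_hat=1.0, inclusion_prob=np.ones(p),
            samples=frame, marker_ids=np.array(["M0", "M1"], dtype=object),
            col_means=np.zeros(p), effect_samples=np.zeros((len(frame), p)),
        )

    def _frame(self, mu):
        n = len(mu)
        return pd.DataFrame({"mu": mu, "sigma2_e": np.ones(n),
                             "pi": np.ones(n)})

    def test_constant_chain_flagged_not_nan(self):
        fit = self._fit_with_samples(self._frame(np.ones(50)))
        rep = eb.mcmc_diagnostics(fit)
        assert rep.table.loc["mu", "rhat"] == 1.0
        assert bool(rep.table.loc["mu", "zero_variance"])
        assert not rep.warn

    def test_iid_normal_chain_near_one(self):
        mu = np.random.default_rng(0).standard_normal(200)
        rep = eb.mcmc_diagnostics(self._fit_with_samples(self._frame(mu)))
        assert 0.9 <= rep.table.loc["mu", "rhat"] <= 1.1

    def test_shifted_halves_raise_warning(self):
        rng = np.random.default_rng(1)
        mu = np.concatenate([rng.standard_normal(100),
                             rng.standard_normal(100) + 5.0])
        rep = eb.mcmc_diagnostics(self._fit_with_samples(self._frame(mu)))
        assert rep.table.loc["mu", "rhat"] > 1.5
        assert rep.warn

    def test_too_few_samples_rejected(self):
        fit = self._fit_with_samples(self._frame(np.ones(10)))
        with pytest.raises(ValidationError):
            eb.mcmc_diagnostics(fit)
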