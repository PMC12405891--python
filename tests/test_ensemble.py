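import numpy as np
import pandas as pd
import pytest

import enbayes as eb
from enbayes.ensemble import LeakageAudit, EvaluationReport
from enbayes.errors import NumericalError, ValidationError
from conftest import make_dataset, make_predictions


@pytest.fixture(scope="module")
def quick_ga():
    return eb.GAConfig(pop_size=80, max_iter=150, seed=0)


class TestMakeSplits:
    def test_sizes(self):
        plan = eb.make_splits(10, n_repeats=5, train_fraction=0.8, seed=0)
        for train, test in plan.splits:
            assert train.size == 8 and test.size == 2

    def test_deterministic(self):
        p1 = eb.make_splits(50, 3, seed=9)
        p2 = eb.make_splits(50, 3, seed=9)
        for (a, b), (c, d) in zip(p1.splits, p2.splits):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_partition_invariants(self):
        plan = eb.make_splits(37, 10, 0.8, seed=1)
        for train, test in plan.splits:
            assert np.intersect1d(train, test).size == 0
            assert np.union1d(train, test).size == 37

    def test_fraction_validation(self):
        with pytest.raises(ValidationError):
            eb.make_splits(20, 2, train_fraction=1.0)


class TestBasePredictionMatrix:
    def test_single_model_composes_fit_and_predict(self, tiny_ds,
                                                   reduced_mcmc):
        ds, _ = tiny_ds
        p_train, p_test = eb.base_prediction_matrix(
            ds, ds.genotypes, ["BayesA"], reduced_mcmc)
        fit = eb.fit_bayes(ds, eb.default_prior("BayesA", ds), reduced_mcmc)
        np.testing.assert_array_equal(
            p_train.values[:, 0], eb.predict_bayes(fit, ds.genotypes).values)
        np.testing.assert_array_equal(p_train.values, p_test.values)

    def test_deterministic_under_seeds(self, tiny_ds, reduced_mcmc):
        ds, _ = tiny_ds
        a = eb.base_prediction_matrix(ds, ds.genotypes,
                                      ["BayesB", "BayesL"], reduced_mcmc)
        b = eb.base_prediction_matrix(ds, ds.genotypes,
                                      ["BayesB", "BayesL"], reduced_mcmc)
        np.testing.assert_array_equal(a[0].values, b[0].values)

    def test_heritable_trait_gives_positive_train_pcc(self, tiny_ds,
                                                      reduced_mcmc):
        ds, _ = tiny_ds
        p_train, _ = eb.base_prediction_matrix(
            ds, ds.genotypes, list(eb.MODEL_NAMES), reduced_mcmc)
        for j in range(p_train.n_models):
            assert eb.pcc(ds.phenotype.values, p_train.values[:, j]) > 0


class TestFitEnsemble:
    def test_perfect_column_takes_all_weight_under_f2(self, quick_ga):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(40)
        p = make_predictions(np.column_stack(
            [y, y + rng.standard_normal(40), rng.standard_normal(40)]))
        ens = eb.fit_ensemble(y, p, "f2", quick_ga)
        assert ens.weights.weights[0] >= 0.99

    def test_single_model_gets_unit_weight(self, quick_ga):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(20)
        p = make_predictions(0.5 * y + rng.standard_normal(20))
        ens = eb.fit_ensemble(y, p, "f1", quick_ga)
        np.testing.assert_array_equal(ens.weights.weights, [1.0])

    def test_train_objective_at_least_best_vertex(self, quick_ga):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(50)
        p = make_predictions(np.column_stack(
            [0.7 * y + rng.standard_normal(50) * s for s in (0.5, 1.0, 2.0)]))
        ens = eb.fit_ensemble(y, p, "f1",
                              eb.GAConfig(pop_size=150, max_iter=300, seed=3))
        best_single = max(eb.pcc(y, p.values[:, j]) for j in range(3))
        assert ens.ga_result.best_fitness >= best_single - 1e-3

    def test_inner_holdout_requires_inner_material(self, quick_ga):
        y = np.arange(10.0)
        p = make_predictions(np.column_stack([y, y + 1]))
        with pytest.raises(ValidationError, match="inner"):
            eb.fit_ensemble(y, p, "f1", quick_ga, scheme="inner_holdout")

    def test_predict_ensemble_alignment_checked(self, quick_ga):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(20)
        p = make_predictions(rng.standard_normal((20, 2)), names=["a", "b"])
        ens = eb.fit_ensemble(y, p, "f2", quick_ga)
        p_bad = make_predictions(rng.standard_normal((5, 2)), names=["b", "a"])
        with pytest.raises(ValidationError):
            eb.predict_ensemble(ens, p_bad)


@pytest.fixture(scope="module")
def tiny_report(tiny_ds):
    ds, _ = tiny_ds
    plan = eb.make_splits(ds.n_lines, n_repeats=2, seed=3)
    ga = eb.GAConfig(pop_size=80, max_iter=150, seed=0)
    return eb.evaluate_repeated(ds, ["BayesRR", "BayesL", "BayesCpi"],
                                eb.MCMCConfig.reduced(seed=1), ga,
                                ["f1", "f2"], plan)


class TestEvaluateRepeated:
    def test_tidy_shape_and_aggregate_consistency(self, tiny_report):
        rep = tiny_report
        # 3 bases + 2 EnBayes variants, 2 repeats
        assert len(rep.per_repeat) == 2 * 5
        for model in rep.aggregates.index:
            sub = rep.per_repeat[rep.per_repeat.model == model]
            assert rep.aggregates.loc[model, "pcc_mean"] == \
                pytest.approx(sub.pcc.mean())

    def test_weights_recorded_per_repeat(self, tiny_report):
        assert tiny_report.weights["f1"].shape == (2, 3)
        np.testing.assert_allclose(tiny_report.weights["f1"].sum(axis=1), 1.0,
                                   atol=1e-8)

    def test_bit_identical_rerun(self, tiny_ds, tiny_report):
        ds, _ = tiny_ds
        plan = eb.make_splits(ds.n_lines, n_repeats=2, seed=3)
        ga = eb.GAConfig(pop_size=80, max_iter=150, seed=0)
        rep2 = eb.evaluate_repeated(ds, ["BayesRR", "BayesL", "BayesCpi"],
                                    eb.MCMCConfig.reduced(seed=1), ga,
                                    ["f1", "f2"], plan)
        pd.testing.assert_frame_equal(tiny_report.per_repeat, rep2.per_repeat)

    def test_leakage_audit_clean(self, tiny_ds):
        ds, _ = tiny_ds
        plan = eb.make_splits(ds.n_lines, n_repeats=2, seed=5)
        audit = LeakageAudit()
        eb.evaluate_repeated(ds, ["BayesRR", "BayesB"],
                             eb.MCMCConfig.reduced(seed=1),
                             eb.GAConfig(pop_size=60, max_iter=60, seed=0),
                             ["f1"], plan, audit=audit)
        assert audit.violations() == []
        # audit actually saw all three stages
        for rec in audit.records:
            assert rec["fit"] and rec["weight"] and rec["test"]


class TestEnBayesRegressor:
    def test_sklearn_fit_predict(self, tiny_ds):
        from sklearn.base import clone
        ds, _ = tiny_ds
        est = eb.EnBayesRegressor(models=("BayesRR", "BayesL"),
                                  niter=400, nburn=200, thin=2,
                                  pop_size=60, max_iter=80, random_state=0)
        assert clone(est).get_params() == est.get_params()
        est.fit(ds.genotypes.dosages, ds.phenotype.values)
        assert est.weights_.sum() == pytest.approx(1.0, abs=1e-8)
        preds = est.predict(ds.genotypes.dosages)
        assert preds.shape == (ds.n_lines,)
        assert eb.pcc(ds.phenotype.values, preds) > 0.0


class TestWeightAccuracyCorrelation:
    def _report(self, mean_weights, mean_pccs, n_repeats=4):
        names = [f"m{j}" for j in range(len(mean_weights))]
        agg = pd.DataFrame({"pcc_mean": mean_pccs}, index=names)
        weights = {"f1": np.tile(mean_weights, (n_repeats, 1))}
        return EvaluationReport(per_repeat=pd.DataFrame(), aggregates=agg,
                                weights=weights, model_names=names,
                                objectives=["f1"], scheme="train_fitted")

    def test_proportional_weights_give_unit_correlation(self):
        pccs = np.array([0.1, 0.2, 0.3, 0.4])
        w = pccs / pccs.sum()
        res = eb.weight_accuracy_correlation(self._report(w, pccs))
        assert res.r == pytest.approx(1.0)

    def test_identical_weights_degenerate(self):
        res = eb.weight_accuracy_correlation(
            self._report(np.full(4, 0.25), [0.1, 0.2, 0.3, 0.4]))
        assert res.degenerate and np.isnan(res.r)

    def test_matches_textbook_pearson_k8(self):
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(8))
        pccs = 0.3 * w + rng.normal(0, 0.05, 8)
        res = eb.weight_accuracy_correlation(self._report(w, pccs))
        assert res.r == pytest.approx(np.corrcoef(w, pccs)[0, 1])

    def test_requires_three_models(self):
        with pytest.raises(ValidationError):
            eb.weight_accuracy_correlation(
                self._report([0.5, 0.5], [0.1, 0.2]))


class TestTradeoffTable:
    def test_rounded_reference_row(self):
        table = eb.tradeoff_table({
            "f1": {"pcc": 0.541, "mse": 1.098},
            "f2": {"pcc": 0.530, "mse": 0.721},
            "f3": {"pcc": 0.533, "mse": 0.718},
            "f4": {"pcc": 0.531, "mse": 0.721},
        })
        assert table.loc["f3", "pcc_decline_pct"] == pytest.approx(1.48, abs=0.005)
        assert table.loc["f3", "mse_decline_pct"] == pytest.approx(34.61, abs=0.005)

    def test_identical_metrics_zero_decline(self):
        v = {"pcc": 0.4, "mse": 0.9}
        table = eb.tradeoff_table({k: dict(v) for k in ("f1", "f2", "f3", "f4")})
        assert (table[["pcc_decline_pct", "mse_decline_pct"]] == 0).all().all()

    def test_missing_variant_rejected(self):
        with pytest.raises(ValidationError):
            eb.tradeoff_table({"f1": {"pcc": 0.5, "mse": 1.0}})


class TestStacking:
    def test_zero_penalty_matches_ols_normal_equations(self):
        rng = np.random.default_rng(4)
        P = rng.standard_normal((50, 3))
        y = P @ [1.0, -2.0, 0.5] + rng.standard_normal(50) * 0.1
        p = make_predictions(P)
        m = eb.fit_stacking(p, y, ridge_penalty=0.0)
        X1 = np.column_stack([np.ones(50), P])
        ols = np.linalg.solve(X1.T @ X1, X1.T @ y)
        np.testing.assert_allclose(m.meta_coefficients, ols, atol=1e-8)

    def test_perfect_column_reproduced(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(30)
        p = make_predictions(y)
        m = eb.fit_stacking(p, y, ridge_penalty=0.0)
        np.testing.assert_allclose(eb.predict_stacking(m, p).values, y)

    def test_infinite_penalty_limit_is_mean(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(30)
        p = make_predictions(rng.standard_normal((30, 2)))
        m = eb.fit_stacking(p, y, ridge_penalty=1e12)
        np.testing.assert_allclose(m.meta_coefficients[1:], 0.0, atol=1e-9)
        np.testing.assert_allclose(eb.predict_stacking(m, p).values,
                                   y.mean(), atol=1e-6)

    def test_singular_system_advises_penalty(self):
        y = np.arange(10.0)
        col = np.arange(10.0)
        p = make_predictions(np.column_stack([col, col]))  # collinear
        with pytest.raises(NumericalError, match="penalty"):
            eb.fit_stacking(p, y, ridge_penalty=0.0)

    def test_pluggable_regressor_contract(self):
        from sklearn.linear_model import LinearRegression
        rng = np.random.default_rng(7)
        P = rng.standard_normal((40, 2))
        y = P @ [0.5, 1.5] + 2.0
        p = make_predictions(P)
        m = eb.fit_stacking(p, y, meta_kind="pluggable",
                            meta_regressor=LinearRegression())
        np.testing.assert_allclose(eb.predict_stacking(m, p).values, y,
                                   atol=1e-8)

    def test_ridge_stacking_regressor_sklearn_face(self):
        rng = np.random.default_rng(8)
        P = rng.standard_normal((40, 3))
        y = P @ [1.0, 0.0, -1.0]
        est = eb.RidgeStackingRegressor(penalty=1e-6).fit(P, y)
        np.testing.assert_allclose(est.predict(P), y, atol=1e-4)


class TestInclusionCurve:
    def test_two_model_curve_and_tie_breaking(self, tiny_ds):
        ds, _ = tiny_ds
        plan = eb.make_splits(ds.n_lines, n_repeats=2, seed=4)
        dec, inc = eb.inclusion_curve(
            ds, ["BayesRR", "BayesB"], eb.MCMCConfig.reduced(seed=1),
            eb.GAConfig(pop_size=60, max_iter=80, seed=0), "f1", plan)
        assert dec.steps.n_models.tolist() == [2]
        # both orders use the same 2-model set: identical final accuracy
        assert dec.steps.accuracy.iloc[-1] == \
            pytest.approx(inc.steps.accuracy.iloc[-1], abs=1e-3)
        assert dec.model_order == list(reversed(inc.model_order))

    def test_requires_two_models(self, tiny_ds):
        ds, _ = tiny_ds
        plan = eb.make_splits(ds.n_lines, n_repeats=1, seed=0)
        with pytest.raises(ValidationError):
            eb.inclusion_curve(ds, ["BayesRR"], eb.MCMCConfig.reduced(),
                               eb.GAConfig(seed=0), "f1", plan)
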