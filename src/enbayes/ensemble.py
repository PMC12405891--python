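"""End-to-end ensemble genomic prediction and its evaluation machinery.

The ensemble ("EnBayes") fits the eight Bayesian-alphabet models as base
learners, finds simplex weights for their predictions with the GA, and
predicts new lines as the weighted average of base predictions.  This module
also carries the evaluation machinery used to characterise the approach:

* repeated random holdout (default 100 x 80/20) with per-repeat PCC, MSE and
  bias regression for every base model and every EnBayes objective variant;
* ordered model-inclusion curves (models added best-first or worst-first);
* correlation between mean model weight and mean model accuracy;
* the PCC/MSE trade-off table across the four objectives;
* a stacking baseline (ridge meta-learner natively; any fit/predict
  regressor pluggable).

Weight-fitting schemes
----------------------
``train_fitted`` optimises weights against the base models' fitted values on
the training set (the most literal reading of the workflow);
``inner_holdout`` (default) carves one inner 80/20 split out of the training
set, fits bases on the inner-train, optimises weights on inner-test
predictions, then refits bases on the full training set -- weights then
reflect out-of-sample behaviour and resist overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .bayes import (MCMCConfig, BayesPriorSpec, FittedBayesModel, default_prior,
                    fit_bayes, predict_bayes, MODEL_NAMES)
from .errors import NumericalError, UndefinedCorrelationError, ValidationError
from .ga import GAConfig, GAResult, run_ga
from .io import Dataset, GenotypeMatrix, PhenotypeVector, PredictionMatrix
from .objectives import (ObjectiveKind, WeightVector, bias_regression,
                         ensemble_prediction, mse, pcc)

__all__ = [
    "SplitPlan",
    "make_splits",
    "base_prediction_matrix",
    "EnsembleModel",
    "fit_ensemble",
    "predict_ensemble",
    "EnBayesRegressor",
    "EvaluationReport",
    "evaluate_repeated",
    "InclusionCurve",
    "inclusion_curve",
    "WeightAccuracyResult",
    "weight_accuracy_correlation",
    "tradeoff_table",
    "StackingModel",
    "fit_stacking",
    "predict_stacking",
    "RidgeStackingRegressor",
    "LeakageAudit",
]


# ---------------------------------------------------------------------------
# repeated random splits


@dataclass
class SplitPlan:
    """Reproducible repeated random train/test splits."""

    n_repeats: int
    train_fraction: float
    seed: int
    splits: list = field(repr=False, default_factory=list)


def make_splits(n: int, n_repeats: int = 100, train_fraction: float = 0.8,
                seed: int = 0) -> SplitPlan:
    """Draw ``n_repeats`` random splits; repeat r uses seed ``seed + r``."""
    if n < 10:
        raise ValidationError("need at least 10 lines to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValidationError("degenerate split sizes; adjust train_fraction")
    splits = []
    for r in range(n_repeats):
        perm = np.random.default_rng(seed + r).permutation(n)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return SplitPlan(n_repeats, train_fraction, seed, splits)


# ---------------------------------------------------------------------------
# leakage audit


class LeakageAudit:
    """Records which line IDs each pipeline stage touches, per repeat.

    Every base-model fit logs the training IDs it sees, weight optimisation
    logs the IDs its objective is evaluated on, and scoring logs the test
    IDs; :meth:`violations` returns the repeats where a test line leaked
    into fitting or weight optimisation.
    """

    def __init__(self) -> None:
        self.records: list[dict] = []

    def start_repeat(self) -> None:
        self.records.append({"fit": set(), "weight": set(), "test": set()})

    def record(self, stage: str, line_ids) -> None:
        if not self.records:
            self.start_repeat()
        self.records[-1][stage].update(map(str, line_ids))

    def violations(self) -> list:
        out = []
        for r, rec in enumerate(self.records):
            leaked = (rec["fit"] | rec["weight"]) & rec["test"]
            if leaked:
                out.append((r, sorted(leaked)))
        return out


# ---------------------------------------------------------------------------
# base model fitting


def _coerce_priors(models, ds_train: Dataset, h2_prior: float = 0.5):
    """Accept model-name strings or ready BayesPriorSpec objects."""
    priors = []
    for m in models:
        if isinstance(m, BayesPriorSpec):
            priors.append(m)
        elif isinstance(m, str):
            priors.append(default_prior(m, ds_train, h2_prior))
        else:
            raise ValidationError(f"cannot interpret base model spec {m!r}")
    if not priors:
        raise ValidationError("need at least one base model")
    return priors


def base_prediction_matrix(ds_train: Dataset, g_test: GenotypeMatrix,
                           models, mcmc: MCMCConfig, h2_prior: float = 0.5,
                           audit: LeakageAudit | None = None,
                           return_fits: bool = False):
    """Fit every base model on the training set and predict train and test.

    Column j holds the predictions of model j; test predictions use
    training-fitted parameters only.  Model j's chain is seeded
    ``mcmc.seed + j`` so streams are reproducible yet distinct.
    """
    priors = _coerce_priors(models, ds_train, h2_prior)
    names, train_cols, test_cols, fits = [], [], [], []
    for j, prior in enumerate(priors):
        if audit is not None:
            audit.record("fit", ds_train.genotypes.line_ids)
        try:
            fit = fit_bayes(ds_train, prior, replace(mcmc, seed=mcmc.seed + j))
        except Exception as exc:
            raise type(exc)(f"base model {prior.model}: {exc}") from exc
        names.append(prior.model)
        train_cols.append(predict_bayes(fit, ds_train.genotypes).values)
        test_cols.append(predict_bayes(fit, g_test).values)
        fits.append(fit)
    p_train = PredictionMatrix(ds_train.genotypes.line_ids,
                               np.array(names, dtype=object),
                               np.column_stack(train_cols))
    p_test = PredictionMatrix(g_test.line_ids, np.array(names, dtype=object),
                              np.column_stack(test_cols))
    if return_fits:
        return p_train, p_test, fits
    return p_train, p_test


# ---------------------------------------------------------------------------
# weight fitting and the ensemble model object


@dataclass
class EnsembleModel:
    """Base fits plus the GA-optimised simplex weights that combine them."""

    base_fits: list
    weights: WeightVector
    objective: ObjectiveKind
    weight_fitting_scheme: str
    ga_result: GAResult | None = field(repr=False, default=None)


def fit_ensemble(y_train, p_train: PredictionMatrix, objective,
                 ga_cfg: GAConfig, scheme: str = "train_fitted",
                 inner: tuple | None = None,
                 base_fits: list | None = None,
                 audit: LeakageAudit | None = None) -> EnsembleModel:
    """Optimise ensemble weights for the given objective.

    With ``scheme="train_fitted"`` the GA sees the training-set fitted
    values; with ``scheme="inner_holdout"`` the caller must pass
    ``inner=(y_inner, p_inner)``, the phenotype and base predictions of an
    inner holdout that the bases were not fitted on (the orchestration in
    :class:`EnBayesRegressor` / :func:`evaluate_repeated` builds these).
    """
    objective = ObjectiveKind.coerce(objective)
    if scheme == "train_fitted":
        y_used, p_used = y_train, p_train
    elif scheme == "inner_holdout":
        if inner is None:
            raise ValidationError(
                "scheme='inner_holdout' needs inner=(y_inner, p_inner)"
            )
        y_used, p_used = inner
    else:
        raise ValidationError(f"unknown weight-fitting scheme {scheme!r}")
    if audit is not None:
        ids = y_used.line_ids if hasattr(y_used, "line_ids") else p_used.line_ids
        audit.record("weight", ids)
    result = run_ga(objective, y_used, p_used, ga_cfg)
    return EnsembleModel(
        base_fits=base_fits if base_fits is not None else list(p_train.model_names),
        weights=result.best_weights,
        objective=objective,
        weight_fitting_scheme=scheme,
        ga_result=result,
    )


def predict_ensemble(model: EnsembleModel, p_test: PredictionMatrix) -> PhenotypeVector:
    """Weighted average of base-model predictions on new lines."""
    return ensemble_prediction(p_test, model.weights)


class EnBayesRegressor(RegressorMixin, BaseEstimator):
    """scikit-learn estimator for the full weighted Bayesian-alphabet ensemble.

    ``fit(X, y)`` fits every base model, optimises simplex weights for the
    chosen objective with the GA, and (under the default inner-holdout
    scheme) refits the bases on all training rows before prediction.
    ``predict(X)`` returns the weighted average of base predictions.

    Fitted attributes: ``weights_`` (k,), ``model_names_``, ``base_fits_``
    (list of :class:`~enbayes.bayes.FittedBayesModel`), ``ga_result_``,
    ``ensemble_model_``.
    """

    def __init__(self, models=MODEL_NAMES, objective: str = "f1",
                 scheme: str = "inner_holdout", h2_prior: float = 0.5,
                 niter: int = 20000, nburn: int = 14000, thin: int = 100,
                 pop_size: int = 300, crossover_rate: float = 0.2,
                 mutation_rate: float = 0.1, max_iter: int = 1000,
                 mutation_step: float = 0.05, patience: int | None = None,
                 inner_train_fraction: float = 0.8, random_state: int = 0):
        self.models = models
        self.objective = objective
        self.scheme = scheme
        self.h2_prior = h2_prior
        self.niter = niter
        self.nburn = nburn
        self.thin = thin
        self.pop_size = pop_size
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.max_iter = max_iter
        self.mutation_step = mutation_step
        self.patience = patience
        self.inner_train_fraction = inner_train_fraction
        self.random_state = random_state

    def _mcmc(self) -> MCMCConfig:
        return MCMCConfig(self.niter, self.nburn, self.thin,
                          seed=self.random_state)

    def _ga(self) -> GAConfig:
        return GAConfig(pop_size=self.pop_size,
                        crossover_rate=self.crossover_rate,
                        mutation_rate=self.mutation_rate,
                        max_iter=self.max_iter,
                        mutation_step=self.mutation_step,
                        patience=self.patience,
                        seed=self.random_state + 10_000)

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        ids = np.array([f"L{i}" for i in range(X.shape[0])], dtype=object)
        markers = np.array([f"M{j}" for j in range(X.shape[1])], dtype=object)
        ds = Dataset(GenotypeMatrix(ids, markers, X), PhenotypeVector(ids, y))
        mcmc, ga_cfg = self._mcmc(), self._ga()
        if self.scheme == "inner_holdout":
            rng = np.random.default_rng(self.random_state + 7777)
            perm = rng.permutation(ds.n_lines)
            n_inner = int(round(self.inner_train_fraction * ds.n_lines))
            inner_train = np.sort(perm[:n_inner])
            inner_test = np.sort(perm[n_inner:])
            _, p_inner = base_prediction_matrix(
                ds.subset(inner_train), ds.subset(inner_test).genotypes,
                list(self.models), mcmc, self.h2_prior)
            inner = (ds.subset(inner_test).phenotype, p_inner)
        else:
            inner = None
        p_train, _, fits = base_prediction_matrix(
            ds, ds.genotypes, list(self.models), mcmc, self.h2_prior,
            return_fits=True)
        model = fit_ensemble(ds.phenotype, p_train, self.objective, ga_cfg,
                             scheme=self.scheme, inner=inner, base_fits=fits)
        self.ensemble_model_ = model
        self.base_fits_ = fits
        self.model_names_ = list(p_train.model_names)
        self.weights_ = model.weights.weights
        self.ga_result_ = model.ga_result
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "ensemble_model_")
        X = check_array(X, dtype=float)
        ids = np.array([f"Q{i}" for i in range(X.shape[0])], dtype=object)
        g = GenotypeMatrix(ids, self.base_fits_[0].marker_ids, X)
        cols = [predict_bayes(fit, g).values for fit in self.base_fits_]
        p = PredictionMatrix(ids, np.array(self.model_names_, dtype=object),
                             np.column_stack(cols))
        return predict_ensemble(self.ensemble_model_, p).values


# ---------------------------------------------------------------------------
# repeated-holdout evaluation


@dataclass
class EvaluationReport:
    """Per-repeat and aggregate accuracy for base models and EnBayes variants."""

    per_repeat: pd.DataFrame
    aggregates: pd.DataFrame
    weights: dict  # objective name -> (n_repeats, k) weight array
    model_names: list
    objectives: list
    scheme: str
    n_failures: int = 0


def _score_rows(repeat: int, y_test, columns: dict) -> list:
    rows = []
    for name, yhat in columns.items():
        bias = bias_regression(y_test, yhat)
        rows.append({
            "repeat": repeat, "model": name,
            "pcc": pcc(y_test, yhat), "mse": mse(y_test, yhat),
            "bias_a": bias.intercept, "bias_b": bias.slope,
        })
    return rows


def _repeat_material(ds: Dataset, models, mcmc: MCMCConfig, plan: SplitPlan,
                     repeat: int, scheme: str, h2_prior: float,
                     inner_train_fraction: float,
                     audit: LeakageAudit | None):
    """Fit bases for one repeat; return everything weight fitting and scoring need."""
    train_idx, test_idx = plan.splits[repeat]
    ds_train = ds.subset(train_idx)
    ds_test = ds.subset(test_idx)
    repeat_seed = plan.seed + repeat
    mcmc_r = replace(mcmc, seed=repeat_seed)
    inner = None
    if scheme == "inner_holdout":
        rng = np.random.default_rng(repeat_seed + 7777)
        perm = rng.permutation(ds_train.n_lines)
        n_inner = int(round(inner_train_fraction * ds_train.n_lines))
        ds_inner_train = ds_train.subset(np.sort(perm[:n_inner]))
        ds_inner_test = ds_train.subset(np.sort(perm[n_inner:]))
        _, p_inner = base_prediction_matrix(
            ds_inner_train, ds_inner_test.genotypes, models, mcmc_r,
            h2_prior, audit=audit)
        inner = (ds_inner_test.phenotype, p_inner)
    p_train, p_test = base_prediction_matrix(
        ds_train, ds_test.genotypes, models, mcmc_r, h2_prior, audit=audit)
    if audit is not None:
        audit.record("test", ds_test.genotypes.line_ids)
    return {
        "y_train": ds_train.phenotype, "y_test": ds_test.phenotype,
        "p_train": p_train, "p_test": p_test, "inner": inner,
        "repeat_seed": repeat_seed,
    }


def evaluate_repeated(ds: Dataset, models, mcmc: MCMCConfig, ga_cfg: GAConfig,
                      objectives, plan: SplitPlan,
                      scheme: str = "inner_holdout", h2_prior: float = 0.5,
                      inner_train_fraction: float = 0.8,
                      audit: LeakageAudit | None = None) -> EvaluationReport:
    """Repeated-holdout evaluation of the base models and EnBayes variants.

    For every repeat: fit bases on the training split only, optimise weights
    per objective, then score every single model and every ``EnBayes(fX)``
    variant on the untouched test split (PCC, MSE, bias regression).
    Aggregates are means and standard errors over repeats.  Repeat-level
    failures (e.g. an undefined correlation on a degenerate test split) are
    excluded and counted in ``n_failures`` rather than silently dropped.
    """
    objectives = [ObjectiveKind.coerce(o) for o in objectives]
    rows, failures = [], 0
    model_list = list(models)
    weight_store: dict[str, list] = {o.value: [] for o in objectives}
    model_names = None
    for r in range(plan.n_repeats):
        if audit is not None:
            audit.start_repeat()
        try:
            mat = _repeat_material(ds, model_list, mcmc, plan, r, scheme,
                                   h2_prior, inner_train_fraction, audit)
            columns = {
                name: mat["p_test"].values[:, j]
                for j, name in enumerate(mat["p_test"].model_names)
            }
            model_names = list(mat["p_test"].model_names)
            for i, obj in enumerate(objectives):
                cfg = replace(ga_cfg, seed=ga_cfg.seed + mat["repeat_seed"]
                              + 101 * i)
                ens = fit_ensemble(mat["y_train"], mat["p_train"], obj, cfg,
                                   scheme=scheme, inner=mat["inner"],
                                   audit=audit)
                weight_store[obj.value].append(ens.weights.weights)
                columns[f"EnBayes({obj.value})"] = predict_ensemble(
                    ens, mat["p_test"]).values
            rows.extend(_score_rows(r, mat["y_test"], columns))
        except (UndefinedCorrelationError, ValidationError):
            failures += 1
            continue
    if not rows:
        raise ValidationError("every repeat failed; nothing to report")
    per_repeat = pd.DataFrame(rows)
    agg = per_repeat.groupby("model")[["pcc", "mse", "bias_a", "bias_b"]].agg(
        ["mean", "sem"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return EvaluationReport(
        per_repeat=per_repeat,
        aggregates=agg,
        weights={k: np.array(v) for k, v in weight_store.items()},
        model_names=model_names,
        objectives=[o.value for o in objectives],
        scheme=scheme,
        n_failures=failures,
    )


# ---------------------------------------------------------------------------
# ordered model-inclusion curves


@dataclass
class InclusionCurve:
    """Ensemble accuracy as models join one-by-one in a fixed order."""

    order: str  # "decreasing" or "increasing" single-model accuracy
    model_order: list
    steps: pd.DataFrame  # columns: n_models, accuracy


def inclusion_curve(ds: Dataset, models, mcmc: MCMCConfig, ga_cfg: GAConfig,
                    objective, plan: SplitPlan,
                    scheme: str = "inner_holdout", h2_prior: float = 0.5,
                    inner_train_fraction: float = 0.8
                    ) -> tuple[InclusionCurve, InclusionCurve]:
    """Build best-first (decreasing) and worst-first (increasing) curves.

    Single-model accuracy for the ordering is the mean test PCC over the
    plan's repeats; ties break by model name.  Base models are fitted once
    per repeat and shared across all subset sizes, so only the GA reruns.
    Returns (decreasing, increasing).
    """
    objective = ObjectiveKind.coerce(objective)
    model_list = list(models)
    if len(model_list) < 2:
        raise ValidationError("inclusion curves need at least 2 models")
    materials = [
        _repeat_material(ds, model_list, mcmc, plan, r, scheme, h2_prior,
                         inner_train_fraction, None)
        for r in range(plan.n_repeats)
    ]
    names = list(materials[0]["p_test"].model_names)
    single_pcc = {
        name: float(np.mean([
            pcc(m["y_test"], m["p_test"].values[:, j]) for m in materials
        ]))
        for j, name in enumerate(names)
    }
    decreasing = sorted(names, key=lambda nm: (-single_pcc[nm], nm))
    increasing = sorted(names, key=lambda nm: (single_pcc[nm], nm))

    def build(order_names: list, label: str) -> InclusionCurve:
        records = []
        for step, j in enumerate(range(2, len(order_names) + 1)):
            subset = order_names[:j]
            accs = []
            for r, mat in enumerate(materials):
                cfg = replace(ga_cfg,
                              seed=ga_cfg.seed + mat["repeat_seed"] + 17 * j)
                inner = mat["inner"]
                if inner is not None:
                    inner = (inner[0], inner[1].select_models(subset))
                ens = fit_ensemble(mat["y_train"],
                                   mat["p_train"].select_models(subset),
                                   objective, cfg, scheme=scheme, inner=inner)
                yhat = predict_ensemble(ens, mat["p_test"].select_models(subset))
                accs.append(pcc(mat["y_test"], yhat))
            records.append({"n_models": j, "accuracy": float(np.mean(accs))})
        return InclusionCurve(order=label, model_order=order_names,
                              steps=pd.DataFrame(records))

    return build(decreasing, "decreasing"), build(increasing, "increasing")


# ---------------------------------------------------------------------------
# weight-accuracy correlation and the trade-off table


@dataclass
class WeightAccuracyResult:
    r: float
    pvalue: float
    degenerate: bool = False


def weight_accuracy_correlation(report: EvaluationReport,
                                objective: str = "f1") -> WeightAccuracyResult:
    """Pearson correlation, across models, of mean weight vs mean PCC.

    Mirrors the question "do more accurate base models receive more
    weight?".  Needs k >= 3 models; identical mean weights (or accuracies)
    make the correlation undefined and are reported as degenerate.
    """
    if objective not in report.weights:
        raise ValidationError(f"report lacks weights for objective {objective!r}")
    W = report.weights[objective]
    if W.shape[1] < 3:
        raise ValidationError("weight-accuracy correlation needs k >= 3 models")
    mean_w = W.mean(axis=0)
    mean_pcc = np.array([
        report.aggregates.loc[name, "pcc_mean"] for name in report.model_names
    ])
    if np.ptp(mean_w) == 0.0 or np.ptp(mean_pcc) == 0.0:
        return WeightAccuracyResult(r=float("nan"), pvalue=float("nan"),
                                    degenerate=True)
    r, p = stats.pearsonr(mean_w, mean_pcc)
    return WeightAccuracyResult(r=float(r), pvalue=float(p))


def tradeoff_table(report) -> pd.DataFrame:
    """PCC and MSE per objective with percent declines relative to f1.

    Accepts an :class:`EvaluationReport` containing all four EnBayes
    variants, or a mapping ``{"f1": {"pcc": .., "mse": ..}, ...}``.  Percent
    decline of metric m under objective fX is
    ``100 * (m(f1) - m(fX)) / m(f1)``.
    """
    if isinstance(report, EvaluationReport):
        values = {}
        for obj in ("f1", "f2", "f3", "f4"):
            name = f"EnBayes({obj})"
            if name not in report.aggregates.index:
                raise ValidationError(f"report lacks the {name} variant")
            values[obj] = {
                "pcc": float(report.aggregates.loc[name, "pcc_mean"]),
                "mse": float(report.aggregates.loc[name, "mse_mean"]),
            }
    else:
        values = dict(report)
        for obj in ("f1", "f2", "f3", "f4"):
            if obj not in values:
                raise ValidationError(f"missing objective {obj!r}")
    base_pcc, base_mse = values["f1"]["pcc"], values["f1"]["mse"]
    rows = []
    for obj in ("f1", "f2", "f3", "f4"):
        v = values[obj]
        rows.append({
            "objective": obj, "pcc": v["pcc"], "mse": v["mse"],
            "pcc_decline_pct": 100.0 * (base_pcc - v["pcc"]) / base_pcc,
            "mse_decline_pct": 100.0 * (base_mse - v["mse"]) / base_mse,
        })
    return pd.DataFrame(rows).set_index("objective")


# ---------------------------------------------------------------------------
# stacking baseline


@dataclass
class StackingModel:
    """Second-stage meta-learner over base-model predictions."""

    meta_kind: str
    ridge_penalty: float
    meta_coefficients: np.ndarray  # intercept first, then one per base model
    model_names: np.ndarray
    regressor: object = None


def fit_stacking(p_train: PredictionMatrix, y_train, meta_kind: str = "ridge",
                 ridge_penalty: float = 1.0,
                 meta_regressor=None) -> StackingModel:
    """Fit a stacking meta-learner on base predictions.

    The native ridge meta-learner solves ``(Pc'Pc + penalty*I) b = Pc' y``
    on centred columns with an unpenalised intercept; penalty 0 on a
    rank-deficient system raises :class:`NumericalError` advising a positive
    penalty.  ``meta_kind="pluggable"`` clones and fits any regressor with
    the fit/predict contract (e.g. a random forest or quantile forest).
    """
    y = y_train.values if hasattr(y_train, "values") else np.asarray(y_train, float)
    P = p_train.values
    if meta_kind == "pluggable":
        if meta_regressor is None:
            raise ValidationError("meta_kind='pluggable' needs meta_regressor")
        reg = clone(meta_regressor).fit(P, y)
        return StackingModel("pluggable", 0.0, np.array([]),
                             p_train.model_names.copy(), regressor=reg)
    if meta_kind != "ridge":
        raise ValidationError(f"unknown meta_kind {meta_kind!r}")
    if ridge_penalty < 0:
        raise ValidationError("ridge_penalty must be >= 0")
    col_means = P.mean(axis=0)
    Pc = P - col_means
    k = P.shape[1]
    G = Pc.T @ Pc + ridge_penalty * np.eye(k)
    if ridge_penalty == 0.0 and np.linalg.matrix_rank(G) < k:
        raise NumericalError(
            "normal equations are singular at penalty 0; use ridge_penalty > 0"
        )
    b = np.linalg.solve(G, Pc.T @ (y - y.mean()))
    intercept = float(y.mean() - col_means @ b)
    return StackingModel("ridge", ridge_penalty,
                         np.concatenate([[intercept], b]),
                         p_train.model_names.copy())


def predict_stacking(m: StackingModel, p_test: PredictionMatrix) -> PhenotypeVector:
    if not np.array_equal(p_test.model_names, m.model_names):
        raise ValidationError("prediction columns do not match the stacking fit")
    if m.meta_kind == "pluggable":
        yhat = m.regressor.predict(p_test.values)
    else:
        yhat = m.meta_coefficients[0] + p_test.values @ m.meta_coefficients[1:]
    return PhenotypeVector(p_test.line_ids, yhat, trait_name="stacking")


class RidgeStackingRegressor(RegressorMixin, BaseEstimator):
    """sklearn face of the ridge stacking meta-learner (X = base predictions)."""

    def __init__(self, penalty: float = 1.0):
        self.penalty = penalty

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        names = np.array([f"m{j}" for j in range(X.shape[1])], dtype=object)
        ids = np.array([f"L{i}" for i in range(X.shape[0])], dtype=object)
        self.model_ = fit_stacking(PredictionMatrix(ids, names, X),
                                   y, ridge_penalty=self.penalty)
        self.coef_ = self.model_.meta_coefficients[1:]
        self.intercept_ = self.model_.meta_coefficients[0]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        return self.intercept_ + X @ self.coef_
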