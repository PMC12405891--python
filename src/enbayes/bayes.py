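"""The eight Bayesian-alphabet whole-genome regression models.

All models share the linear mixed model ``y = mu*1 + X beta + Z u + e`` with
an intercept (plus optional fixed covariates), marker dosages ``Z`` and
i.i.d. normal residuals, and differ only in the prior on the marker effects
``u_j`` and their variances:

=========  ==========================================================
BayesA     u_j ~ N(0, s2_j); per-marker scaled-inv-chi2 variances
BayesB     pi0*N(0, s2_j) + (1-pi0)*delta0, pi0 fixed (default 0.05)
BayesBpi   as BayesB with pi estimated (Beta prior)
BayesC     pi0*N(0, s2) + (1-pi0)*delta0, common slab variance
BayesCpi   as BayesC with pi estimated
BayesR     mixture of delta0 and N(0, c*s2) for c in {1e-3, 1e-2, 1e-1},
           proportions (pi1, pi2, pi3) = (1e-4, 1e-3, 1e-2) a priori,
           Dirichlet-updated
BayesRR    u_j ~ N(0, s2), common variance (ridge-like shrinkage)
BayesL     Bayesian lasso (Park-Casella): double-exponential effects
=========  ==========================================================

``delta0`` is an exact point mass at zero.  Effect variances carry
scaled-inv-chi2(nu, S) priors; the residual variance carries
scaled-inv-chi2(nu_e, S_e).  Hyper-parameters default to a weakly
informative nu = nu_e = 4.2 with scales derived from a prior heritability
guess (see :func:`default_prior`).

Fitting is single-site Gibbs sampling; production settings follow the
reference experimental protocol (niter=20000, nburn=14000, thin=100) and a
reduced desk-scale profile (2000/1000/5) is provided for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import _sampler
from .errors import SamplerError, ValidationError
from .io import Dataset, GenotypeMatrix, PhenotypeVector

__all__ = [
    "MODEL_NAMES",
    "BayesPriorSpec",
    "MCMCConfig",
    "FittedBayesModel",
    "default_prior",
    "fit_bayes",
    "predict_bayes",
    "BayesAlphabetRegressor",
]

MODEL_NAMES = (
    "BayesRR", "BayesA", "BayesB", "BayesBpi",
    "BayesC", "BayesCpi", "BayesR", "BayesL",
)
_MODEL_CODES = {name: code for code, name in enumerate(MODEL_NAMES)}

#: models with a point mass at zero in the effect prior
POINT_MASS_MODELS = ("BayesB", "BayesBpi", "BayesC", "BayesCpi", "BayesR")


@dataclass
class BayesPriorSpec:
    """Prior hyper-parameters for one Bayesian-alphabet model."""

    model: str
    pi0: float = 0.05
    nu: float = 4.2
    S: float = 0.01
    nu_e: float = 4.2
    S_e: float = 1.0
    eta1: float = 1.0
    eta2: float = 1.0
    eta_dirichlet: float = 1.0
    lambda_: float = 1.0
    mixture_scalers: tuple = (1e-3, 1e-2, 1e-1)
    mixture_props: tuple = (1e-4, 1e-3, 1e-2)

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValidationError(
                f"unknown model {self.model!r}; choose from {MODEL_NAMES}"
            )
        if not 0.0 < self.pi0 <= 1.0:
            raise ValidationError("pi0 must be in (0, 1]")
        for name in ("nu", "S", "nu_e", "S_e", "eta1", "eta2", "lambda_",
                     "eta_dirichlet"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        props = np.asarray(self.mixture_props, dtype=float)
        if (props < 0).any() or props.sum() >= 1.0:
            raise ValidationError(
                "mixture proportions must be nonnegative with sum < 1 "
                "(the remainder is the null point mass)"
            )


@dataclass
class MCMCConfig:
    """Chain length settings; defaults are the production protocol."""

    niter: int = 20000
    nburn: int = 14000
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.nburn < self.niter:
            raise ValidationError("need 0 <= nburn < niter")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if (self.niter - self.nburn) // self.thin < 10:
            raise ValidationError(
                "fewer than 10 retained samples; increase niter or reduce thin"
            )

    @classmethod
    def reduced(cls, seed: int = 0) -> "MCMCConfig":
        """Desk-scale profile for tests and quick runs (2000/1000/5)."""
        return cls(niter=2000, nburn=1000, thin=5, seed=seed)

    @property
    def n_retained(self) -> int:
        return (self.niter - self.nburn) // self.thin


@dataclass
class FittedBayesModel:
    """Posterior summaries from one Bayesian-alphabet fit.

    ``u_hat`` is the posterior-mean marker effect including zero draws for
    point-mass models (effect x inclusion averaged); predictions use the
    training-mean marker centring stored in ``col_means``.
    """

    model: str
    mu_hat: float
    u_hat: np.ndarray
    sigma2_e_hat: float
    pi_hat: float
    inclusion_prob: np.ndarray
    samples: pd.DataFrame = field(repr=False)
    marker_ids: np.ndarray = field(repr=False)
    col_means: np.ndarray = field(repr=False)
    effect_samples: np.ndarray = field(repr=False)
    prior: BayesPriorSpec = field(repr=False, default=None)
    mcmc: MCMCConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not np.isfinite(self.u_hat).all():
            raise ValidationError("non-finite posterior-mean effects")
        if self.sigma2_e_hat <= 0:
            raise ValidationError("posterior residual variance must be > 0")
        if not 0.0 <= self.pi_hat <= 1.0:
            raise ValidationError("pi_hat must be in [0, 1]")


def _sum_2pq(g_dosages: np.ndarray) -> float:
    f = g_dosages.mean(axis=0) / 2.0
    return float((2.0 * f * (1.0 - f)).sum())


def default_prior(model: str, ds: Dataset, h2_prior: float = 0.5) -> BayesPriorSpec:
    """Data-scaled weakly informative prior for one model.

    The effect-variance scale ``S`` is chosen so the prior-mode total genetic
    variance matches ``h2_prior * var(y)``: the per-(nonzero-)marker effect
    variance target is ``h2_prior*var(y) / (pi_eff * sum_j 2 f_j (1-f_j))``
    with ``pi_eff`` the expected nonzero proportion, and the mode of
    scaled-inv-chi2(nu, S) being ``nu*S/(nu+2)`` gives
    ``S = target*(nu+2)/nu``.  The residual scale is set analogously from
    ``(1-h2_prior)*var(y)``.  The Bayesian-lasso rate is initialised so the
    prior effect variance matches the same target.
    """
    spec = BayesPriorSpec(model=model)
    var_y = float(np.var(ds.phenotype.values))
    if var_y <= 0:
        raise ValidationError("constant phenotype: cannot scale priors")
    if not 0.0 < h2_prior < 1.0:
        raise ValidationError("h2_prior must be in (0, 1)")
    if ds.n_markers < 1:
        raise ValidationError("need at least one marker")
    s2pq = _sum_2pq(ds.genotypes.dosages)
    if s2pq <= 0:
        s2pq = ds.n_markers * 0.5  # all-monomorphic fallback

    if model in ("BayesB", "BayesC"):
        pi_eff = spec.pi0
    elif model in ("BayesBpi", "BayesCpi"):
        pi_eff = spec.pi0  # initial value; pi is then estimated
    elif model == "BayesR":
        pi_eff = 1.0  # handled through the mixture second moment below
    else:
        pi_eff = 1.0

    genetic_target = h2_prior * var_y
    if model == "BayesR":
        second_moment = float(
            np.dot(spec.mixture_props, spec.mixture_scalers)
        )
        sigma2_target = genetic_target / (s2pq * second_moment)
    else:
        sigma2_target = genetic_target / (s2pq * pi_eff)
    S = sigma2_target * (spec.nu + 2.0) / spec.nu
    resid_target = (1.0 - h2_prior) * var_y
    S_e = resid_target * (spec.nu_e + 2.0) / spec.nu_e
    # lasso: prior Var(u_j) = E[tau2]*s2e = (2/lambda2)*s2e; match the
    # dense-model per-marker target
    lam = float(np.sqrt(2.0 * resid_target / (genetic_target / s2pq)))
    return replace(spec, S=S, S_e=S_e, lambda_=lam)


def _run_kernel(Zc, y, prior: BayesPriorSpec, mcmc: MCMCConfig,
                fixed_variances: dict | None):
    model_code = _MODEL_CODES[prior.model]
    fix = fixed_variances is not None
    sigma2_fixed = float(fixed_variances.get("sigma2", prior.S)) if fix else 0.0
    sigma2_e_fixed = float(fixed_variances.get("sigma2_e", prior.S_e)) if fix else 0.0
    estimate_pi = prior.model in ("BayesBpi", "BayesCpi")
    if prior.model in ("BayesB", "BayesC"):
        pi_init = prior.pi0
    elif estimate_pi:
        pi_init = prior.pi0
    elif prior.model == "BayesR":
        pi_init = float(sum(prior.mixture_props))
    else:
        pi_init = 1.0
    props = np.array(
        [1.0 - sum(prior.mixture_props), *prior.mixture_props], dtype=float
    )
    lam2 = prior.lambda_ ** 2
    # Gamma(1, rate) hyperprior on lambda2 with prior mean at the initial value
    lambda_shape, lambda_rate = 1.0, 1.0 / max(lam2, 1e-12)
    out = _sampler.run_chain(
        np.asfortranarray(Zc), np.ascontiguousarray(y, dtype=float),
        model_code, mcmc.niter, mcmc.nburn, mcmc.thin,
        int(mcmc.seed) % (2**31), prior.nu, prior.S, prior.nu_e, prior.S_e,
        pi_init, estimate_pi, prior.eta1, prior.eta2,
        np.asarray(prior.mixture_scalers, dtype=float), props,
        prior.eta_dirichlet, lam2, lambda_shape, lambda_rate,
        fix, sigma2_fixed, sigma2_e_fixed,
    )
    diverged_at = out[-1]
    if diverged_at >= 0:
        raise SamplerError(
            f"{prior.model} chain reached a non-finite state at iteration "
            f"{diverged_at}"
        )
    return out


def fit_bayes(ds: Dataset, prior: BayesPriorSpec, mcmc: MCMCConfig,
              fixed_variances: dict | None = None) -> FittedBayesModel:
    """Fit one Bayesian-alphabet model by Gibbs sampling.

    Marker columns are centred at their training means (the intercept
    absorbs the offset); posterior summaries are means over post-burn-in
    thinned draws.  ``fixed_variances={"sigma2": .., "sigma2_e": ..}`` holds
    both variances fixed (no variance updates), which makes BayesRR exactly
    conjugate with the ridge closed form.  Same seed implies bit-identical
    output.
    """
    if ds.n_lines < 10:
        raise ValidationError("need at least 10 lines to fit")
    col_means = ds.genotypes.dosages.mean(axis=0)
    Zc = ds.genotypes.dosages - col_means
    (mu_mean, u_mean, s2e_mean, pi_mean, incl_prob, scalars, u_samples,
     _) = _run_kernel(Zc, ds.phenotype.values, prior, mcmc, fixed_variances)
    samples = pd.DataFrame(scalars, columns=["mu", "sigma2_e", "pi"])
    return FittedBayesModel(
        model=prior.model,
        mu_hat=float(mu_mean),
        u_hat=u_mean,
        sigma2_e_hat=float(s2e_mean),
        pi_hat=float(min(max(pi_mean, 0.0), 1.0)),
        inclusion_prob=incl_prob,
        samples=samples,
        marker_ids=ds.genotypes.marker_ids.copy(),
        col_means=col_means,
        effect_samples=u_samples,
        prior=prior,
        mcmc=mcmc,
    )


def predict_bayes(fit: FittedBayesModel, g: GenotypeMatrix) -> PhenotypeVector:
    """Predict phenotypes ``yhat = mu_hat + (Z - training means) u_hat``.

    Markers are matched by ID (re-ordered if necessary); missing markers
    raise a :class:`ValidationError` naming them.
    """
    if np.array_equal(g.marker_ids, fit.marker_ids):
        Z = g.dosages
    else:
        lookup = {m: i for i, m in enumerate(g.marker_ids)}
        missing = [m for m in fit.marker_ids if m not in lookup]
        if missing:
            raise ValidationError(
                f"genotypes lack {len(missing)} fitted markers, e.g. {missing[:5]}"
            )
        idx = np.array([lookup[m] for m in fit.marker_ids])
        Z = g.dosages[:, idx]
    yhat = fit.mu_hat + (Z - fit.col_means) @ fit.u_hat
    return PhenotypeVector(g.line_ids, yhat, trait_name=f"pred_{fit.model}")


class BayesAlphabetRegressor(RegressorMixin, BaseEstimator):
    """scikit-learn estimator wrapping the Bayesian-alphabet Gibbs samplers.

    Parameters
    ----------
    model:
        One of ``MODEL_NAMES``.
    h2_prior:
        Prior heritability guess used to scale the variance priors.
    pi0:
        Fixed (BayesB/C) or initial (BayesBpi/Cpi) nonzero-effect proportion.
    niter, nburn, thin:
        Chain settings; defaults are the production protocol
        (20000/14000/100).
    random_state:
        Seed for the single RNG stream of the fit.

    Attributes (post-fit)
    ---------------------
    intercept_ : float posterior-mean intercept
    coef_ : (p,) posterior-mean marker effects
    sigma2_e_ : posterior-mean residual variance
    pi_ : posterior-mean nonzero proportion (fixed value where not estimated)
    inclusion_prob_ : per-marker posterior inclusion probability
    result_ : the full :class:`FittedBayesModel`
    """

    def __init__(self, model: str = "BayesA", h2_prior: float = 0.5,
                 pi0: float = 0.05, nu: float = 4.2, nu_e: float = 4.2,
                 niter: int = 20000, nburn: int = 14000, thin: int = 100,
                 random_state: int = 0):
        self.model = model
        self.h2_prior = h2_prior
        self.pi0 = pi0
        self.nu = nu
        self.nu_e = nu_e
        self.niter = niter
        self.nburn = nburn
        self.thin = thin
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        ids = np.array([f"L{i}" for i in range(X.shape[0])], dtype=object)
        markers = np.array([f"M{j}" for j in range(X.shape[1])], dtype=object)
        ds = Dataset(GenotypeMatrix(ids, markers, X), PhenotypeVector(ids, y))
        prior = default_prior(self.model, ds, self.h2_prior)
        prior = replace(prior, pi0=self.pi0, nu=self.nu, nu_e=self.nu_e)
        mcmc = MCMCConfig(self.niter, self.nburn, self.thin,
                          seed=self.random_state)
        self.result_ = fit_bayes(ds, prior, mcmc)
        self.intercept_ = self.result_.mu_hat
        self.coef_ = self.result_.u_hat
        self.sigma2_e_ = self.result_.sigma2_e_hat
        self.pi_ = self.result_.pi_hat
        self.inclusion_prob_ = self.result_.inclusion_prob
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} markers, got {X.shape[1]}"
            )
        return self.intercept_ + (X - self.result_.col_means) @ self.coef_
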