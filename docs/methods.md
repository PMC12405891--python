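# Methods

## Model

All eight base models are whole-genome regressions

    y = mu·1 + X beta + Z u + e,   e_i ~ N(0, sigma_e^2),

with an intercept (optional fixed covariates enter through `X`; the default
is intercept-only, matching how these models are normally run on processed
crop datasets), marker dosages `Z` (n lines × p markers, alternate-allele
counts in [0, 2]) and random marker effects `u`. The models differ only in
the prior on `u_j` and its variance; see the table in the README. Point
masses (`delta_0` in BayesB/Bpi/C/Cpi/R) are exact zeros, not small-variance
normals. Effect variances carry scaled-inv-χ²(ν, S) priors, the residual
variance scaled-inv-χ²(ν_ε, S_ε), the estimated nonzero proportion π a
Beta(η₁, η₂) prior, and the BayesR mixture proportions a Dirichlet prior.

## Gibbs sampler

Fitting is single-site Gibbs with adjusted right-hand sides. For marker j
with prior variance v, the conditional is

    u_j | rest ~ N(r/l, sigma_e^2/l),  r = z_j' e + C_j u_j,  l = C_j + sigma_e^2/v,

with `C_j = z_j' z_j` and `e` the running residual. Spike-and-slab
inclusion uses the conditional posterior odds
`pi·BF / (pi·BF + 1 − pi)` with
`log BF = ½[log(sigma_e^2/(v·l)) + r²/(sigma_e^2·l)]`; BayesR generalises
this to a 4-way categorical over {δ₀, three scaled normals}. Variance
updates are the standard conjugate draws (per-marker scaled-inv-χ²(ν+1, ·)
for BayesA/B/Bpi; pooled over included effects for BayesC/Cpi/R/RR;
ν_ε + n for the residual). BayesL follows Park–Casella:
`u_j ~ N(0, tau_j^2·sigma_e^2)`,
`1/tau_j^2 | u_j ~ inverse-Gaussian(sqrt(lambda^2 sigma_e^2/u_j^2), lambda^2)`,
and `lambda^2` gets a Gamma(1, rate) hyperprior whose prior mean equals the
initialisation. π (Bpi/Cpi) is Beta(η₁ + #nonzero, η₂ + #zero); BayesR
proportions are Dirichlet(η + counts) including the null component.

Numerical choices:

* Marker columns are centred at training means; the intercept absorbs the
  offset and predictions apply the same centring. The intercept has a flat
  prior.
* One RNG stream per fit, seeded from the chain config; marker updates
  consume draws in column order, which makes fits bit-reproducible.
* The running residual is refreshed from scratch every 100 iterations to
  bound float drift.
* Monomorphic (zero-variance) marker columns are held at effect zero.
* Spike log-odds are clamped at ±35 before the logistic; the
  inverse-Gaussian mean is capped at 1e8 for near-zero effects.
* A non-finite chain state aborts with the iteration number.

The kernel is one numba-compiled routine dispatching on a model code, so it
compiles once per process and the same update machinery serves all eight
priors.

### Hyper-parameter defaults

The reference protocol for these models publishes chain settings
(niter 20,000 / burn-in 14,000 / thin 100 — the production default here)
and the mixture constants (π₀ = 0.05; BayesR scalers 10⁻³/10⁻²/10⁻¹ with
proportions 10⁻⁴/10⁻³/10⁻²) but not ν, S, η or λ. Defaults chosen:
ν = ν_ε = 4.2 (conventional weakly informative choice in this literature)
and η₁ = η₂ = 1 (uniform Beta). Scales are set from a prior heritability
guess h² (default 0.5): the per-(nonzero-)marker effect-variance target is

    sigma_u^2 = h^2 · var(y) / (pi_eff · Σ_j 2 f_j (1 − f_j)),

and S solves mode(scaled-inv-χ²(ν, S)) = νS/(ν+2) = target; S_ε is set the
same way from (1 − h²)·var(y); λ is initialised so the lasso prior variance
2/λ² times sigma_e² matches the dense target. For BayesR the mixture second
moment Σ π_c·c replaces pi_eff. All of this is exposed in `BayesPriorSpec`
so any other implementation's settings can be reproduced.

A reduced desk-scale profile (2000/1000/5, 200 retained draws) is the
testing default; it is enough for the posterior-mean summaries the ensemble
consumes at the fixture sizes below.

### Diagnostics

`mcmc_diagnostics` reports split-half R̂ and an initial-positive-sequence
ESS for the retained scalars (mu, sigma_e², π), warning above R̂ = 1.1.
A constant chain is reported as R̂ = 1 with a zero-variance flag rather
than NaN. These are deliberately minimal single-chain diagnostics for short
thinned traces, implemented directly because the degenerate-chain behaviour
is part of the contract.

## Ensemble weights

Weights live on the probability simplex. The GA is generational with
elitism 1: linear-rank proportionate selection (robust to the scale and
sign of raw fitness, which can be negative under f3), single-point
crossover at a uniformly random cut (probability 0.2 per pair), per-gene
uniform(±0.05) mutation (probability 0.1), population 300, 1000
generations. Feasibility is maintained by projection-by-normalisation
(clip to [0, 1], divide by the sum; an all-zero vector resets to uniform);
an exact Euclidean projection is available behind `projection="euclidean"`.
Elitism makes the best-so-far trajectory monotone, which the tests assert
every generation.

Degenerate fitness is mapped deterministically: a constant ensemble
prediction under f1/f3/f4 ranks as worst (−inf), a zero-MSE ensemble under
f4 as best (+inf). f4 is the ratio f1/f2 (a product form is available via
`f4_form="product"` for auditing). Internally variance/covariance use the
population convention (divisor n), consistent with f2's divisor; Pearson
correlation is divisor-invariant.

### Weight-fitting schemes

How the GA's objective sample is chosen is a genuine design fork:

* `train_fitted` — optimise against the base models' fitted values on the
  full training set. This is the most literal reading of the workflow, but
  with flexible dense-prior models the training fit is nearly perfect, the
  most overfit base model wins all the weight, and the four objectives
  collapse to the same solution.
* `inner_holdout` (default) — carve one inner 80/20 split from the training
  set, fit bases on the inner-train, optimise weights on inner-test
  predictions, then refit bases on the full training set for prediction.
  Weights then reflect out-of-sample behaviour.

Both are recorded in outputs. The trade-off analyses (f1- vs f2-optimal
weights, f3/f4 intermediacy) are asserted on the common out-of-fold sample
the weights were optimised on, where GA near-optimality makes the ordering
checkable at 1e−3; out-of-sample per-objective accuracies are reported but
carry O(10⁻²) split noise at these fixture sizes.

## Evaluation machinery

* `make_splits`: repeated random holdout (default 100 × 80/20); repeat r is
  seeded `base + r`, base model j inside repeat r `base + r + j`, so runs
  are reproducible and all compared models share identical splits.
* Per repeat and model: test-set Pearson correlation, MSE, and the bias
  regression y = a + b·ŷ (slope b > 1 labelled overestimation, b < 1
  underestimation — the convention of the genomic-prediction literature
  this package follows).
* Inclusion curves: single models ranked by mean test PCC (ties broken by
  name), then ensembles of the best-first / worst-first j = 2..k models;
  base fits are shared across subset sizes so only the GA reruns.
* Weight-accuracy correlation: Pearson r (with t-test p-value) across
  models between mean weight and mean PCC; needs k ≥ 3, degenerate inputs
  are flagged rather than silently zeroed.
* Trade-off table: PCC/MSE per objective with percent declines relative to
  f1, `100·(m(f1) − m(fX))/m(f1)`.
* Stacking baseline: ridge meta-learner on centred base predictions with an
  unpenalised intercept, solved from the normal equations
  (`(Pc'Pc + λI) b = Pc'y`); a rank-deficient system at λ = 0 raises an
  error advising a positive penalty. Any fit/predict regressor (e.g. random
  forest or quantile forest) can be plugged in; only ridge is native.
* Leakage audit: an optional recorder logs the line IDs seen by base
  fitting, weight optimisation and scoring in every repeat; the test suite
  asserts the test split never intersects the first two.

External (non-Bayesian) models enter only as extra columns of a
`PredictionMatrix` or through the pluggable meta-regressor contract; they
are deliberately not re-implemented here.

## Synthetic data

The simulator exists so the whole pipeline is testable without downloading
crop datasets. Genotypes: two Bernoulli gametes per line; allele
frequencies uniform on a configurable range (default 0.05–0.5, echoing the
usual <5% MAF exclusion applied to real marker sets); linkage
disequilibrium via an AR(1) latent Gaussian per gamete thresholded at the
frequency quantile (`ld_rho` = adjacent-marker latent correlation), which
keeps marginal frequencies exact. Traits: strictly additive, with effect
architectures matching the four prior families (dense normal, sparse
spike-and-slab, scaled-normal mixture with a null mass, Laplace); noise is
calibrated against the *realized* genetic variance so the target
heritability holds per fixture; h² = 0 is approximated by noise of 10⁶ ×
the genetic variance so the decomposition stays exact. Fixture traits are
standardized to unit phenotypic variance — the scale processed
genomic-prediction traits are usually distributed on, and the scale at
which MSE is commensurable with correlation in the composite objectives.

Presets: `tiny` (60 × 50), `small` (300 × 500), `medium` (600 × 2000),
with documented seeds and bit-identical regeneration.

What the simulator does **not** emulate: population structure and
relatedness, multi-environment/GxE effects, dominance and epistasis,
genotyping error, and realistic long-range LD decay. Passing tests
therefore demonstrate the statistical machinery (shrinkage behaviour,
weight optimisation, evaluation protocol) under the architectures the
priors assume — not field performance on structured breeding populations.

## Problem sizes used in checks

The automated checks run at desk scale: the `small` fixture with the
reduced MCMC profile, 2–10 holdout repeats, 100 seeded replicates for the
single-large-effect detection experiment (n = 200, p = 50, h² = 0.8), 10–20
instances for the GA-vs-grid and conjugate-ridge oracles, and a fixed k = 8
prediction-matrix fixture for the crossover-rate comparison. These sizes
were chosen so the full property suite characterises every component while
remaining reproducible in minutes on one CPU.

## Known limitations

* Single-trait, additive models only; no GBLUP/RKHS kernels.
* Mean imputation only for missing genotypes.
* The label-equivariance of the sampler holds in the weak sense (training
  predictions agree within Monte-Carlo error under column permutation);
  exact per-marker stream alignment is not attempted.
* Inference quality at the reduced chain profile is adequate for posterior
  means but not for tail quantities; use the production profile for real
  analyses.
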