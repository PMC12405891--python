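"""Single-site Gibbs kernel shared by the eight Bayesian-alphabet models.

One numba-compiled routine runs the whole chain for any model; the model is
dispatched by an integer code so the kernel compiles once.  Update equations
are the standard literature-consistent conditionals:

* marker effect: ``u_j | rest ~ N(r/lhs, s2e/lhs)`` with
  ``r = z_j' e + C_j u_j`` (right-hand side with marker j's contribution
  restored), ``C_j = z_j' z_j`` and ``lhs = C_j + s2e / prior_var_j``;
* per-marker effect variance (BayesA/B/Bpi):
  ``s2_j ~ scaled-inv-chi2(nu + 1, (nu*S + u_j^2)/(nu + 1))``;
* common effect variance (BayesRR/C/Cpi/R) with the sum of squares over
  included effects (scaled by the mixture multiplier for BayesR);
* spike-and-slab inclusion from the conditional posterior odds
  ``pi*BF / (pi*BF + 1 - pi)`` with
  ``log BF = 0.5*[log(s2e/(v*lhs)) + r^2/(s2e*lhs)]``;
* pi (Bpi/Cpi): ``Beta(eta1 + #nonzero, eta2 + #zero)``;
* BayesR: 4-way categorical over {point mass, three scaled normals}, mixture
  proportions from a Dirichlet with concentration eta + counts;
* BayesL (Park-Casella): ``u_j ~ N(0, tau2_j * s2e)``,
  ``1/tau2_j ~ inverse-Gaussian(sqrt(lambda2*s2e/u_j^2), lambda2)`` and a
  Gamma hyperprior on lambda2;
* residual variance:
  ``s2e ~ scaled-inv-chi2(nu_e + n, (nu_e*S_e + e'e)/(nu_e + n))``.

The intercept absorbs the training-mean centring of the marker columns and
is sampled with a flat prior.  One RNG stream per fit (seeded once at kernel
entry) with marker updates consuming draws in column order makes runs
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# model codes (fixed; keep in sync with bayes.MODEL_NAMES)
RR, A, B, BPI, C, CPI, R, L = 0, 1, 2, 3, 4, 5, 6, 7


@njit(cache=True)
def _rscinvchi2(df, scale):
    """Draw from scaled-inv-chi2(df, scale) = df*scale / chi2(df)."""
    return df * scale / np.random.chisquare(df)


@njit(cache=True)
def _rinvgauss(mu, lam):
    """Inverse-Gaussian draw (Michael-Schucany-Haas)."""
    v = np.random.standard_normal()
    w = v * v
    x = mu + mu * mu * w / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _dot(a, b):
    s = 0.0
    for i in range(a.shape[0]):
        s += a[i] * b[i]
    return s


@njit(cache=True)
def run_chain(Z, y, model, niter, nburn, thin, seed,
              nu, S, nu_e, S_e,
              pi_init, estimate_pi, eta1, eta2,
              scalers, props_init, eta_dir,
              lambda2_init, lambda_shape, lambda_rate,
              fix_variances, sigma2_fixed, sigma2_e_fixed):
    """Run one Gibbs chain; returns posterior summaries and retained draws.

    Z must be column-centred and Fortran-ordered.  Returns
    (mu_mean, u_mean, s2e_mean, pi_mean, incl_prob, scalar_samples,
    u_samples, diverged_at); ``diverged_at`` is -1 for a clean run, else the
    1-based iteration at which the state became non-finite.
    """
    np.random.seed(seed)
    n, p = Z.shape
    cdiag = np.empty(p)
    for j in range(p):
        cdiag[j] = _dot(Z[:, j], Z[:, j])

    u = np.zeros(p)
    mu = y.mean()
    e = y - mu
    sigma2_e = sigma2_e_fixed if fix_variances else max(S_e, 1e-8)
    sigma2 = sigma2_fixed if fix_variances else max(S, 1e-12)
    sigma2_j = np.full(p, max(S, 1e-12))
    tau2 = np.ones(p)
    lambda2 = lambda2_init
    pi = pi_init
    props = props_init.copy()  # BayesR: [null, c1, c2, c3]
    incl = np.ones(p)  # inclusion indicator (1 for always-in models)

    nsave = (niter - nburn) // thin
    scalar_samples = np.empty((nsave, 3))  # mu, sigma2_e, pi
    u_samples = np.empty((nsave, p))
    incl_sum = np.zeros(p)
    isave = 0

    spike = model == B or model == BPI or model == C or model == CPI
    per_marker_var = model == A or model == B or model == BPI

    for it in range(1, niter + 1):
        # intercept (flat prior)
        e += mu
        mu = e.mean() + np.random.standard_normal() * np.sqrt(sigma2_e / n)
        e -= mu

        m_incl = 0
        ssq = 0.0  # sum of (scaled) squared included effects
        r_counts = np.zeros(4)
        tau2_sum = 0.0

        for j in range(p):
            cj = cdiag[j]
            if cj <= 0.0:
                u[j] = 0.0
                continue
            uold = u[j]
            r = _dot(Z[:, j], e) + cj * uold

            if model == R:
                # 4-way categorical: component 0 is the exact point mass
                logw = np.empty(4)
                maxlw = -1e300
                for c in range(4):
                    pc_ = props[c]
                    lp = np.log(pc_ + 1e-300)
                    if c > 0:
                        v = scalers[c - 1] * sigma2
                        lhs_c = cj + sigma2_e / v
                        lp += 0.5 * (np.log(sigma2_e / (v * lhs_c))
                                     + r * r / (sigma2_e * lhs_c))
                    logw[c] = lp
                    if lp > maxlw:
                        maxlw = lp
                tot = 0.0
                for c in range(4):
                    logw[c] = np.exp(logw[c] - maxlw)
                    tot += logw[c]
                uarg = np.random.random() * tot
                comp = 0
                acc = 0.0
                for c in range(4):
                    acc += logw[c]
                    if uarg <= acc:
                        comp = c
                        break
                r_counts[comp] += 1.0
                if comp == 0:
                    unew = 0.0
                    incl[j] = 0.0
                else:
                    v = scalers[comp - 1] * sigma2
                    lhs = cj + sigma2_e / v
                    unew = (r / lhs
                            + np.random.standard_normal() * np.sqrt(sigma2_e / lhs))
                    ssq += unew * unew / scalers[comp - 1]
                    m_incl += 1
                    incl[j] = 1.0
            elif spike:
                v = sigma2_j[j] if per_marker_var else sigma2
                lhs = cj + sigma2_e / v
                pj = min(max(pi, 1e-12), 1.0 - 1e-12)
                logodds = (np.log(pj / (1.0 - pj))
                           + 0.5 * (np.log(sigma2_e / (v * lhs))
                                    + r * r / (sigma2_e * lhs)))
                if logodds > 35.0:
                    p1 = 1.0
                elif logodds < -35.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + np.exp(-logodds))
                if np.random.random() < p1:
                    unew = (r / lhs
                            + np.random.standard_normal() * np.sqrt(sigma2_e / lhs))
                    m_incl += 1
                    incl[j] = 1.0
                    ssq += unew * unew
                else:
                    unew = 0.0
                    incl[j] = 0.0
            else:
                if model == A:
                    v = sigma2_j[j]
                elif model == L:
                    v = tau2[j] * sigma2_e
                else:  # RR
                    v = sigma2
                lhs = cj + sigma2_e / v
                unew = (r / lhs
                        + np.random.standard_normal() * np.sqrt(sigma2_e / lhs))
                ssq += unew * unew

            d = unew - uold
            if d != 0.0:
                for i in range(n):
                    e[i] -= Z[i, j] * d
            u[j] = unew

            # per-marker variance / scale updates
            if per_marker_var and not fix_variances:
                sigma2_j[j] = _rscinvchi2(nu + 1.0,
                                          (nu * S + unew * unew) / (nu + 1.0))
            if model == L:
                u2 = unew * unew
                if u2 < 1e-12 * sigma2_e:
                    u2 = 1e-12 * sigma2_e
                mu_ig = np.sqrt(lambda2 * sigma2_e / u2)
                if mu_ig > 1e8:
                    mu_ig = 1e8
                inv_tau2 = _rinvgauss(mu_ig, lambda2)
                tau2[j] = 1.0 / inv_tau2
                tau2_sum += tau2[j]

        # common effect variance
        if not fix_variances:
            if model == RR:
                sigma2 = _rscinvchi2(nu + p, (nu * S + ssq) / (nu + p))
            elif model == C or model == CPI or model == R:
                df = nu + m_incl
                sigma2 = _rscinvchi2(df, (nu * S + ssq) / df)

        # mixture / inclusion proportions
        if model == BPI or model == CPI:
            pi = np.random.beta(eta1 + m_incl, eta2 + (p - m_incl))
        elif model == R:
            tot = 0.0
            for c in range(4):
                props[c] = np.random.gamma(eta_dir + r_counts[c], 1.0)
                tot += props[c]
            for c in range(4):
                props[c] /= tot
            pi = 1.0 - props[0]

        # Bayesian-lasso rate hyper-parameter
        if model == L:
            lambda2 = np.random.gamma(lambda_shape + p,
                                      1.0 / (lambda_rate + 0.5 * tau2_sum))

        # residual variance
        if not fix_variances:
            ete = _dot(e, e)
            sigma2_e = _rscinvchi2(nu_e + n, (nu_e * S_e + ete) / (nu_e + n))

        if not (np.isfinite(sigma2_e) and np.isfinite(mu)):
            return (mu, u, sigma2_e, pi, incl_sum, scalar_samples, u_samples, it)

        # periodic residual refresh against float drift
        if it % 100 == 0:
            for i in range(n):
                acc = y[i] - mu
                for j in range(p):
                    acc -= Z[i, j] * u[j]
                e[i] = acc

        if it > nburn and (it - nburn) % thin == 0 and isave < nsave:
            scalar_samples[isave, 0] = mu
            scalar_samples[isave, 1] = sigma2_e
            scalar_samples[isave, 2] = pi
            u_samples[isave, :] = u
            incl_sum += incl
            isave += 1

    mu_mean = scalar_samples[:, 0].mean()
    s2e_mean = scalar_samples[:, 1].mean()
    pi_mean = scalar_samples[:, 2].mean()
    u_mean = np.empty(p)
    for j in range(p):
        u_mean[j] = u_samples[:, j].mean()
    incl_prob = incl_sum / nsave
    return (mu_mean, u_mean, s2e_mean, pi_mean, incl_prob,
            scalar_samples, u_samples, -1)
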