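"""Convergence diagnostics for the retained MCMC draws.

Monitors the scalar traces (intercept, residual variance, pi) kept by every
fit.  The potential scale reduction factor uses the split-chain formulation:
the single thinned chain is split into halves treated as two chains, and

    R-hat = sqrt(((l-1)/l * W + B/l) / W)

with l the half length, W the mean within-half variance and B the
between-half variance of the half means (times l).  A constant chain has
W = B = 0; it is reported as R-hat = 1 with a zero-variance flag rather than
NaN.  Effective sample size uses the initial-positive-sequence estimator on
the autocorrelation function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .bayes import FittedBayesModel

__all__ = ["split_rhat", "effective_sample_size", "mcmc_diagnostics",
           "DiagnosticsReport"]

RHAT_WARN = 1.1


def split_rhat(chain: np.ndarray) -> tuple[float, bool]:
    """Split-half potential scale reduction; returns (R-hat, zero_variance)."""
    chain = np.asarray(chain, dtype=float)
    half = chain.size // 2
    a, b = chain[:half], chain[half:2 * half]
    w = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
    means = np.array([a.mean(), b.mean()])
    bvar = half * means.var(ddof=1)
    if w == 0.0:
        return 1.0, True
    var_plus = (half - 1) / half * w + bvar / half
    return float(np.sqrt(var_plus / w)), False


def effective_sample_size(chain: np.ndarray) -> float:
    """Initial-positive-sequence ESS of a single chain."""
    chain = np.asarray(chain, dtype=float)
    n = chain.size
    c = chain - chain.mean()
    var0 = (c * c).mean()
    if var0 == 0.0:
        return float(n)
    rho_sum = 0.0
    for lag in range(1, n):
        rho = (c[:-lag] * c[lag:]).mean() / var0
        if rho <= 0.0:
            break
        rho_sum += rho
    return float(n / (1.0 + 2.0 * rho_sum))


@dataclass
class DiagnosticsReport:
    """Per-scalar R-hat/ESS table plus an overall warning flag."""

    table: pd.DataFrame
    warn: bool


def mcmc_diagnostics(fit: FittedBayesModel) -> DiagnosticsReport:
    """Split-R-hat and ESS for the monitored scalars (mu, sigma2_e, pi).

    Requires at least 20 retained samples; flags the report when any R-hat
    exceeds 1.1.
    """
    samples = fit.samples
    if len(samples) < 20:
        raise ValidationError(
            f"need >= 20 retained samples for diagnostics, have {len(samples)}"
        )
    rows = []
    for name in ("mu", "sigma2_e", "pi"):
        chain = samples[name].to_numpy()
        rhat, zero_var = split_rhat(chain)
        rows.append({
            "parameter": name,
            "rhat": rhat,
            "ess": effective_sample_size(chain),
            "zero_variance": zero_var,
            "warn": (not zero_var) and rhat > RHAT_WARN,
        })
    table = pd.DataFrame(rows).set_index("parameter")
    return DiagnosticsReport(table=table, warn=bool(table["warn"].any()))
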