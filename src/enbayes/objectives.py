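"""Ensemble objective functions, accuracy metrics and the bias regression.

The ensemble prediction for weight vector ``w`` on a prediction matrix with
columns ``yhat_j`` is the convex combination ``sum_j w_j * yhat_j`` with
``0 <= w_j <= 1`` and ``sum_j w_j = 1`` (the probability simplex).  Four
scalar objectives drive the weight search:

====  ==============================  =========
name  definition                      sense
====  ==============================  =========
f1    PCC(y, ensemble prediction)     maximise
f2    MSE(y, ensemble prediction)     minimise
f3    f1 - f2                         maximise
f4    f1 / f2                         maximise
====  ==============================  =========

Prediction bias is quantified by ordinary least squares of observed on
predicted values, ``y = a + b*yhat``; slope b > 1 is reported as
overestimation and b < 1 as underestimation (the convention used throughout
the genomic-prediction literature this package follows).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import DegenerateObjectiveError, UndefinedCorrelationError, ValidationError
from .io import PhenotypeVector, PredictionMatrix

__all__ = [
    "WeightVector",
    "ObjectiveKind",
    "BiasEstimate",
    "ensemble_prediction",
    "pcc",
    "mse",
    "objective_value",
    "bias_regression",
]

_SIMPLEX_TOL = 1e-8


@dataclass
class WeightVector:
    """Simplex-constrained ensemble weights, one per base model."""

    weights: np.ndarray
    model_names: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.model_names = np.asarray(list(self.model_names), dtype=object)
        if self.weights.shape != (self.model_names.size,):
            raise ValidationError("one weight per model name required")
        if self.weights.min() < -_SIMPLEX_TOL or self.weights.max() > 1 + _SIMPLEX_TOL:
            raise ValidationError("weights must lie in [0, 1]")
        if abs(self.weights.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValidationError(
                f"weights must sum to 1 within {_SIMPLEX_TOL}; got {self.weights.sum()}"
            )

    @property
    def k(self) -> int:
        return self.weights.size


class ObjectiveKind(Enum):
    """The four ensemble objectives; ``sense`` is fixed by kind."""

    f1 = "f1"
    f2 = "f2"
    f3 = "f3"
    f4 = "f4"

    @property
    def sense(self) -> str:
        return "minimize" if self is ObjectiveKind.f2 else "maximize"

    @classmethod
    def coerce(cls, kind) -> "ObjectiveKind":
        return kind if isinstance(kind, cls) else cls(str(kind))


@dataclass
class BiasEstimate:
    """OLS fit of observed on predicted: y = a + b*yhat."""

    intercept: float
    slope: float
    interpretation: str  # "unbiased" | "over" | "under"


def _values(x) -> np.ndarray:
    if isinstance(x, PhenotypeVector):
        return x.values
    return np.asarray(x, dtype=float)


def ensemble_prediction(p: PredictionMatrix, w: WeightVector) -> PhenotypeVector:
    """Weighted average of model predictions, ``yhat_i = sum_j w_j yhat_ij``."""
    if not np.array_equal(p.model_names, w.model_names):
        raise ValidationError(
            f"model names/order mismatch: predictions {list(p.model_names)} "
            f"vs weights {list(w.model_names)}"
        )
    return PhenotypeVector(p.line_ids, p.values @ w.weights, trait_name="ensemble")


def pcc(y, yhat) -> float:
    """Pearson correlation between observed and predicted values.

    Raises :class:`UndefinedCorrelationError` for constant input rather than
    silently returning 0.
    """
    yv, pv = _values(y), _values(yhat)
    if yv.shape != pv.shape:
        raise ValidationError("length mismatch between observed and predicted")
    if yv.size < 3:
        raise ValidationError("PCC needs at least 3 observations")
    yc, pc_ = yv - yv.mean(), pv - pv.mean()
    denom = np.sqrt((yc * yc).sum() * (pc_ * pc_).sum())
    if denom == 0.0:
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    return float((yc * pc_).sum() / denom)


def mse(y, yhat) -> float:
    """Mean squared prediction error with divisor n."""
    yv, pv = _values(y), _values(yhat)
    if yv.shape != pv.shape:
        raise ValidationError("length mismatch between observed and predicted")
    d = yv - pv
    return float((d * d).mean())


def objective_value(kind, y, p: PredictionMatrix, w: WeightVector,
                    f4_form: str = "ratio") -> float:
    """Evaluate one of f1..f4 for a weight vector.

    ``f4_form`` defaults to the ratio f1/f2; ``"product"`` evaluates f1*f2
    for auditing alternative readings of the objective.

    Degenerate cases raise: a constant ensemble prediction under f1/f3/f4
    raises :class:`DegenerateObjectiveError` (optimisers map it to worst
    fitness); f2 = 0 under f4 signals a perfect fit and is returned as
    ``inf``.
    """
    kind = ObjectiveKind.coerce(kind)
    yhat = ensemble_prediction(p, w)
    if kind is ObjectiveKind.f2:
        return mse(y, yhat)
    f2 = mse(y, yhat)
    try:
        f1 = pcc(y, yhat)
    except UndefinedCorrelationError as exc:
        raise DegenerateObjectiveError(
            "ensemble prediction is constant; f1-based objectives undefined"
        ) from exc
    if kind is ObjectiveKind.f1:
        return f1
    if kind is ObjectiveKind.f3:
        return f1 - f2
    if f4_form == "product":
        return f1 * f2
    if f2 == 0.0:
        return float("inf")  # perfect fit, best possible ratio
    return f1 / f2


def bias_regression(y, yhat) -> BiasEstimate:
    """Regress observed on predicted values: ``y = a + b*yhat``.

    b = cov(y, yhat)/var(yhat); a = mean(y) - b*mean(yhat).  Interpretation
    follows the stated convention: b > 1 overestimation, b < 1
    underestimation (classification uses a 1e-9 relative tolerance around 1).
    """
    yv, pv = _values(y), _values(yhat)
    if yv.shape != pv.shape:
        raise ValidationError("length mismatch between observed and predicted")
    if yv.size < 3:
        raise ValidationError("bias regression needs at least 3 observations")
    var_p = np.var(pv)
    if var_p == 0.0:
        raise ValidationError("bias regression undefined for constant predictions")
    b = float(np.cov(yv, pv, bias=True)[0, 1] / var_p)
    a = float(yv.mean() - b * pv.mean())
    if abs(b - 1.0) <= 1e-9 * max(1.0, abs(b)):
        interp = "unbiased"
    elif b > 1.0:
        interp = "over"
    else:
        interp = "under"
    return BiasEstimate(intercept=a, slope=b, interpretation=interp)
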