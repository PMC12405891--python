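"""Genetic-algorithm search for simplex-constrained ensemble weights.

A generational GA with elitism optimises one of the four ensemble objectives
over the probability simplex.  Individuals are weight vectors; feasibility is
maintained by projection-by-normalisation (clip to [0, 1], divide by the
coordinate sum) after every crossover and mutation, so every individual in
every generation satisfies the simplex constraints.  An exact Euclidean
simplex projection is available via ``projection="euclidean"``.

Defaults follow the hyper-parameters used for the genomic-prediction
experiments this package reproduces: population 300, crossover rate 0.2,
per-gene mutation rate 0.1, 1000 generations, elitism 1.

Selection is linear-rank proportionate (robust to fitness scaling; raw f3
fitness can be negative), crossover is single-point with a uniformly random
cut, and mutation perturbs genes by uniform(-step, +step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import OptimizationError, ValidationError
from .io import PredictionMatrix
from .objectives import ObjectiveKind, WeightVector

__all__ = [
    "GAConfig",
    "GAResult",
    "initialize_population",
    "select_parents",
    "crossover_single_point",
    "mutate",
    "run_ga",
]


@dataclass
class GAConfig:
    """Hyper-parameters of the weight-search GA."""

    pop_size: int = 300
    crossover_rate: float = 0.2
    mutation_rate: float = 0.1
    max_iter: int = 1000
    mutation_step: float = 0.05
    elitism: int = 1
    seed: int = 0
    patience: int | None = None
    projection: str = "normalize"  # or "euclidean"

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValidationError("pop_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.mutation_step <= 0:
            raise ValidationError("mutation_step must be > 0")
        if self.elitism < 0 or self.elitism >= self.pop_size:
            raise ValidationError("elitism must be in [0, pop_size)")
        if self.projection not in ("normalize", "euclidean"):
            raise ValidationError(f"unknown projection {self.projection!r}")


@dataclass
class GAResult:
    """Best weight vector found, its fitness, and the per-generation record."""

    best_weights: WeightVector
    best_fitness: float
    fitness_trajectory: np.ndarray = field(repr=False)
    generations_run: int = 0


def _project_rows(W: np.ndarray, method: str = "normalize") -> np.ndarray:
    """Repair a batch of weight rows onto the simplex."""
    W = np.clip(W, 0.0, 1.0)
    if method == "euclidean":
        return np.apply_along_axis(_euclidean_simplex, 1, W)
    s = W.sum(axis=1, keepdims=True)
    dead = (s <= 0.0).ravel()
    if dead.any():
        W[dead] = 1.0 / W.shape[1]
        s = W.sum(axis=1, keepdims=True)
    return W / s


def _euclidean_simplex(v: np.ndarray) -> np.ndarray:
    """Exact Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, v.size + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def initialize_population(k: int, cfg: GAConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``pop_size`` weight vectors uniform on [0,1]^k, projected to the simplex."""
    if k < 1:
        raise ValidationError("need at least one model (k >= 1)")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if k == 1:
        return np.ones((cfg.pop_size, 1))
    return _project_rows(rng.uniform(size=(cfg.pop_size, k)), cfg.projection)


def select_parents(population: np.ndarray, fitnesses: np.ndarray, cfg: GAConfig,
                   rng: np.random.Generator, n_pairs: int) -> np.ndarray:
    """Linear-rank proportionate selection of parent index pairs.

    Selection probability is proportional to the (average-tie) linear rank of
    the fitness, so strictly higher fitness means strictly higher selection
    probability and all-tied fitness degrades gracefully to uniform sampling.
    Fitness is in the maximisation sense (callers negate for minimisation);
    -inf encodes degenerate individuals.
    """
    finite = np.where(np.isfinite(fitnesses), fitnesses, -np.inf)
    # rankdata handles -inf (lowest ranks); average ranks break ties fairly
    ranks = rankdata(finite, method="average")
    probs = ranks / ranks.sum()
    return rng.choice(population.shape[0], size=(n_pairs, 2), p=probs)


def crossover_single_point(c1: np.ndarray, c2: np.ndarray, point: int,
                           projection: str = "normalize") -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover after gene ``point`` (1-based cut, 1 <= point < k).

    Offspring are re-projected to the simplex.  For k = 1 crossover is a
    no-op.
    """
    k = c1.size
    if k == 1:
        return c1.copy(), c2.copy()
    if not 1 <= point < k:
        raise ValidationError(f"crossover point must be in [1, {k - 1}], got {point}")
    o1 = np.concatenate([c1[:point], c2[point:]])
    o2 = np.concatenate([c2[:point], c1[point:]])
    projected = _project_rows(np.vstack([o1, o2]), projection)
    return projected[0], projected[1]


def mutate(c: np.ndarray, cfg: GAConfig,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """Perturb each gene w.p. ``mutation_rate`` by uniform(-step, +step), then repair."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    out = c.astype(float).copy()
    mask = rng.random(c.size) < cfg.mutation_rate
    if mask.any():
        out[mask] += rng.uniform(-cfg.mutation_step, cfg.mutation_step, mask.sum())
    return _project_rows(out[None, :], cfg.projection)[0]


def _evaluate_population(kind: ObjectiveKind, y: np.ndarray, P: np.ndarray,
                         W: np.ndarray, f4_form: str = "ratio") -> np.ndarray:
    """Vectorised objective values for every row of ``W``.

    Degenerate f1/f3/f4 individuals get -inf; a zero-MSE individual under f4
    gets +inf (perfect fit).  Returned values are in objective units.
    """
    Yh = P @ W.T  # n x m
    resid = y[:, None] - Yh
    f2 = (resid * resid).mean(axis=0)
    if kind is ObjectiveKind.f2:
        return f2
    yc = y - y.mean()
    Yc = Yh - Yh.mean(axis=0, keepdims=True)
    denom = np.sqrt((yc * yc).sum() * (Yc * Yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = (yc @ Yc) / denom
    degenerate = denom == 0.0
    if kind is ObjectiveKind.f1:
        out = f1
    elif kind is ObjectiveKind.f3:
        out = f1 - f2
    elif f4_form == "product":
        out = f1 * f2
    else:
        with np.errstate(divide="ignore"):
            out = np.where(f2 == 0.0, np.inf, f1 / f2)
    out = np.asarray(out, dtype=float)
    out[degenerate] = -np.inf
    return out


def run_ga(objective, y, p: PredictionMatrix, cfg: GAConfig,
           f4_form: str = "ratio", on_generation=None) -> GAResult:
    """Run the full generational GA loop and return the best-ever individual.

    The loop is evaluate -> rank select -> single-point crossover ->
    mutation -> elitist generational replacement.  Elitism makes the
    best-so-far trajectory monotone in the objective's optimisation sense.
    Identical inputs and seed give bit-identical results.

    ``on_generation(gen, population, objective_values)`` is called after
    every evaluation (generation 0 included) for monitoring/auditing.
    """
    kind = ObjectiveKind.coerce(objective)
    yv = y.values if hasattr(y, "values") else np.asarray(y, dtype=float)
    P = p.values
    if P.shape[0] != yv.size:
        raise ValidationError("phenotype and prediction matrix length mismatch")
    k = p.n_models
    sign = 1.0 if kind.sense == "maximize" else -1.0
    rng = np.random.default_rng(cfg.seed)

    W = initialize_population(k, cfg, rng)
    obj = _evaluate_population(kind, yv, P, W, f4_form)
    score = sign * obj
    if on_generation is not None:
        on_generation(0, W, obj)

    if k == 1:
        best = WeightVector(np.ones(1), p.model_names)
        return GAResult(best, float(obj[0]), np.array([obj[0]]), generations_run=1)

    if not np.isfinite(score).any() and kind is not ObjectiveKind.f2:
        raise OptimizationError(
            "every individual in the initial population has a degenerate "
            f"objective under {kind.value}; consider objective f2"
        )

    best_idx = int(np.argmax(score))
    best_w = W[best_idx].copy()
    best_score = score[best_idx]
    trajectory = [sign * best_score]
    stall = 0
    gen = 0
    col = np.arange(k)
    for gen in range(1, cfg.max_iter + 1):
        n_children = cfg.pop_size - cfg.elitism
        n_pairs = (n_children + 1) // 2
        pairs = select_parents(W, score, cfg, rng, n_pairs)
        p1, p2 = W[pairs[:, 0]], W[pairs[:, 1]]
        # vectorised single-point crossover (per-pair probability p_c)
        do_cx = rng.random(n_pairs) < cfg.crossover_rate
        points = rng.integers(1, k, size=n_pairs)
        tail = col[None, :] >= points[:, None]
        swap = do_cx[:, None] & tail
        o1 = np.where(swap, p2, p1)
        o2 = np.where(swap, p1, p2)
        if do_cx.any():
            o1[do_cx] = _project_rows(o1[do_cx], cfg.projection)
            o2[do_cx] = _project_rows(o2[do_cx], cfg.projection)
        children = np.empty((2 * n_pairs, k))
        children[0::2], children[1::2] = o1, o2
        children = children[:n_children]
        # vectorised per-gene mutation
        mask = rng.random(children.shape) < cfg.mutation_rate
        steps = rng.uniform(-cfg.mutation_step, cfg.mutation_step,
                            children.shape)
        children = _project_rows(np.where(mask, children + steps, children),
                                 cfg.projection)
        elite_order = np.argsort(score)[::-1][: cfg.elitism]
        W = np.vstack([W[elite_order], children])
        obj = _evaluate_population(kind, yv, P, W, f4_form)
        score = sign * obj
        if on_generation is not None:
            on_generation(gen, W, obj)
        gen_best = int(np.argmax(score))
        if score[gen_best] > best_score:
            best_score = score[gen_best]
            best_w = W[gen_best].copy()
            stall = 0
        else:
            stall += 1
        trajectory.append(sign * best_score)
        if cfg.patience is not None and stall >= cfg.patience:
            break

    best = WeightVector(_project_rows(best_w[None, :], cfg.projection)[0],
                        p.model_names)
    return GAResult(best, float(sign * best_score), np.asarray(trajectory),
                    generations_run=gen)
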