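"""Cuckoo Search over fusion weights, with Lévy-flight proposals.

The search treats each fusion weight vector as an egg in a nest. Every
generation each nest proposes a new egg by a Lévy flight — a heavy-tailed
random step that mixes many small local moves with occasional long jumps —
and the egg displaces a randomly chosen nest if it scores better (brood
parasitism). A fraction ``pa`` of the worst nests is then abandoned and
re-drawn uniformly, keeping the population diverse. The incumbent best is
never abandoned, so the best-fitness history is non-decreasing.

Lévy steps use the Mantegna construction: each component is u / |v|^(1/beta)
with u ~ N(0, sigma_u^2), v ~ N(0, 1), and

    sigma_u = [ Gamma(1+b) sin(pi b / 2) / (Gamma((1+b)/2) b 2^((b-1)/2)) ]^(1/b)

which gives an approximately beta-stable step distribution.

Weights are searched as a free box in [0, 1]^M — no simplex constraint, since
the fused argmax is scale-invariant and near-one-sum weight pairs like
(0.5, 0.45) are meaningful. Fitness is typically validation accuracy of the
fused argmax labels, or Scott's Pi against truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import ClassScheme, PredictionSet, validate_alignment
from .errors import OptimizationError, ParameterError, ValidationError
from .fusion import WeightVector
from .metrics import accuracy as _accuracy
from .metrics import scotts_pi as _scotts_pi

FitnessFn = Callable[[np.ndarray], float]


def levy_sigma(beta: float) -> float:
    """Mantegna scale sigma_u(beta) for the numerator normal."""
    if not (0.0 < beta <= 2.0):
        raise ParameterError(f"levy beta must be in (0, 2], got {beta}")
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(beta: float, dim: int, rng: np.random.Generator) -> np.ndarray:
    """One heavy-tailed step vector, component-wise u / |v|^(1/beta)."""
    if dim < 1:
        raise ParameterError(f"dim must be >= 1, got {dim}")
    sigma = levy_sigma(beta)
    u = rng.normal(0.0, sigma, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return u / np.abs(v) ** (1.0 / beta)


@dataclass(frozen=True)
class CSConfig:
    """Cuckoo Search hyperparameters.

    Defaults are standard CS settings sized for low-dimensional weight
    boxes: 25 nests, abandon fraction 0.25, Lévy exponent 1.5, step scale
    0.05 (in weight units), and an improvement-based stop (less than ``tol``
    gain in best fitness for ``patience`` consecutive generations).
    """

    n_nests: int = 25
    pa: float = 0.25
    levy_beta: float = 1.5
    step_scale: float = 0.05
    bounds: tuple = (0.0, 1.0)      # (lo, hi) for all dims, or per-dim pairs
    max_generations: int = 200
    tol: float = 1e-6
    patience: int = 10
    seed: int = 0
    archive_size: int = 10

    def __post_init__(self):
        if self.n_nests < 2:
            raise ParameterError(f"n_nests must be >= 2, got {self.n_nests}")
        if not (0.0 <= self.pa < 1.0):
            raise ParameterError(f"pa must be in [0, 1), got {self.pa}")
        levy_sigma(self.levy_beta)  # validates beta
        if self.step_scale <= 0:
            raise ParameterError(f"step_scale must be positive, got {self.step_scale}")
        if self.max_generations < 0:
            raise ParameterError("max_generations must be >= 0")
        if self.tol < 0:
            raise ParameterError("tol must be >= 0")
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")
        if self.archive_size < 1:
            raise ParameterError("archive_size must be >= 1")

    def bounds_arrays(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        b = np.asarray(self.bounds, dtype=np.float64)
        if b.shape == (2,):
            lo = np.full(dim, b[0])
            hi = np.full(dim, b[1])
        elif b.shape == (dim, 2):
            lo, hi = b[:, 0].copy(), b[:, 1].copy()
        else:
            raise ParameterError(
                f"bounds must be (lo, hi) or {dim} pairs, got shape {b.shape}"
            )
        if np.any(lo >= hi) or np.any(lo < 0) or np.any(hi > 1):
            raise ParameterError(f"bounds must be well-ordered within [0, 1], got {self.bounds}")
        return lo, hi


@dataclass
class Nest:
    """One candidate weight vector and its fitness (None = unevaluated)."""

    weights: np.ndarray
    fitness: Optional[float] = None


@dataclass
class SearchResult:
    """Outcome of one Cuckoo Search run."""

    best_weights: WeightVector
    best_fitness: float
    history: list[float]
    archive: list[tuple[tuple[float, ...], float]]
    evaluations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "best_weights": list(self.best_weights.weights),
            "best_fitness": self.best_fitness,
            "history": self.history,
            "archive": [{"weights": list(w), "fitness": f} for w, f in self.archive],
            "evaluations": self.evaluations,
            "seed": self.seed,
        }


def init_nests(cfg: CSConfig, dim: int, rng: np.random.Generator) -> list[Nest]:
    """Uniformly sample ``n_nests`` weight vectors inside the bounds."""
    if dim < 1:
        raise ParameterError(f"dim must be >= 1, got {dim}")
    lo, hi = cfg.bounds_arrays(dim)
    return [Nest(rng.uniform(lo, hi)) for _ in range(cfg.n_nests)]


def make_accuracy_fitness(models: Sequence[PredictionSet],
                          scheme: ClassScheme) -> FitnessFn:
    """Fitness = accuracy of the fused argmax labels against truth.

    Equivalent to ``accuracy(truth, argmax_labels(weighted_fuse(models, w)))``
    but evaluated on a pre-stacked probability tensor for speed inside the
    optimizer.
    """
    stacked, truth = _stack_models(models)
    n = truth.size

    def fitness(w) -> float:
        w = np.asarray(w, dtype=np.float64)
        fused = np.tensordot(w, stacked, axes=1)
        return float(np.count_nonzero(np.argmax(fused, axis=1) == truth)) / n

    return fitness


def make_agreement_fitness(models: Sequence[PredictionSet], scheme: ClassScheme,
                           weighting: str = "none") -> FitnessFn:
    """Fitness = Scott's Pi between truth and the fused argmax labels.

    An undefined pi (degenerate pooled marginals) maps to -1 so the search
    can still rank such candidates (they are maximally bad).
    """
    stacked, truth = _stack_models(models)
    K = stacked.shape[2]

    def fitness(w) -> float:
        w = np.asarray(w, dtype=np.float64)
        fused = np.tensordot(w, stacked, axes=1)
        res = _scotts_pi(truth, np.argmax(fused, axis=1), K, weighting)
        return -1.0 if res.pi is None else res.pi

    return fitness


def _stack_models(models: Sequence[PredictionSet]) -> tuple[np.ndarray, np.ndarray]:
    models = list(models)
    if len(models) < 2:
        raise ValidationError(f"need at least 2 models, got {len(models)}")
    validate_alignment(models)
    truth = next((m.truth for m in models if m.truth is not None), None)
    if truth is None:
        raise ValidationError("fitness construction requires truth labels")
    return np.stack([m.probs for m in models]), truth


def _archive_key(weights: np.ndarray, fitness: float):
    # higher fitness first; ties: smaller Euclidean norm, then lexicographic
    return (-fitness, float(np.dot(weights, weights)), tuple(weights))


class _Archive:
    """Top-A (weights, fitness) list with a deterministic tie order."""

    def __init__(self, size: int):
        self.size = size
        self.entries: list[tuple[tuple[float, ...], float]] = []

    def push(self, weights: np.ndarray, fitness: float) -> None:
        key = tuple(float(x) for x in weights)
        for w, _ in self.entries:
            if w == key:
                return
        self.entries.append((key, float(fitness)))
        self.entries.sort(key=lambda e: _archive_key(np.asarray(e[0]), e[1]))
        del self.entries[self.size:]

    @property
    def best(self) -> tuple[tuple[float, ...], float]:
        return self.entries[0]


def cs_optimize(fitness: FitnessFn, dim: int, cfg: CSConfig) -> SearchResult:
    """Run Cuckoo Search and return the best weights found.

    Per generation: (i) each nest proposes
    ``x' = x + step_scale * levy ⊙ (x - x_best)`` (the incumbent best takes a
    pure Lévy perturbation of magnitude ``step_scale``), clipped to bounds,
    and replaces a *random* nest if fitter; (ii) the worst
    ``ceil(pa * n_nests)`` nests are abandoned and re-drawn uniformly;
    (iii) the global best and archive are updated. Stops at
    ``max_generations`` or after ``patience`` consecutive generations with
    best-fitness improvement below ``tol``. Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds_arrays(dim)
    archive = _Archive(cfg.archive_size)
    evaluations = 0

    def evaluate(w: np.ndarray) -> float:
        nonlocal evaluations
        f = float(fitness(w))
        evaluations += 1
        if not math.isfinite(f):
            raise OptimizationError(
                f"fitness returned non-finite value {f!r} at weights {list(w)}"
            )
        archive.push(w, f)
        return f

    nests = init_nests(cfg, dim, rng)
    for nest in nests:
        nest.fitness = evaluate(nest.weights)

    best_w, best_f = archive.best
    history = [best_f]
    stagnant = 0

    for _ in range(cfg.max_generations):
        x_best = np.asarray(best_w)
        # (i) egg laying: Levy proposals, each displacing a random nest if fitter
        for nest in nests:
            diff = nest.weights - x_best
            step = levy_step(cfg.levy_beta, dim, rng)
            if np.all(diff == 0.0):
                proposal = nest.weights + cfg.step_scale * step
            else:
                proposal = nest.weights + cfg.step_scale * step * diff
            proposal = np.clip(proposal, lo, hi)
            f_prop = evaluate(proposal)
            j = int(rng.integers(cfg.n_nests))
            if nests[j].fitness is None or f_prop > nests[j].fitness:
                nests[j] = Nest(proposal, f_prop)

        # (ii) abandon the worst pa-fraction, re-draw uniformly in bounds
        n_abandon = math.ceil(cfg.pa * cfg.n_nests)
        if n_abandon:
            order = sorted(range(cfg.n_nests),
                           key=lambda i: _archive_key(nests[i].weights, nests[i].fitness))
            for i in order[cfg.n_nests - n_abandon:]:
                fresh = rng.uniform(lo, hi)
                nests[i] = Nest(fresh, evaluate(fresh))

        # (iii) global best + convergence bookkeeping
        new_w, new_f = archive.best
        improvement = new_f - best_f
        best_w, best_f = new_w, new_f
        history.append(best_f)
        stagnant = stagnant + 1 if improvement < cfg.tol else 0
        if stagnant >= cfg.patience:
            break

    return SearchResult(
        best_weights=WeightVector(best_w),
        best_fitness=best_f,
        history=history,
        archive=list(archive.entries),
        evaluations=evaluations,
        seed=cfg.seed,
    )


def grid_sweep(fitness: FitnessFn, dim: int, step: float = 0.05,
               lo: float = 0.0, hi: float = 1.0) -> list[tuple[tuple[float, ...], float]]:
    """Exhaustive fitness sweep over a regular weight grid.

    Enumerates every weight vector on the ``step``-spaced grid in
    [lo, hi]^dim (the all-zero corner is skipped: it carries no decision).
    Returns (weights, fitness) pairs in grid order — useful both for
    weight-sweep tables and as a brute-force reference for the search.
    """
    if step <= 0:
        raise ParameterError(f"grid step must be positive, got {step}")
    axis = np.round(np.arange(lo, hi + step / 2, step), 10)
    grids = np.meshgrid(*([axis] * dim), indexing="ij")
    points = np.stack([g.ravel() for g in grids], axis=1)
    out = []
    for p in points:
        if np.all(p == 0.0):
            continue
        out.append((tuple(float(x) for x in p), float(fitness(p))))
    return out
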