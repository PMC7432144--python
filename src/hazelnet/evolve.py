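"""Real-coded genetic algorithm for architecture search and input optimization.

A population of real-valued chromosomes evolves by fitness-proportional
(roulette-wheel) selection, arithmetic (blend) crossover, per-gene
Gaussian mutation clipped to the box bounds, and elitism.  Inequality
constraints are handled by an additive penalty proportional to the
violation magnitude.  Defaults follow the classical small-population
setup for bioprocess optimization: population 50, crossover rate 0.85,
500 generations, mutation rate 0.01.

Two domain-specific drivers sit on top of the generic optimizer: hidden
neuron-count selection for the perceptron (an integer gene obtained by
rounding, with cached candidate evaluations against an inner validation
split of the training subset), and constrained maximization of the
culture inputs (CE, CF, elicitor adding day, harvest day) under a
fitted surrogate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neuralnet import MLPModel, TrainConfig, forward, train


class ConstraintError(RuntimeError):
    """No feasible individual could be sampled."""


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 500
    crossover_rate: float = 0.85
    mutation_rate: float = 0.01
    elitism_count: int = 1
    mutation_scale: float = 0.1  # mutation sd as a fraction of the gene range
    penalty_coeff: float = 1e3
    seed: int = 0

    def validate(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")


@dataclass
class GAResult:
    best_chromosome: np.ndarray
    best_fitness: float
    history: pd.DataFrame  # per-generation best and mean (penalized) fitness
    evaluations: int


def _selection_probabilities(fitness: np.ndarray,
                             feasible: np.ndarray | None = None) -> np.ndarray:
    """Roulette-wheel probabilities on min-shifted fitness.

    The shift uses the minimum over feasible individuals (when any
    exist) so that a single heavily-penalized outlier cannot flatten
    the selection pressure among the feasible; fitness below the shift
    point clips to a vanishing share.
    """
    ref = fitness[feasible] if feasible is not None and feasible.any() else fitness
    shifted = np.maximum(fitness - ref.min(), 0.0) + 1e-12
    return shifted / shifted.sum()


def ga_optimize(fitness, bounds, constraints=(), config: GAConfig | None = None
                ) -> GAResult:
    """Maximize ``fitness`` over a box, subject to inequality constraints.

    ``bounds`` is a sequence of (low, high) per gene; each constraint is
    a callable g with the convention g(x) <= 0 when satisfied, and
    violations are penalized as ``penalty_coeff * sum(max(0, g(x)))``.
    With elitism the per-generation best penalized fitness is monotone
    non-decreasing.  Deterministic for a given seed.
    """
    config = config or GAConfig()
    config.validate()
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    if lo.size == 0 or np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)):
        raise ValueError("bounds must be finite and non-empty")
    if np.any(lo > hi):
        raise ValueError("each bound must satisfy low <= high")
    span = hi - lo
    rng = np.random.default_rng(config.seed)
    n_pop, n_genes = config.population_size, lo.size

    evaluations = 0

    def violation(x) -> float:
        return float(sum(max(0.0, float(g(x))) for g in constraints))

    def penalized(x) -> tuple[float, bool]:
        nonlocal evaluations
        evaluations += 1
        v = violation(x)
        return float(fitness(x)) - config.penalty_coeff * v, v == 0.0

    pop = lo + rng.uniform(size=(n_pop, n_genes)) * span
    if constraints:
        for _ in range(100):
            if any(violation(x) == 0.0 for x in pop):
                break
            pop = lo + rng.uniform(size=(n_pop, n_genes)) * span
        else:
            raise ConstraintError(
                "no feasible individual found in 100 population resamples"
            )
    scored = [penalized(x) for x in pop]
    fit = np.array([s[0] for s in scored])
    feas = np.array([s[1] for s in scored])

    best_idx = int(np.argmax(fit))
    best_x, best_f = pop[best_idx].copy(), float(fit[best_idx])
    history = [(0, best_f, float(fit.mean()))]

    for gen in range(1, config.generations + 1):
        probs = _selection_probabilities(fit, feas)
        parents = pop[rng.choice(n_pop, size=n_pop, p=probs)]
        children = parents.copy()
        for i in range(0, n_pop - 1, 2):
            if rng.uniform() < config.crossover_rate:
                # extended blend crossover: alpha beyond [0, 1] lets the
                # offspring explore outside the parents' segment, which
                # counteracts the contraction of pure averaging
                a = rng.uniform(-0.25, 1.25)
                p1, p2 = parents[i], parents[i + 1]
                children[i] = a * p1 + (1.0 - a) * p2
                children[i + 1] = a * p2 + (1.0 - a) * p1
        mutate = rng.uniform(size=children.shape) < config.mutation_rate
        noise = rng.normal(0.0, 1.0, children.shape) * config.mutation_scale * span
        children = np.where(mutate, children + noise, children)
        children = np.clip(children, lo, hi)
        scored = [penalized(x) for x in children]
        child_fit = np.array([s[0] for s in scored])
        child_feas = np.array([s[1] for s in scored])
        if config.elitism_count > 0:
            elite_order = np.argsort(fit)[::-1][: config.elitism_count]
            worst = np.argsort(child_fit)[: config.elitism_count]
            children[worst] = pop[elite_order]
            child_fit[worst] = fit[elite_order]
            child_feas[worst] = feas[elite_order]
        pop, fit, feas = children, child_fit, child_feas
        gen_best = int(np.argmax(fit))
        if float(fit[gen_best]) > best_f:
            best_f = float(fit[gen_best])
            best_x = pop[gen_best].copy()
        history.append((gen, float(fit[gen_best]), float(fit.mean())))

    return GAResult(
        best_chromosome=best_x,
        best_fitness=best_f,
        history=pd.DataFrame(history, columns=["generation", "best", "mean"]),
        evaluations=evaluations,
    )


def select_architecture(X_train, y_train, hidden_range=range(1, 16),
                        train_config: TrainConfig | None = None,
                        config: GAConfig | None = None,
                        inner_val_fraction: float = 0.15,
                        train_seed: int = 0):
    """Choose the hidden-neuron count by GA, then retrain on all rows.

    The single gene is the neuron count (a rounded real).  Candidate
    fitness is the negative RMSE on an inner validation slice of the
    training subset (never the test subset), with a fixed training seed
    per candidate; evaluations are cached, so each count is trained at
    most once.  Returns ``(n_hidden, model, candidate_rmse)`` where the
    model is retrained on the full training subset.
    """
    counts = sorted(set(int(h) for h in hidden_range))
    if not counts:
        raise ValueError("hidden_range must not be empty")
    train_config = train_config or TrainConfig()
    config = config or GAConfig()
    X = np.atleast_2d(np.asarray(X_train, float))
    y = np.asarray(y_train, float).ravel()

    rng = np.random.default_rng(train_seed)
    n = X.shape[0]
    n_val = max(int(round(inner_val_fraction * n)), 1)
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]

    cache: dict[int, float] = {}

    def candidate_rmse(n_hidden: int) -> float:
        if n_hidden not in cache:
            model = train(X[fit_idx], y[fit_idx], n_hidden,
                          config=train_config, seed=train_seed)
            pred = forward(model, X[val_idx])
            cache[n_hidden] = float(np.sqrt(np.mean((pred - y[val_idx]) ** 2)))
        return cache[n_hidden]

    if len(counts) == 1:
        best_n = counts[0]
    else:
        lo, hi = counts[0], counts[-1]

        def fitness(x):
            n_hidden = int(np.clip(round(float(x[0])), lo, hi))
            if n_hidden not in counts:  # sparse ranges snap to nearest
                n_hidden = min(counts, key=lambda c: abs(c - n_hidden))
            return -candidate_rmse(n_hidden)

        result = ga_optimize(fitness, [(lo - 0.49, hi + 0.49)], config=config)
        decoded = int(np.clip(round(float(result.best_chromosome[0])), lo, hi))
        best_n = min(counts, key=lambda c: abs(c - decoded))
        # the cache holds every evaluated count; take the true argmin
        best_n = min(cache, key=cache.get)
    model = train(X, y, best_n, config=train_config, seed=train_seed)
    return best_n, model, dict(cache)


def optimize_inputs(model: MLPModel, bounds=None, config: GAConfig | None = None,
                    final_day: float = 23.0, response: str = "response",
                    dose_limit: float | None = None, n_restarts: int = 5):
    """Maximize the surrogate's prediction over the culture inputs.

    Bounds default to the model's training ranges (harvest capped at
    ``final_day``); the harvest day is constrained to follow the
    elicitor adding day, and ``dose_limit`` (when given) caps the
    combined elicitor dose ce + cf at the largest total dose actually
    applied, keeping the search off never-sampled corners of the box
    where a data-driven surrogate is untrustworthy.  The GA is restarted
    ``n_restarts`` times from seeds derived from ``config.seed`` and the
    best run is kept (the surrogate can carry several local basins, and
    a low-mutation GA commits to one early).  Returns a
    :class:`hazelnet.pipeline.OptimizationResult` with derived blend and
    timing quantities.
    """
    from .pipeline import make_optimization_result  # deferred: avoids cycle

    config = config or GAConfig()
    if bounds is None:
        bounds = [
            (float(model.input_min[i]), float(model.input_max[i]))
            for i in range(4)
        ]
        bounds[3] = (bounds[3][0], min(bounds[3][1], final_day))

    def fitness(x):
        return float(forward(model, np.asarray(x, float).reshape(1, 4))[0])

    constraints = [lambda x: x[2] - x[3]]  # adding_day <= harvest_day
    if dose_limit is not None:
        constraints.append(lambda x: x[0] + x[1] - dose_limit)

    result = None
    for k in range(max(n_restarts, 1)):
        sub = dataclasses.replace(config, seed=(config.seed + 7919 * k) % 2**31)
        run = ga_optimize(fitness, bounds, constraints=constraints, config=sub)
        if result is None or run.best_fitness > result.best_fitness:
            result = run
    ce, cf, adding, harvest = (float(g) for g in result.best_chromosome)
    predicted = fitness(result.best_chromosome)
    return make_optimization_result(
        response=response, ce_conc=ce, cf_conc=cf,
        adding_day=adding, harvest_day=harvest,
        predicted=predicted, ga_result=result,
    )
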