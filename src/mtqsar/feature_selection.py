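"""Descriptor subset selection: Wilks lambda and a genetic algorithm.

Wilks lambda is the classical discriminant-analysis separation statistic,

    lambda = det(W) / det(T)

with ``W`` the pooled within-class sum-of-squares-and-cross-products
(SSCP) matrix and ``T`` the total SSCP over the candidate columns.
Values near 0 mean strong class separation, near 1 none.  The genetic
algorithm searches fixed-length binary chromosomes (one bit per
descriptor) for the subset minimising a size-penalised lambda; an
exhaustive enumerator over small pools provides the ground-truth optimum
for testing and for tiny problems.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAConfig",
    "SelectionResult",
    "wilks_lambda",
    "subset_fitness",
    "ga_select",
    "exhaustive_select",
]


def _as_matrix(X, subset: Optional[Sequence[str]] = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        if subset is not None:
            missing = [s for s in subset if s not in X.columns]
            if missing:
                raise KeyError(f"subset names not in feature matrix: {missing}")
            X = X[list(subset)]
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    names = [str(i) for i in range(X.shape[1])]
    if subset is not None:
        idx = [int(s) for s in subset]
        X = X[:, idx]
        names = [names[i] for i in idx]
    return X, names


def wilks_lambda(X, y, subset: Optional[Sequence[str]] = None) -> float:
    """Wilks lambda = det(W)/det(T) for a two-class (or multi-class) split.

    Computed through slogdet for numerical stability.  Raises for a
    single-class ``y`` or a degenerate (singular total-SSCP) feature set.
    """
    M, _ = _as_matrix(X, subset)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("Wilks lambda needs at least two classes")
    if M.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    grand = M.mean(axis=0)
    Tc = M - grand
    T = Tc.T @ Tc
    W = np.zeros_like(T)
    for c in classes:
        G = M[y == c]
        Gc = G - G.mean(axis=0)
        W += Gc.T @ Gc
    # deviation features can be *exactly* collinear (e.g. the _st/_at pair
    # differences of several descriptors span only the condition-group
    # indicator space), so test definiteness through eigenvalues rather
    # than trusting a determinant sign
    eig_t = np.linalg.eigvalsh(T)
    if eig_t[0] <= eig_t[-1] * 1e-10 or eig_t[-1] <= 0:
        raise ValueError("degenerate feature set: singular total SSCP matrix")
    eig_w = np.linalg.eigvalsh(W)
    if eig_w[0] <= 0:
        # exact within-class collinearity with a regular T: total separation
        return 0.0
    lam = float(np.exp(np.sum(np.log(eig_w)) - np.sum(np.log(eig_t))))
    return float(np.clip(lam, 0.0, 1.0))


@dataclass
class GAConfig:
    """Genetic-algorithm settings (conventional defaults of the tool family)."""

    population_size: int = 100
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.01
    subset_min: int = 2
    subset_max: int = 12
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0
    fitness_name: str = "wilks_lambda"
    size_penalty: float = 0.01

    def validate(self, pool_size: int) -> None:
        if not (0 < self.subset_min <= self.subset_max <= pool_size):
            raise ValueError(
                f"infeasible subset bounds [{self.subset_min}, {self.subset_max}] "
                f"for pool of {pool_size}"
            )
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")


@dataclass
class SelectionResult:
    chosen: list[str]
    fitness: float
    fitness_trace: list[float] = field(default_factory=list)
    seed: int = 0
    uninformative: bool = False

    def to_json(self, path: str | Path, config: Optional[GAConfig] = None) -> None:
        payload = {
            "chosen": self.chosen,
            "fitness": self.fitness,
            "fitness_trace": self.fitness_trace,
            "seed": self.seed,
            "uninformative": self.uninformative,
        }
        if config is not None:
            payload["config"] = config.__dict__
        Path(path).write_text(json.dumps(payload, indent=2))


def subset_fitness(
    X, y, subset: Sequence[str], subset_max: int, size_penalty: float = 0.01
) -> float:
    """Size-penalised Wilks lambda, minimised by the search.

    fitness = lambda + penalty * |subset| / subset_max.  The penalty keeps
    the search from accreting uninformative descriptors.  Degenerate
    subsets score worst (fitness 1 + penalty cap).
    """
    try:
        lam = wilks_lambda(X, y, subset)
    except ValueError:
        return 1.0 + size_penalty * 2
    return lam + size_penalty * (len(subset) / subset_max)


def _tie_key(names: list[str], fitness: float) -> tuple:
    return (round(fitness, 12), len(names), tuple(sorted(names)))


def exhaustive_select(
    X, y, k: int, config: Optional[GAConfig] = None, budget: int = 100_000
) -> SelectionResult:
    """Global optimum of the GA fitness over all size-``k`` subsets.

    Intended as an oracle on small pools; refuses combinatorial blowups
    beyond ``budget`` subsets.  Ties break toward the lexicographically
    smallest name tuple.
    """
    config = config or GAConfig(subset_min=k, subset_max=k)
    _, names = _as_matrix(X)
    if comb(len(names), k) > budget:
        raise ValueError(
            f"exhaustive enumeration of C({len(names)}, {k}) subsets exceeds budget {budget}"
        )
    best: Optional[tuple] = None
    best_subset: list[str] = []
    best_fit = np.inf
    for combo in itertools.combinations(names, k):
        fit = subset_fitness(X, y, combo, config.subset_max, config.size_penalty)
        key = _tie_key(list(combo), fit)
        if best is None or key < best:
            best = key
            best_subset = list(combo)
            best_fit = fit
    lam = wilks_lambda(X, y, best_subset)
    return SelectionResult(
        chosen=best_subset,
        fitness=best_fit,
        fitness_trace=[best_fit],
        seed=config.seed,
        uninformative=lam > 0.95,
    )


def _repair(chrom: np.ndarray, lo: int, hi: int, rng: np.random.Generator) -> None:
    """Random bit flips toward the nearest subset-size bound, in place."""
    k = int(chrom.sum())
    while k < lo:
        zeros = np.flatnonzero(~chrom)
        chrom[rng.choice(zeros)] = True
        k += 1
    while k > hi:
        ones = np.flatnonzero(chrom)
        chrom[rng.choice(ones)] = False
        k -= 1


def ga_select(X, y, config: Optional[GAConfig] = None) -> SelectionResult:
    """Elitist genetic-algorithm subset search minimising penalised lambda.

    Tournament selection, one-point crossover, per-bit mutation, repair of
    out-of-bound chromosomes, one elite carried unchanged.  Deterministic
    given ``config.seed``.  Fitness values are memoised per chromosome, so
    revisiting a subset is free.
    """
    config = config or GAConfig()
    _, names = _as_matrix(X)
    pool = len(names)
    config.validate(pool)
    rng = np.random.default_rng(config.seed)

    cache: dict[bytes, float] = {}

    def fitness(chrom: np.ndarray) -> float:
        key = chrom.tobytes()
        if key not in cache:
            subset = [names[i] for i in np.flatnonzero(chrom)]
            cache[key] = subset_fitness(X, y, subset, config.subset_max, config.size_penalty)
        return cache[key]

    # init: uniform subset sizes within bounds
    population = np.zeros((config.population_size, pool), dtype=bool)
    for i in range(config.population_size):
        k = int(rng.integers(config.subset_min, config.subset_max + 1))
        population[i, rng.choice(pool, size=k, replace=False)] = True

    def best_of(pop: np.ndarray) -> tuple[np.ndarray, float]:
        keyed = sorted(
            (( _tie_key([names[j] for j in np.flatnonzero(c)], fitness(c)), c) for c in pop),
            key=lambda t: t[0],
        )
        chrom = keyed[0][1]
        return chrom, fitness(chrom)

    trace: list[float] = []
    elite, elite_fit = best_of(population)
    for _ in range(config.generations):
        fits = np.array([fitness(c) for c in population])
        children = [elite.copy() for _ in range(config.elitism)]
        while len(children) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size, size=config.tournament_size)
                parents.append(population[contenders[np.argmin(fits[contenders])]].copy())
            a, b = parents
            if rng.random() < config.crossover_prob and pool > 1:
                cut = int(rng.integers(1, pool))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                flips = rng.random(pool) < config.mutation_prob
                child ^= flips
                _repair(child, config.subset_min, config.subset_max, rng)
                if len(children) < config.population_size:
                    children.append(child)
        population = np.array(children)
        gen_best, gen_fit = best_of(population)
        if _tie_key([names[j] for j in np.flatnonzero(gen_best)], gen_fit) < _tie_key(
            [names[j] for j in np.flatnonzero(elite)], elite_fit
        ):
            elite, elite_fit = gen_best.copy(), gen_fit
        trace.append(elite_fit)

    chosen = [names[i] for i in np.flatnonzero(elite)]
    try:
        lam = wilks_lambda(X, y, chosen)
    except ValueError:
        lam = 1.0
    return SelectionResult(
        chosen=chosen,
        fitness=elite_fit,
        fitness_trace=trace,
        seed=config.seed,
        uninformative=lam > 0.95,
    )
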