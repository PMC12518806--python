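"""Baseline wrapper feature selectors: genetic algorithm, binary particle
swarm, simulated annealing, and plain ant colony.

All four consume the identical logistic-regression cross-validation
fitness evaluator used by the HACO engine, so reported fitness for a given
mask is selector-independent. GA/PSO/SA search over binary masks (variable
size under a cap); the plain-ACO baseline is the HACO engine run in its
degenerate mode (no elite term, constant deposit intensity, constant
evaporation, mutation off).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ants import HACOParams, evaluate_fitness, run_haco

__all__ = [
    "SelectorConfig",
    "SelectionResult",
    "run_ga",
    "run_pso",
    "run_sqa",
    "run_plain_aco",
    "BaselineSelector",
]

METHODS = ("ga", "pso", "sqa", "aco", "haco")


@dataclass
class SelectorConfig:
    """Shared configuration for the baseline selectors."""

    method: str = "ga"
    population_size: int = 20
    iterations: int = 30
    size_cap: Optional[int] = None   # max selected features; None = 50%
    # GA
    crossover_rate: float = 0.7
    mutation_rate: float = 0.02
    tournament_k: int = 2
    # PSO
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    # SA (geometric schedule T_k = T0 * r^k)
    t0: float = 0.05
    cooling: float = 0.95
    # ACO degenerate mode
    subset_size: Optional[int] = None
    constant_rho: float = 0.5
    # shared fitness
    cv_folds: int = 3
    lambda_size: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.method in ("ga", "pso") and self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling ratio must be in (0, 1)")


@dataclass
class SelectionResult:
    method: str
    selected: np.ndarray          # sorted feature indices
    fitness: float
    cost: float
    history: list = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        n = int(self.selected.max()) + 1 if self.selected.size else 0
        m = np.zeros(n, dtype=bool)
        m[self.selected] = True
        return m


class _FitnessCache:
    """Mask-keyed wrapper around the shared LR-CV fitness evaluator
    (smaller cost is better; fitness is CV accuracy)."""

    def __init__(self, X, y, config: SelectorConfig):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.config = config
        self._cache: dict = {}

    def __call__(self, mask: np.ndarray) -> tuple[float, float]:
        idx = tuple(np.flatnonzero(mask))
        if not idx:
            return 0.0, 1.0
        if idx not in self._cache:
            self._cache[idx] = evaluate_fitness(
                list(idx), self.X, self.y,
                cv_folds=self.config.cv_folds,
                lambda_size=self.config.lambda_size,
                seed=self.config.seed,
            )
        return self._cache[idx]


def _cap_for(config: SelectorConfig, n_features: int) -> int:
    cap = config.size_cap
    if cap is None:
        cap = max(2, n_features // 2)
    return min(cap, n_features)


def _repair(mask: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Keep masks nonempty and within the size cap."""
    mask = mask.copy()
    on = np.flatnonzero(mask)
    if on.size == 0:
        mask[rng.integers(mask.size)] = True
    elif on.size > cap:
        drop = rng.choice(on, size=on.size - cap, replace=False)
        mask[drop] = False
    return mask


def _random_mask(n: int, cap: int, rng: np.random.Generator) -> np.ndarray:
    k = int(rng.integers(1, cap + 1))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def run_ga(X, y, config: SelectorConfig,
           initial_population: Optional[list] = None) -> SelectionResult:
    """Binary-chromosome GA: tournament selection, uniform crossover,
    bit-flip mutation; elitist carry-over of the best chromosome."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = np.asarray(X).shape[1]
    cap = _cap_for(config, n)
    fit = _FitnessCache(X, y, config)
    if initial_population is not None:
        pop = [np.asarray(m, dtype=bool) for m in initial_population]
    else:
        pop = [_random_mask(n, cap, rng) for _ in range(config.population_size)]
    scores = [fit(m) for m in pop]
    best_i = int(np.argmax([s[0] for s in scores]))
    best_mask, (best_fit, best_cost) = pop[best_i].copy(), scores[best_i]
    history = []
    for _ in range(config.iterations):
        new_pop = [best_mask.copy()]  # elitism
        while len(new_pop) < config.population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                cand = rng.choice(len(pop), size=config.tournament_k,
                                  replace=False)
                winner = max(cand, key=lambda i: scores[i][0])
                parents.append(pop[winner])
            a, b = parents
            if rng.random() < config.crossover_rate:
                swap = rng.random(n) < 0.5
                child = np.where(swap, a, b)
            else:
                child = a.copy()
            flip = rng.random(n) < config.mutation_rate
            child = np.logical_xor(child, flip)
            new_pop.append(_repair(child, cap, rng))
        pop = new_pop
        scores = [fit(m) for m in pop]
        i = int(np.argmax([s[0] for s in scores]))
        if scores[i][0] > best_fit:
            best_mask, (best_fit, best_cost) = pop[i].copy(), scores[i]
        history.append(float(best_fit))
    return SelectionResult("ga", np.flatnonzero(best_mask), best_fit,
                           best_cost, history)


def run_pso(X, y, config: SelectorConfig) -> SelectionResult:
    """Binary PSO with global-best topology.

    Real velocities are squashed through a V-shaped transfer function:
    each bit flips with probability |tanh(v)|, so zero velocity leaves a
    position unchanged (the "positions never change" degenerate case with
    all weights zero)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = np.asarray(X).shape[1]
    cap = _cap_for(config, n)
    fit = _FitnessCache(X, y, config)
    P = config.population_size
    pos = np.stack([_random_mask(n, cap, rng) for _ in range(P)])
    vel = np.zeros((P, n))
    pbest = pos.copy()
    pscores = [fit(m) for m in pos]
    g = int(np.argmax([s[0] for s in pscores]))
    gbest, (gfit, gcost) = pos[g].copy(), pscores[g]
    history = []
    for _ in range(config.iterations):
        r1 = rng.random((P, n))
        r2 = rng.random((P, n))
        vel = (config.inertia * vel
               + config.cognitive * r1 * (pbest.astype(float) - pos)
               + config.social * r2 * (gbest.astype(float) - pos))
        flip = rng.random((P, n)) < np.abs(np.tanh(vel))
        pos = np.logical_xor(pos, flip)
        for i in range(P):
            pos[i] = _repair(pos[i], cap, rng)
            f, c = fit(pos[i])
            if f > pscores[i][0]:
                pbest[i] = pos[i].copy()
                pscores[i] = (f, c)
            if f > gfit:
                gbest, gfit, gcost = pos[i].copy(), f, c
        history.append(float(gfit))
    return SelectionResult("pso", np.flatnonzero(gbest), gfit, gcost, history)


def run_sqa(X, y, config: SelectorConfig) -> SelectionResult:
    """Simulated annealing over masks: single-bit-flip neighbourhood,
    geometric temperature schedule, worse states accepted with
    probability exp(-delta_cost / T)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = np.asarray(X).shape[1]
    cap = _cap_for(config, n)
    fit = _FitnessCache(X, y, config)
    cur = _random_mask(n, cap, rng)
    cur_fit, cur_cost = fit(cur)
    best, best_fit, best_cost = cur.copy(), cur_fit, cur_cost
    T = config.t0
    history = []
    for _ in range(config.iterations):
        cand = cur.copy()
        cand[rng.integers(n)] ^= True
        cand = _repair(cand, cap, rng)
        f, c = fit(cand)
        d = c - cur_cost
        if d <= 0 or (T > 0 and rng.random() < np.exp(-d / T)):
            cur, cur_fit, cur_cost = cand, f, c
            if f > best_fit:
                best, best_fit, best_cost = cand.copy(), f, c
        T *= config.cooling
        history.append(float(best_fit))
    return SelectionResult("sqa", np.flatnonzero(best), best_fit,
                           best_cost, history)


def plain_aco_params(config: SelectorConfig) -> HACOParams:
    """Degenerate HACO parameters reproducing the textbook ant system:
    no elite reinforcement, constant deposit intensity, constant
    evaporation, no boundary mutation."""
    return HACOParams(
        n_ants=config.population_size,
        max_iterations=config.iterations,
        delta=0.0,
        P1=1.0, P2=1.0, P3=1.0,
        subset_size=config.subset_size,
        mutation_rate=0.0,
        constant_rho=config.constant_rho,
        cv_folds=config.cv_folds,
        lambda_size=config.lambda_size,
        seed=config.seed,
    )


def run_plain_aco(X, y, config: SelectorConfig) -> SelectionResult:
    """Classic ACO baseline = the HACO engine in its degenerate mode."""
    config.validate()
    res = run_haco(np.asarray(X, dtype=float), np.asarray(y),
                   plain_aco_params(config))
    return SelectionResult(
        "aco", np.sort(np.asarray(res.best_path)), res.best_fitness,
        res.best_cost, [h["best_fitness"] for h in res.history])


_RUNNERS = {"ga": run_ga, "pso": run_pso, "sqa": run_sqa,
            "aco": run_plain_aco}


class BaselineSelector:
    """Estimator facade over the baseline selectors (method in
    {'ga', 'pso', 'sqa', 'aco'})."""

    def __init__(self, method="ga", **config):
        self.method = method
        self.config = config

    def fit(self, X, y):
        cfg = SelectorConfig(method=self.method, **self.config)
        self.result_ = _RUNNERS[self.method](X, y, cfg)
        self.n_features_in_ = np.asarray(X).shape[1]
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.result_.selected] = True
        self.support_ = mask
        return self

    def get_support(self, indices=False):
        if not hasattr(self, "support_"):
            raise RuntimeError("BaselineSelector is not fitted")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.get_support()]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"method": self.method, **self.config}

    def set_params(self, **params):
        self.method = params.pop("method", self.method)
        self.config.update(params)
        return self
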