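"""Hybrid ant-colony-optimization (HACO) wrapper feature selection.

Features are nodes of a complete graph; an ant's path is an ordered
feature subset and edges are consecutive selections. Each edge carries a
pheromone value bounded in [tau_min, tau_max]; heuristic information for
a candidate feature is its label-association score (absolute point-biserial
correlation for binary labels, correlation ratio for multi-class),
normalized so the best feature scores 1. Path construction follows a
roulette over

    Q_ji = tau_ji^alpha * eta_i^beta * a_ji / sum over allowed,

where the adaptive factor a_ji = M*s / (M*s + delta * P_d(j,i) * eta_i /
eta_max) discounts edges already traversed often (P_d is the cumulative
traversal count since the first iteration). Subset fitness is the
cross-validated accuracy of a logistic model on the subset; the path cost
is (1 - fitness) + lambda_size * K / n_features with a small positive
floor. Pheromone updates combine a time-varying evaporation schedule
rho(s) (a linear "curve decay" in s, clamped into (0, 1] by default), a
piecewise-constant deposit intensity P(s), per-ant deposits P(s)/cost on
traversed edges, and an elitist deposit delta*P/L* on the incumbent best
path. A symmetrical boundary mutation occasionally swaps a selected
feature whose pheromone mass sits in the central band for an unselected
one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "HACOParams",
    "PheromoneState",
    "AntSolution",
    "HACOResult",
    "heuristic_scores",
    "transition_probabilities",
    "start_probabilities",
    "adaptive_factor",
    "construct_solution",
    "evaluate_fitness",
    "pheromone_intensity",
    "evaporation_rate",
    "ant_deposit",
    "elite_deposit",
    "update_pheromone",
    "boundary_mutation",
    "init_state",
    "run_haco",
    "HACOSelector",
]


@dataclass
class HACOParams:
    """Tunable constants of the HACO engine.

    ``subset_size=None`` resolves to 10% of the feature count (minimum 2).
    ``S1``/``S2``/``S3=None`` resolve to S/3, 2S/3 and S. ``constant_rho``
    overrides the evaporation schedule with a fixed rate (the classic
    ant-system mode used by the plain-ACO baseline).
    """

    n_ants: int = 20
    max_iterations: int = 30
    alpha: float = 1.0
    beta: float = 2.0
    delta: float = 1.0
    subset_size: Optional[int] = None
    P1: float = 1.0
    P2: float = 0.5
    P3: float = 0.25
    S1: Optional[int] = None
    S2: Optional[int] = None
    S3: Optional[int] = None
    tau_max: float = 1.0
    tau_min: float = 0.1
    mutation_rate: float = 0.1
    mutation_band: float = 0.25
    elite_constant: float = 1.0
    lambda_size: float = 0.01
    cost_floor: float = 1e-6
    cv_folds: int = 3
    clamp_evaporation: bool = True
    constant_rho: Optional[float] = None
    seed: int = 0

    def resolved(self, n_features: int) -> "HACOParams":
        """Copy with subset size and schedule thresholds made concrete."""
        import dataclasses as _dc
        K = self.subset_size
        if K is None:
            K = max(2, round(0.1 * n_features))
        S = self.max_iterations
        S3 = self.S3 if self.S3 is not None else S
        S1 = self.S1 if self.S1 is not None else min(max(1, S // 3), S3)
        S2 = self.S2 if self.S2 is not None else min(max(S1, (2 * S) // 3), S3)
        out = _dc.replace(self, subset_size=K, S1=S1, S2=S2, S3=S3)
        out.validate(n_features)
        return out

    def validate(self, n_features: Optional[int] = None) -> None:
        if self.n_ants < 1 or self.max_iterations < 1:
            raise ValueError("n_ants and max_iterations must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not (0 < self.tau_min < self.tau_max):
            raise ValueError("require 0 < tau_min < tau_max")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if min(self.P1, self.P2, self.P3) <= 0 or self.elite_constant <= 0:
            raise ValueError("pheromone intensities must be > 0")
        if self.S1 is not None and self.S2 is not None and self.S3 is not None:
            if not (self.S1 <= self.S2 <= self.S3):
                raise ValueError("require S1 <= S2 <= S3")
        if n_features is not None and self.subset_size is not None:
            if self.subset_size > n_features:
                raise ValueError("subset_size exceeds number of features")


@dataclass
class PheromoneState:
    """Per-edge pheromone trails plus heuristic information and traversal
    counts; ``s`` is the current (1-based) iteration."""

    tau: np.ndarray
    eta: np.ndarray
    eta_max: float
    traversal_counts: np.ndarray
    s: int = 1

    @property
    def n_features(self) -> int:
        return self.tau.shape[0]

    def node_pheromone(self) -> np.ndarray:
        """Per-node pheromone marginal (column mean of incoming edges),
        used for start selection and mutation banding."""
        return self.tau.mean(axis=0)


@dataclass
class AntSolution:
    """One ant's ordered feature subset with its evaluation."""

    path: list
    taboo: set
    fitness: float = float("nan")
    cost: float = float("nan")

    def edges(self) -> list:
        return list(zip(self.path[:-1], self.path[1:]))


@dataclass
class HACOResult:
    best_path: list
    best_fitness: float
    best_cost: float
    history: list
    iterations_run: int

    def to_dict(self) -> dict:
        return {
            "best_path": [int(i) for i in self.best_path],
            "best_fitness": float(self.best_fitness),
            "best_cost": float(self.best_cost),
            "iterations_run": int(self.iterations_run),
            "history": self.history,
        }


def heuristic_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature-label association scores, normalized to max 1.

    Binary labels: absolute point-biserial (Pearson) correlation.
    Multi-class: square root of the correlation ratio (between-class
    variance over total variance of the feature).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n = X.shape[0]
    total_var = X.var(axis=0)
    total_var = np.where(total_var > 0, total_var, 1.0)
    if len(classes) == 2:
        yc = (y == classes[1]).astype(float)
        yc = (yc - yc.mean())
        Xc = X - X.mean(axis=0)
        denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
        denom = np.where(denom > 0, denom, 1.0)
        score = np.abs(Xc.T @ yc) / denom
    else:
        grand = X.mean(axis=0)
        between = np.zeros(X.shape[1])
        for c in classes:
            mask = y == c
            between += mask.sum() / n * (X[mask].mean(axis=0) - grand) ** 2
        score = np.sqrt(between / total_var)
    mx = score.max()
    if mx <= 0:
        return np.ones_like(score)
    return score / mx


def adaptive_factor(M: int, S_d: int, P_d: float, eta: float,
                    eta_max: float, delta: float) -> float:
    """a_ji = M*S_d / (M*S_d + delta * P_d * eta / eta_max), in (0, 1]."""
    if M < 1 or S_d < 1:
        raise ValueError("M and S_d must be >= 1")
    if eta_max <= 0:
        raise ValueError("eta_max must be > 0")
    return (M * S_d) / (M * S_d + delta * P_d * eta / eta_max)


def _adaptive_factors_row(state: PheromoneState, j: int,
                          params: HACOParams) -> np.ndarray:
    M, s = params.n_ants, state.s
    return (M * s) / (
        M * s
        + params.delta * state.traversal_counts[j] * state.eta / state.eta_max
    )


def transition_probabilities(
    state: PheromoneState,
    current: int,
    allowed: Sequence[int],
    params: HACOParams,
) -> np.ndarray:
    """Probability over all features of moving from ``current`` to each
    allowed feature; exactly 0 outside ``allowed``; sums to 1."""
    allowed = np.asarray(sorted(allowed), dtype=int)
    if allowed.size == 0:
        raise ValueError("no admissible feature")
    a_row = _adaptive_factors_row(state, current, params)
    num = (
        state.tau[current, allowed] ** params.alpha
        * state.eta[allowed] ** params.beta
        * a_row[allowed]
    )
    total = num.sum()
    probs = np.zeros(state.n_features)
    if not np.isfinite(total) or total <= 0:
        warnings.warn("all-zero transition numerators; uniform fallback")
        probs[allowed] = 1.0 / allowed.size
    else:
        probs[allowed] = num / total
    return probs


def start_probabilities(
    state: PheromoneState,
    allowed: Sequence[int],
    params: HACOParams,
) -> np.ndarray:
    """First-feature selection law: roulette over the per-node pheromone
    marginal and heuristic score (no adaptive factor at the start)."""
    allowed = np.asarray(sorted(allowed), dtype=int)
    if allowed.size == 0:
        raise ValueError("no admissible feature")
    node = state.node_pheromone()
    num = node[allowed] ** params.alpha * state.eta[allowed] ** params.beta
    total = num.sum()
    probs = np.zeros(state.n_features)
    if not np.isfinite(total) or total <= 0:
        probs[allowed] = 1.0 / allowed.size
    else:
        probs[allowed] = num / total
    return probs


def construct_solution(
    state: PheromoneState,
    params: HACOParams,
    rng: np.random.Generator,
    update_counts: bool = True,
) -> AntSolution:
    """Build one ant's path of ``subset_size`` distinct features by
    sequential roulette sampling, excluding visited features via the taboo
    set. Traversal counts are incremented per edge unless frozen."""
    n = state.n_features
    K = params.subset_size
    if K is None or K > n:
        raise ValueError("subset_size must be set and <= n_features")
    path: list = []
    taboo: set = set()
    allowed = set(range(n))
    probs = start_probabilities(state, allowed, params)
    current = int(rng.choice(n, p=probs))
    path.append(current)
    taboo.add(current)
    allowed.discard(current)
    while len(path) < K:
        probs = transition_probabilities(state, current, allowed, params)
        nxt = int(rng.choice(n, p=probs))
        if update_counts:
            state.traversal_counts[current, nxt] += 1
        path.append(nxt)
        taboo.add(nxt)
        allowed.discard(nxt)
        current = nxt
    return AntSolution(path=path, taboo=taboo)


def evaluate_fitness(
    path: Sequence[int],
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 3,
    lambda_size: float = 0.01,
    cost_floor: float = 1e-6,
    seed: int = 0,
) -> tuple[float, float]:
    """Wrapper fitness: stratified cross-validated accuracy of a logistic
    model on the path's columns; cost = (1 - fitness) + lambda_size * K /
    n_features, floored at ``cost_floor``."""
    path = list(path)
    if not path:
        raise ValueError("path must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Xs = X[:, path]
    _, counts = np.unique(y, return_counts=True)
    folds = min(cv_folds, int(counts.min()))
    if folds < cv_folds:
        warnings.warn(
            f"class too small for {cv_folds}-fold CV; refolding to {folds}")
    if folds < 2:
        clf = LogisticRegression(max_iter=1000)
        clf.fit(Xs, y)
        fitness = float(clf.score(Xs, y))
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(Xs, y):
            clf = LogisticRegression(max_iter=1000)
            clf.fit(Xs[tr], y[tr])
            accs.append(clf.score(Xs[te], y[te]))
        fitness = float(np.mean(accs))
    cost = (1.0 - fitness) + lambda_size * len(path) / X.shape[1]
    return fitness, max(cost, cost_floor)


def pheromone_intensity(s: int, params: HACOParams) -> float:
    """Piecewise-constant deposit intensity P(s): P1 up to S1, P2 up to
    S2, P3 up to S3."""
    S1, S2, S3 = params.S1, params.S2, params.S3
    if S1 is None or S2 is None or S3 is None:
        raise ValueError("schedule thresholds unresolved; call resolved()")
    if s < 1 or s > S3:
        raise ValueError(f"iteration {s} outside [1, {S3}]")
    if s <= S1:
        return params.P1
    if s <= S2:
        return params.P2
    return params.P3


def evaporation_rate(
    s: int,
    S: int,
    tau_max: float,
    tau_min: float,
    clamp: bool = True,
) -> float:
    """Linear curve-decay schedule
    rho(s) = [S*(tau_max - tau_min)*s + S*tau_min - tau_max] / (S - 1),
    clamped into (0, 1] by default (the raw line can exceed 1)."""
    if S < 2:
        raise ValueError("S must be >= 2")
    if not (1 <= s <= S):
        raise ValueError("s must satisfy 1 <= s <= S")
    rho = (S * (tau_max - tau_min) * s) / (S - 1) + (S * tau_min - tau_max) / (S - 1)
    if clamp:
        rho = min(max(rho, np.finfo(float).tiny), 1.0)
    return float(rho)


def ant_deposit(solution: AntSolution, s: int, params: HACOParams,
                n_features: Optional[int] = None) -> np.ndarray:
    """Per-edge deposit matrix: P(s) / cost on every edge the ant
    traversed this iteration, 0 elsewhere."""
    if not np.isfinite(solution.cost) or solution.cost <= 0:
        raise ValueError("solution must have positive finite cost")
    return _deposit_matrix(solution.edges(),
                           pheromone_intensity(s, params) / solution.cost,
                           n_features)


def _deposit_matrix(edges, amount, n: Optional[int] = None) -> np.ndarray:
    if n is None:
        n = max(max(j, i) for j, i in edges) + 1
    dep = np.zeros((n, n))
    for j, i in edges:
        dep[j, i] += amount
    return dep


def elite_deposit(best, params: HACOParams, n_features: Optional[int] = None) -> np.ndarray:
    """Elitist reinforcement delta * P / L* on the incumbent best path's
    edges, 0 elsewhere."""
    path = list(best.best_path)
    cost = float(best.best_cost)
    if cost <= 0:
        raise ValueError("best cost must be > 0")
    amount = params.delta * params.elite_constant / cost
    edges = list(zip(path[:-1], path[1:]))
    return _deposit_matrix(edges, amount, n_features)


def update_pheromone(
    state: PheromoneState,
    ant_deposits: np.ndarray,
    elite_deposits: np.ndarray,
    rho: float,
    params: HACOParams,
) -> PheromoneState:
    """tau(s+1) = rho * tau(s) + sum-of-ant-deposits + elite deposit,
    clamped to [tau_min, tau_max]; increments the iteration counter."""
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"evaporation rate {rho} outside (0, 1]")
    if np.any(ant_deposits < 0) or np.any(elite_deposits < 0):
        raise ValueError("deposits must be nonnegative")
    tau = rho * state.tau + ant_deposits + elite_deposits
    np.clip(tau, params.tau_min, params.tau_max, out=tau)
    state.tau = tau
    state.s += 1
    return state


def boundary_mutation(
    solution: AntSolution,
    state: PheromoneState,
    params: HACOParams,
    rng: np.random.Generator,
    counts_were_updated: bool = True,
) -> AntSolution:
    """With probability ``mutation_rate``, swap one selected feature whose
    per-node pheromone marginal lies inside the central symmetric band for
    a uniformly chosen unselected feature. Taboo set and traversal counts
    stay consistent with the mutated path."""
    if rng.random() >= params.mutation_rate:
        return solution
    q = params.mutation_band
    lo = params.tau_min + q * (params.tau_max - params.tau_min)
    hi = params.tau_max - q * (params.tau_max - params.tau_min)
    node = state.node_pheromone()
    eligible = [k for k, f in enumerate(solution.path) if lo <= node[f] <= hi]
    if not eligible:
        return solution
    unselected = [f for f in range(state.n_features) if f not in solution.taboo]
    if not unselected:
        return solution
    k = int(rng.choice(eligible))
    new_f = int(rng.choice(unselected))
    old_f = solution.path[k]
    old_edges = solution.edges()
    solution.path[k] = new_f
    solution.taboo.discard(old_f)
    solution.taboo.add(new_f)
    if counts_were_updated:
        for j, i in old_edges:
            state.traversal_counts[j, i] -= 1
        for j, i in solution.edges():
            state.traversal_counts[j, i] += 1
    return solution


def init_state(X: np.ndarray, y: np.ndarray, params: HACOParams) -> PheromoneState:
    """Fresh state: pheromone at tau_max on every edge (max-min ant-system
    convention), heuristic scores from the data, zero traversal counts."""
    n = X.shape[1]
    eta = heuristic_scores(X, y)
    return PheromoneState(
        tau=np.full((n, n), params.tau_max),
        eta=eta,
        eta_max=float(eta.max()),
        traversal_counts=np.zeros((n, n)),
        s=1,
    )


def run_haco(X: np.ndarray, y: np.ndarray, params: HACOParams) -> HACOResult:
    """Full HACO loop: construct -> mutate -> evaluate -> deposit ->
    update for ``max_iterations`` iterations; returns the best-ever
    subset. Fully reproducible under the seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = params.resolved(X.shape[1])
    state = init_state(X, y, p)
    rng = np.random.default_rng(p.seed)
    n = state.n_features
    S = p.max_iterations
    best: Optional[AntSolution] = None
    history: list = []
    cache: dict = {}
    for s in range(1, S + 1):
        state.s = s
        if p.constant_rho is not None:
            rho = p.constant_rho
        elif S < 2:
            # Eq-style schedule undefined for a single iteration; use its
            # s = 1 algebraic value (tau_max) clamped into (0, 1]
            rho = min(max(p.tau_max, np.finfo(float).tiny), 1.0)
        else:
            rho = evaporation_rate(s, S, p.tau_max, p.tau_min,
                                   clamp=p.clamp_evaporation)
        Ps = pheromone_intensity(s, p)
        ant_dep = np.zeros((n, n))
        for _ in range(p.n_ants):
            sol = construct_solution(state, p, rng)
            sol = boundary_mutation(sol, state, p, rng)
            key = frozenset(sol.path)
            if key in cache:
                sol.fitness, sol.cost = cache[key]
            else:
                sol.fitness, sol.cost = evaluate_fitness(
                    sol.path, X, y,
                    cv_folds=p.cv_folds,
                    lambda_size=p.lambda_size,
                    cost_floor=p.cost_floor,
                    seed=p.seed,
                )
                cache[key] = (sol.fitness, sol.cost)
            if not np.isfinite(sol.fitness):
                raise RuntimeError(
                    f"non-finite fitness for path {sol.path}")
            for j, i in sol.edges():
                ant_dep[j, i] += Ps / sol.cost
            if best is None or sol.fitness > best.fitness:
                best = AntSolution(list(sol.path), set(sol.taboo),
                                   sol.fitness, sol.cost)
        incumbent = HACOResult(best.path, best.fitness, best.cost, [], s)
        elite = elite_deposit(incumbent, p, n_features=n)
        update_pheromone(state, ant_dep, elite, rho, p)
        history.append({
            "iteration": s,
            "best_fitness": float(best.fitness),
            "mean_pheromone": float(state.tau.mean()),
        })
    return HACOResult(
        best_path=list(best.path),
        best_fitness=float(best.fitness),
        best_cost=float(best.cost),
        history=history,
        iterations_run=S,
    )


class HACOSelector:
    """scikit-learn style wrapper feature selector driven by the HACO
    engine; ``fit`` runs the optimization, ``transform`` keeps the
    selected columns."""

    def __init__(self, n_ants=20, max_iterations=30, alpha=1.0, beta=2.0,
                 delta=1.0, subset_size=None, mutation_rate=0.1,
                 cv_folds=3, seed=0, **extra):
        self.n_ants = n_ants
        self.max_iterations = max_iterations
        self.alpha = alpha
        self.beta = beta
        self.delta = delta
        self.subset_size = subset_size
        self.mutation_rate = mutation_rate
        self.cv_folds = cv_folds
        self.seed = seed
        self.extra = extra

    def _params(self) -> HACOParams:
        return HACOParams(
            n_ants=self.n_ants, max_iterations=self.max_iterations,
            alpha=self.alpha, beta=self.beta, delta=self.delta,
            subset_size=self.subset_size, mutation_rate=self.mutation_rate,
            cv_folds=self.cv_folds, seed=self.seed, **self.extra)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.result_ = run_haco(X, y, self._params())
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.result_.best_path] = True
        self.support_ = mask
        return self

    def get_support(self, indices: bool = False):
        if not hasattr(self, "support_"):
            raise RuntimeError("HACOSelector is not fitted")
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.get_support()]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        out = {
            "n_ants": self.n_ants, "max_iterations": self.max_iterations,
            "alpha": self.alpha, "beta": self.beta, "delta": self.delta,
            "subset_size": self.subset_size,
            "mutation_rate": self.mutation_rate,
            "cv_folds": self.cv_folds, "seed": self.seed,
        }
        out.update(self.extra)
        return out

    def set_params(self, **params):
        for k, v in params.items():
            if hasattr(self, k):
                setattr(self, k, v)
            else:
                self.extra[k] = v
        return self
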