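"""HACO engine: transition law, adaptive factor, pheromone schedules,
deposits, mutation, and the full optimization loop."""

import numpy as np
import pytest

from dtiforest.ants import (AntSolution, HACOParams, HACOResult,
                            HACOSelector, adaptive_factor, ant_deposit,
                            boundary_mutation, construct_solution,
                            elite_deposit, evaluate_fitness,
                            evaporation_rate, heuristic_scores, init_state,
                            pheromone_intensity, run_haco,
                            start_probabilities, transition_probabilities,
                            update_pheromone)
from dtiforest.synthetic import TableSpec, generate_feature_table


def _state(n=3, tau=None, eta=None, counts=None, s=1):
    from dtiforest.ants import PheromoneState
    tau = np.full((n, n), 1.0) if tau is None else np.asarray(tau, float)
    eta = np.ones(n) if eta is None else np.asarray(eta, float)
    counts = np.zeros((n, n)) if counts is None else np.asarray(counts, float)
    return PheromoneState(tau=tau, eta=eta, eta_max=float(eta.max()),
                          traversal_counts=counts, s=s)


def _params(**kw):
    base = dict(n_ants=5, max_iterations=10, subset_size=2, seed=0)
    base.update(kw)
    return HACOParams(**base).resolved(n_features=kw.pop("nf", 10))


class TestTransition:
    def test_symmetric_case(self):
        state = _state(3)
        p = transition_probabilities(state, 0, [1, 2], _params())
        assert p[1] == pytest.approx(0.5) and p[2] == pytest.approx(0.5)
        assert p[0] == 0.0

    def test_zero_exponents_uniform(self):
        state = _state(4, tau=np.random.default_rng(0).random((4, 4)) + 0.5,
                       eta=[0.2, 0.4, 0.9, 1.0])
        p = transition_probabilities(
            state, 0, [1, 2, 3], _params(alpha=0.0, beta=0.0))
        assert np.allclose(p[[1, 2, 3]], 1 / 3)

    def test_direct_evaluation(self):
        tau = np.ones((3, 3))
        tau[0, 1], tau[0, 2] = 2.0, 1.0
        state = _state(3, tau=tau)
        p = transition_probabilities(
            state, 0, [1, 2], _params(alpha=1.0, beta=1.0))
        assert p[1] == pytest.approx(2 / 3)
        assert p[2] == pytest.approx(1 / 3)

    def test_normalization_and_support(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 6
            state = _state(n, tau=rng.random((n, n)) * 0.9 + 0.1,
                           eta=rng.random(n) + 0.1,
                           counts=rng.integers(0, 30, (n, n)))
            allowed = sorted(rng.choice(n, size=3, replace=False).tolist())
            p = transition_probabilities(state, 0, allowed,
                                         _params(alpha=1.3, beta=2.0))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            off = [i for i in range(n) if i not in allowed]
            assert np.all(p[off] == 0.0)

    def test_empty_allowed_raises(self):
        with pytest.raises(ValueError, match="admissible"):
            transition_probabilities(_state(3), 0, [], _params())


class TestAdaptiveFactor:
    def test_no_traversals_gives_one(self):
        assert adaptive_factor(5, 3, 0.0, 1.0, 1.0, 1.0) == 1.0

    def test_stated_point(self):
        assert adaptive_factor(10, 1, 10.0, 1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_monotone_decreasing_in_traversals(self):
        vals = [adaptive_factor(10, 2, pd, 0.8, 1.0, 1.0)
                for pd in (0, 5, 20, 100)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_zero_eta_max_rejected(self):
        with pytest.raises(ValueError):
            adaptive_factor(5, 1, 1.0, 1.0, 0.0, 1.0)


class TestSchedules:
    def test_intensity_boundaries(self):
        p = _params(max_iterations=30, S1=10, S2=20, S3=30,
                    P1=1.0, P2=0.5, P3=0.25)
        assert pheromone_intensity(10, p) == 1.0
        assert pheromone_intensity(11, p) == 0.5
        assert pheromone_intensity(20, p) == 0.5
        assert pheromone_intensity(21, p) == 0.25
        with pytest.raises(ValueError):
            pheromone_intensity(31, p)

    def test_constant_schedule_degenerates(self):
        p = _params(P1=0.7, P2=0.7, P3=0.7)
        for s in range(1, p.max_iterations + 1):
            assert pheromone_intensity(s, p) == 0.7

    def test_evaporation_at_first_iteration_is_tau_max(self):
        assert evaporation_rate(1, 11, 1.0, 0.5, clamp=False) == pytest.approx(1.0)
        assert evaporation_rate(1, 7, 0.8, 0.2, clamp=False) == pytest.approx(0.8)

    def test_evaporation_strictly_increasing(self):
        vals = [evaporation_rate(s, 10, 1.0, 0.1, clamp=False)
                for s in range(1, 11)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_clamp_into_unit_interval(self):
        for s in range(1, 11):
            assert 0 < evaporation_rate(s, 10, 1.0, 0.1) <= 1.0

    def test_short_run_rejected(self):
        with pytest.raises(ValueError):
            evaporation_rate(1, 1, 1.0, 0.1)


class TestDeposits:
    def test_ant_deposit_arithmetic(self):
        sol = AntSolution(path=[0, 2, 1], taboo={0, 1, 2},
                          fitness=0.9, cost=4.0)
        p = _params(P1=2.0, P2=2.0, P3=2.0)
        dep = ant_deposit(sol, 1, p, n_features=3)
        assert dep[0, 2] == pytest.approx(0.5)
        assert dep[2, 1] == pytest.approx(0.5)
        assert dep[1, 0] == 0.0  # edge not in path

    def test_better_solution_deposits_more(self):
        p = _params(P1=1.0, P2=1.0, P3=1.0)
        good = AntSolution([0, 1], {0, 1}, 0.95, 0.1)
        bad = AntSolution([0, 1], {0, 1}, 0.60, 0.5)
        assert ant_deposit(good, 1, p, 2)[0, 1] > ant_deposit(bad, 1, p, 2)[0, 1]

    def test_elite_deposit(self):
        best = HACOResult([0, 1], 0.9, 0.5, [], 1)
        p = _params(delta=1.0, elite_constant=1.0)
        dep = elite_deposit(best, p, n_features=3)
        assert dep[0, 1] == pytest.approx(2.0)
        assert dep[1, 2] == 0.0

    def test_elite_vanishes_at_zero_delta(self):
        best = HACOResult([0, 1], 0.9, 0.5, [], 1)
        dep = elite_deposit(best, _params(delta=0.0), n_features=3)
        assert np.all(dep == 0.0)


class TestUpdate:
    def test_decay_only(self):
        state = _state(2, tau=np.full((2, 2), 0.8))
        p = _params(tau_min=0.1, tau_max=1.0)
        update_pheromone(state, np.zeros((2, 2)), np.zeros((2, 2)), 0.5, p)
        assert np.allclose(state.tau, 0.4)
        assert state.s == 2

    def test_additive_no_decay(self):
        state = _state(2, tau=np.full((2, 2), 0.5))
        dep = np.zeros((2, 2))
        dep[0, 1] = 0.2
        p = _params(tau_min=0.1, tau_max=1.0)
        update_pheromone(state, dep, np.zeros((2, 2)), 1.0, p)
        assert state.tau[0, 1] == pytest.approx(0.7)
        assert state.tau[1, 0] == pytest.approx(0.5)

    def test_direct_evaluation_with_bounds(self):
        state = _state(1, tau=np.array([[0.8]]))
        p = _params(tau_min=0.1, tau_max=1.0)
        update_pheromone(state, np.array([[0.1]]), np.array([[0.2]]), 0.5, p)
        assert state.tau[0, 0] == pytest.approx(0.7)

    def test_bounds_enforced(self):
        state = _state(2, tau=np.full((2, 2), 0.9))
        p = _params(tau_min=0.1, tau_max=1.0)
        update_pheromone(state, np.full((2, 2), 5.0), np.zeros((2, 2)), 1.0, p)
        assert np.all(state.tau == 1.0)
        update_pheromone(state, np.zeros((2, 2)), np.zeros((2, 2)), 1e-300, p)
        # rho outside (0,1] rejected
        with pytest.raises(ValueError):
            update_pheromone(state, np.zeros((2, 2)), np.zeros((2, 2)), 1.5, p)

    def test_negative_deposits_rejected(self):
        state = _state(2)
        with pytest.raises(ValueError):
            update_pheromone(state, np.full((2, 2), -0.1),
                             np.zeros((2, 2)), 0.5, _params())


class TestConstruction:
    def test_exhaustive_path_is_permutation(self):
        state = _state(4)
        p = _params(subset_size=4)
        sol = construct_solution(state, p, np.random.default_rng(0))
        assert sorted(sol.path) == [0, 1, 2, 3]
        assert sol.taboo == set(sol.path)

    def test_seeded_determinism(self):
        state1, state2 = _state(6), _state(6)
        p = _params(subset_size=3)
        s1 = construct_solution(state1, p, np.random.default_rng(42))
        s2 = construct_solution(state2, p, np.random.default_rng(42))
        assert s1.path == s2.path

    def test_concentrated_pheromone_dominates(self):
        n = 4
        tau = np.full((n, n), 0.1)
        tau[:, 1] = 1.0  # feature 1 strongly marked
        state = _state(n, tau=tau)
        p = _params(subset_size=2, alpha=6.0, beta=0.0, delta=0.0)
        hits = 0
        rng = np.random.default_rng(7)
        for _ in range(1000):
            sol = construct_solution(state, p, rng, update_counts=False)
            hits += 1 in sol.path
        assert hits / 1000 > 0.95

    def test_counts_accumulate(self):
        state = _state(5)
        p = _params(subset_size=3)
        rng = np.random.default_rng(1)
        construct_solution(state, p, rng)
        assert state.traversal_counts.sum() == 2  # K-1 edges
        construct_solution(state, p, rng)
        assert state.traversal_counts.sum() == 4


class TestFitness:
    def test_separable_feature_perfect(self, separable_xy):
        X, y = separable_xy
        fitness, cost = evaluate_fitness([2], X, y, cv_folds=3, seed=0)
        assert fitness == 1.0
        assert cost == pytest.approx(0.01 * 1 / 4, abs=1e-9)

    def test_noise_features_chance_level(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((600, 5))
            y = np.repeat([0, 1], 300)
            f, _ = evaluate_fitness([0, 1, 2], X, y, seed=seed)
            accs.append(f)
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_deterministic(self, separable_xy):
        X, y = separable_xy
        a = evaluate_fitness([0, 2], X, y, seed=3)
        b = evaluate_fitness([0, 2], X, y, seed=3)
        assert a == b


class TestMutation:
    def test_rate_zero_identity(self, separable_xy):
        state = _state(6)
        sol = AntSolution([0, 1, 2], {0, 1, 2})
        p = _params(subset_size=3, mutation_rate=0.0)
        out = boundary_mutation(sol, state, p, np.random.default_rng(0))
        assert out.path == [0, 1, 2]

    def test_mutated_path_stays_valid(self):
        rng = np.random.default_rng(5)
        p = _params(subset_size=3, mutation_rate=1.0)
        for _ in range(50):
            state = _state(8, tau=np.full((8, 8), 0.55))
            sol = AntSolution([0, 1, 2], {0, 1, 2})
            out = boundary_mutation(sol, state, p, rng)
            assert len(set(out.path)) == 3
            assert out.taboo == set(out.path)

    def test_empirical_mutation_rate(self):
        rng = np.random.default_rng(11)
        p = _params(subset_size=3, mutation_rate=0.3)
        mutated = 0
        for _ in range(1000):
            state = _state(8, tau=np.full((8, 8), 0.55))
            sol = AntSolution([0, 1, 2], {0, 1, 2})
            out = boundary_mutation(sol, state, p, rng)
            mutated += out.path != [0, 1, 2]
        assert abs(mutated / 1000 - 0.3) < 0.05

    def test_band_excludes_extreme_pheromone(self):
        # all selected features sit at tau_max: outside the central band
        state = _state(6, tau=np.full((6, 6), 1.0))
        sol = AntSolution([0, 1, 2], {0, 1, 2})
        p = _params(subset_size=3, mutation_rate=1.0)
        out = boundary_mutation(sol, state, p, np.random.default_rng(0))
        assert out.path == [0, 1, 2]


class TestRunHaco:
    def test_single_ant_single_iteration(self, separable_xy):
        X, y = separable_xy
        res = run_haco(X, y, HACOParams(n_ants=1, max_iterations=1,
                                        subset_size=2, seed=0))
        assert len(res.history) == 1
        assert res.iterations_run == 1
        assert res.best_fitness == res.history[0]["best_fitness"]

    def test_seeded_reproducibility(self, separable_xy):
        X, y = separable_xy
        p = HACOParams(n_ants=4, max_iterations=5, subset_size=2, seed=9)
        r1 = run_haco(X, y, p)
        r2 = run_haco(X, y, p)
        assert r1.to_dict() == r2.to_dict()

    def test_elitist_history_nondecreasing(self, separable_xy):
        X, y = separable_xy
        res = run_haco(X, y, HACOParams(n_ants=4, max_iterations=8,
                                        subset_size=2, seed=2))
        fits = [h["best_fitness"] for h in res.history]
        assert all(a <= b for a, b in zip(fits, fits[1:]))

    def test_pheromone_bounds_all_iterations(self, separable_xy):
        X, y = separable_xy
        p = HACOParams(n_ants=3, max_iterations=6, subset_size=2,
                       seed=1).resolved(X.shape[1])
        state = init_state(X, y, p)
        rng = np.random.default_rng(p.seed)
        for s in range(1, 7):
            state.s = s
            sol = construct_solution(state, p, rng)
            sol.fitness, sol.cost = evaluate_fitness(sol.path, X, y, seed=1)
            dep = ant_deposit(sol, s, p, state.n_features)
            rho = evaporation_rate(s, 6, p.tau_max, p.tau_min)
            update_pheromone(state, dep, np.zeros_like(dep), rho, p)
            assert np.all(state.tau >= p.tau_min - 1e-12)
            assert np.all(state.tau <= p.tau_max + 1e-12)

    def test_selector_estimator(self, small_table):
        X, y, informative = small_table
        sel = HACOSelector(n_ants=8, max_iterations=8, subset_size=8, seed=0)
        Xt = sel.fit_transform(X, y)
        assert Xt.shape == (X.shape[0], 8)
        assert sel.get_support().sum() == 8

    def test_oversized_subset_rejected(self, separable_xy):
        X, y = separable_xy
        with pytest.raises(ValueError):
            run_haco(X, y, HACOParams(subset_size=99))


def test_heuristic_scores_identify_signal(small_table):
    X, y, informative = small_table
    eta = heuristic_scores(X, y)
    assert eta.max() == 1.0
    top5 = set(np.argsort(eta)[-5:].tolist())
    assert len(top5 & set(informative.tolist())) >= 4
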