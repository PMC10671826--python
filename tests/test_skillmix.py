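import itertools

import numpy as np
import pytest
from scipy import integrate, optimize
from scipy.stats import norm

from hhcteams.skillmix import (InfeasibleError, SkillMixProblem,
                               expected_excess_normal, ratio_curve,
                               shortfall_probability,
                               solve_unconstrained,
                               solve_with_min_contract)


class TestExpectedExcessNormal:
    def test_symmetric_point(self):
        assert expected_excess_normal(50.0, 50.0, 10.0) == pytest.approx(
            10.0 / np.sqrt(2 * np.pi))

    def test_two_sigma_point_from_normal_tables(self):
        got = expected_excess_normal(70.0, 50.0, 10.0)
        assert got == pytest.approx(20 * norm.cdf(2) + 10 * norm.pdf(2))
        assert got == pytest.approx(20.085, abs=0.001)

    @pytest.mark.parametrize("c, mu, sigma", [
        (70.0, 50.0, 10.0), (40.0, 50.0, 10.0), (0.0, 5.0, 3.0),
        (120.0, 100.0, 25.0),
    ])
    def test_matches_numerical_integration(self, c, mu, sigma):
        oracle, _ = integrate.quad(
            lambda y: (c - y) * norm.pdf(y, mu, sigma),
            mu - 12 * sigma, c)
        assert expected_excess_normal(c, mu, sigma) == pytest.approx(
            oracle, abs=1e-8)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(42)
        c, mu, sigma = 110.0, 100.0, 20.0
        draws = rng.normal(mu, sigma, 1_000_000)
        mc = np.clip(c - draws, 0, None)
        se = mc.std() / 1000.0
        assert abs(expected_excess_normal(c, mu, sigma) - mc.mean()) \
            < 3 * se

    def test_degenerate_sigma(self):
        assert expected_excess_normal(7.0, 5.0, 0.0) == 2.0
        assert expected_excess_normal(3.0, 5.0, 0.0) == 0.0


class TestUnconstrainedRecursion:
    def test_single_level_takes_full_safety_capacity(self):
        p = SkillMixProblem(mu=(100.0,), sigma=(20.0,), eta_alpha=2.0)
        sol = solve_unconstrained(p)
        assert sol.capacity[0] == pytest.approx(140.0)

    def test_two_level_hand_computation(self):
        # top level: C2 = 50 + 2*10 = 70; excess to level 1 is the normal
        # loss at two sigma, 20.085; C1 = 100 + 2*20 - 20.085
        p = SkillMixProblem(mu=(100.0, 50.0), sigma=(20.0, 10.0),
                            eta_alpha=2.0)
        sol = solve_unconstrained(p)
        assert sol.capacity[1] == pytest.approx(70.0)
        assert sol.excess[0] == pytest.approx(20.085, abs=0.001)
        assert sol.capacity[0] == pytest.approx(119.915, abs=0.001)

    def test_substitution_never_dearer_than_no_substitution(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = int(rng.integers(1, 5))
            p = SkillMixProblem(
                mu=tuple(rng.uniform(5, 200, k)),
                sigma=tuple(rng.uniform(1, 40, k)),
                eta_alpha=float(rng.uniform(0.5, 3.0)))
            sol = solve_unconstrained(p)
            standalone = np.array(p.mu) + p.eta_alpha * np.array(p.sigma)
            assert sol.total_cost <= float(
                np.dot(p.cost, standalone)) + 1e-9

    def test_constraints_hold_with_equality_where_capacity_positive(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            k = int(rng.integers(1, 5))
            p = SkillMixProblem(mu=tuple(rng.uniform(5, 200, k)),
                                sigma=tuple(rng.uniform(1, 40, k)))
            sol = solve_unconstrained(p)
            for j in range(k):
                slack = (sol.capacity[j] + sol.excess[j]
                         - p.mu[j] - p.eta_alpha * p.sigma[j])
                assert slack >= -1e-9
                if sol.capacity[j] > 1e-9:
                    assert slack == pytest.approx(0.0, abs=1e-9)


def _oracle_min_cost(problem):
    """Independent brute force: enumerate support patterns; optimize each
    pattern's active capacities with SLSQP under the excess-chain
    constraints (multi-start)."""
    k = problem.n_levels
    req = np.array(problem.mu) + problem.eta_alpha * np.array(problem.sigma)

    def chain_excess(cap):
        e = np.zeros(k)
        for j in range(k - 1, 0, -1):
            e[j - 1] = expected_excess_normal(
                cap[j] + e[j], problem.mu[j], problem.sigma[j])
        return e

    best = np.inf
    for pattern in itertools.product([0, 1], repeat=k):
        active = [j for j in range(k) if pattern[j]]
        if not active:
            if np.all(req <= 0):
                best = min(best, 0.0)
            continue

        def expand(x):
            cap = np.zeros(k)
            cap[active] = x
            return cap

        cons = [{"type": "ineq",
                 "fun": (lambda x, j=j: (expand(x)[j]
                                         + chain_excess(expand(x))[j]
                                         - req[j]))}
                for j in range(k)]
        bounds = [(problem.min_contract, None)] * len(active)
        for start_scale in (1.0, 2.0, 5.0):
            x0 = np.maximum(req[active], problem.min_contract) * start_scale
            res = optimize.minimize(
                lambda x: float(np.dot(np.array(problem.cost)[active], x)),
                x0, method="SLSQP", bounds=bounds, constraints=cons,
                options={"maxiter": 400, "ftol": 1e-12})
            if res.success and all(c["fun"](res.x) >= -1e-6 for c in cons):
                best = min(best, float(res.fun))
    return best


class TestMinContractSolver:
    def test_reduces_to_recursion_without_minimum(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(1, 4))
            p = SkillMixProblem(mu=tuple(rng.uniform(5, 200, k)),
                                sigma=tuple(rng.uniform(1, 40, k)))
            a = solve_unconstrained(p)
            b = solve_with_min_contract(p)
            assert np.allclose(a.capacity, b.capacity)

    def test_binding_lower_bound_single_level(self):
        p = SkillMixProblem(mu=(10.0,), sigma=(2.0,), min_contract=50.0)
        sol = solve_with_min_contract(p)
        assert sol.capacity[0] == pytest.approx(50.0)

    def test_small_capacity_level_dropped_or_lifted_optimally(self):
        # unconstrained C1 falls in (0, min_contract): the solver must pick
        # the cheaper of C1 = min_contract and C1 = 0 with extra top-level
        # capacity
        p = SkillMixProblem(mu=(60.0, 100.0), sigma=(5.0, 20.0),
                            cost=(1.0, 1.4), min_contract=60.0)
        unconstrained = solve_unconstrained(
            SkillMixProblem(mu=p.mu, sigma=p.sigma, cost=p.cost))
        assert 0 < unconstrained.capacity[0] < 60.0
        sol = solve_with_min_contract(p)
        assert sol.capacity[0] == pytest.approx(60.0) \
            or sol.capacity[0] == 0.0
        assert sol.total_cost == pytest.approx(_oracle_min_cost(p),
                                               rel=1e-5)

    def test_matches_exhaustive_pattern_search_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(12):
            k = int(rng.integers(1, 4))
            p = SkillMixProblem(
                mu=tuple(rng.uniform(10, 150, k)),
                sigma=tuple(rng.uniform(2, 30, k)),
                cost=tuple(np.sort(rng.uniform(1, 3, k))),
                min_contract=float(rng.uniform(0.0, 80.0)),
                eta_alpha=2.0)
            sol = solve_with_min_contract(p)
            oracle = _oracle_min_cost(p)
            assert sol.total_cost <= oracle * (1 + 1e-5) + 1e-6

    def test_solution_respects_contract_and_coverage(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            k = int(rng.integers(1, 4))
            p = SkillMixProblem(
                mu=tuple(rng.uniform(10, 150, k)),
                sigma=tuple(rng.uniform(2, 30, k)),
                min_contract=float(rng.uniform(0.0, 80.0)))
            sol = solve_with_min_contract(p)
            for j in range(k):
                c = sol.capacity[j]
                assert c == 0.0 or c >= p.min_contract - 1e-6
                assert c + sol.excess[j] >= (
                    p.mu[j] + p.eta_alpha * p.sigma[j] - 1e-6)


class TestShortfall:
    def test_bounded_by_alpha_at_every_level(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            k = int(rng.integers(1, 5))
            p = SkillMixProblem(mu=tuple(rng.uniform(5, 200, k)),
                                sigma=tuple(rng.uniform(1, 40, k)),
                                eta_alpha=2.0)
            sol = solve_unconstrained(p)
            for level in range(1, k + 1):
                assert shortfall_probability(sol, p, level) \
                    <= 1 - norm.cdf(2.0) + 1e-12

    def test_top_level_exactly_at_alpha(self):
        p = SkillMixProblem(mu=(80.0, 40.0), sigma=(15.0, 8.0),
                            eta_alpha=2.0)
        sol = solve_unconstrained(p)
        assert shortfall_probability(sol, p, 2) == pytest.approx(
            1 - norm.cdf(2.0))

    def test_monte_carlo_shortfall_frequency(self):
        p = SkillMixProblem(mu=(100.0, 50.0), sigma=(20.0, 10.0),
                            eta_alpha=1.0)
        sol = solve_unconstrained(p)
        rng = np.random.default_rng(77)
        n = 200_000
        for level in (1, 2):
            draws = rng.normal(p.mu[level - 1], p.sigma[level - 1], n)
            thresh = sol.capacity[level - 1] + sol.excess[level - 1]
            freq = float(np.mean(draws > thresh))
            prob = shortfall_probability(sol, p, level)
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(freq - prob) < 3 * se + 1e-12


class TestRatioCurve:
    def test_converges_to_demand_ratios(self):
        p = SkillMixProblem(mu=(67.0, 9.0, 24.0), sigma=(12.0, 4.0, 8.0))
        ratios = ratio_curve(p, [1e4])[0]
        demand = np.array(p.mu) / np.sum(p.mu)
        assert np.max(np.abs(ratios - demand)) < 0.01

    def test_single_level_always_unit_ratio(self):
        p = SkillMixProblem(mu=(50.0,), sigma=(10.0,))
        ratios = ratio_curve(p, [0.1, 1.0, 10.0, 100.0])
        assert np.allclose(ratios, 1.0)

    def test_top_level_overweighted_at_small_scale(self):
        # equal demand in all three levels: at small scale the top level's
        # capacity share strictly exceeds its demand share 1/3
        p = SkillMixProblem(mu=(50.0, 50.0, 50.0),
                            sigma=(15.0, 15.0, 15.0))
        ratios = ratio_curve(p, [0.2])[0]
        assert ratios[2] > 1.0 / 3.0 + 0.01

    def test_top_level_capacity_scales_to_its_load(self):
        p = SkillMixProblem(mu=(60.0, 30.0), sigma=(12.0, 6.0))
        m = 1e4
        sol = solve_with_min_contract(p.scaled(m))
        assert sol.capacity[1] / (m * p.mu[1]) == pytest.approx(1.0,
                                                                abs=0.01)
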