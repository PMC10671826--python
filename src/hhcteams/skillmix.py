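"""Capacity per qualification level under hierarchical substitution.

Qualification levels (QLs) ``1..K`` are ordered so that capacity of level
``k`` may also serve any level ``j <= k``. Weekly demand per level is
normal, ``N_k ~ Normal(mu_k, sigma_k^2)``; capacities ``C_k`` cost ``w_k``
per hour (non-decreasing in k) and must satisfy

    C_k + e_k >= mu_k + eta_alpha * sigma_k        for every k,

where ``e_K = 0`` and ``e_{k-1} = E(C_k + e_k - N_k)^+`` is the expected
excess trickling down from the levels above, computed with the normal loss
function. ``eta_alpha`` bounds the shortfall probability at each level by
``1 - Phi(eta_alpha)``.

Without a minimum contract size (``min_contract = 0``) the optimum is the
backward recursion ``C_k = max(0, mu_k + eta_alpha sigma_k - e_k)`` from
the top level down. With a minimum contract, each used level must deploy at
least ``min_contract`` hours; the solver enumerates the support patterns
(which levels are used) and, where a skipped level's requirement is not met
by the excess from above, lifts the cheapest active higher level by the
smallest sufficient amount (a monotone one-dimensional root find).

A structural consequence: the top level always carries full safety capacity
``C_K = mu_K + eta_alpha sigma_K``, so small teams are top-heavy, while the
optimal capacity ratios converge to the demand ratios as the demand scale
grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

_MAX_LEVELS = 10


@dataclass(frozen=True)
class SkillMixProblem:
    """Per-level demand moments, costs, minimum contract and safety factor.

    ``mu``/``sigma`` are hours per week; ``cost`` per capacity hour must be
    non-decreasing in the level; ``eta_alpha = Phi^{-1}(1 - alpha)`` bounds
    the per-level shortfall probability at ``alpha``.
    """

    mu: tuple[float, ...]
    sigma: tuple[float, ...]
    cost: tuple[float, ...] | None = None
    min_contract: float = 0.0
    eta_alpha: float = 2.0

    def __post_init__(self) -> None:
        k = len(self.mu)
        if k == 0 or k > _MAX_LEVELS:
            raise ValueError(f"need 1..{_MAX_LEVELS} levels")
        if len(self.sigma) != k:
            raise ValueError("mu and sigma lengths differ")
        if any(m < 0 for m in self.mu) or any(s < 0 for s in self.sigma):
            raise ValueError("mu and sigma must be non-negative")
        if self.cost is None:
            object.__setattr__(self, "cost",
                               tuple(float(j + 1) for j in range(k)))
        if len(self.cost) != k:
            raise ValueError("cost length differs from mu")
        if any(self.cost[j] > self.cost[j + 1] for j in range(k - 1)):
            raise ValueError("costs must be non-decreasing in level")
        if self.min_contract < 0 or self.eta_alpha < 0:
            raise ValueError("min_contract and eta_alpha must be >= 0")

    @property
    def n_levels(self) -> int:
        return len(self.mu)

    def scaled(self, m: float) -> "SkillMixProblem":
        """The problem at demand scale ``m``: arrival rate scaling sends
        ``mu -> m mu`` and ``sigma -> sqrt(m) sigma``."""
        return SkillMixProblem(
            mu=tuple(m * x for x in self.mu),
            sigma=tuple(np.sqrt(m) * s for s in self.sigma),
            cost=self.cost, min_contract=self.min_contract,
            eta_alpha=self.eta_alpha)


@dataclass(frozen=True)
class SkillMixSolution:
    """Capacities ``C_k``, excess-from-above ``e_k`` (``e_K = 0``), total
    cost, and capacity ratios ``C_k / sum_j C_j``."""

    capacity: tuple[float, ...]
    excess: tuple[float, ...]
    total_cost: float

    @property
    def ratios(self) -> np.ndarray:
        c = np.asarray(self.capacity)
        return c / c.sum()


class InfeasibleError(ValueError):
    """No support pattern satisfies the constraints."""


def expected_excess_normal(c: float, mu: float, sigma: float) -> float:
    """Normal loss function ``E(C - Y)^+`` for ``Y ~ Normal(mu, sigma^2)``:
    ``(C - mu) Phi(x) + sigma phi(x)`` with ``x = (C - mu)/sigma``.

    Degenerate ``sigma = 0`` returns ``max(C - mu, 0)``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return max(c - mu, 0.0)
    x = (c - mu) / sigma
    return float((c - mu) * norm.cdf(x) + sigma * norm.pdf(x))


def _chain(problem: SkillMixProblem, capacity: np.ndarray) -> np.ndarray:
    """Excess available to each level for given capacities: ``e[K-1] = 0``
    and ``e[k-1] = E(C_k + e_k - N_k)^+`` going down (0-based arrays)."""
    k = problem.n_levels
    e = np.zeros(k)
    for j in range(k - 1, 0, -1):
        e[j - 1] = expected_excess_normal(capacity[j] + e[j],
                                          problem.mu[j], problem.sigma[j])
    return e


def solve_unconstrained(problem: SkillMixProblem) -> SkillMixSolution:
    """Closed-form optimum for ``min_contract = 0``: backward recursion
    ``C_k = max(0, mu_k + eta_alpha sigma_k - e_k)`` from the top level.

    Because higher levels are never cheaper, it is optimal to hold every
    constraint at its lower bound; each level's requirement is met exactly
    wherever its own capacity is positive.
    """
    if problem.min_contract != 0:
        raise ValueError("use solve_with_min_contract for min_contract > 0")
    k = problem.n_levels
    cap = np.zeros(k)
    e = 0.0
    excess = np.zeros(k)
    for j in range(k - 1, -1, -1):
        excess[j] = e
        req = problem.mu[j] + problem.eta_alpha * problem.sigma[j]
        cap[j] = max(0.0, req - e)
        if j > 0:
            e = expected_excess_normal(cap[j] + e, problem.mu[j],
                                       problem.sigma[j])
    cost = float(np.dot(problem.cost, cap))
    return SkillMixSolution(tuple(cap), tuple(excess), cost)


def _solve_pattern(problem: SkillMixProblem,
                   active: Sequence[bool]) -> SkillMixSolution | None:
    """Cheapest feasible capacities for one support pattern, or None.

    Active levels take ``max(min_contract, requirement - excess)``. When a
    skipped level is short, the cheapest active level above it is lifted by
    the smallest amount that closes the gap; the excess chain is monotone
    in any capacity above, so a bracketing root find applies.
    """
    k = problem.n_levels
    ell = problem.min_contract
    req = np.array(problem.mu) + problem.eta_alpha * np.array(problem.sigma)
    base = np.zeros(k)   # capacities before lifts
    lifts = np.zeros(k)  # extra capacity added on active levels

    def build(with_lifts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cap = np.zeros(k)
        e = 0.0
        ex = np.zeros(k)
        for j in range(k - 1, -1, -1):
            ex[j] = e
            if active[j]:
                cap[j] = max(ell, req[j] - e) + with_lifts[j]
            if j > 0:
                e = expected_excess_normal(cap[j] + e, problem.mu[j],
                                           problem.sigma[j])
        return cap, ex

    for j in range(k - 1, -1, -1):
        cap, ex = build(lifts)
        if active[j] or cap[j] + ex[j] >= req[j] - 1e-12:
            continue
        donors = [i for i in range(j + 1, k) if active[i]]
        if not donors:
            return None
        donor = min(donors, key=lambda i: problem.cost[i])

        def gap(delta: float, donor=donor, j=j) -> float:
            trial = lifts.copy()
            trial[donor] += delta
            cap_t, ex_t = build(trial)
            return cap_t[j] + ex_t[j] - req[j]

        hi = max(req[j], 1.0)
        while gap(hi) < 0:
            hi *= 2.0
            if hi > 1e12:
                return None
        delta = optimize.brentq(gap, 0.0, hi, xtol=1e-10, rtol=1e-12)
        lifts[donor] += delta

    cap, ex = build(lifts)
    if np.any(cap + ex < req - 1e-6):
        return None
    if np.any(cap[np.asarray(active, dtype=bool)] < ell - 1e-9):
        return None
    cost = float(np.dot(problem.cost, cap))
    return SkillMixSolution(tuple(cap), tuple(ex), cost)


def solve_with_min_contract(problem: SkillMixProblem) -> SkillMixSolution:
    """Minimize total capacity cost subject to the per-level coverage
    constraints and ``C_k in {0} union [min_contract, inf)``.

    With ``min_contract = 0`` this coincides with the closed-form backward
    recursion. Otherwise all ``2^K`` support patterns are enumerated (K is
    small in practice) and the cheapest feasible one returned.
    """
    if problem.min_contract == 0:
        return solve_unconstrained(problem)
    best: SkillMixSolution | None = None
    for pattern in product([True, False], repeat=problem.n_levels):
        sol = _solve_pattern(problem, pattern)
        if sol is not None and (best is None
                                or sol.total_cost < best.total_cost - 1e-12):
            best = sol
    if best is None:
        raise InfeasibleError("no support pattern satisfies the constraints")
    return best


def shortfall_probability(solution: SkillMixSolution,
                          problem: SkillMixProblem, level: int) -> float:
    """``P(N_k > C_k + e_k) = 1 - Phi((C_k + e_k - mu_k)/sigma_k)`` for the
    1-based ``level``; at most ``1 - Phi(eta_alpha)`` in any feasible
    solution. Degenerate ``sigma_k = 0`` gives 0 or 1 by sign."""
    j = level - 1
    slack = solution.capacity[j] + solution.excess[j] - problem.mu[j]
    if problem.sigma[j] == 0:
        return 0.0 if slack >= 0 else 1.0
    return float(1.0 - norm.cdf(slack / problem.sigma[j]))


def ratio_curve(problem: SkillMixProblem,
                scales: Sequence[float]) -> np.ndarray:
    """Optimal capacity ratios ``C_k / sum_j C_j`` at each demand scale.

    Scaling the arrival rate by ``m`` sends ``mu -> m mu`` and
    ``sigma -> sqrt(m) sigma``; as ``m`` grows the ratios converge to the
    demand ratios ``mu_k / sum mu_j``. Returns an array of shape
    ``(len(scales), K)``.
    """
    if any(m <= 0 for m in scales):
        raise ValueError("scales must be positive")
    rows = [solve_with_min_contract(problem.scaled(m)).ratios
            for m in scales]
    return np.vstack(rows)
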