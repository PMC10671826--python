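"""Team-merging scenario engine.

Merging teams pools their (independent) demand streams: loads add,
variances add, so the pooled peakedness is the load-weighted mean. Each
cluster is scored on four metrics — capacity utilization, availability
``P(P > l)`` of effective capacity, the positive deviation of optimal
skill-mix capacity ratios from demand ratios, and the pairwise interaction
count — combined in the weighted objective

    lambda1 * utilization + lambda3 * availability
    - lambda4 * ql_deviation - lambda6 * interactions,

where ``lambda6`` also rescales the interaction count against the three
fraction-valued terms. Scanning a merge order step by step traces the
economies of scale (first three metrics improve, with diminishing returns)
against the quadratic growth of coordination complexity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from hhcteams.capacity import (AvailabilityModel, interactions_complete,
                               prob_effective_capacity_below)
from hhcteams.demand import (DemandSummary, StaffingPolicy, TeamDemandModel,
                             pool_teams, utilization)
from hhcteams.io import TeamParameters
from hhcteams.skillmix import SkillMixProblem, solve_unconstrained

#: Default split of a team's demand over the three qualification levels
#: (PV niveau 2+, PV niveau 3, VP niveau 3) when per-level case streams are
#: not available: the organization-wide planned-care proportions.
DEFAULT_QL_SHARES = (0.67, 0.09, 0.24)


@dataclass(frozen=True)
class TeamProfile:
    """A team (or merged cluster) entering the scenario analysis.

    ``demand`` may be a full :class:`TeamDemandModel` or a pooled
    ``(rho, z)`` summary; ``per_ql`` optionally carries per-level summaries
    whose loads must add to the total within 1%.
    """

    team_id: str
    demand: TeamDemandModel | DemandSummary
    per_ql: tuple[DemandSummary, ...] | None = None
    location: tuple[float, float] | None = None
    team_size: float | None = None

    def __post_init__(self) -> None:
        if self.per_ql is not None:
            total = sum(s.rho for s in self.per_ql)
            if abs(total - self.summary.rho) > 0.01 * self.summary.rho:
                raise ValueError("per-QL loads do not add to the total")

    @property
    def summary(self) -> DemandSummary:
        d = self.demand
        return d.summary() if isinstance(d, TeamDemandModel) else d

    @classmethod
    def from_team_parameters(cls, tp: TeamParameters,
                             **kwargs) -> "TeamProfile":
        return cls(team_id=tp.team_id,
                   demand=TeamDemandModel.from_team_parameters(tp), **kwargs)


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights of the merging objective and the availability threshold."""

    lambda1: float = 1.0
    lambda3: float = 1.0
    lambda4: float = 1.0
    lambda6: float = 1e-3
    l_threshold: float = 0.6

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda3, self.lambda4, self.lambda6) < 0:
            raise ValueError("weights must be >= 0")
        if not 0 <= self.l_threshold <= 1:
            raise ValueError("l_threshold must be in [0, 1]")


@dataclass(frozen=True)
class ScenarioMetrics:
    """The four per-cluster metrics entering the objective."""

    utilization: float
    availability: float
    ql_deviation: float | None
    interactions: int


def merge_cluster(profiles: Sequence[TeamProfile],
                  hours_per_worker: float = 20.0) -> TeamProfile:
    """Pool a collection of teams into one cluster profile.

    Demand pools by summing loads and variances (total and per level); the
    cluster team size is recomputed from the pooled load. Merging is
    associative: any grouping of the same teams gives the same cluster.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    if len(profiles) == 1:
        return profiles[0]
    pooled = pool_teams([p.summary for p in profiles])
    per_ql = None
    if all(p.per_ql is not None for p in profiles):
        n_levels = {len(p.per_ql) for p in profiles}
        if len(n_levels) == 1:
            per_ql = tuple(
                pool_teams([p.per_ql[j] for p in profiles])
                for j in range(n_levels.pop()))
    return TeamProfile(
        team_id="+".join(p.team_id for p in profiles),
        demand=pooled,
        per_ql=per_ql,
        team_size=team_size_from_demand(pooled.rho, hours_per_worker),
    )


def team_size_from_demand(rho: float,
                          hours_per_worker: float = 20.0) -> int:
    """Workers needed for a load of ``rho`` hours/week at the average
    direct-care time per worker (default 20 h/week): ``ceil(rho / h)``."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    return math.ceil(rho / hours_per_worker)


def _ql_problem(profile: TeamProfile, eta_alpha: float,
                ql_shares: Sequence[float]) -> SkillMixProblem:
    """Per-level normal demand for the skill-mix term.

    Uses the profile's per-level summaries when present (mu_k = rho_k,
    sigma_k = sqrt(z_k rho_k)); otherwise splits the team total by the
    default share vector, keeping the team's peakedness at every level.
    """
    if profile.per_ql is not None:
        mu = tuple(s.rho for s in profile.per_ql)
        sigma = tuple(np.sqrt(s.z * s.rho) for s in profile.per_ql)
    else:
        rho, z = profile.summary
        mu = tuple(w * rho for w in ql_shares)
        sigma = tuple(np.sqrt(z * m) for m in mu)
    return SkillMixProblem(mu=mu, sigma=sigma, eta_alpha=eta_alpha)


def evaluate(profile: TeamProfile,
             policy: StaffingPolicy = StaffingPolicy(),
             p_present: float = 0.79,
             l_threshold: float = 0.6,
             eta_alpha: float = 2.0,
             hours_per_worker: float = 20.0,
             ql_shares: Sequence[float] | None = DEFAULT_QL_SHARES,
             ) -> ScenarioMetrics:
    """Score one team or cluster on the four merging metrics.

    Utilization uses square-root staffing on the pooled ``(rho, z)``;
    availability is ``P(P > l)`` at the demand-implied team size; the QL
    deviation is ``sum_k (C_k/sum C - mu_k/sum mu)^+`` from the optimal
    skill mix (minimum contract 0); interactions are the complete-graph
    count. With neither per-level summaries nor a share vector the QL term
    is reported as None (and later omitted from the objective with a
    warning).
    """
    rho, z = profile.summary
    m = profile.team_size
    if m is None:
        m = team_size_from_demand(rho, hours_per_worker)
    util = utilization(rho, z, policy)
    avail = 1.0 - prob_effective_capacity_below(
        AvailabilityModel(team_size=m, p_present=p_present), l_threshold)
    if profile.per_ql is None and ql_shares is None:
        ql_dev = None
    else:
        problem = _ql_problem(profile, eta_alpha, ql_shares or ())
        sol = solve_unconstrained(problem)
        mu = np.asarray(problem.mu)
        ql_dev = float(np.sum(np.clip(sol.ratios - mu / mu.sum(), 0, None)))
    return ScenarioMetrics(
        utilization=util, availability=avail, ql_deviation=ql_dev,
        interactions=interactions_complete(int(math.ceil(m))))


def objective(metrics: ScenarioMetrics,
              weights: ObjectiveWeights = ObjectiveWeights()) -> float:
    """Weighted merging objective (to be maximized)."""
    score = (weights.lambda1 * metrics.utilization
             + weights.lambda3 * metrics.availability
             - weights.lambda6 * metrics.interactions)
    if metrics.ql_deviation is None:
        if weights.lambda4 > 0:
            warnings.warn("QL deviation unavailable; omitting the lambda4 "
                          "term from the objective", stacklevel=2)
    else:
        score -= weights.lambda4 * metrics.ql_deviation
    return score


def scan_merge_sequence(profiles: Sequence[TeamProfile],
                        order: Sequence[str] | None = None,
                        policy: StaffingPolicy = StaffingPolicy(),
                        p_present: float = 0.79,
                        l_threshold: float = 0.6,
                        eta_alpha: float = 2.0,
                        hours_per_worker: float = 20.0,
                        ql_shares: Sequence[float] | None = DEFAULT_QL_SHARES,
                        lambda6_values: Sequence[float] = (1e-3,),
                        lambda1: float = 1.0, lambda3: float = 1.0,
                        lambda4: float = 1.0) -> pd.DataFrame:
    """Evaluate a merge order step by step.

    Step ``j`` scores the cluster of the first ``j + 1`` teams in ``order``
    (default: the given profile order). Returns a DataFrame with one row
    per step: cluster id, pooled rho and z, the four metrics, and one
    objective column per ``lambda6`` value.
    """
    by_id = {p.team_id: p for p in profiles}
    if len(by_id) != len(profiles):
        raise ValueError("duplicate team ids")
    ids = list(order) if order is not None else [p.team_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate team ids in order")
    unknown = [i for i in ids if i not in by_id]
    if unknown:
        raise ValueError(f"unknown team ids in order: {unknown}")

    rows = []
    for j in range(len(ids)):
        cluster = merge_cluster([by_id[i] for i in ids[:j + 1]],
                                hours_per_worker)
        metrics = evaluate(cluster, policy, p_present, l_threshold,
                           eta_alpha, hours_per_worker, ql_shares)
        row = {
            "step": j,
            "cluster": cluster.team_id,
            "rho": cluster.summary.rho,
            "z": cluster.summary.z,
            "utilization": metrics.utilization,
            "availability": metrics.availability,
            "ql_deviation": metrics.ql_deviation,
            "interactions": metrics.interactions,
        }
        for lam6 in lambda6_values:
            w = ObjectiveWeights(lambda1, lambda3, lambda4, lam6,
                                 l_threshold)
            row[f"objective_{lam6:g}"] = objective(metrics, w)
        rows.append(row)
    return pd.DataFrame(rows)
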