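"""Weekly care demand as a batch-arrival infinite-server queue.

Each case arriving in week ``s`` brings ``B_i`` care hours per week for
``S_i`` weeks; with weekly new-case counts ``A_s``, the demand in week ``t``
is ``N_t = sum_i 1{S_i^r >= t} Bhat_i + sum_{s<t} sum_i 1{S_i >= t-s} B_i``.
All three ingredients are i.i.d. and mutually independent with means
``m_a, m_s, m_g`` and variances ``var_a, var_s, var_g``.

In stationarity ``E[N] = rho = m_a m_s m_g`` and ``Var(N) = z rho`` with the
peakedness

    z = var_g/m_g + m_g + m_g (1 - G_s) (var_a/m_a - 1),

where ``G_s`` is the Gini coefficient of the LoS. The normal (QED-regime)
approximation of N then gives the square-root staffing rule
``C = rho + gamma sqrt(z rho)`` and utilization
``1 / (1 + gamma sqrt(z / rho))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from hhcteams.estimation import LosTail
from hhcteams.io import TeamParameters


@dataclass(frozen=True)
class StaffingPolicy:
    """Grade-of-service multiplier gamma for square-root staffing.

    The capacity ``C = rho + gamma sqrt(z rho)`` keeps the probability that
    demand exceeds capacity at ``1 - Phi(gamma)``; typical values lie in
    [0.5, 2].
    """

    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


class DemandSummary(NamedTuple):
    """Offered load and peakedness of a (possibly pooled) demand stream."""

    rho: float
    z: float


@dataclass(frozen=True)
class TeamDemandModel:
    """Demand-generating parameters of one team.

    Built either from a full LoS tail (``from_los``) or from a summary
    parameter row (``from_team_parameters``), in which case only the mean
    LoS and its Gini coefficient are known — enough for all stationary
    quantities. Transient quantities need the full tail.
    """

    m_a: float
    var_a: float
    m_g: float
    var_g: float
    m_s: float
    gini_s: float
    los: LosTail | None = None

    def __post_init__(self) -> None:
        if min(self.m_g, self.m_s) <= 0 or self.m_a < 0:
            raise ValueError("means must be positive (m_a may be 0)")
        if min(self.var_a, self.var_g) < 0:
            raise ValueError("variances must be non-negative")
        if not 0 <= self.gini_s < 1:
            raise ValueError("gini_s must be in [0, 1)")

    @classmethod
    def from_team_parameters(cls, tp: TeamParameters) -> "TeamDemandModel":
        return cls(m_a=tp.m_a, var_a=tp.vmr_a * tp.m_a, m_g=tp.m_g,
                   var_g=tp.vmr_g * tp.m_g, m_s=tp.m_s_implied,
                   gini_s=tp.gini_s)

    @classmethod
    def from_los(cls, m_a: float, var_a: float, m_g: float, var_g: float,
                 los: LosTail) -> "TeamDemandModel":
        return cls(m_a=m_a, var_a=var_a, m_g=m_g, var_g=var_g,
                   m_s=los.mean, gini_s=los.gini, los=los)

    @property
    def rho(self) -> float:
        """Offered load: mean weekly care hours ``m_a * m_s * m_g``."""
        return self.m_a * self.m_s * self.m_g

    @property
    def z(self) -> float:
        """Peakedness ``Var(N) / E[N]`` of stationary weekly demand."""
        return peakedness(self)

    def summary(self) -> DemandSummary:
        return DemandSummary(self.rho, self.z)


@dataclass(frozen=True)
class CurrentLoad:
    """Cases currently in service: per-case weekly hours and the remaining
    LoS tail shared by all of them (default: the equilibrium tail of S)."""

    case_hours: tuple[float, ...]
    remaining_tail: LosTail | None = None

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.case_hours):
            raise ValueError("case hours must be positive")

    @property
    def n0(self) -> float:
        """Current total weekly demand."""
        return float(sum(self.case_hours))


def peakedness(model: TeamDemandModel) -> float:
    """Peakedness ``z = var_g/m_g + m_g + m_g (1 - G_s)(var_a/m_a - 1)``.

    The three terms carry the variability of the case demand, the batching
    of hours within a case, and the over/underdispersion of arrivals damped
    by LoS inequality. With unit deterministic case demand this reduces to
    the classical G/G/inf peakedness ``1 + (1 - G_s)(c_IA^2 - 1)``.
    """
    if model.m_a == 0:
        raise ValueError("peakedness is undefined for m_a = 0")
    vmr_a = model.var_a / model.m_a
    return (model.var_g / model.m_g + model.m_g
            + model.m_g * (1.0 - model.gini_s) * (vmr_a - 1.0))


def stationary_moments(model: TeamDemandModel) -> tuple[float, float]:
    """Stationary mean and variance of weekly demand:
    ``(rho, z * rho)``."""
    rho = model.rho
    if rho == 0:
        return 0.0, 0.0
    return rho, peakedness(model) * rho


def transient_moments(model: TeamDemandModel, load: CurrentLoad,
                      t: int) -> tuple[float, float]:
    """Mean and variance of demand ``t`` weeks ahead given the current load.

    ``E[N_t] = N_0 Sr(t) + m_a m_g sum_{u=1}^{t} S(u)`` and

    ``Var(N_t) = Sr(t)(1 - Sr(t)) sum_i Bhat_i^2
    + m_a (var_g + m_g^2) sum_u S(u)
    + m_g^2 (var_a - m_a) sum_u S(u)^2``.

    As ``t`` grows both converge to the stationary moments. Tails evaluate
    to 0 beyond their horizon.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if model.los is None:
        raise ValueError("transient moments need the full LoS tail")
    sr_tail = load.remaining_tail or model.los.equilibrium()
    sr = float(sr_tail.survival(t))
    hours = np.asarray(load.case_hours, dtype=float)
    s_vals = model.los.survival(np.arange(1, t + 1))
    s_sum = float(np.sum(s_vals))
    s2_sum = float(np.sum(np.square(s_vals)))
    mean = load.n0 * sr + model.m_a * model.m_g * s_sum
    var = (sr * (1.0 - sr) * float(np.sum(hours ** 2))
           + model.m_a * (model.var_g + model.m_g ** 2) * s_sum
           + model.m_g ** 2 * (model.var_a - model.m_a) * s2_sum)
    return mean, var


def required_capacity(rho: float, z: float,
                      policy: StaffingPolicy = StaffingPolicy()) -> float:
    """Square-root staffing: ``C = rho + gamma sqrt(z rho)``.

    Fractional capacities are meaningful (capacity is in hours/week)."""
    if rho <= 0 or z <= 0:
        raise ValueError("rho and z must be positive")
    return rho + policy.gamma * np.sqrt(z * rho)


def utilization(rho: float, z: float,
                policy: StaffingPolicy = StaffingPolicy()) -> float:
    """Capacity utilization ``E[N]/C = 1 / (1 + gamma sqrt(z / rho))``.

    Increasing in rho at fixed z and gamma — the economies-of-scale side of
    square-root staffing — and decreasing in both z and gamma.
    """
    if rho <= 0 or z <= 0:
        raise ValueError("rho and z must be positive")
    return 1.0 / (1.0 + policy.gamma * np.sqrt(z / rho))


def pool_teams(
    models: Iterable[TeamDemandModel | DemandSummary],
) -> DemandSummary:
    """Pool independent demand streams: loads add, variances add, so the
    pooled peakedness is the load-weighted mean of the per-team values."""
    summaries = [m.summary() if isinstance(m, TeamDemandModel) else
                 DemandSummary(*m) for m in models]
    if not summaries:
        raise ValueError("need at least one demand model to pool")
    rho = sum(s.rho for s in summaries)
    var = sum(s.z * s.rho for s in summaries)
    return DemandSummary(rho, var / rho)
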