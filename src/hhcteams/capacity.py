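"""Effective capacity, contract-mix bounds, and team-interaction complexity.

Three stylized models of the supply side:

* **Availability.** Each of ``M`` scheduled workers is present with
  probability ``p``, so the effective capacity ``P`` (present fraction) has
  mean ``p`` and variance ``p(1-p)/M``. The dip probability ``P(P <= l)``
  is the binomial CDF, expressed through the incomplete beta function so it
  extends to non-integer team sizes.
* **Contracts.** With short shifts of one day part, long shifts ``a`` times
  as long, and ``b_FT``/``b_PT`` short-shift equivalents per full/part-time
  week, the scarcity of afternoon work (fraction ``f2``, plus ``f0``
  schedulable any time) caps the full-time contract fraction if split
  shifts are to be avoided.
* **Interactions.** A fully connected team of ``M`` members has
  ``M(M-1)/2`` communication lines; splitting into sub-teams joined by one
  mediator reduces this by roughly the number of sub-teams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special


@dataclass(frozen=True)
class AvailabilityModel:
    """Team size ``M`` (fractional allowed), presence probability ``p``,
    and optional per-worker weekly hours for the weighted variant."""

    team_size: float
    p_present: float = 0.79
    weekly_hours: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.team_size <= 0:
            raise ValueError("team_size must be positive")
        if not 0 < self.p_present < 1:
            raise ValueError("p_present must be in (0, 1)")
        if self.weekly_hours is not None and any(
                w <= 0 for w in self.weekly_hours):
            raise ValueError("weekly hours must be positive")


@dataclass(frozen=True)
class ContractModel:
    """Shift-structure parameters.

    ``a`` is the long/short shift length ratio; ``b_ft``/``b_pt`` the number
    of short-shift equivalents in a full-/part-time week (at most 5 working
    days); ``f0`` the fraction of work schedulable at any moment and ``f2``
    the fraction fixed in the afternoon.
    """

    a: float = 1.5
    b_ft: float = 8.0
    b_pt: float = 5.0
    f0: float = 0.0
    f2: float = 0.073

    def __post_init__(self) -> None:
        if self.a <= 1:
            raise ValueError("a must be > 1")
        if self.b_ft < 5:
            raise ValueError("b_ft must be >= 5")
        if not 0 < self.b_pt <= 5:
            raise ValueError("b_pt must be in (0, 5]")
        if self.f0 < 0 or self.f2 < 0 or self.f0 + self.f2 > 1:
            raise ValueError("f0, f2 must be >= 0 with f0 + f2 <= 1")


@dataclass(frozen=True)
class TeamStructure:
    """Sub-team sizes joined by an optional mediator post."""

    subteam_sizes: tuple[int, ...]
    mediator: bool = True

    def __post_init__(self) -> None:
        if len(self.subteam_sizes) == 0:
            raise ValueError("need at least one sub-team")
        if any(m < 1 for m in self.subteam_sizes):
            raise ValueError("sub-team sizes must be >= 1")

    @property
    def total(self) -> int:
        return int(sum(self.subteam_sizes))


# ---------------------------------------------------------------------------
# Availability (effective capacity)


def effective_capacity_moments(m: AvailabilityModel) -> tuple[float, float]:
    """Mean and variance of the effective capacity ``P``.

    Unweighted: ``(p, p(1-p)/M)``. With per-worker hours ``w_i``, the
    variance becomes ``p(1-p) sum w_i^2 / C^2`` with ``C = sum w_i``; equal
    hours reduce to the unweighted case. The standard deviation falls as
    ``1/sqrt(M)`` — economies of scale with diminishing returns.
    """
    p = m.p_present
    if m.weekly_hours is None:
        return p, p * (1.0 - p) / m.team_size
    w = np.asarray(m.weekly_hours, dtype=float)
    return p, p * (1.0 - p) * float(np.sum(w ** 2)) / float(np.sum(w)) ** 2


def prob_effective_capacity_below(m: AvailabilityModel, l: float) -> float:
    """Probability that the effective capacity is at most ``l``.

    Evaluates ``P(Binomial(M, p) <= l M)`` through the incomplete-beta
    representation ``1 - I_p(lM + 1, (1-l)M)`` (regularized), which is also
    defined for non-integer ``M`` and coincides with the exact binomial CDF
    at integer thresholds.
    """
    if not 0 <= l <= 1:
        raise ValueError("l must be in [0, 1]")
    if l == 1:
        return 1.0
    return float(1.0 - special.betainc(l * m.team_size + 1.0,
                                       (1.0 - l) * m.team_size,
                                       m.p_present))


# ---------------------------------------------------------------------------
# Contract mix


def _ft_threshold(c: ContractModel) -> float:
    """Feasibility threshold on ``f0 + f2`` for all-full-time contracts."""
    second = 1.0 - 1.0 / c.a
    if c.b_ft == c.b_pt:
        return second
    return min((c.b_ft - 5.0) / (c.b_ft - c.b_pt), second)


def full_time_all_feasible(c: ContractModel) -> bool:
    """True iff every contract can be full time without split shifts:
    ``f0 + f2 >= min((b_ft - 5)/(b_ft - b_pt), 1 - 1/a)``."""
    return c.f0 + c.f2 >= _ft_threshold(c)


def max_full_time_fraction(c: ContractModel) -> float:
    """Upper bound on the full-time contract fraction avoiding split shifts.

    ``p_FT <= f b_pt / (b_ft - 5 + (b_pt - b_ft) f)`` with ``f = f0 + f2``,
    clamped to [0, 1]; returns 1 when all-full-time is already feasible or
    the bound is vacuous (non-positive denominator).
    """
    if full_time_all_feasible(c):
        return 1.0
    f = c.f0 + c.f2
    denom = c.b_ft - 5.0 + (c.b_pt - c.b_ft) * f
    if denom <= 0:
        return 1.0
    return float(np.clip(f * c.b_pt / denom, 0.0, 1.0))


def required_afternoon_fraction(c: ContractModel,
                                target_p_ft: float) -> float:
    """Smallest ``f0 + f2`` at which the full-time bound reaches the target.

    Closed-form inversion of the bound:
    ``f = p (b_ft - 5) / (b_pt + p (b_ft - b_pt))``. Returns 0 for target 0
    and the all-feasible threshold when the target is unreachable along the
    bound (target 1 with b_ft > b_pt).
    """
    if not 0 <= target_p_ft <= 1:
        raise ValueError("target_p_ft must be in [0, 1]")
    if target_p_ft == 0:
        return 0.0
    p = target_p_ft
    f = p * (c.b_ft - 5.0) / (c.b_pt + p * (c.b_ft - c.b_pt))
    return float(min(f, _ft_threshold(c)))


# ---------------------------------------------------------------------------
# Interaction complexity


def interactions_complete(team_size: int) -> int:
    """Communication lines in a fully connected team: ``M(M-1)/2``."""
    m = int(team_size)
    if m != team_size or m < 1:
        raise ValueError("team_size must be a positive integer")
    return m * (m - 1) // 2


def interactions_subteams(ts: TeamStructure) -> int:
    """Interactions with disjoint sub-teams joined by one mediator:
    ``M + sum_j M_j (M_j - 1) / 2`` (the mediator adds M edges)."""
    if not ts.mediator:
        raise ValueError("sub-team interaction count assumes a mediator")
    within = sum(m * (m - 1) // 2 for m in ts.subteam_sizes)
    return ts.total + within


def interactions_equal_split(team_size: float, k: int) -> float:
    """Mediator interactions for an equal split into ``k`` sub-teams:
    ``M/2 + M^2/(2k)``; fractional sub-team sizes allowed. The ratio to
    the complete graph tends to ``1/k`` as M grows."""
    if k < 1:
        raise ValueError("k must be >= 1")
    m = float(team_size)
    return m / 2.0 + m * m / (2.0 * k)
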