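"""Synthetic visit data and Monte-Carlo demand oracles.

The generator emulates the statistical structure of planned home-care
demand: weekly new-case counts with a chosen mean and dispersion, a length
of stay (LoS) per case (geometric by default, Weibull optionally), a
constant weekly care volume per case drawn from a gamma distribution,
a qualification-level mix, a day-part profile, and a weekday/weekend
demand imbalance. Defaults follow the study's cross-team medians: 3.6 new
cases/week with VMR 1.4, 3.3 h/week per case with VMR 4, mean LoS 20
weeks, QL mix 67/9/24%, day parts 68.6/7.3/24.2%, weekend demand 19.3%
below weekdays.

Two direct simulators of the week-``t`` demand sum serve as
distribution-free oracles for the closed-form mean/variance formulas of
the demand model.

Arrival counts are drawn from a family chosen by the variance-to-mean
ratio — negative binomial (VMR > 1), Poisson (VMR = 1), or binomial
(VMR < 1; the integer number of trials may make the achieved VMR differ
slightly from the requested one, so the exact achieved moments are
exposed via :func:`arrival_moments`).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hhcteams.demand import CurrentLoad, TeamDemandModel
from hhcteams.estimation import LosTail
from hhcteams.io import DAY_PARTS, VisitRecord

#: Monday anchoring week 0 of generated datasets.
_EPOCH = _dt.date(2020, 1, 6)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic visit generator (defaults: the study's
    cross-team medians, see module docstring)."""

    weeks: int = 104
    m_a: float = 3.6
    vmr_a: float = 1.4
    los_dist: str = "geometric"
    m_s: float = 20.0
    weibull_shape: float = 1.3
    m_g: float = 3.3
    vmr_g: float = 4.0
    ql_mix: tuple[float, ...] = (0.67, 0.09, 0.24)
    daypart_mix: tuple[float, float, float] = (0.686, 0.073, 0.242)
    weekend_factor: float = 0.807
    team_id: str = "T1"
    area: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weeks < 1:
            raise ValueError("weeks must be >= 1")
        if self.m_a < 0 or self.vmr_a < 0:
            raise ValueError("m_a and vmr_a must be >= 0")
        if self.los_dist not in ("geometric", "weibull"):
            raise ValueError("los_dist must be 'geometric' or 'weibull'")
        if self.m_s < 1 or self.m_g <= 0 or self.vmr_g < 0:
            raise ValueError("m_s must be >= 1 and m_g > 0")
        for probs, name in ((self.ql_mix, "ql_mix"),
                            (self.daypart_mix, "daypart_mix")):
            # printed percentage profiles may be off unity by rounding
            # (the default day-part profile sums to 100.1%); shares are
            # renormalized at draw time
            if abs(sum(probs) - 1.0) > 5e-3 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be a probability vector")
        if not 0 < self.weekend_factor <= 1.5:
            raise ValueError("weekend_factor out of range")

    def los_tail(self) -> LosTail:
        """Exact LoS tail of the generator's LoS distribution."""
        if self.los_dist == "geometric":
            return LosTail.from_geometric(self.m_s)
        scale = _weibull_scale(self.weibull_shape, self.m_s)
        return LosTail.from_weibull(self.weibull_shape, scale)

    def demand_model(self) -> TeamDemandModel:
        """The closed-form demand model matching the generator exactly
        (using the achieved arrival moments)."""
        mean_a, var_a = arrival_moments(self.m_a, self.vmr_a)
        return TeamDemandModel.from_los(
            m_a=mean_a, var_a=var_a, m_g=self.m_g,
            var_g=self.vmr_g * self.m_g, los=self.los_tail())


def _weibull_scale(shape: float, target_mean: float) -> float:
    """Scale making the discretized (ceiling) Weibull LoS mean equal the
    target: solved on the exact tail sum by bisection."""
    lo, hi = 1e-6, max(4.0 * target_mean, 4.0)
    while LosTail.from_weibull(shape, hi).mean < target_mean:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if LosTail.from_weibull(shape, mid).mean < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Elementary samplers


def arrival_moments(m_a: float, vmr_a: float) -> tuple[float, float]:
    """Exact (mean, variance) achieved by the arrival-count sampler."""
    if m_a == 0:
        return 0.0, 0.0
    if vmr_a == 1.0:
        return m_a, m_a
    if vmr_a > 1.0:
        return m_a, vmr_a * m_a
    n = max(int(math.ceil(m_a)), int(round(m_a / (1.0 - vmr_a))))
    p = m_a / n
    return m_a, m_a * (1.0 - p)


def _draw_arrivals(rng: np.random.Generator, m_a: float, vmr_a: float,
                   size) -> np.ndarray:
    if m_a == 0:
        return np.zeros(size, dtype=np.int64)
    if vmr_a == 1.0:
        return rng.poisson(m_a, size)
    if vmr_a > 1.0:
        r = m_a / (vmr_a - 1.0)
        return rng.negative_binomial(r, 1.0 / vmr_a, size)
    n = max(int(math.ceil(m_a)), int(round(m_a / (1.0 - vmr_a))))
    return rng.binomial(n, m_a / n, size)


def _draw_los(rng: np.random.Generator, spec: GeneratorSpec,
              size: int) -> np.ndarray:
    if spec.los_dist == "geometric":
        return rng.geometric(1.0 / spec.m_s, size)
    scale = _weibull_scale(spec.weibull_shape, spec.m_s)
    return np.ceil(scale * rng.weibull(spec.weibull_shape, size)
                   ).astype(np.int64).clip(min=1)


def _draw_case_hours(rng: np.random.Generator, m_g: float, vmr_g: float,
                     size: int) -> np.ndarray:
    if vmr_g == 0:
        return np.full(size, m_g)
    return rng.gamma(m_g / vmr_g, vmr_g, size)


def _sum_gamma(rng: np.random.Generator, counts: np.ndarray, m_g: float,
               vmr_g: float) -> np.ndarray:
    """Sum of ``counts`` i.i.d. case-hour draws per entry, using the gamma
    convolution identity (the sum of k Gamma(a, s) is Gamma(k a, s))."""
    if vmr_g == 0:
        return counts * m_g
    shape = counts * (m_g / vmr_g)
    out = np.zeros(counts.shape, dtype=float)
    pos = shape > 0
    out[pos] = rng.gamma(shape[pos], vmr_g)
    return out


# ---------------------------------------------------------------------------
# Visit generation


def generate_visits(spec: GeneratorSpec) -> list[VisitRecord]:
    """Generate a visit-record dataset with the spec's demand structure.

    Weekly case starts are drawn over the horizon; each case receives a
    qualification level, an LoS, a constant weekly care volume, and client
    coordinates uniform over a square of the spec's area. Each active
    (case, week) materializes one record per day part with a positive
    share, dated within the week by weekday/weekend weights. Deterministic
    under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    side = math.sqrt(spec.area)
    ql_mix = np.asarray(spec.ql_mix) / np.sum(spec.ql_mix)
    daypart_mix = np.asarray(spec.daypart_mix) / np.sum(spec.daypart_mix)
    day_weights = np.array([1.0] * 5 + [spec.weekend_factor] * 2)
    day_weights /= day_weights.sum()
    records: list[VisitRecord] = []
    client_no = 0
    for week in range(spec.weeks):
        for _ in range(int(_draw_arrivals(rng, spec.m_a, spec.vmr_a, ()))):
            client_no += 1
            client_id = f"c{client_no:06d}"
            ql = 1 + int(rng.choice(len(ql_mix), p=ql_mix))
            los = int(_draw_los(rng, spec, 1)[0])
            hours = float(_draw_case_hours(rng, spec.m_g, spec.vmr_g, 1)[0])
            x, y = (float(c) for c in rng.uniform(0.0, side, 2))
            for w in range(week, min(week + los, spec.weeks)):
                day = int(rng.choice(7, p=day_weights))
                date = _EPOCH + _dt.timedelta(weeks=w, days=day)
                for part, share in zip(DAY_PARTS, daypart_mix):
                    if share <= 0:
                        continue
                    records.append(VisitRecord(
                        client_id=client_id, team_id=spec.team_id,
                        date=date, day_part=part,
                        duration=hours * share,
                        qualification_level=ql, x=x, y=y))
    records.sort(key=lambda r: (r.client_id, r.qualification_level, r.date))
    return records


# ---------------------------------------------------------------------------
# Monte-Carlo oracles for the demand model


def simulate_stationary_demand(model: TeamDemandModel, reps: int = 5000,
                               seed: int | None = None,
                               horizon: int | None = None) -> np.ndarray:
    """Replications of stationary weekly demand by direct simulation.

    Each replication sums, over case ages ``t = 1..horizon``, the care
    volumes of the cases that arrived ``t`` weeks ago and are still active
    (arrival count thinned by ``P(S >= t)``). The sample mean and variance
    are a distribution-free oracle for ``rho`` and ``z * rho``. The horizon
    defaults to the LoS tail's; a tail mass above 1e-3 at the horizon
    raises, since stationarity would be materially truncated.
    """
    if model.los is None:
        raise ValueError("simulation needs the full LoS tail")
    rng = np.random.default_rng(seed)
    horizon = model.los.horizon if horizon is None else horizon
    if model.los.survival(horizon) > 1e-3:
        raise ValueError("LoS tail mass at the horizon exceeds 1e-3; "
                         "increase the horizon")
    vmr_a = model.var_a / model.m_a if model.m_a > 0 else 1.0
    survivors = np.zeros(reps, dtype=np.int64)
    for t in range(1, horizon + 1):
        s_t = float(model.los.survival(t))
        if s_t == 0.0:
            break
        arrivals = _draw_arrivals(rng, model.m_a, vmr_a, reps)
        survivors += rng.binomial(arrivals, s_t)
    vmr_g = model.var_g / model.m_g
    return _sum_gamma(rng, survivors, model.m_g, vmr_g)


def simulate_transient_demand(model: TeamDemandModel, load: CurrentLoad,
                              t: int, reps: int = 5000,
                              seed: int | None = None) -> np.ndarray:
    """Replications of the demand ``t`` weeks ahead given the current load.

    Current cases survive to week ``t`` independently with probability
    ``Sr(t)``; cases arriving in weeks ``0..t-1`` survive with
    ``P(S >= t - s)`` and draw fresh care volumes. Sample moments oracle
    the transient mean/variance formulas.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if model.los is None:
        raise ValueError("simulation needs the full LoS tail")
    rng = np.random.default_rng(seed)
    sr_tail = load.remaining_tail or model.los.equilibrium()
    sr = float(sr_tail.survival(t))
    hours = np.asarray(load.case_hours, dtype=float)
    if hours.size:
        alive = rng.random((reps, hours.size)) < sr
        current = alive @ hours
    else:
        current = np.zeros(reps)
    vmr_a = model.var_a / model.m_a if model.m_a > 0 else 1.0
    vmr_g = model.var_g / model.m_g
    survivors = np.zeros(reps, dtype=np.int64)
    for s in range(t):
        s_prob = float(model.los.survival(t - s))
        if s_prob == 0.0:
            continue
        arrivals = _draw_arrivals(rng, model.m_a, vmr_a, reps)
        survivors += rng.binomial(arrivals, s_prob)
    return current + _sum_gamma(rng, survivors, model.m_g, vmr_g)
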