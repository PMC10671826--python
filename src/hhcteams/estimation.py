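"""Descriptive demand estimation from visit records.

Turns raw visit records into the quantities that drive the capacity models:
cases (episodes of care for one client at one qualification level, closed by
a >30-day gap between visits), weekly demand series, arrival and case-demand
moments, the Kaplan–Meier length-of-stay tail with a Weibull curve fit, the
Gini coefficient of the length of stay, and day-part demand fractions.

Week indices are 0-based from the ISO week containing the earliest visit;
length of stay (LoS) is measured in weeks with the convention that a case
observed in exactly one week has LoS 1.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from hhcteams.io import VisitRecord, TeamParameters, DAY_PARTS


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class MomentSummary:
    """Mean, variance and variance-to-mean ratio of a sample."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")

    @property
    def vmr(self) -> float:
        """Variance-to-mean ratio (dispersion index)."""
        return self.variance / self.mean


@dataclass(frozen=True)
class CaseRecord:
    """An episode of care for one client at one qualification level.

    ``start_week``/``end_week`` are 0-based indices into the observation
    window; ``weekly_hours[w]`` is the care delivered in week
    ``start_week + w``. ``left_open`` marks cases already active in the
    first observed week (unknown true start); ``right_censored`` marks cases
    still active in the last observed week.
    """

    client_id: str
    qualification_level: int
    team_id: str
    start_week: int
    end_week: int
    weekly_hours: tuple[float, ...]
    left_open: bool = False
    right_censored: bool = False

    def __post_init__(self) -> None:
        if self.end_week < self.start_week:
            raise ValueError("end_week must be >= start_week")
        if len(self.weekly_hours) != self.end_week - self.start_week + 1:
            raise ValueError("weekly_hours length must match the week span")
        if any(h < 0 for h in self.weekly_hours):
            raise ValueError("weekly hours must be >= 0")

    @property
    def los(self) -> int:
        """Length of stay in weeks (single-week cases have LoS 1)."""
        return self.end_week - self.start_week + 1


class LosTail:
    """Discrete survival function of the length of stay, in weeks.

    ``tail[t] = P(S >= t)`` for ``t = 0, 1, ..., horizon`` with
    ``tail[0] = 1``; beyond the horizon the tail is treated as 0. Provides
    the mean, variance and Gini coefficient of S, and the equilibrium
    (stationary-excess) tail used for the remaining LoS of cases already in
    service.
    """

    def __init__(self, tail: Sequence[float],
                 at_risk: Sequence[float] | None = None,
                 events: Sequence[float] | None = None):
        t = np.asarray(tail, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("tail must be a non-empty 1-d sequence")
        if abs(t[0] - 1.0) > 1e-12:
            raise ValueError("tail must start at S(0) = 1")
        if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
            raise ValueError("tail values must lie in [0, 1]")
        if np.any(np.diff(t) > 1e-12):
            raise ValueError("tail must be non-increasing")
        self.tail = np.clip(t, 0.0, 1.0)
        self.at_risk = None if at_risk is None else np.asarray(at_risk, float)
        self.events = None if events is None else np.asarray(events, float)

    @property
    def horizon(self) -> int:
        return len(self.tail) - 1

    def survival(self, t) -> np.ndarray | float:
        """``P(S >= t)``, 0 beyond the horizon; vectorized over ``t``."""
        t = np.asarray(t)
        out = np.where(t <= self.horizon,
                       self.tail[np.minimum(t, self.horizon)], 0.0)
        return float(out) if out.ndim == 0 else out

    def exceed(self, k) -> np.ndarray | float:
        """``P(S > k) = P(S >= k + 1)``."""
        return self.survival(np.asarray(k) + 1)

    @property
    def mean(self) -> float:
        """``E[S] = sum_{t>=1} P(S >= t)`` (truncated at the horizon)."""
        return float(self.tail[1:].sum())

    @property
    def variance(self) -> float:
        # E[S^2] = sum_{t>=1} (2t - 1) P(S >= t)
        t = np.arange(1, self.horizon + 1)
        second = float(((2 * t - 1) * self.tail[1:]).sum())
        return second - self.mean ** 2

    @property
    def gini(self) -> float:
        """Gini coefficient ``1 - sum_k P(S>k)^2 / E[S]`` of the LoS."""
        m = self.mean
        if m <= 0:
            raise ValueError("tail has zero implied mean")
        return 1.0 - float((self.tail[1:] ** 2).sum()) / m

    def equilibrium(self) -> "LosTail":
        """Stationary-excess tail: ``Sr(t) = sum_{u>t} S(u) / E[S]``.

        This is the remaining-LoS distribution of a case picked at a random
        time in steady state; ``Sr(0) = 1``.
        """
        m = self.mean
        if m <= 0:
            raise ValueError("tail has zero implied mean")
        cum = np.cumsum(self.tail[1:][::-1])[::-1] / m  # Sr(0), Sr(1), ...
        return LosTail(np.append(cum, 0.0))

    @classmethod
    def from_geometric(cls, mean: float, horizon: int | None = None,
                       tol: float = 1e-9) -> "LosTail":
        """Geometric LoS on {1, 2, ...} with the given mean.

        ``P(S >= t) = q^(t-1)`` with ``q = 1 - 1/mean``.
        """
        if mean < 1:
            raise ValueError("geometric LoS mean must be >= 1")
        q = 1.0 - 1.0 / mean
        if horizon is None:
            horizon = 1 if q == 0 else min(
                int(np.ceil(np.log(tol) / np.log(q))) + 1, 20000)
        t = np.arange(horizon + 1, dtype=float)
        tail = np.ones(horizon + 1)
        tail[1:] = q ** (t[1:] - 1)
        return cls(tail)

    @classmethod
    def from_weibull(cls, shape: float, scale: float,
                     horizon: int | None = None,
                     tol: float = 1e-9) -> "LosTail":
        """Discretized Weibull LoS: ``S = ceil(W)`` for continuous W.

        ``P(S >= t) = exp(-((t-1)/scale)^shape)`` for ``t >= 1``.
        """
        if shape <= 0 or scale <= 0:
            raise ValueError("shape and scale must be positive")
        if horizon is None:
            horizon = min(int(np.ceil(scale * (-np.log(tol)) ** (1 / shape)))
                          + 2, 20000)
        t = np.arange(horizon + 1, dtype=float)
        tail = np.exp(-((np.maximum(t - 1, 0.0) / scale) ** shape))
        tail[0] = 1.0
        return cls(tail)


# ---------------------------------------------------------------------------
# Week bookkeeping


def _monday_of(date: _dt.date) -> _dt.date:
    return date - _dt.timedelta(days=date.weekday())


def week_index(dates: Sequence[_dt.date],
               origin: _dt.date | None = None) -> np.ndarray:
    """0-based week index of each date, relative to the Monday of the ISO
    week containing ``origin`` (default: the earliest date given)."""
    if len(dates) == 0:
        return np.array([], dtype=int)
    if origin is None:
        origin = min(dates)
    monday0 = _monday_of(origin)
    return np.array([(d - monday0).days // 7 for d in dates], dtype=int)


def _window(visits: Sequence[VisitRecord]) -> tuple[_dt.date, int]:
    """(origin date, number of weeks) of the observation window."""
    origin = min(v.date for v in visits)
    n_weeks = int(week_index([max(v.date for v in visits)], origin)[0]) + 1
    return origin, n_weeks


# ---------------------------------------------------------------------------
# Case construction and demand series


def build_cases(visits: Sequence[VisitRecord],
                gap_days: int = 30) -> list[CaseRecord]:
    """Group visits into cases: one client, one qualification level, and no
    gap between consecutive visits longer than ``gap_days`` days.

    A longer gap closes the case and starts a new one. Cases active in the
    first (last) observed week are flagged ``left_open`` (``right_censored``).
    Returns an empty list for empty input.
    """
    if len(visits) == 0:
        return []
    origin, n_weeks = _window(visits)
    ordered = sorted(visits, key=lambda v: (v.client_id,
                                            v.qualification_level, v.date))
    cases: list[CaseRecord] = []
    run: list[VisitRecord] = []

    def _close(run: list[VisitRecord]) -> None:
        weeks = week_index([v.date for v in run], origin)
        start, end = int(weeks.min()), int(weeks.max())
        hours = np.zeros(end - start + 1)
        for v, w in zip(run, weeks):
            hours[w - start] += v.duration
        cases.append(CaseRecord(
            client_id=run[0].client_id,
            qualification_level=run[0].qualification_level,
            team_id=run[0].team_id,
            start_week=start,
            end_week=end,
            weekly_hours=tuple(hours),
            left_open=(start == 0),
            right_censored=(end == n_weeks - 1),
        ))

    for v in ordered:
        if run and (
            v.client_id != run[-1].client_id
            or v.qualification_level != run[-1].qualification_level
            or (v.date - run[-1].date).days > gap_days
        ):
            _close(run)
            run = []
        run.append(v)
    _close(run)
    return cases


def weekly_demand_series(visits: Sequence[VisitRecord],
                         team_id: str) -> np.ndarray:
    """Total care hours per week for one team, over the full observation
    window of the supplied visits (zeros in empty weeks)."""
    if len(visits) == 0:
        return np.array([])
    origin, n_weeks = _window(visits)
    team = [v for v in visits if v.team_id == team_id]
    if not team:
        warnings.warn(f"no visits for team {team_id!r}; returning empty "
                      "series", stacklevel=2)
        return np.array([])
    series = np.zeros(n_weeks)
    for v, w in zip(team, week_index([v.date for v in team], origin)):
        series[w] += v.duration
    return series


def arrival_stats(cases: Sequence[CaseRecord]) -> MomentSummary:
    """Moments of the number of new cases per week.

    Left-open cases do not have an observed start, so they are excluded and
    week 0 is dropped from the counting window (its starts are confounded
    with the left-censoring). Sample variance uses the n-1 denominator.
    """
    if not cases:
        raise ValueError("no cases supplied")
    n_weeks = max(c.end_week for c in cases) + 1
    if n_weeks < 3:
        raise ValueError("window too short to estimate arrival variance")
    counts = np.zeros(n_weeks, dtype=float)
    for c in cases:
        if not c.left_open:
            counts[c.start_week] += 1
    counts = counts[1:]
    return MomentSummary(float(counts.mean()), float(counts.var(ddof=1)))


def case_demand_stats(cases: Sequence[CaseRecord]) -> MomentSummary:
    """Moments of weekly care hours per active case, over all
    (case, active week) observations."""
    obs = np.concatenate([np.asarray(c.weekly_hours, float) for c in cases]) \
        if cases else np.array([])
    if obs.size == 0:
        raise ValueError("no case-weeks supplied")
    var = float(obs.var(ddof=1)) if obs.size > 1 else 0.0
    return MomentSummary(float(obs.mean()), var)


# ---------------------------------------------------------------------------
# Length of stay


def km_survival(cases: Sequence[CaseRecord],
                drop_left_open: bool = True) -> LosTail:
    """Kaplan–Meier (product-limit) tail of the length of stay in weeks.

    Cases still active at the end of the window enter as right-censored at
    their observed duration; cases with unknown start (``left_open``) are
    dropped by default, since their observed duration understates the true
    LoS. The returned tail carries the at-risk and event counts on the
    integer timeline for downstream curve fitting.
    """
    usable = [c for c in cases if not (drop_left_open and c.left_open)]
    if not usable:
        raise ValueError("no usable cases for LoS estimation")
    durations = np.array([c.los for c in usable], dtype=float)
    observed = np.array([not c.right_censored for c in usable], dtype=bool)
    horizon = int(durations.max())
    timeline = np.arange(horizon + 1)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed, timeline=timeline)
    # lifelines S(t) = P(S > t); our tail is P(S >= t) = P(S > t - 1)
    s_gt = kmf.survival_function_.values.ravel()
    tail = np.ones(horizon + 1)
    tail[1:] = s_gt[:-1]
    table = kmf.event_table.reindex(timeline, fill_value=0)
    return LosTail(tail, at_risk=table["at_risk"].to_numpy(),
                   events=table["observed"].to_numpy())


def weibull_fit(tail: LosTail,
                weights: Sequence[float] | None = None) -> tuple[float, float]:
    """Fit a Weibull tail ``S(t) = exp(-(t/scale)^shape)`` to a survival
    curve by weighted least squares on the log(-log) transform.

    Regresses ``log(-log S(t))`` on ``log t`` over the points with
    ``0 < S(t) < 1``; the slope is the shape and the intercept gives the
    scale. Weights default to the at-risk counts attached to the tail (all
    ones otherwise). This is a curve fit to the nonparametric estimate, not
    a maximum-likelihood fit to the raw durations.
    """
    t = np.arange(1, tail.horizon + 1, dtype=float)
    s = tail.tail[1:]
    mask = (s > 0) & (s < 1)
    if mask.sum() < 3:
        raise ValueError("need at least 3 tail points with 0 < S < 1")
    if weights is None:
        weights = tail.at_risk[1:] if tail.at_risk is not None \
            else np.ones_like(t)
    w = np.asarray(weights, float)[mask]
    x = np.log(t[mask])
    y = np.log(-np.log(s[mask]))
    if np.ptp(x) == 0:
        raise ValueError("degenerate tail: all mass at one duration")
    shape, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    if shape <= 0:
        raise ValueError("fit produced non-positive shape")
    scale = np.exp(-intercept / shape)
    return float(shape), float(scale)


def gini_from_tail(tail: LosTail) -> float:
    """Gini coefficient of the LoS: ``1 - sum_{k>=0} P(S>k)^2 / E[S]``.

    Equals 0 for a deterministic LoS and approaches 1 as the LoS becomes
    maximally unequal across cases.
    """
    return tail.gini


def implied_ms(mean_demand: float, m_a: float, m_g: float) -> float:
    """Implied mean LoS (weeks) from ``rho = m_a * m_s * m_g``."""
    if m_a * m_g <= 0:
        raise ValueError("m_a * m_g must be positive")
    return mean_demand / (m_a * m_g)


# ---------------------------------------------------------------------------
# Day-part profile and the composite table


def daypart_fractions(
    visits: Sequence[VisitRecord],
) -> tuple[float, float, float, float]:
    """Duration-weighted (morning, afternoon, evening) fractions and the
    weekend-to-weekday ratio of mean daily demand.

    Day counts use the full calendar span of the data so that empty days
    count as zero demand.
    """
    if len(visits) == 0:
        raise ValueError("no visits supplied")
    totals = dict.fromkeys(DAY_PARTS, 0.0)
    weekend_hours = weekday_hours = 0.0
    for v in visits:
        totals[v.day_part] += v.duration
        if v.date.weekday() >= 5:
            weekend_hours += v.duration
        else:
            weekday_hours += v.duration
    grand = sum(totals.values())
    start, end = min(v.date for v in visits), max(v.date for v in visits)
    n_days = (end - start).days + 1
    all_days = [start + _dt.timedelta(days=i) for i in range(n_days)]
    n_weekend = sum(1 for d in all_days if d.weekday() >= 5)
    n_weekday = n_days - n_weekend
    if n_weekend == 0 or n_weekday == 0 or weekday_hours == 0:
        ratio = float("nan")
    else:
        ratio = (weekend_hours / n_weekend) / (weekday_hours / n_weekday)
    return (totals["morning"] / grand, totals["afternoon"] / grand,
            totals["evening"] / grand, ratio)


def team_parameter_table(visits: Sequence[VisitRecord],
                         gap_days: int = 30) -> list[TeamParameters]:
    """Estimate the full parameter row for every team present in the visits:
    mean weekly demand, arrival moments, case-demand moments, LoS Gini from
    the Kaplan–Meier tail, and the implied mean LoS."""
    if len(visits) == 0:
        raise ValueError("no visits supplied")
    team_ids = sorted({v.team_id for v in visits})
    rows = []
    for tid in team_ids:
        team_visits = [v for v in visits if v.team_id == tid]
        series = weekly_demand_series(visits, tid)
        cases = build_cases(team_visits, gap_days=gap_days)
        arr = arrival_stats(cases)
        dem = case_demand_stats(cases)
        gini = km_survival(cases).gini
        rows.append(TeamParameters(
            team_id=tid,
            mean_demand=float(series.mean()),
            m_a=arr.mean,
            vmr_a=arr.vmr,
            m_g=dem.mean,
            vmr_g=dem.vmr,
            gini_s=gini,
            m_s_implied=implied_ms(float(series.mean()), arr.mean, dem.mean),
        ))
    return rows
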