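"""File formats: visit records, team-parameter tables, and policy config.

Canonical formats are UTF-8 CSV with a header row and ``.`` decimal
separator, and a small YAML config of policy constants. A built-in
nine-team parameter table (the merging-study teams) ships with the package.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

DAY_PARTS = ("morning", "afternoon", "evening")

VISIT_COLUMNS = (
    "client_id", "team_id", "date", "day_part", "duration_hours",
    "qualification_level",
)
VISIT_OPTIONAL_COLUMNS = ("x_km", "y_km")


class VisitFormatError(ValueError):
    """The visit file violates the format contract (e.g. missing column)."""


class VisitValidationError(ValueError):
    """One or more rows failed validation; ``errors`` lists (line, message)."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:10])
        more = f" (+{len(errors) - 10} more)" if len(errors) > 10 else ""
        super().__init__(f"{len(errors)} invalid row(s): {lines}{more}")


@dataclass(frozen=True)
class VisitRecord:
    """A single planned care activity.

    Durations are in hours; ``qualification_level`` is a 1-based rank in the
    hierarchical skill ordering (1 = PV niveau 2+, 2 = PV niveau 3,
    3 = VP niveau 3 in the study setting). Coordinates, when present, are
    planar km.
    """

    client_id: str
    team_id: str
    date: _dt.date
    day_part: str
    duration: float
    qualification_level: int
    x: float | None = None
    y: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.day_part not in DAY_PARTS:
            raise ValueError(f"day_part must be one of {DAY_PARTS}")
        if self.qualification_level < 1:
            raise ValueError("qualification_level must be >= 1")


@dataclass(frozen=True)
class TeamParameters:
    """One row of the team-parameter table.

    ``mean_demand`` is the average weekly care volume rho (hours/week);
    ``m_a``/``vmr_a`` the mean and variance-to-mean ratio of weekly new-case
    arrivals; ``m_g``/``vmr_g`` the mean and VMR of weekly hours per case;
    ``gini_s`` the Gini coefficient of the length of stay; ``m_s_implied``
    the implied mean length of stay rho / (m_a * m_g) in weeks.
    """

    team_id: str
    mean_demand: float
    m_a: float
    vmr_a: float
    m_g: float
    vmr_g: float
    gini_s: float
    m_s_implied: float

    def __post_init__(self) -> None:
        for name in ("mean_demand", "m_a", "vmr_a", "m_g", "vmr_g",
                     "m_s_implied"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.gini_s < 1:
            raise ValueError(f"gini_s must be in [0, 1), got {self.gini_s}")


# Parameter table of the nine teams selected for the merging study:
# (team_id, mean_demand, m_a, vmr_a, m_g, vmr_g, gini_s, m_s_implied).
TEAM_TABLE_BUILTIN: tuple[tuple, ...] = (
    ("2", 183.46, 1.99, 1.10, 3.61, 3.18, 0.79, 25.50),
    ("5", 132.30, 1.58, 1.30, 3.00, 3.72, 0.74, 27.93),
    ("9", 206.06, 3.69, 1.12, 3.24, 3.13, 0.78, 17.25),
    ("11", 125.41, 2.43, 1.64, 3.06, 1.97, 0.79, 16.85),
    ("15", 211.13, 3.06, 1.28, 2.78, 2.15, 0.77, 24.81),
    ("38", 268.71, 3.64, 1.78, 3.82, 3.23, 0.81, 19.32),
    ("39", 159.07, 3.49, 1.68, 2.68, 2.51, 0.78, 17.03),
    ("40", 265.53, 3.04, 1.19, 3.60, 3.50, 0.75, 24.29),
    ("41", 290.75, 5.33, 0.90, 3.31, 3.44, 0.82, 16.49),
)


def read_visits(path: str | Path, *, n_levels: int = 3,
                **csv_options) -> list[VisitRecord]:
    """Read a visits CSV into validated records.

    The file must carry the columns ``client_id, team_id, date, day_part,
    duration_hours, qualification_level`` (optionally ``x_km, y_km``); rows
    are returned sorted by (client_id, qualification_level, date). A missing
    column raises :class:`VisitFormatError`; invalid rows are collected and
    reported together in a :class:`VisitValidationError` with line numbers.
    """
    df = pd.read_csv(path, dtype={"client_id": str, "team_id": str},
                     **csv_options)
    for col in VISIT_COLUMNS:
        if col not in df.columns:
            raise VisitFormatError(f"missing required column {col!r}")
    has_xy = all(c in df.columns for c in VISIT_OPTIONAL_COLUMNS)

    records: list[VisitRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            date = _dt.date.fromisoformat(str(row.date))
        except ValueError:
            errors.append((line, f"unparseable date {row.date!r}"))
            continue
        try:
            duration = float(row.duration_hours)
        except (TypeError, ValueError):
            errors.append((line, f"unparseable duration {row.duration_hours!r}"))
            continue
        x = float(row.x_km) if has_xy and pd.notna(row.x_km) else None
        y = float(row.y_km) if has_xy and pd.notna(row.y_km) else None
        try:
            records.append(VisitRecord(
                client_id=str(row.client_id),
                team_id=str(row.team_id),
                date=date,
                day_part=str(row.day_part),
                duration=duration,
                qualification_level=int(row.qualification_level),
                x=x,
                y=y,
            ))
        except ValueError as exc:
            errors.append((line, str(exc)))
            continue
        if records[-1].qualification_level > n_levels:
            errors.append((line, f"qualification_level > {n_levels}"))
            records.pop()
    if errors:
        raise VisitValidationError(errors)
    records.sort(key=lambda r: (r.client_id, r.qualification_level, r.date))
    return records


def write_visits(records: Iterable[VisitRecord], path: str | Path) -> None:
    """Write visit records to CSV in the canonical column order."""
    rows = []
    for r in records:
        row = {
            "client_id": r.client_id,
            "team_id": r.team_id,
            "date": r.date.isoformat(),
            "day_part": r.day_part,
            "duration_hours": r.duration,
            "qualification_level": r.qualification_level,
        }
        if r.x is not None:
            row["x_km"] = r.x
            row["y_km"] = r.y
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_team_parameters(path: str | Path | None = None) -> list[TeamParameters]:
    """Load a team-parameter table; ``path=None`` returns the built-in table.

    The built-in table holds the nine teams of the merging study. Any loaded
    row is validated (positive parameters, Gini in [0, 1)).
    """
    if path is None:
        return [TeamParameters(*row) for row in TEAM_TABLE_BUILTIN]
    df = pd.read_csv(path, dtype={"team_id": str})
    required = ("team_id", "mean_demand", "m_a", "vmr_a", "m_g", "vmr_g",
                "gini_s", "m_s_implied")
    for col in required:
        if col not in df.columns:
            raise VisitFormatError(f"missing required column {col!r}")
    return [
        TeamParameters(str(row.team_id), float(row.mean_demand),
                       float(row.m_a), float(row.vmr_a), float(row.m_g),
                       float(row.vmr_g), float(row.gini_s),
                       float(row.m_s_implied))
        for row in df.itertuples(index=False)
    ]


def write_team_parameters(teams: Sequence[TeamParameters],
                          path: str | Path) -> None:
    """Write a team-parameter table to CSV."""
    pd.DataFrame([{
        "team_id": t.team_id, "mean_demand": t.mean_demand, "m_a": t.m_a,
        "vmr_a": t.vmr_a, "m_g": t.m_g, "vmr_g": t.vmr_g,
        "gini_s": t.gini_s, "m_s_implied": t.m_s_implied,
    } for t in teams]).to_csv(path, index=False)


#: Policy constants used across the principles, with the study's defaults:
#: grade of service gamma, presence probability p, skill-mix safety factor
#: eta_alpha, direct-care hours per worker per week, contract shape
#: parameters, travel constants, and merging-objective weights.
DEFAULT_CONFIG: dict = {
    "gamma": 1.0,
    "p_present": 0.79,
    "eta_alpha": 2.0,
    "hours_per_worker": 20.0,
    "contract": {"a": 1.5, "b_ft": 8.0, "b_pt": 5.0},
    "travel": {"k_l": 0.5, "k_c": 2.0},
    "objective": {"lambda1": 1.0, "lambda3": 1.0, "lambda4": 1.0,
                  "lambda6": 1e-3, "l_threshold": 0.6},
}


def load_config(path: str | Path | None = None) -> dict:
    """Load the YAML policy config, merged over :data:`DEFAULT_CONFIG`."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg
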