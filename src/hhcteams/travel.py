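"""Square-root tour-length approximation for daily care routes.

The total distance of ``M`` efficient routes visiting ``n`` clients in an
area of ``A`` km² from a central location at mean client distance ``rbar``
is approximately ``k_l sqrt(A n) + k_c rbar M`` (empirical constants
``k_l`` in [0.44, 0.59], ``k_c`` near 2). Two scenario variants quantify
that merging identical regions yields no travel gain (the length is exactly
R times one region's) while pre-assigning clients to individual workers
inflates the touring term by ``sqrt(M)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TravelScenario:
    """One day part of routing: area (km²), client visits ``n`` (repeat
    visits count), workers/routes ``M``, mean depot distance ``rbar`` (km),
    and the approximation constants."""

    area: float
    clients: int
    workers: int = 1
    depot_distance: float = 0.0
    k_l: float = 0.5
    k_c: float = 2.0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.clients < 0:
            raise ValueError("clients must be >= 0")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.depot_distance < 0:
            raise ValueError("depot_distance must be >= 0")
        if not 0.4 <= self.k_l <= 0.6:
            warnings.warn(f"k_l = {self.k_l} lies outside the empirically "
                          "supported range [0.4, 0.6]", stacklevel=2)


def route_length(s: TravelScenario) -> float:
    """Total route length ``k_l sqrt(A n) + k_c rbar M`` in km."""
    return (s.k_l * np.sqrt(s.area * s.clients)
            + s.k_c * s.depot_distance * s.workers)


def merged_route_length(s: TravelScenario, regions: int) -> float:
    """Total route length after merging ``R`` identical regions.

    With area, clients and workers all scaled by R and the depot distance
    unchanged, this is exactly ``R * route_length(s)`` — no economies of
    scale in travel.
    """
    if regions < 1 or regions != int(regions):
        raise ValueError("regions must be a positive integer")
    r = int(regions)
    return (s.k_l * np.sqrt((s.area * r) * (s.clients * r))
            + s.k_c * s.depot_distance * s.workers * r)


def individual_routes_length(s: TravelScenario) -> float:
    """Total route length when the n clients are pre-assigned randomly to
    the M workers, each touring their own clients over the whole area:
    ``M (k_l sqrt(A n / M) + k_c rbar) = sqrt(M) k_l sqrt(A n)
    + M k_c rbar`` — a ``sqrt(M)`` touring penalty for continuity of care.
    """
    return s.workers * (s.k_l * np.sqrt(s.area * s.clients / s.workers)
                        + s.k_c * s.depot_distance)
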