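"""Full-factorial experimentation over the simulator.

Factors map named capacities (TriageBed, ZoneNurse, ZoneBed — or the
explicit five-pool names for a joint design) onto scenario resource
counts.  Every design point is simulated with the same seed so that
points share common random numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .config import ScenarioConfig
from .kpi import zone_kpis, NoDataError
from .simulator import run_scenario

__all__ = [
    "Factor",
    "DesignPoint",
    "DesignError",
    "full_factorial",
    "run_design",
    "default_factors",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class Factor:
    """One experimental factor with ordered capacity levels."""

    name: str
    levels: Tuple[float, ...]
    coding: str = "raw"

    def __post_init__(self):
        if len(set(self.levels)) < 2:
            raise DesignError(f"factor {self.name!r} needs >= 2 distinct levels")
        if list(self.levels) != sorted(self.levels):
            raise DesignError(f"levels of {self.name!r} must be strictly increasing")
        if self.coding not in ("raw", "coded"):
            raise DesignError(f"unknown coding {self.coding!r}")


@dataclass(frozen=True)
class DesignPoint:
    id: int
    assignment: Tuple[Tuple[str, float], ...]  # ordered (factor, level) pairs

    @property
    def levels(self) -> Dict[str, float]:
        return dict(self.assignment)


#: published 3-level capacity grids per factor role
TABLE_LEVELS = {
    ("ZoneNurse", "adult"): (7, 9, 11),
    ("ZoneNurse", "peds"): (5, 7, 9),
    ("ZoneBed", "adult"): (20, 26, 32),
    ("ZoneBed", "peds"): (8, 10, 12),
    ("TriageBed", None): (1, 2, 3),
}

#: factor name -> resource key (zone-generic names resolved at run time)
_FACTOR_KEYS = {
    "TriageBed": "triage_room",
    "ZoneNurse": "{zone}_nurse",
    "ZoneBed": "{zone}_bed",
    "AdultNurse": "adult_nurse",
    "PedsNurse": "peds_nurse",
    "AdultBed": "adult_bed",
    "PedsBed": "peds_bed",
}


def default_factors(zone: str = "adult") -> List[Factor]:
    """The per-zone 3-factor, 3-level design (27 points)."""
    return [
        Factor("TriageBed", TABLE_LEVELS[("TriageBed", None)]),
        Factor("ZoneNurse", TABLE_LEVELS[("ZoneNurse", zone)]),
        Factor("ZoneBed", TABLE_LEVELS[("ZoneBed", zone)]),
    ]


def full_factorial(factors: Sequence[Factor]) -> List[DesignPoint]:
    """Cartesian product of factor levels in lexicographic order
    (first factor slowest, last factor fastest)."""
    factors = list(factors)
    if not factors:
        raise DesignError("need at least one factor")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise DesignError(f"duplicate factor names in {names}")
    points = []
    for i, combo in enumerate(itertools.product(*(f.levels for f in factors))):
        points.append(DesignPoint(id=i, assignment=tuple(zip(names, combo))))
    return points


def _apply_point(base: ScenarioConfig, point: DesignPoint, zone: str) -> ScenarioConfig:
    cfg = base.copy()
    for name, level in point.assignment:
        if name not in _FACTOR_KEYS:
            raise DesignError(f"no resource mapping for factor {name!r}")
        key = _FACTOR_KEYS[name].format(zone=zone)
        if level < 0 or int(level) != level:
            raise DesignError(
                f"infeasible capacity {level!r} for {name!r} at design point {point.id}"
            )
        cfg.resources[key] = int(level)
    cfg.validate()
    return cfg


def run_design(
    points: Iterable[DesignPoint],
    base_config: ScenarioConfig,
    replications: Optional[int] = None,
    seed: Optional[int] = None,
    zone: str = "adult",
    responses: Sequence[str] = ("AtD", "LOS"),
) -> pd.DataFrame:
    """Simulate every design point and collect per-replication responses.

    Every point runs with the same seed (common random numbers).  The
    returned frame has one row per (point, replication) with columns:
    ``point_id``, one column per factor, ``replication``, ``zone`` and
    one column per requested response (post-warm-up zone means).
    """
    points = list(points)
    rows = []
    for point in points:
        cfg = _apply_point(base_config, point, zone)
        if replications is not None:
            cfg.replications = replications
        if seed is not None:
            cfg.seed = seed
        logs = run_scenario(cfg)
        for rep, log in enumerate(logs):
            try:
                k = zone_kpis(log, zone)
            except NoDataError:
                continue
            row = {"point_id": point.id, **point.levels, "replication": rep, "zone": zone}
            for resp in responses:
                row[resp] = k[resp]
            rows.append(row)
    if not rows:
        raise DesignError("design produced no responses")
    return pd.DataFrame(rows)
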