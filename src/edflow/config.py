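"""Scenario configuration: resource capacities, service laws, arrival
profile, routing probabilities and run controls, with YAML/JSON I/O."""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import yaml

from .distributions import DistributionSpec, parse_distribution


class ConfigError(ValueError):
    """Invalid scenario configuration."""


#: Service-time laws for every task of the pathway, in the string grammar
#: of :mod:`edflow.distributions`.  Times are minutes.
DEFAULT_SERVICE_TIMES: Dict[str, str] = {
    "registration": "TRI(2, 3, 5)",
    "triage": "1 + 2 * Gamma(0.1, 2.5, 2.5)",
    "triage_notes": "1.7 * TRIA(1, 0.3, 10.1)",
    "consult_notes": "LogNORM(1.3, 2, 1)",
    "consult_exam": "LogNORM(0.5, 1, 5.5)",
    "nurse_notes": "Gamma(0.77, 0.4667, 13.24)",
    "test_ct": "TRIA(5, 10, 15)",
    "test_delay": "Gamma(0.77, 0.446, 14)",
    "test_xray": "TRIA(5, 7, 10)",
    "test_lab": "TRIA(5, 7, 10)",
    "reassess_exam": "LogNORM(0.5, 1, 5.5)",
    "reassess_notes": "LogNORM(0.1, 1, 2)",
    "reassess_nurse_notes": "Gamma(0.77, 0.4667, 13.24)",
    "discharge_notes": "LogNORM(0.1, 1, 2)",
    "discharge": "TRIA(10, 20, 30)",
    "discharge_delay": "LogNORM(1, 2, 4.5)",
    # used only by the single-stage queueing reduction
    "single_stage_consult": "EXPO(20)",
}

#: Baseline capacities.  Nurse and bed counts are the documented Level-0
#: scenario values; physician/registration/technician counts are not
#: published and are calibratable defaults.
DEFAULT_RESOURCES: Dict[str, int] = {
    "registration_agent": 2,
    "triage_room": 2,
    "triage_nurse": 2,
    "technician": 2,
    "adult_physician": 4,
    "peds_physician": 2,
    "adult_nurse": 7,
    "peds_nurse": 5,
    "adult_bed": 20,
    "peds_bed": 8,
}

DEFAULT_TEST_PROBS: Dict[str, float] = {
    "ct": 0.25,
    "xray": 0.25,
    "lab": 0.30,
    "none": 0.20,
}

ZONES = ("adult", "peds")


def default_arrival_profile() -> List[float]:
    """Smooth unimodal 24-hour profile (patients/hour), mid-day peak."""
    from .synth import generate_arrival_profile

    return [float(r) for r in generate_arrival_profile(total_per_day=80, peak_hour=11, ratio=3.0)]


@dataclass
class ScenarioConfig:
    """Full description of one simulation scenario.

    Attributes
    ----------
    arrival_profile : list of 24 floats
        Hourly arrival rates (patients/hour), indexed by hour of day.
    arrival_scale : float
        Global multiplier on the profile (a calibration knob).
    p_peds, p_esi3 : float
        Zone mix P(pediatric) and acuity mix P(ESI 3) for new arrivals.
    test_probs : dict
        Routing mix over {ct, xray, lab, none}; must sum to 1.
    reassess_extra_prob : float
        Probability of each additional reassessment pass beyond the
        first (0 = exactly one pass).
    resources : dict
        Capacity per pool; keys as in :data:`DEFAULT_RESOURCES`.
    schedules : dict, optional
        Per-pool shift roster ``{pool: [(start_hour, end_hour, capacity), ...]}``
        overriding the flat capacity during the given windows.
    service_times : dict
        Task -> distribution string.
    pathway : str
        ``"full"`` for the complete pathway, ``"single_stage"`` for the
        M/M/c reduction (arrive -> physician -> discharge).
    horizon_days, warmup_days : float
    replications : int
    seed : int
    queue_warning_cap : int
        Queue length above which an unbounded-queue warning is recorded.
    """

    arrival_profile: List[float] = field(default_factory=default_arrival_profile)
    arrival_scale: float = 1.0
    p_peds: float = 0.3
    p_esi3: float = 0.5
    test_probs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TEST_PROBS))
    reassess_extra_prob: float = 0.0
    max_reassess: int = 3
    resources: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_RESOURCES))
    schedules: Optional[Dict[str, List[Tuple[float, float, int]]]] = None
    service_times: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SERVICE_TIMES)
    )
    pathway: str = "full"
    horizon_days: float = 14.0
    warmup_days: float = 1.0
    replications: int = 10
    seed: int = 0
    queue_warning_cap: int = 1000

    def __post_init__(self):
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if len(self.arrival_profile) != 24:
            raise ConfigError("arrival_profile must have 24 hourly rates")
        if any(r < 0 for r in self.arrival_profile):
            raise ConfigError("arrival rates must be nonnegative")
        if self.arrival_scale < 0:
            raise ConfigError("arrival_scale must be nonnegative")
        for name, p in (("p_peds", self.p_peds), ("p_esi3", self.p_esi3)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        total = sum(self.test_probs.values())
        if any(p < 0 for p in self.test_probs.values()) or total > 1.0 + 1e-9:
            raise ConfigError("test_probs must be nonnegative and sum to <= 1")
        if not 0.0 <= self.reassess_extra_prob < 1.0:
            raise ConfigError("reassess_extra_prob must be in [0, 1)")
        for key, cap in self.resources.items():
            if key not in DEFAULT_RESOURCES:
                raise ConfigError(f"unknown resource pool {key!r}")
            if int(cap) != cap or cap < 0:
                raise ConfigError(f"capacity for {key!r} must be a nonnegative integer")
        if self.pathway not in ("full", "single_stage"):
            raise ConfigError(f"unknown pathway {self.pathway!r}")
        if self.warmup_days < 0 or self.horizon_days <= self.warmup_days:
            raise ConfigError("need horizon_days > warmup_days >= 0")
        if self.replications < 1:
            raise ConfigError("replications must be >= 1")

    # -- derived -------------------------------------------------------
    def parsed_service_times(self) -> Dict[str, DistributionSpec]:
        return {task: parse_distribution(s) for task, s in self.service_times.items()}

    def horizon_minutes(self) -> float:
        return self.horizon_days * 1440.0

    def warmup_minutes(self) -> float:
        return self.warmup_days * 1440.0

    def copy(self) -> "ScenarioConfig":
        return copy.deepcopy(self)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = {}
        for key in ("resources", "service_times", "test_probs"):
            if key in data:
                base = dict(getattr(cls(), key))
                base.update(data[key])
                merged[key] = base
        return cls(**{**data, **merged})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
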