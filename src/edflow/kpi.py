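"""KPIs from event logs and percentage-difference validation.

KPIs are mean durations in minutes: AtT (arrive to triage), AtD (arrive
to doctor), and stratified lengths of stay LOS1/LOS2.  Validation
compares simulated against reference means with the signed percentage
difference (simulated − real) / real × 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Union

import numpy as np
import pandas as pd

from .eventlog import EventLog

__all__ = [
    "KPISet",
    "ValidationRow",
    "ValidationReport",
    "NoDataError",
    "compute_kpis",
    "zone_kpis",
    "percentage_difference",
    "validate",
]

KPI_LABELS = ("AtT", "AtD", "LOS1", "LOS2")

#: stratum rule -> (column, value-for-LOS1, value-for-LOS2)
STRATUM_RULES = {
    "zone": ("zone", "adult", "peds"),
    "esi": ("esi", 3, 4),
    "status": ("status", "Discharged with approval", "Admitted"),
}


class NoDataError(RuntimeError):
    """No post-warm-up records to aggregate."""


@dataclass
class KPISet:
    """Mean KPIs (minutes) pooled over replications, with standard errors."""

    means: Dict[str, float]
    se: Dict[str, float] = field(default_factory=dict)
    n: Dict[str, int] = field(default_factory=dict)
    per_zone: Dict[str, Dict[str, float]] = field(default_factory=dict)
    stratum_rule: str = "zone"
    replications: int = 1

    def __getitem__(self, label: str) -> float:
        return self.means[label]

    def labels(self) -> List[str]:
        return list(self.means)


def _durations(records: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=records.index)
    out["AtT"] = records["triage"] - records["arrive"]
    out["AtD"] = records["doc"] - records["arrive"]
    out["LOS"] = records["discharge"] - records["arrive"]
    return out


def _mean_se(x: pd.Series):
    x = x.dropna()
    n = len(x)
    if n == 0:
        return math.nan, math.nan, 0
    se = float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return float(x.mean()), se, n


def compute_kpis(
    logs: Union[EventLog, Iterable[EventLog]],
    warmup_days: Optional[float] = None,
    stratum_rule: str = "zone",
) -> KPISet:
    """Pool per-patient durations across replications and average.

    Parameters
    ----------
    logs : EventLog or iterable of EventLog
    warmup_days : float, optional
        Drop patients arriving before this point.  Defaults to the
        ``warmup`` flag already carried by the records.
    stratum_rule : {"zone", "esi", "status"}
        How LOS1/LOS2 are stratified (default: LOS1 = adult zone,
        LOS2 = pediatric zone).

    Raises
    ------
    NoDataError
        If no records survive warm-up filtering.
    """
    if isinstance(logs, EventLog):
        logs = [logs]
    logs = list(logs)
    if not logs:
        raise NoDataError("no event logs supplied")
    if stratum_rule not in STRATUM_RULES:
        raise ValueError(f"unknown stratum rule {stratum_rule!r}")
    records = pd.concat([lg.records for lg in logs], ignore_index=True)
    if warmup_days is not None:
        keep = records["arrive"] >= warmup_days * 1440.0
    else:
        keep = ~records["warmup"].astype(bool)
    records = records[keep]
    if len(records) == 0:
        raise NoDataError("no records after warm-up filtering")

    dur = _durations(records)
    col, v1, v2 = STRATUM_RULES[stratum_rule]
    strata = records[col]

    means: Dict[str, float] = {}
    se: Dict[str, float] = {}
    n: Dict[str, int] = {}
    for label, series in (
        ("AtT", dur["AtT"]),
        ("AtD", dur["AtD"]),
        ("LOS1", dur["LOS"][strata == v1]),
        ("LOS2", dur["LOS"][strata == v2]),
    ):
        means[label], se[label], n[label] = _mean_se(series)

    per_zone: Dict[str, Dict[str, float]] = {}
    for zone in records["zone"].dropna().unique():
        sub = dur[records["zone"] == zone]
        per_zone[str(zone)] = {
            "AtT": float(sub["AtT"].mean()),
            "AtD": float(sub["AtD"].mean()),
            "LOS": float(sub["LOS"].mean()),
            "n": int(len(sub)),
        }

    return KPISet(
        means=means,
        se=se,
        n=n,
        per_zone=per_zone,
        stratum_rule=stratum_rule,
        replications=len(logs),
    )


def zone_kpis(log: EventLog, zone: str, warmup_days: Optional[float] = None) -> Dict[str, float]:
    """Mean AtT/AtD/LOS for one zone of one log (a DOE response row)."""
    records = log.records
    if warmup_days is not None:
        records = records[records["arrive"] >= warmup_days * 1440.0]
    else:
        records = records[~records["warmup"].astype(bool)]
    records = records[records["zone"] == zone]
    if len(records) == 0:
        raise NoDataError(f"no post-warm-up records for zone {zone!r}")
    dur = _durations(records)
    return {
        "AtT": float(dur["AtT"].mean()),
        "AtD": float(dur["AtD"].mean()),
        "LOS": float(dur["LOS"].mean()),
        "n": int(len(records)),
    }


def percentage_difference(simulated: float, real: float) -> float:
    """Signed percentage difference (simulated − real) / real × 100."""
    if real <= 0:
        raise ValueError(f"reference value must be positive, got {real!r}")
    return (simulated - real) / real * 100.0


@dataclass
class ValidationRow:
    variable: str
    real: float
    simulated: float
    pct_diff: float
    pct_diff_rounded: int

    @classmethod
    def build(cls, variable: str, real: float, simulated: float) -> "ValidationRow":
        d = percentage_difference(simulated, real)
        return cls(variable, real, simulated, d, int(round(d)))


@dataclass
class ValidationReport:
    rows: List[ValidationRow]
    threshold: float
    passed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "real": r.real,
                    "simulated": r.simulated,
                    "pct_diff": r.pct_diff,
                    "pct_diff_rounded": r.pct_diff_rounded,
                }
                for r in self.rows
            ]
        )


def validate(
    sim: Union[KPISet, Dict[str, float]],
    reference: Union[KPISet, Dict[str, float]],
    threshold: float = 5.0,
) -> ValidationReport:
    """One percentage-difference row per reference KPI.

    ``passed`` is True when every LOS row deviates by at most
    ``threshold`` percent in absolute value.
    """
    sim_means = sim.means if isinstance(sim, KPISet) else dict(sim)
    ref_means = reference.means if isinstance(reference, KPISet) else dict(reference)
    missing = [k for k in ref_means if k not in sim_means]
    if missing:
        raise KeyError(f"simulated KPIs missing labels {missing}")
    rows = [
        ValidationRow.build(label, float(ref_means[label]), float(sim_means[label]))
        for label in ref_means
    ]
    los_rows = [r for r in rows if r.variable.upper().startswith("LOS")]
    passed = all(abs(r.pct_diff) <= threshold for r in los_rows)
    return ValidationReport(rows=rows, threshold=threshold, passed=passed)
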