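"""Synthetic data with known ground truth.

Generates timestamp event logs in the eight-column CSV schema and
smooth 24-hour arrival-rate profiles, so the KPI, validation, DOE and
calibration layers are testable without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .config import ScenarioConfig
from .distributions import RandomStream
from .eventlog import EventLog
from .simulator import run_replication

__all__ = [
    "GroundTruth",
    "generate_arrival_profile",
    "generate_event_log",
    "no_contention_kpis",
]


def generate_arrival_profile(
    total_per_day: float, peak_hour: int = 11, ratio: float = 3.0
) -> np.ndarray:
    """Smooth unimodal 24-hour profile (patients/hour).

    A raised-cosine shape with its maximum at ``peak_hour`` and
    max/min rate ratio exactly ``ratio``, normalized so the 24 hourly
    rates sum to ``total_per_day``.
    """
    if total_per_day <= 0:
        raise ValueError("total_per_day must be positive")
    if ratio < 1:
        raise ValueError("peak-to-trough ratio must be >= 1")
    if not 0 <= peak_hour <= 23:
        raise ValueError("peak_hour must be in 0..23")
    hours = np.arange(24)
    shape = 1.0 + (ratio - 1.0) * (1.0 + np.cos(2.0 * np.pi * (hours - peak_hour) / 24.0)) / 2.0
    return shape * (total_per_day / shape.sum())


@dataclass
class GroundTruth:
    """What generated a synthetic log: config, seed and reference means."""

    config: Dict
    seed: int
    n_patients: int
    realized_kpis: Dict[str, float]
    no_contention_kpis: Optional[Dict[str, float]] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "n_patients": self.n_patients,
                    "realized_kpis": self.realized_kpis,
                    "no_contention_kpis": self.no_contention_kpis,
                },
                fh,
                indent=2,
                default=str,
            )


def no_contention_kpis(
    config: ScenarioConfig, n_mc: int = 20000, seed: int = 0
) -> Dict[str, float]:
    """Monte-Carlo long-run means assuming zero queueing.

    With ample resources AtT is the triage wait (zero), AtD is the time
    until both the registration and the triage branch have finished,
    and LOS adds the consult/notes/test/reassessment/discharge stages.
    Used as an analytic-ish oracle for generated logs.
    """
    dists = config.parsed_service_times()
    rng = RandomStream(seed, "no_contention")

    def draw(task, size):
        return rng.draw(dists[task], size=size)

    reg = draw("registration", n_mc)
    triage = draw("triage", n_mc) + draw("triage_notes", n_mc)
    to_bed = np.maximum(reg, triage)
    consult = draw("consult_notes", n_mc) + draw("consult_exam", n_mc)
    nurse = draw("nurse_notes", n_mc)

    u = rng.rng.uniform(size=n_mc)
    p_ct = config.test_probs.get("ct", 0)
    p_xr = config.test_probs.get("xray", 0)
    p_lab = config.test_probs.get("lab", 0)
    test = np.zeros(n_mc)
    delay = draw("test_delay", n_mc)
    for lo, hi, task in (
        (0.0, p_ct, "test_ct"),
        (p_ct, p_ct + p_xr, "test_xray"),
        (p_ct + p_xr, p_ct + p_xr + p_lab, "test_lab"),
    ):
        mask = (u >= lo) & (u < hi)
        test[mask] = draw(task, n_mc)[mask] + delay[mask]

    reassess = (
        draw("reassess_exam", n_mc)
        + draw("reassess_notes", n_mc)
        + draw("reassess_nurse_notes", n_mc)
    )
    discharge = (
        draw("discharge_notes", n_mc) + draw("discharge", n_mc) + draw("discharge_delay", n_mc)
    )
    los = to_bed + consult + nurse + test + reassess + discharge
    return {
        "AtT": 0.0,
        "AtD": float(to_bed.mean()),
        "LOS": float(los.mean()),
    }


def generate_event_log(
    config: ScenarioConfig, n_patients: int, seed: Optional[int] = None
):
    """Simulate until ``n_patients`` have discharged and return
    ``(EventLog, GroundTruth)``.

    The log keeps the first ``n_patients`` discharges in discharge
    order; ``n_patients=0`` yields an empty, schema-valid log.
    Regeneration with the same config and seed is byte-identical.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    cfg = config.copy()
    if seed is not None:
        cfg.seed = seed

    # stretch the horizon until enough patients discharge (or give up)
    daily = sum(cfg.arrival_profile) * cfg.arrival_scale
    if daily > 0:
        need_days = max(cfg.horizon_days, n_patients / daily * 1.5 + 1.0)
        cfg.horizon_days = max(need_days, cfg.warmup_days + 1.0)
    log = run_replication(cfg, 0)
    records = log.records.sort_values("discharge", kind="mergesort").head(n_patients)
    records = records.reset_index(drop=True)
    out = EventLog(records=records, meta=dict(log.meta, requested_n=n_patients))

    if len(records):
        realized = {
            "AtT": float((records["triage"] - records["arrive"]).mean()),
            "AtD": float((records["doc"] - records["arrive"]).mean()),
            "LOS": float((records["discharge"] - records["arrive"]).mean()),
        }
    else:
        realized = {}
    truth = GroundTruth(
        config=cfg.to_dict(),
        seed=cfg.seed,
        n_patients=len(records),
        realized_kpis=realized,
        no_contention_kpis=no_contention_kpis(cfg) if cfg.pathway == "full" else None,
    )
    return out, truth
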