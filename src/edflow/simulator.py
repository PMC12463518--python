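"""Event-driven simulation of the two-zone ED pathway.

Patients arrive by a non-homogeneous Poisson process, then flow through
registration and triage (parallel branches), bed placement, physician
consultation, nurse notes, optional imaging/lab tests, reassessment and
a discharge process, competing for seven capacity-constrained resource
pools.  Milestone timestamps (arrive, reg, triage, bed, doc, discharge)
are emitted per discharged patient.

Service times for every task are pre-drawn per patient in arrival order
from one named random substream per (task, zone) pair, so that design
points sharing a seed see common random numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional

import numpy as np

from . import des
from .config import ScenarioConfig, ZONES
from .distributions import DistributionSpec, RandomStream
from .eventlog import EventLog, records_from_patients

__all__ = [
    "Arrival",
    "Patient",
    "UnboundedQueueWarning",
    "generate_arrivals",
    "run_replication",
    "run_scenario",
]


class UnboundedQueueWarning(UserWarning):
    """A resource queue exceeded the configured cap during a run."""


class Arrival(NamedTuple):
    time: float  # minutes since start
    zone: str
    esi: int


@dataclass
class Patient:
    """One simulated patient: identity, pre-drawn durations, milestones."""

    id: int
    zone: str
    esi: int
    arrival: float
    durations: Dict[str, float] = field(default_factory=dict)
    test_route: str = "none"
    n_reassess: int = 1
    times: Dict[str, Optional[float]] = field(default_factory=dict)
    status: str = "Discharged with approval"

    def record(self) -> dict:
        rec = {k: self.times.get(k) for k in ("arrive", "reg", "triage", "bed", "doc", "discharge")}
        rec.update(zone=self.zone, esi=self.esi, status=self.status, warmup=False)
        return rec


# ---------------------------------------------------------------------------
# arrivals
# ---------------------------------------------------------------------------

def generate_arrivals(
    profile,
    horizon_days: float,
    stream: RandomStream,
    p_peds: float = 0.3,
    p_esi3: float = 0.5,
    scale: float = 1.0,
) -> List[Arrival]:
    """Sample a non-homogeneous Poisson arrival sequence by inversion.

    ``profile`` holds 24 hourly rates (patients/hour) cycled over the
    horizon; ``scale`` multiplies the whole profile.  Unit-rate Poisson
    points are mapped through the inverse cumulative rate, so the same
    stream yields smoothly co-varying arrival times as the scale or
    profile changes (common random numbers across scenarios).  Zone and
    acuity marks come from a derived substream, keeping the k-th
    patient's identity stable.  Times are strictly increasing.
    """
    rates = [float(r) * scale for r in profile]
    if len(rates) != 24 or any(r < 0 for r in rates):
        raise ValueError("profile must be 24 nonnegative hourly rates")
    if max(rates) == 0:
        return []
    horizon = horizon_days * 1440.0
    n_hours = int(np.ceil(horizon / 60.0))
    widths = np.full(n_hours, 60.0)
    widths[-1] = horizon - 60.0 * (n_hours - 1)
    seg_rates = np.array([rates[k % 24] for k in range(n_hours)])
    cum = np.concatenate([[0.0], np.cumsum(seg_rates * widths / 60.0)])
    total = float(cum[-1])
    if total == 0:
        return []

    rng = stream.rng
    gammas_parts = []
    level = 0.0
    while level < total:
        block = rng.exponential(1.0, size=max(64, int(total - level) + 40))
        g = level + np.cumsum(block)
        gammas_parts.append(g)
        level = float(g[-1])
    gammas = np.concatenate(gammas_parts)
    gammas = gammas[gammas < total]

    idx = np.searchsorted(cum, gammas, side="right") - 1
    ok = seg_rates[idx] > 0  # guards the measure-zero boundary hit
    idx, gammas = idx[ok], gammas[ok]
    times = 60.0 * idx + (gammas - cum[idx]) / seg_rates[idx] * 60.0

    marks = RandomStream(stream.seed, stream.stream_id + "/marks").rng
    u_zone = marks.uniform(size=len(times))
    u_esi = marks.uniform(size=len(times))
    return [
        Arrival(float(t), "peds" if uz < p_peds else "adult", 3 if ue < p_esi3 else 4)
        for t, uz, ue in zip(times, u_zone, u_esi)
    ]


# ---------------------------------------------------------------------------
# per-patient duration bundles (common random numbers)
# ---------------------------------------------------------------------------

class _StreamSet:
    """Lazy cache of per-(task, zone, replication) substreams."""

    def __init__(self, seed: int, rep: int):
        self.seed = seed
        self.rep = rep
        self._cache: Dict[str, RandomStream] = {}

    def get(self, task: str, zone: str = "shared") -> RandomStream:
        key = f"{task}/{zone}/rep{self.rep}"
        if key not in self._cache:
            self._cache[key] = RandomStream(self.seed, key)
        return self._cache[key]

    def truncation_total(self) -> int:
        return sum(s.truncated for s in self._cache.values())


_TEST_TASK = {"ct": "test_ct", "xray": "test_xray", "lab": "test_lab"}


def _draw_bundle(
    patient: Patient,
    cfg: ScenarioConfig,
    dists: Dict[str, DistributionSpec],
    streams: _StreamSet,
) -> None:
    """Pre-draw every duration and routing decision for one patient.

    Draws happen in arrival order from fixed per-(task, zone) streams,
    which pins the k-th patient's service realizations across scenarios
    that share a seed (common random numbers).
    """
    z = patient.zone
    d = patient.durations

    if cfg.pathway == "single_stage":
        d["single_stage_consult"] = streams.get("single_stage_consult", z).draw(
            dists["single_stage_consult"]
        )
        return

    d["registration"] = streams.get("registration", z).draw(dists["registration"])
    d["triage"] = streams.get("triage", z).draw(dists["triage"])
    d["triage_notes"] = streams.get("triage_notes", z).draw(dists["triage_notes"])
    d["consult_notes"] = streams.get("consult_notes", z).draw(dists["consult_notes"])
    d["consult_exam"] = streams.get("consult_exam", z).draw(dists["consult_exam"])
    d["nurse_notes"] = streams.get("nurse_notes", z).draw(dists["nurse_notes"])

    u = streams.get("test_route", z).rng.uniform()
    cum = 0.0
    patient.test_route = "none"
    for kind in ("ct", "xray", "lab"):
        cum += cfg.test_probs.get(kind, 0.0)
        if u < cum:
            patient.test_route = kind
            break
    # draw test durations regardless of route to keep streams aligned
    d["test_ct"] = streams.get("test_ct", z).draw(dists["test_ct"])
    d["test_xray"] = streams.get("test_xray", z).draw(dists["test_xray"])
    d["test_lab"] = streams.get("test_lab", z).draw(dists["test_lab"])
    d["test_delay"] = streams.get("test_delay", z).draw(dists["test_delay"])

    loop = streams.get("reassess_loop", z)
    n = 1
    while (
        n < cfg.max_reassess
        and cfg.reassess_extra_prob > 0
        and loop.rng.uniform() < cfg.reassess_extra_prob
    ):
        n += 1
    patient.n_reassess = n
    passes = []
    for i in range(cfg.max_reassess):
        total = (
            streams.get("reassess_exam", z).draw(dists["reassess_exam"])
            + streams.get("reassess_notes", z).draw(dists["reassess_notes"])
            + streams.get("reassess_nurse_notes", z).draw(dists["reassess_nurse_notes"])
        )
        passes.append(total)
    d["reassess_passes"] = passes

    d["discharge_total"] = (
        streams.get("discharge_notes", z).draw(dists["discharge_notes"])
        + streams.get("discharge", z).draw(dists["discharge"])
        + streams.get("discharge_delay", z).draw(dists["discharge_delay"])
    )


# ---------------------------------------------------------------------------
# resource pools
# ---------------------------------------------------------------------------

class _Pools:
    """Resource pools for one replication."""

    def __init__(self, env: des.Environment, cfg: ScenarioConfig):
        r = cfg.resources
        self.registration = des.Resource(env, r["registration_agent"], "registration_agent")
        self.triage_room = des.Resource(env, r["triage_room"], "triage_room")
        self.triage_nurse = des.Resource(env, r["triage_nurse"], "triage_nurse")
        self.technician = des.Resource(env, r["technician"], "technician")
        self.physician = {z: des.Resource(env, r[f"{z}_physician"], f"{z}_physician") for z in ZONES}
        self.nurse = {z: des.Resource(env, r[f"{z}_nurse"], f"{z}_nurse") for z in ZONES}
        self.bed = {z: des.Resource(env, r[f"{z}_bed"], f"{z}_bed") for z in ZONES}
        if cfg.schedules:
            for pool_name, roster in cfg.schedules.items():
                env.process(self._roster_proc(env, self._by_name(pool_name), roster, cfg))

    def _by_name(self, name: str) -> des.Resource:
        flat = {
            "registration_agent": self.registration,
            "triage_room": self.triage_room,
            "triage_nurse": self.triage_nurse,
            "technician": self.technician,
        }
        if name in flat:
            return flat[name]
        zone, kind = name.split("_", 1)
        return {"physician": self.physician, "nurse": self.nurse, "bed": self.bed}[kind][zone]

    @staticmethod
    def _roster_proc(env, resource, roster, cfg):
        """Cycle daily through (start_hour, end_hour, capacity) windows."""
        events = sorted((float(s), int(c)) for s, _e, c in roster)
        while env.now < cfg.horizon_minutes():
            day_start = (env.now // 1440.0) * 1440.0
            for start_h, cap in events:
                at = day_start + start_h * 60.0
                if at >= env.now:
                    yield env.timeout(at - env.now)
                    resource.set_capacity(cap)
            yield env.timeout(day_start + 1440.0 - env.now)

    def all_pools(self) -> Dict[str, des.Resource]:
        out = {
            "registration_agent": self.registration,
            "triage_room": self.triage_room,
            "triage_nurse": self.triage_nurse,
            "technician": self.technician,
        }
        for z in ZONES:
            out[f"{z}_physician"] = self.physician[z]
            out[f"{z}_nurse"] = self.nurse[z]
            out[f"{z}_bed"] = self.bed[z]
        return out


# ---------------------------------------------------------------------------
# patient pathway
# ---------------------------------------------------------------------------

def _registration_branch(env, p: Patient, pools: _Pools):
    yield pools.registration.request()
    yield env.timeout(p.durations["registration"])
    pools.registration.release()
    p.times["reg"] = env.now


def _triage_branch(env, p: Patient, pools: _Pools):
    yield pools.triage_room.request()
    yield pools.triage_nurse.request()
    p.times["triage"] = env.now  # triage begins
    yield env.timeout(p.durations["triage"])
    yield env.timeout(p.durations["triage_notes"])
    pools.triage_nurse.release()
    pools.triage_room.release()


def _full_pathway(env, p: Patient, pools: _Pools, done: list):
    p.times["arrive"] = env.now
    reg = env.process(_registration_branch(env, p, pools))
    tri = env.process(_triage_branch(env, p, pools))
    yield env.all_of([reg, tri])

    bed = pools.bed[p.zone]
    yield bed.request()
    p.times["bed"] = env.now

    physician = pools.physician[p.zone]
    nurse = pools.nurse[p.zone]

    # physician consultation (notes + exam), physician with zone nurse
    yield physician.request()
    yield nurse.request()
    p.times["doc"] = env.now
    yield env.timeout(p.durations["consult_notes"] + p.durations["consult_exam"])
    physician.release()
    nurse.release()

    # post-consult nurse notes
    yield nurse.request()
    yield env.timeout(p.durations["nurse_notes"])
    nurse.release()

    # optional tests: zone nurse + technician through test and result delay
    if p.test_route != "none":
        yield nurse.request()
        yield pools.technician.request()
        yield env.timeout(p.durations[_TEST_TASK[p.test_route]] + p.durations["test_delay"])
        pools.technician.release()
        nurse.release()

    # reassessment pass(es): physician + zone nurse at the bed
    for i in range(p.n_reassess):
        yield physician.request()
        yield nurse.request()
        yield env.timeout(p.durations["reassess_passes"][i])
        physician.release()
        nurse.release()

    # discharge process at the bed with the zone nurse
    yield nurse.request()
    yield env.timeout(p.durations["discharge_total"])
    nurse.release()
    bed.release()
    p.times["discharge"] = env.now
    done.append(p)


def _single_stage_pathway(env, p: Patient, pools: _Pools, done: list):
    """M/M/c reduction: arrive, queue for a physician, serve, leave."""
    p.times["arrive"] = env.now
    p.times["reg"] = env.now
    p.times["triage"] = env.now
    physician = pools.physician[p.zone]
    yield physician.request()
    p.times["bed"] = env.now
    p.times["doc"] = env.now
    yield env.timeout(p.durations["single_stage_consult"])
    physician.release()
    p.times["discharge"] = env.now
    done.append(p)


def _source_proc(env, arrivals, patients, pools, pathway, done):
    prev = 0.0
    for p, arr in zip(patients, arrivals):
        yield env.timeout(arr.time - prev)
        prev = arr.time
        env.process(pathway(env, p, pools, done))


# ---------------------------------------------------------------------------
# replication driver
# ---------------------------------------------------------------------------

def run_replication(config: ScenarioConfig, rep_index: int = 0) -> EventLog:
    """Run one replication and return its :class:`EventLog`.

    Replications differ only in substream offsets; identical
    ``(config, rep_index)`` reproduces the identical log.
    """
    cfg = config
    dists = cfg.parsed_service_times()
    streams = _StreamSet(cfg.seed, rep_index)

    arrivals = generate_arrivals(
        cfg.arrival_profile,
        cfg.horizon_days,
        streams.get("arrivals"),
        p_peds=cfg.p_peds,
        p_esi3=cfg.p_esi3,
        scale=cfg.arrival_scale,
    )

    env = des.Environment()
    pools = _Pools(env, cfg)

    patients = []
    for i, arr in enumerate(arrivals):
        p = Patient(id=i, zone=arr.zone, esi=arr.esi, arrival=arr.time)
        _draw_bundle(p, cfg, dists, streams)
        patients.append(p)

    pathway = _full_pathway if cfg.pathway == "full" else _single_stage_pathway
    done: List[Patient] = []
    env.process(_source_proc(env, arrivals, patients, pools, pathway, done))
    env.run(until=cfg.horizon_minutes())

    queue_warnings = {}
    for name, pool in pools.all_pools().items():
        if pool.max_queue > cfg.queue_warning_cap:
            queue_warnings[name] = pool.max_queue
    if queue_warnings:
        warnings.warn(
            f"queue length exceeded cap {cfg.queue_warning_cap}: {queue_warnings}",
            UnboundedQueueWarning,
            stacklevel=2,
        )

    records = records_from_patients([p.record() for p in done])
    if len(records):
        records["warmup"] = records["arrive"] < cfg.warmup_minutes()
    log = EventLog(
        records=records,
        meta={
            "seed": cfg.seed,
            "replication": rep_index,
            "config_hash": cfg.config_hash(),
            "n_arrivals": len(arrivals),
            "n_discharged": len(done),
            "n_in_system": len(arrivals) - len(done),
            "peak_users": {k: v.peak_users for k, v in pools.all_pools().items()},
            "max_queue": {k: v.max_queue for k, v in pools.all_pools().items()},
            "queue_warnings": queue_warnings,
            "truncated_variates": streams.truncation_total(),
        },
    )
    log.check_invariants()
    return log


def run_scenario(config: ScenarioConfig) -> List[EventLog]:
    """Run ``config.replications`` independent replications."""
    return [run_replication(config, rep) for rep in range(config.replications)]
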