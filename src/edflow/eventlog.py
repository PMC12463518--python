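"""Per-patient milestone logs and their CSV dialects.

The on-disk schema is the eight-column timestamp table
``Arrive,Reg,Triage,Bed,Doc,Discharge,Room,Discharge status`` with zone
labels ``Zone A`` (adult) and ``PEDS``.  Three timestamp dialects:

``minutes``
    Fractional minutes since simulation start (lossless; default for
    analysis round-trips).
``table``
    ``MM/DD H:MM`` minute-resolution style of the source logs (lossy).
``iso``
    ISO-8601 timestamps anchored at ``ANCHOR`` (lossless to seconds).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Dict, List

import pandas as pd

CSV_HEADER = ["Arrive", "Reg", "Triage", "Bed", "Doc", "Discharge", "Room", "Discharge status"]
MILESTONES = ["arrive", "reg", "triage", "bed", "doc", "discharge"]
ZONE_LABELS = {"adult": "Zone A", "peds": "PEDS"}
LABEL_ZONES = {v: k for k, v in ZONE_LABELS.items()}
DEFAULT_STATUS = "Discharged with approval"
ANCHOR = datetime(2022, 1, 1)

#: internal record columns, in order
RECORD_COLUMNS = MILESTONES + ["zone", "esi", "status", "warmup"]


class EventLogError(ValueError):
    pass


@dataclass
class EventLog:
    """Completed-patient milestone records plus run metadata.

    ``records`` columns are :data:`RECORD_COLUMNS`; milestone times are
    minutes since simulation start.  ``meta`` carries seed, replication
    index, config hash and bookkeeping counters.
    """

    records: pd.DataFrame
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise EventLogError(f"records missing columns {missing}")

    def __len__(self) -> int:
        return len(self.records)

    def check_invariants(self) -> None:
        """Raise if any record violates milestone monotonicity."""
        r = self.records
        if len(r) == 0:
            return
        ok = (
            (r["arrive"] <= r["triage"])
            & (r["triage"] <= r["bed"])
            & (r["bed"] <= r["doc"])
            & (r["doc"] <= r["discharge"])
            & (r["reg"] >= r["arrive"])
        )
        if not bool(ok.all()):
            bad = r.index[~ok].tolist()
            raise EventLogError(f"milestone monotonicity violated for records {bad}")
        if r[["arrive", "discharge"]].isna().any().any():
            raise EventLogError("records with missing arrive or discharge")


def _minutes_to_table(minutes: float) -> str:
    t = ANCHOR + timedelta(minutes=float(minutes))
    return f"{t.month:02d}/{t.day:02d} {t.hour}:{t.minute:02d}"


def _table_to_minutes(text: str) -> float:
    date_part, time_part = text.strip().split()
    month, day = (int(x) for x in date_part.split("/"))
    hour, minute = (int(x) for x in time_part.split(":"))
    t = datetime(ANCHOR.year, month, day, hour, minute)
    return (t - ANCHOR).total_seconds() / 60.0


def write_event_log(log: EventLog, path, dialect: str = "minutes") -> None:
    """Serialize to the eight-column CSV schema in the given dialect."""
    frame = pd.DataFrame(index=log.records.index)
    for col, ms in zip(CSV_HEADER[:6], MILESTONES):
        values = log.records[ms]
        if dialect == "minutes":
            frame[col] = values.map(lambda v: f"{v:.4f}")
        elif dialect == "table":
            frame[col] = values.map(_minutes_to_table)
        elif dialect == "iso":
            frame[col] = values.map(
                lambda v: (ANCHOR + timedelta(minutes=float(v))).isoformat()
            )
        else:
            raise EventLogError(f"unknown dialect {dialect!r}")
    frame["Room"] = log.records["zone"].map(ZONE_LABELS)
    frame["Discharge status"] = log.records["status"]
    frame.to_csv(path, index=False)


def _detect_dialect(token: str) -> str:
    if "T" in token:
        return "iso"
    if "/" in token:
        return "table"
    return "minutes"


def read_event_log(path) -> EventLog:
    """Read any dialect back into minute-resolution records."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != CSV_HEADER:
        raise EventLogError(
            f"unexpected header {list(frame.columns)}; want {CSV_HEADER}"
        )
    out = pd.DataFrame(index=frame.index, columns=RECORD_COLUMNS)
    if len(frame):
        dialect = _detect_dialect(frame.iloc[0, 0])
        for col, ms in zip(CSV_HEADER[:6], MILESTONES):
            if dialect == "minutes":
                out[ms] = frame[col].astype(float)
            elif dialect == "table":
                out[ms] = frame[col].map(_table_to_minutes)
            else:
                out[ms] = frame[col].map(
                    lambda s: (datetime.fromisoformat(s) - ANCHOR).total_seconds() / 60.0
                )
    out["zone"] = frame["Room"].map(lambda s: LABEL_ZONES.get(s, s))
    out["esi"] = pd.NA
    out["status"] = frame["Discharge status"]
    out["warmup"] = False
    return EventLog(records=out, meta={"source": str(path)})


def records_from_patients(patients: List[dict]) -> pd.DataFrame:
    """Assemble the records frame from per-patient dicts."""
    if not patients:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.DataFrame(patients, columns=RECORD_COLUMNS)


def event_log_csv_text(log: EventLog, dialect: str = "minutes") -> str:
    buf = io.StringIO()
    write_event_log(log, buf, dialect=dialect)
    return buf.getvalue()
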