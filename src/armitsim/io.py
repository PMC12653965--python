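"""Serialization of trial logs and scored tables.

The canonical on-disk form of a trial log is a flat delimited table,
one row per stage presentation, with columns::

    subject_id, radiation_group, sleep_condition, day, sequence_index,
    stage, lit_holes, action, correct, rewarded, latency_s

``lit_holes`` is a pipe-joined hole list ("2|4"); ``action`` is a hole
id, "omission" or "premature"; ``latency_s`` is empty for
non-responses.  A line-delimited JSON stream with the same fields is
provided as an alternative; both round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .task import OMISSION, PREMATURE, SessionLog, TrialEvent

EVENT_COLUMNS = ["subject_id", "radiation_group", "sleep_condition", "day",
                 "sequence_index", "stage", "lit_holes", "action", "correct",
                 "rewarded", "latency_s"]


def sessions_to_frame(logs: Iterable[SessionLog]) -> pd.DataFrame:
    """Flatten session logs into the canonical tidy events table."""
    rows = []
    for log in logs:
        for ev in log.events:
            rows.append({
                "subject_id": log.subject_id,
                "radiation_group": log.radiation_group,
                "sleep_condition": log.sleep_condition,
                "day": ev.day,
                "sequence_index": ev.sequence_index,
                "stage": ev.stage_id,
                "lit_holes": "|".join(str(h) for h in ev.lit),
                "action": str(ev.action),
                "correct": bool(ev.correct),
                "rewarded": bool(ev.rewarded),
                "latency_s": np.nan if ev.latency is None else float(ev.latency),
            })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_sessions(frame: pd.DataFrame) -> list:
    """Rebuild :class:`SessionLog` objects from the canonical events table."""
    logs = []
    keys = ["subject_id", "radiation_group", "sleep_condition", "day"]
    for (sid, group, cond, day), sub in frame.groupby(keys, sort=False):
        log = SessionLog(str(sid), str(group), str(cond), int(day))
        for _, row in sub.iterrows():
            action = row["action"]
            if action not in (OMISSION, PREMATURE):
                action = int(action)
            latency = row["latency_s"]
            log.events.append(TrialEvent(
                day=int(row["day"]), sequence_index=int(row["sequence_index"]),
                stage_id=str(row["stage"]),
                lit=tuple(int(h) for h in str(row["lit_holes"]).split("|")),
                action=action, correct=bool(row["correct"]),
                rewarded=bool(row["rewarded"]),
                latency=None if pd.isna(latency) else float(latency)))
        logs.append(log)
    return logs


def write_events_csv(logs_or_frame, path) -> Path:
    frame = _as_frame(logs_or_frame)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_events_csv(path) -> pd.DataFrame:
    """Read an events table, validating structure and reporting bad rows."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"action": str})
    if frame.empty:
        raise ValueError(f"{path}: empty trial log")
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = _bad_rows(frame)
    if bad:
        raise ValueError(f"{path}: malformed rows (1-based, excluding header): {bad[:10]}")
    frame["latency_s"] = pd.to_numeric(frame["latency_s"], errors="coerce")
    for col in ("correct", "rewarded"):
        frame[col] = frame[col].astype(bool)
    return frame[EVENT_COLUMNS]


def _bad_rows(frame: pd.DataFrame) -> list:
    bad = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        action = str(row.action)
        if action not in (OMISSION, PREMATURE) and not action.isdigit():
            bad.append(i)
            continue
        try:
            lit = [int(h) for h in str(row.lit_holes).split("|")]
        except ValueError:
            bad.append(i)
            continue
        if action.isdigit() and int(action) not in lit:
            bad.append(i)
    return bad


def write_events_jsonl(logs_or_frame, path) -> Path:
    frame = _as_frame(logs_or_frame)
    path = Path(path)
    with open(path, "w") as fh:
        for rec in frame.to_dict(orient="records"):
            if pd.isna(rec["latency_s"]):
                rec["latency_s"] = None
            fh.write(json.dumps(rec) + "\n")
    return path


def read_events_jsonl(path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    if not records:
        raise ValueError(f"{path}: empty trial log")
    frame = pd.DataFrame.from_records(records, columns=EVENT_COLUMNS)
    frame["latency_s"] = pd.to_numeric(frame["latency_s"], errors="coerce")
    return frame


def roster_to_frame(cohort: Sequence) -> pd.DataFrame:
    """Cohort roster as a delimited-table-ready frame (no parameters leak)."""
    return pd.DataFrame([{
        "subject_id": s.subject_id,
        "radiation_group": s.radiation_group,
        "phenotype": s.phenotype,
        "alpha_rested": s.params_rested.alpha,
        "beta_rested": s.params_rested.beta,
        "kappa_rested": s.params_rested.kappa,
        "alpha_sf": s.params_sf.alpha,
        "beta_sf": s.params_sf.beta,
        "kappa_sf": s.params_sf.kappa,
    } for s in cohort])


def _as_frame(logs_or_frame) -> pd.DataFrame:
    if isinstance(logs_or_frame, pd.DataFrame):
        return logs_or_frame
    return sessions_to_frame(logs_or_frame)
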