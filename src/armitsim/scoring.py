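"""Per-subject descriptive metrics for ARMIT trial logs.

Covers stage success rates, the initial/perseverative/regressive error
taxonomy for the four-option C13 stage, hole-selection frequencies,
response-latency "processing speed", the Sleep Fragmentation Index
(SFI = post-SF / rested success rate per stage), and the high-performer
filter (rested success > chance + 20 points in both C12 and C13).

Conventions (all configurable where noted): a stage *presentation* is a
response or an omission (premature ITI touches are not presentations);
omissions count against success rates; error classification considers
response trials only, with "immediately preceding trial" meaning the
preceding response trial of the same session (one subject-day).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .io import _as_frame
from .task import OMISSION, PREMATURE, STAGE_ORDER, make_stage_config

#: High performers must exceed chance by this margin in C12 and C13.
HIGH_PERFORMER_MARGIN = 0.20


def high_performer_thresholds() -> dict:
    """Strict lower bounds on rested success rates, per stage: chance + 20 points."""
    return {s: stats.chance_level(s) + HIGH_PERFORMER_MARGIN for s in ("C12", "C13")}


# ---------------------------------------------------------------------------
# Stage success rates
# ---------------------------------------------------------------------------

def stage_success_rates(logs_or_frame) -> pd.DataFrame:
    """Per-stage success summary for one subject in one sleep condition.

    Presentations (responses + omissions) are pooled across the
    condition's days; omissions count as presentations that were not
    correct.  ``first_try_rate`` is the alternate per-sequence view: the
    fraction of sequences whose *first* presentation of the stage was
    correct.  A stage never presented yields an undefined (NaN) rate
    with ``defined=False``.
    """
    frame = _as_frame(logs_or_frame)
    _require_single_condition(frame)
    rows = []
    for stage in STAGE_ORDER:
        sub = frame[(frame["stage"] == stage) & (frame["action"] != PREMATURE)]
        n = len(sub)
        n_correct = int(sub["correct"].sum())
        lat = sub["latency_s"].dropna()
        first = sub.groupby(["day", "sequence_index"], sort=False).head(1)
        rows.append({
            "stage": stage,
            "n_presentations": n,
            "n_correct": n_correct,
            "success_rate": n_correct / n if n else np.nan,
            "first_try_rate": float(first["correct"].mean()) if len(first) else np.nan,
            "mean_latency_s": float(lat.mean()) if len(lat) else np.nan,
            "sem_latency_s": float(lat.sem()) if len(lat) > 1 else (0.0 if len(lat) else np.nan),
            "defined": n > 0,
        })
    return pd.DataFrame(rows)


def _require_single_condition(frame: pd.DataFrame) -> None:
    if frame.empty:
        raise ValueError("empty trial log")
    for col in ("subject_id", "sleep_condition"):
        if frame[col].nunique() > 1:
            raise ValueError(f"expected one {col}, got {sorted(frame[col].unique())}")


# ---------------------------------------------------------------------------
# Error taxonomy (C13)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorCounts:
    """Counts of C13 error classes; classes partition the incorrect response trials."""

    n_trials_examined: int
    n_initial: int
    n_perseverative: int
    n_regressive: int

    @property
    def n_incorrect(self) -> int:
        return self.n_initial + self.n_perseverative + self.n_regressive

    def proportions(self) -> dict:
        """Per-class share of incorrect response trials (NaN if none)."""
        n = self.n_incorrect
        if n == 0:
            return {"initial": np.nan, "perseverative": np.nan, "regressive": np.nan}
        return {"initial": self.n_initial / n, "perseverative": self.n_perseverative / n,
                "regressive": self.n_regressive / n}

    def __add__(self, other: "ErrorCounts") -> "ErrorCounts":
        return ErrorCounts(self.n_trials_examined + other.n_trials_examined,
                           self.n_initial + other.n_initial,
                           self.n_perseverative + other.n_perseverative,
                           self.n_regressive + other.n_regressive)


def classify_errors(choices: Sequence, rewarded_hole: int = 12) -> ErrorCounts:
    """Classify one session's ordered C13 choices into error classes.

    Decision rules, applied to each trial in session order:

    1. a correct trial carries no error class;
    2. an incorrect choice matching the choice on the immediately
       preceding (response) trial is *perseverative*;
    3. an incorrect choice made earlier in the session but not on the
       immediately preceding trial is *regressive*;
    4. an incorrect choice not made before in the session is *initial*.

    ``choices`` holds hole ids of response trials only (omissions are
    excluded beforehand); a ``None`` entry marks an adjacency break (used
    when omissions are configured to interrupt "immediately preceding").
    """
    valid = set(make_stage_config("C13").lit) | {rewarded_hole}
    n_examined = 0
    n_initial = n_pers = n_reg = 0
    prev = None
    seen: set = set()
    for choice in choices:
        if choice is None:  # adjacency break
            prev = None
            continue
        choice = int(choice)
        if choice not in valid:
            raise ValueError(f"unknown hole id {choice} in C13 choices")
        n_examined += 1
        if choice != rewarded_hole:
            if choice == prev:
                n_pers += 1
            elif choice in seen:
                n_reg += 1
            else:
                n_initial += 1
        seen.add(choice)
        prev = choice
    return ErrorCounts(n_examined, n_initial, n_pers, n_reg)


def classify_errors_sessions(logs_or_frame, rewarded_hole: int = 12,
                             omissions_break_adjacency: bool = False) -> ErrorCounts:
    """Sum :func:`classify_errors` over each subject-day session in a log set.

    The session scope for "earlier in the session" is one subject-day.
    By default omission trials are simply dropped (adjacency is computed
    over response trials); set ``omissions_break_adjacency`` to make an
    omission interrupt the "immediately preceding trial" relation.
    """
    frame = _as_frame(logs_or_frame)
    sub = frame[(frame["stage"] == "C13") & (frame["action"] != PREMATURE)]
    total = ErrorCounts(0, 0, 0, 0)
    for _, sess in sub.groupby(["subject_id", "sleep_condition", "day"], sort=False):
        choices = []
        for action in sess["action"]:
            if str(action) == OMISSION:
                if omissions_break_adjacency:
                    choices.append(None)
            else:
                choices.append(int(action))
        total = total + classify_errors(choices, rewarded_hole)
    return total


# ---------------------------------------------------------------------------
# Hole selection, processing speed, SFI, high performers
# ---------------------------------------------------------------------------

def hole_selection_frequencies(logs_or_frame) -> dict:
    """C13 selection proportions per lit hole plus omissions.

    Normalized over presentations (responses + omissions); the values
    sum to 1.
    """
    frame = _as_frame(logs_or_frame)
    sub = frame[(frame["stage"] == "C13") & (frame["action"] != PREMATURE)]
    holes = sorted(make_stage_config("C13").lit)
    n = len(sub)
    freq = {h: 0.0 for h in holes}
    freq[OMISSION] = 0.0
    if n == 0:
        return freq
    counts = sub["action"].astype(str).value_counts()
    for h in holes:
        freq[h] = counts.get(str(h), 0) / n
    freq[OMISSION] = counts.get(OMISSION, 0) / n
    return freq


@dataclass(frozen=True)
class SpeedSummary:
    """Mean/SEM response latency (seconds) for one stage."""

    mean: float
    sem: float
    n: int
    defined: bool = True
    degenerate: bool = False  # single latency: SEM reported as 0


def processing_speed(logs_or_frame, stage: str) -> SpeedSummary:
    """Latency between stimulus onset and response, omissions excluded.

    SEM uses the n-1 denominator.  With a single latency the SEM is
    reported as 0 and flagged degenerate; with none, the result is
    flagged undefined.
    """
    frame = _as_frame(logs_or_frame)
    lat = frame.loc[frame["stage"] == stage, "latency_s"].dropna().to_numpy(float)
    if lat.size == 0:
        return SpeedSummary(np.nan, np.nan, 0, defined=False)
    if lat.size == 1:
        return SpeedSummary(float(lat[0]), 0.0, 1, degenerate=True)
    return SpeedSummary(float(lat.mean()),
                        float(lat.std(ddof=1) / np.sqrt(lat.size)), int(lat.size))


def sfi(rested_summaries: pd.DataFrame, post_sf_summaries: pd.DataFrame) -> pd.DataFrame:
    """Sleep Fragmentation Index: post-SF / rested success rate per stage.

    1 means sleep fragmentation left performance unchanged.  A stage
    with zero (or undefined) rested rate yields NaN with
    ``defined=False`` — never infinity.
    """
    merged = rested_summaries.merge(post_sf_summaries, on="stage",
                                    suffixes=("_rested", "_sf"))
    rested = merged["success_rate_rested"]
    post = merged["success_rate_sf"]
    ok = rested.notna() & (rested > 0) & post.notna()
    out = pd.DataFrame({"stage": merged["stage"],
                        "sfi": np.where(ok, post / rested, np.nan),
                        "defined": ok})
    return out


def is_high_performer(logs_or_frame) -> bool:
    """Whether one subject's rested logs clear the high-performer filter.

    Requires success strictly above chance + 20 points in both C12
    (> 0.70) and C13 (> 0.45).
    """
    summary = stage_success_rates(logs_or_frame).set_index("stage")
    thresholds = high_performer_thresholds()
    for stage, thr in thresholds.items():
        rate = summary.loc[stage, "success_rate"]
        if not summary.loc[stage, "defined"] or not rate > thr:
            return False
    return True


def select_high_performers(summaries: pd.DataFrame) -> list:
    """Subset of subjects passing the high-performer filter.

    ``summaries`` is a tidy frame with columns ``subject_id``, ``stage``
    and ``success_rate`` from the rested condition.  Subjects missing a
    required stage are excluded with a warning.
    """
    thresholds = high_performer_thresholds()
    selected = []
    for sid, sub in summaries.groupby("subject_id", sort=False):
        rates = sub.set_index("stage")["success_rate"]
        missing = [s for s in thresholds if s not in rates.index or pd.isna(rates[s])]
        if missing:
            warnings.warn(f"subject {sid}: missing stage(s) {missing}; excluded")
            continue
        if all(rates[s] > thr for s, thr in thresholds.items()):
            selected.append(sid)
    return selected


# ---------------------------------------------------------------------------
# Cohort-level tidy tables (one artifact per figure analogue)
# ---------------------------------------------------------------------------

def summarize_subjects(logs_or_frame) -> pd.DataFrame:
    """Tidy per-(subject, condition, stage) success/latency table."""
    frame = _as_frame(logs_or_frame)
    rows = []
    for (sid, group, cond), sub in frame.groupby(
            ["subject_id", "radiation_group", "sleep_condition"], sort=False):
        summary = stage_success_rates(sub)
        summary.insert(0, "subject_id", sid)
        summary.insert(1, "radiation_group", group)
        summary.insert(2, "sleep_condition", cond)
        rows.append(summary)
    return pd.concat(rows, ignore_index=True)


def score_bundle(logs_or_frame, omissions_break_adjacency: bool = False) -> dict:
    """All scored tables for a full experiment's logs, keyed by artifact name.

    Returns stage summaries, per-subject SFI, C13 hole-selection
    frequencies, C13 error counts, and processing speed — the tabular
    analogues of the study's group figures.
    """
    frame = _as_frame(logs_or_frame)
    stage_summary = summarize_subjects(frame)

    sfi_rows, hole_rows, err_rows, speed_rows = [], [], [], []
    for (sid, group), sub in frame.groupby(["subject_id", "radiation_group"], sort=False):
        rested = sub[sub["sleep_condition"] == "rested"]
        post = sub[sub["sleep_condition"] == "sf"]
        if len(rested) and len(post):
            rec = sfi(stage_success_rates(rested), stage_success_rates(post))
            rec.insert(0, "subject_id", sid)
            rec.insert(1, "radiation_group", group)
            sfi_rows.append(rec)
        for cond, csub in sub.groupby("sleep_condition", sort=False):
            freq = hole_selection_frequencies(csub)
            hole_rows.append({"subject_id": sid, "radiation_group": group,
                              "sleep_condition": cond,
                              **{f"hole_{h}" if isinstance(h, int) else h: v
                                 for h, v in freq.items()}})
            counts = classify_errors_sessions(
                csub, omissions_break_adjacency=omissions_break_adjacency)
            props = counts.proportions()
            err_rows.append({"subject_id": sid, "radiation_group": group,
                             "sleep_condition": cond,
                             "n_trials_examined": counts.n_trials_examined,
                             "n_incorrect": counts.n_incorrect,
                             "n_initial": counts.n_initial,
                             "n_perseverative": counts.n_perseverative,
                             "n_regressive": counts.n_regressive,
                             "prop_initial": props["initial"],
                             "prop_perseverative": props["perseverative"],
                             "prop_regressive": props["regressive"]})
            for stage in STAGE_ORDER:
                speed = processing_speed(csub, stage)
                speed_rows.append({"subject_id": sid, "radiation_group": group,
                                   "sleep_condition": cond, "stage": stage,
                                   "mean_latency_s": speed.mean,
                                   "sem_latency_s": speed.sem, "n": speed.n})

    return {
        "stage_summary": stage_summary,
        "sfi": (pd.concat(sfi_rows, ignore_index=True) if sfi_rows
                else pd.DataFrame(columns=["subject_id", "radiation_group",
                                           "stage", "sfi", "defined"])),
        "hole_frequencies": pd.DataFrame(hole_rows),
        "errors": pd.DataFrame(err_rows),
        "processing_speed": pd.DataFrame(speed_rows),
    }
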