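"""State machine for the ARMIT touchscreen task.

The Associative Recognition Memory and Interference Touchscreen (ARMIT)
task presents a rat with lit holes on a 3 x 5 touchscreen grid and cycles
it through three configurations per sequence:

* **C11** — holes 2 and 4 lit, *either* rewarded (the familiar pattern).
* **C12** — holes 2 and 14 lit, only the novel hole 14 rewarded.
* **C13** — holes 2, 4, 12 and 14 lit, only hole 12 rewarded.

A correct response in C11 or C12 advances the animal to the next stage.
An incorrect choice or an omission triggers a timeout and a restart at
C11, consuming one of the session's sequence progressions.  In C13 *any*
response (rewarded only if correct) ends the sequence and restarts at
C11.  A premature touch during the inter-trial interval also restarts at
C11.  A session offers at most ``max_progressions`` (default 10) sequence
progressions; the transition task runs for two consecutive test days.

Holes are numbered 1-15 in row-major order with the top-left hole as 1,
so holes 2 and 4 sit on the top row and holes 12 and 14 on the bottom
row.  Time is logical (event-ordered); latencies are values carried on
events, never measured.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

N_ROWS = 3
N_COLS = 5
HOLE_IDS = frozenset(range(1, N_ROWS * N_COLS + 1))

STAGE_ORDER = ("C11", "C12", "C13")

#: Sentinel actions (any other action is a lit hole id).
OMISSION = "omission"
PREMATURE = "premature"


class ConfigurationError(ValueError):
    """Raised for invalid stage or protocol configurations."""


class StateError(RuntimeError):
    """Raised when the state machine is driven past its terminal state."""


@dataclass(frozen=True)
class StageConfig:
    """One ARMIT configuration: which holes are lit and which rewarded."""

    stage_id: str
    lit: frozenset
    rewarded: frozenset
    response_window: float = 30.0
    timeout: float = 5.0

    def __post_init__(self):
        if self.stage_id not in STAGE_ORDER:
            raise ConfigurationError(f"unknown stage_id {self.stage_id!r}")
        lit = frozenset(self.lit)
        rewarded = frozenset(self.rewarded)
        if not lit <= HOLE_IDS:
            raise ConfigurationError(f"lit holes {sorted(lit)} outside grid 1-{max(HOLE_IDS)}")
        if not rewarded <= lit:
            raise ConfigurationError("rewarded holes must be a subset of lit holes")
        object.__setattr__(self, "lit", lit)
        object.__setattr__(self, "rewarded", rewarded)


#: Canonical hole assignments for the three configurations.
_CANONICAL = {
    "C11": (frozenset({2, 4}), frozenset({2, 4})),
    "C12": (frozenset({2, 14}), frozenset({14})),
    "C13": (frozenset({2, 4, 12, 14}), frozenset({12})),
}


def make_stage_config(stage_id: str, response_window: float = 30.0,
                      timeout: float = 5.0) -> StageConfig:
    """Return the canonical :class:`StageConfig` for ``stage_id``.

    Raises
    ------
    ConfigurationError
        If ``stage_id`` is not one of ``C11``/``C12``/``C13``.
    """
    try:
        lit, rewarded = _CANONICAL[stage_id]
    except KeyError:
        raise ConfigurationError(f"unknown stage_id {stage_id!r}") from None
    return StageConfig(stage_id, lit, rewarded, response_window, timeout)


def default_stages(response_window: float = 30.0, timeout: float = 5.0) -> dict:
    """Canonical stage table keyed by stage id."""
    return {s: make_stage_config(s, response_window, timeout) for s in STAGE_ORDER}


@dataclass(frozen=True)
class ProtocolConfig:
    """Session-level protocol parameters (defaults are the task's published values)."""

    max_progressions: int = 10
    iti: float = 5.0
    response_window: float = 30.0
    timeout: float = 5.0
    n_test_days: int = 2
    familiarization_trials: int = 50
    familiarization_days: int = 5
    #: whether a premature ITI touch consumes one of the sequence progressions
    consume_premature: bool = True

    def __post_init__(self):
        if self.max_progressions < 1:
            raise ConfigurationError("max_progressions must be >= 1")
        for name in ("iti", "response_window", "timeout"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    def stages(self) -> dict:
        return default_stages(self.response_window, self.timeout)


@dataclass(frozen=True)
class TrialEvent:
    """One stage presentation: what was shown, what the subject did."""

    day: int
    sequence_index: int
    stage_id: str
    lit: tuple
    action: object  # hole id (int), OMISSION or PREMATURE
    correct: bool
    rewarded: bool
    latency: float | None = None

    @property
    def is_response(self) -> bool:
        return isinstance(self.action, int)


@dataclass(frozen=True)
class TaskState:
    """Current position of one subject inside a session."""

    current_stage: str = "C11"
    progressions_completed: int = 0
    sequences_started: int = 0
    in_iti: bool = True  # True between sequences (no sequence currently active)


@dataclass
class SessionLog:
    """Ordered trial events for one subject-day plus condition labels."""

    subject_id: str
    radiation_group: str  # "sham" | "gcr"
    sleep_condition: str  # "rested" | "sf"
    day: int
    events: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


def is_terminal(state: TaskState, protocol: ProtocolConfig) -> bool:
    """A session ends once all progressions are used and no sequence is active."""
    return state.in_iti and state.sequences_started >= protocol.max_progressions


def advance(state: TaskState, action, protocol: ProtocolConfig | None = None,
            stages: Mapping[str, StageConfig] | None = None,
            day: int = 1) -> tuple:
    """Apply one action to the state machine; returns ``(new_state, TrialEvent)``.

    Pure function of its arguments: identical inputs yield identical
    outputs.  ``action`` is a lit hole id, :data:`OMISSION` or
    :data:`PREMATURE`.  Touches to unlit holes have no programmed effect
    and never generate events; passing an unlit hole id here is treated
    as a caller bug and raises ``ValueError``.
    """
    protocol = protocol or ProtocolConfig()
    stages = stages or protocol.stages()
    if is_terminal(state, protocol):
        raise StateError("advance() called on a terminal session state")

    cfg = stages[state.current_stage]
    # A presentation while between sequences begins the next sequence.
    seq = state.sequences_started + 1 if state.in_iti else state.sequences_started
    started = seq

    def event(action, correct, rewarded):
        return TrialEvent(day=day, sequence_index=seq, stage_id=cfg.stage_id,
                          lit=tuple(sorted(cfg.lit)), action=action,
                          correct=correct, rewarded=rewarded)

    if action == PREMATURE:
        ev = event(PREMATURE, False, False)
        if protocol.consume_premature:
            new = TaskState("C11", state.progressions_completed, started, True)
        else:
            # restart at C11 without spending the progression opportunity
            new = TaskState("C11", state.progressions_completed, started, False)
        return new, ev

    if action == OMISSION:
        ev = event(OMISSION, False, False)
        return TaskState("C11", state.progressions_completed, started, True), ev

    hole = int(action)
    if hole not in cfg.lit:
        raise ValueError(f"hole {hole} is not lit in stage {cfg.stage_id}")
    correct = hole in cfg.rewarded
    rewarded = correct  # reward granted iff chosen hole is rewarded
    ev = event(hole, correct, rewarded)

    if cfg.stage_id == "C13":
        # any response ends the sequence and counts the progression
        new = TaskState("C11", state.progressions_completed + 1, started, True)
    elif correct:
        nxt = STAGE_ORDER[STAGE_ORDER.index(cfg.stage_id) + 1]
        new = TaskState(nxt, state.progressions_completed, started, False)
    else:
        new = TaskState("C11", state.progressions_completed, started, True)
    return new, ev


def run_session(agent, protocol: ProtocolConfig | None = None, day: int = 1,
                seed=None, *, subject_id: str = "S0", radiation_group: str = "sham",
                sleep_condition: str = "rested",
                stages: Mapping[str, StageConfig] | None = None) -> SessionLog:
    """Run one full session of an agent through the transition task.

    ``agent`` must provide ``act(stage_config, rng) -> (action, latency)``
    and may provide ``observe(event)`` for learning updates.  All
    randomness flows through ``seed``; identical ``(agent, protocol, day,
    seed)`` produce identical logs.
    """
    import numpy as np

    protocol = protocol or ProtocolConfig()
    stages = stages or protocol.stages()
    rng = np.random.default_rng(seed)
    state = TaskState()
    log = SessionLog(subject_id, radiation_group, sleep_condition, day)
    observe = getattr(agent, "observe", None)

    while not is_terminal(state, protocol):
        cfg = stages[state.current_stage]
        action, latency = agent.act(cfg, rng)
        state, ev = advance(state, action, protocol, stages, day=day)
        if ev.is_response and latency is not None:
            ev = replace(ev, latency=float(min(latency, cfg.response_window)))
        log.events.append(ev)
        if observe is not None:
            observe(ev)
    return log


# ---------------------------------------------------------------------------
# Stimulus-response training (SRT) advancement criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SRTStageCriteria:
    """Advancement criterion for one stimulus-response training stage."""

    name: str
    response_window: float | None  # seconds; None where not applicable
    min_correct: int
    min_completion_rate: float
    max_sessions: int
    days_at_criterion: int

    def __post_init__(self):
        if not 0 < self.min_completion_rate <= 1:
            raise ConfigurationError("min_completion_rate must be in (0, 1]")
        if self.days_at_criterion > self.max_sessions:
            raise ConfigurationError("days_at_criterion cannot exceed max_sessions")

    def session_meets(self, n_correct: int, completion_rate: float) -> bool:
        return n_correct >= self.min_correct and completion_rate >= self.min_completion_rate


#: Published SRT curriculum criteria, keyed by stage name.
SRT_CRITERIA = {
    "SRT15": SRTStageCriteria("SRT15", None, 30, 0.60, 8, 1),
    "SRT4": SRTStageCriteria("SRT4", None, 30, 0.60, 8, 1),
    "SRT1-Timed": SRTStageCriteria("SRT1-Timed", 30.0, 30, 0.75, 8, 2),
    "SRT1-Fast": SRTStageCriteria("SRT1-Fast", 10.0, 30, 0.75, 10, 2),
}


def srt_advance_check(stage: SRTStageCriteria,
                      history: Sequence[tuple]) -> str:
    """Decide ``advance``/``continue``/``exclude`` from a session history.

    ``history`` is a chronological list of per-session ``(n_correct,
    completion_rate)`` pairs.  A subject advances at the first session
    after which the last ``days_at_criterion`` consecutive sessions each
    meet the stage criterion, and is excluded if it has used up
    ``max_sessions`` sessions without advancing.
    """
    if not history:
        raise ValueError("history must be non-empty")
    streak = 0
    for i, entry in enumerate(history[: stage.max_sessions], start=1):
        try:
            n_correct, rate = entry
        except (TypeError, ValueError):
            raise ValueError(f"malformed history entry at session {i}: {entry!r}") from None
        streak = streak + 1 if stage.session_meets(int(n_correct), float(rate)) else 0
        if streak >= stage.days_at_criterion:
            return "advance"
    if len(history) >= stage.max_sessions:
        return "exclude"
    return "continue"
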