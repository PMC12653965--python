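"""Parametric choice agents and synthetic cohorts for the ARMIT task.

The generative model is deliberately minimal: per-hole values learned by
a delta rule, a softmax choice rule, and a perseveration bonus toward
the most recently rewarded hole.  These expose exactly the two knobs a
reinforcement-learning account of radiation-induced impairment
implicates — a blunted learning rate (``alpha``) and a bias toward
outdated, previously rewarded cues (``kappa``).  The model is
interpretive: it reproduces the statistical structure the analysis
pipeline assumes (chance performers, high performers, perseverative
collapse under sleep fragmentation), not rat neurobiology.

Cohorts mix four phenotypes:

* ``sham`` — unirradiated controls; parameters are sleep-invariant.
* ``overt`` — overtly radiosensitive subjects (~30 % of the irradiated
  group), impaired in both sleep conditions (low ``beta``/``alpha``).
* ``conditional`` — conditionally sensitive subjects (~half of the
  non-overt remainder): high-performer parameters when rested, elevated
  perseveration only after sleep fragmentation (the "two-hit" mode).
* ``refractory`` — irradiated but resilient in both conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import scoring
from .task import (HOLE_IDS, OMISSION, PREMATURE, ProtocolConfig, SessionLog,
                   StageConfig, TrialEvent, make_stage_config, run_session)

PHENOTYPES = ("sham", "overt", "conditional", "refractory")


@dataclass(frozen=True)
class AgentParams:
    """Parameters of one simulated subject in one sleep condition.

    alpha
        Delta-rule learning rate in [0, 1].
    beta
        Softmax inverse temperature (>= 0); 0 gives uniform choice
        over the lit holes.
    kappa
        Perseveration weight (>= 0): additive softmax bonus for the
        most recently rewarded hole when it is lit.
    p_omit
        Per-presentation probability of failing to respond within the
        response window.
    p_premature
        Per-presentation probability of touching the screen during the
        preceding inter-trial interval.
    latency_log_mean, latency_log_sd
        Log-normal response-latency parameters in log-seconds; draws
        are truncated to (0, response_window].
    v_init
        Initial value assigned to every hole.  Optimistic (> 0)
        initialisation drives directed exploration of novel rewarded
        positions, the standard delta-rule device for tasks whose
        contingencies shift.
    """

    alpha: float = 0.3
    beta: float = 2.0
    kappa: float = 0.0
    p_omit: float = 0.05
    p_premature: float = 0.02
    latency_log_mean: float = math.log(3.5)
    latency_log_sd: float = 0.5
    v_init: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0 or self.kappa < 0:
            raise ValueError("beta and kappa must be >= 0")
        for name in ("p_omit", "p_premature"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.latency_log_sd < 0:
            raise ValueError("latency_log_sd must be >= 0")
        if not 0.0 <= self.v_init <= 1.0:
            raise ValueError("v_init must lie in [0, 1]")


@dataclass
class AgentState:
    """Learned values and recency trackers of one agent."""

    values: dict = field(default_factory=lambda: {h: 0.0 for h in sorted(HOLE_IDS)})
    last_rewarded_hole: int | None = None
    last_chosen_hole: int | None = None


def update_values(state: AgentState, chosen: int, reward: int,
                  alpha: float) -> AgentState:
    """Delta-rule update ``V <- V + alpha * (r - V)`` for the chosen hole.

    Returns a new :class:`AgentState`; only the chosen hole's value
    changes, ``last_rewarded_hole`` updates iff the trial was rewarded,
    and ``last_chosen_hole`` always updates.
    """
    if chosen not in HOLE_IDS:
        raise ValueError(f"unknown hole id {chosen}")
    values = dict(state.values)
    values[chosen] = values[chosen] + alpha * (float(reward) - values[chosen])
    return AgentState(values=values,
                      last_rewarded_hole=chosen if reward else state.last_rewarded_hole,
                      last_chosen_hole=chosen)


def choice_probabilities(params: AgentParams, state: AgentState,
                         lit) -> dict:
    """Softmax response distribution over the lit holes (given a response).

    Scores are ``beta * V[h] + kappa * 1[h == last_rewarded_hole]``.
    """
    holes = sorted(lit)
    if not holes:
        raise ValueError("lit set must be non-empty")
    scores = np.array([params.beta * state.values[h]
                       + (params.kappa if h == state.last_rewarded_hole else 0.0)
                       for h in holes])
    scores -= scores.max()
    w = np.exp(scores)
    p = w / w.sum()
    return dict(zip(holes, p))


def action_probabilities(params: AgentParams, state: AgentState, lit) -> dict:
    """Full per-presentation action distribution over lit holes + omission."""
    probs = {h: (1.0 - params.p_omit) * p
             for h, p in choice_probabilities(params, state, lit).items()}
    probs[OMISSION] = params.p_omit
    return probs


def choose(params: AgentParams, state: AgentState, lit, rng,
           response_window: float = 30.0):
    """Sample one action: omission with ``p_omit``, else a softmax hole draw.

    Returns ``(action, latency)`` where latency is ``None`` for an
    omission and a truncated log-normal draw (seconds) otherwise.
    """
    if not lit:
        raise ValueError("lit set must be non-empty")
    if params.p_omit > 0 and rng.random() < params.p_omit:
        return OMISSION, None
    probs = choice_probabilities(params, state, lit)
    holes = list(probs)
    action = int(rng.choice(holes, p=list(probs.values())))
    return action, _draw_latency(params, rng, response_window)


def _draw_latency(params: AgentParams, rng, response_window: float) -> float:
    for _ in range(16):
        x = float(rng.lognormal(params.latency_log_mean, params.latency_log_sd))
        if 0.0 < x <= response_window:
            return x
    return float(response_window)


class RLAgent:
    """Delta-rule / softmax / perseveration agent driving :func:`run_session`."""

    def __init__(self, params: AgentParams, state: AgentState | None = None):
        self.params = params
        self.state = state or AgentState(
            values={h: params.v_init for h in sorted(HOLE_IDS)})

    def act(self, cfg: StageConfig, rng):
        if self.params.p_premature > 0 and rng.random() < self.params.p_premature:
            return PREMATURE, None
        return choose(self.params, self.state, cfg.lit, rng, cfg.response_window)

    def observe(self, event: TrialEvent):
        if event.is_response:
            self.state = update_values(self.state, event.action,
                                       int(event.rewarded), self.params.alpha)


def uniform_agent(p_omit: float = 0.0) -> RLAgent:
    """Agent choosing uniformly over the lit holes (chance performer)."""
    return RLAgent(AgentParams(alpha=0.0, beta=0.0, kappa=0.0,
                               p_omit=p_omit, p_premature=0.0))


class PerseverativeAgent:
    """Mixture agent: picks the most recently rewarded hole with fixed probability.

    With probability ``p_persev`` it reselects the last rewarded hole
    (when lit); otherwise it chooses uniformly among the remaining lit
    holes.  Used as a reference generator for hole-selection analyses.
    """

    def __init__(self, p_persev: float = 0.7):
        if not 0.0 <= p_persev <= 1.0:
            raise ValueError("p_persev must lie in [0, 1]")
        self.p_persev = p_persev
        self.last_rewarded_hole: int | None = None

    def act(self, cfg: StageConfig, rng):
        holes = sorted(cfg.lit)
        target = self.last_rewarded_hole
        if target in holes and rng.random() < self.p_persev:
            return target, None
        if target in holes and len(holes) > 1:
            holes = [h for h in holes if h != target]
        return int(rng.choice(holes)), None

    def observe(self, event: TrialEvent):
        if event.is_response and event.rewarded:
            self.last_rewarded_hole = event.action


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------

#: Per-phenotype parameter presets: (rested, sleep-fragmented) pairs.
#: Calibrated so the rested sham group lands near 70 % success in C12 and
#: 50-60 % in C13, overtly sensitive irradiated agents near/below the C12
#: chance level, and conditionally sensitive agents collapse in C13 with a
#: perseverative hole-selection bias only after sleep fragmentation.
DEFAULT_PRESETS: dict = {
    "sham": (
        AgentParams(alpha=0.45, beta=8.0, kappa=0.2, p_omit=0.07,
                    p_premature=0.03, latency_log_mean=math.log(3.7),
                    latency_log_sd=0.5, v_init=1.0),
        None,  # sleep-invariant
    ),
    "overt": (
        AgentParams(alpha=0.10, beta=1.0, kappa=1.0, p_omit=0.15,
                    p_premature=0.06, latency_log_mean=math.log(4.2),
                    latency_log_sd=0.55, v_init=1.0),
        None,  # impaired in both conditions
    ),
    "conditional": (
        AgentParams(alpha=0.30, beta=10.0, kappa=0.2, p_omit=0.05,
                    p_premature=0.02, latency_log_mean=math.log(4.0),
                    latency_log_sd=0.5, v_init=1.0),
        AgentParams(alpha=0.20, beta=10.0, kappa=4.0, p_omit=0.08,
                    p_premature=0.03, latency_log_mean=math.log(5.0),
                    latency_log_sd=0.5, v_init=1.0),
    ),
    "refractory": (
        AgentParams(alpha=0.30, beta=2.0, kappa=0.2, p_omit=0.08,
                    p_premature=0.03, latency_log_mean=math.log(4.0),
                    latency_log_sd=0.5, v_init=1.0),
        None,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a simulated experiment cohort."""

    n_sham: int = 24
    n_gcr: int = 20
    f_overt_sensitive: float = 0.30
    f_conditional: float = 0.50
    presets: Mapping = None
    jitter_sigma: float = 0.25
    seed: int = 0
    assignment: str = "quota"  # "quota" | "binomial"

    def __post_init__(self):
        if self.n_sham < 1 or self.n_gcr < 1:
            raise ValueError("cohort sizes must be >= 1")
        for name in ("f_overt_sensitive", "f_conditional"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.assignment not in ("quota", "binomial"):
            raise ValueError("assignment must be 'quota' or 'binomial'")
        if self.presets is None:
            object.__setattr__(self, "presets", DEFAULT_PRESETS)


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated subject: labels plus per-condition parameters."""

    subject_id: str
    radiation_group: str  # "sham" | "gcr"
    phenotype: str
    params_rested: AgentParams
    params_sf: AgentParams


def _jitter(params: AgentParams, factor_beta: float, factor_kappa: float) -> AgentParams:
    return replace(params, beta=params.beta * factor_beta,
                   kappa=params.kappa * factor_kappa)


def generate_cohort(spec: CohortSpec) -> list:
    """Build the subject roster for one experiment.

    Phenotypes within the irradiated group are assigned by exact quota
    (default; ``round`` of the stated fractions) or binomially.  Each
    subject's multiplicative log-normal jitter on ``beta``/``kappa`` is
    drawn from a seed stream split per subject index, so extending the
    cohort never perturbs existing subjects; the same jitter applies to
    both sleep conditions (it is a subject trait).
    """
    presets = spec.presets
    n_overt, n_conditional = _phenotype_counts(spec)
    phenotypes = (["sham"] * spec.n_sham + ["overt"] * n_overt
                  + ["conditional"] * n_conditional
                  + ["refractory"] * (spec.n_gcr - n_overt - n_conditional))

    roster = []
    for idx, pheno in enumerate(phenotypes):
        group = "sham" if pheno == "sham" else "gcr"
        rested, sf = presets[pheno]
        sf = sf if sf is not None else rested
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1, idx)))
        fb = float(rng.lognormal(0.0, spec.jitter_sigma))
        fk = float(rng.lognormal(0.0, spec.jitter_sigma))
        roster.append(SubjectSpec(
            subject_id=f"{group.upper()}{idx:03d}", radiation_group=group,
            phenotype=pheno, params_rested=_jitter(rested, fb, fk),
            params_sf=_jitter(sf, fb, fk)))
    return roster


def _phenotype_counts(spec: CohortSpec) -> tuple:
    if spec.assignment == "quota":
        n_overt = round(spec.n_gcr * spec.f_overt_sensitive)
        n_conditional = round((spec.n_gcr - n_overt) * spec.f_conditional)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
        n_overt = int(rng.binomial(spec.n_gcr, spec.f_overt_sensitive))
        n_conditional = int(rng.binomial(spec.n_gcr - n_overt, spec.f_conditional))
    return n_overt, n_conditional


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

def familiarize(agent, protocol: ProtocolConfig, rng) -> None:
    """Pre-training on the familiar two-hole configuration.

    Emulates the familiarization phase (default 5 days x 50 C11
    presentations, either hole rewarded) purely to warm up the agent's
    values; no events are logged and nothing here enters test-phase
    scoring.
    """
    cfg = make_stage_config("C11", protocol.response_window, protocol.timeout)
    observe = getattr(agent, "observe", None)
    n = protocol.familiarization_days * protocol.familiarization_trials
    for _ in range(n):
        action, _lat = agent.act(cfg, rng)
        if action in (OMISSION, PREMATURE):
            continue
        ev = TrialEvent(day=0, sequence_index=0, stage_id="C11",
                        lit=tuple(sorted(cfg.lit)), action=int(action),
                        correct=action in cfg.rewarded,
                        rewarded=action in cfg.rewarded)
        if observe is not None:
            observe(ev)


def simulate_experiment(cohort: Sequence, protocol: ProtocolConfig | None = None,
                        seed: int = 0) -> list:
    """Simulate the full test design for every subject in ``cohort``.

    Each subject runs the familiarization phase, then the two rested
    transition-task test days.  Subjects passing the high-performer
    filter (rested C12 > 70 % and C13 > 45 %) are re-tested for one
    additional day after sleep fragmentation, using their SF-condition
    parameters, mirroring the published re-test design.  Learning state
    persists across days.  All randomness derives from ``seed`` split
    hierarchically per (subject, day), so edits to one subject never
    reshuffle another.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    protocol = protocol or ProtocolConfig()
    logs: list = []
    for idx, subj in enumerate(cohort):
        agent = RLAgent(subj.params_rested)
        fam_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, idx, 0)))
        familiarize(agent, protocol, fam_rng)

        rested = []
        for day in range(1, protocol.n_test_days + 1):
            rested.append(run_session(
                agent, protocol, day=day,
                seed=np.random.SeedSequence(seed, spawn_key=(2, idx, day)),
                subject_id=subj.subject_id, radiation_group=subj.radiation_group,
                sleep_condition="rested"))
        logs.extend(rested)

        if scoring.is_high_performer(rested):
            agent.params = subj.params_sf
            sf_day = protocol.n_test_days + 1
            logs.append(run_session(
                agent, protocol, day=sf_day,
                seed=np.random.SeedSequence(seed, spawn_key=(2, idx, sf_day)),
                subject_id=subj.subject_id, radiation_group=subj.radiation_group,
                sleep_condition="sf"))
    return logs
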