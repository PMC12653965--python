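# Methods

## The task and its state machine

`armitsim` simulates a staged rodent touchscreen paradigm played on a
3 × 5 grid of holes, numbered 1–15 in row-major order from the top
left.  Each *sequence progression* walks a subject through three
configurations:

| stage | lit holes | rewarded | note |
|-------|-----------|----------|------|
| C11   | 2, 4      | either   | the familiar pattern, over-trained beforehand |
| C12   | 2, 14     | 14       | contingency shift to a novel position |
| C13   | 2, 4, 12, 14 | 12    | four-option interference stage |

A correct response in C11 or C12 advances the sequence; an incorrect
choice or an omission (no response within the 30 s window) triggers a
5 s timeout and a restart at C11; in C13 *any* response ends the
sequence (rewarded only if hole 12 was chosen).  A premature touch
during the 5 s inter-trial interval also restarts at C11 and, by
default, consumes one of the session's 10 sequence progressions (the
protocol leaves this ambiguous; `ProtocolConfig.consume_premature`
makes it explicit).  Test sessions run on two consecutive rested days;
time is logical and event-ordered — latencies are values carried on
events, never measured.

Unlit-hole touches have no programmed effect and generate no events;
"incorrect" therefore always means a lit-but-unrewarded hole, which is
what the four-option hole-selection and error analyses assume.

The stimulus–response training curriculum is represented only by its
advancement criteria (`SRT_CRITERIA`, `srt_advance_check`): a stage is
passed after the required number of consecutive sessions at criterion,
and a subject is excluded once the permitted session count is used up.

## The generative agent model

Agents choose among lit holes by a softmax over
`beta · V[h] + kappa · 1[h = last rewarded hole]`, update per-hole
values with the delta rule `V ← V + alpha · (r − V)`, omit with
probability `p_omit`, touch prematurely with probability
`p_premature`, and draw log-normal response latencies truncated to the
response window.  This is the minimal standard form exposing the two
knobs a reinforcement-learning reading of the radiation phenotype
implicates: a blunted learning rate (`alpha`) and a perseverative bias
toward outdated, previously rewarded cues (`kappa`).  It is an
interpretive model of the *statistical structure* of the behaviour,
not of neural circuitry.

Values are initialised optimistically (`v_init = 1`).  With a sharp
softmax, optimistic initialisation is what drives directed exploration
of the novel rewarded position after a contingency shift; with neutral
initialisation the agent never samples hole 12 in C13 and the whole
cohort floors at chance, which no empirical group does.

A structural consequence worth knowing: because C11 re-rewards hole 2
or 4 on every sequence and C12 re-rewards hole 14 immediately before
every C13 presentation, a per-hole value map caps C13 performance near
50–55 % even for an ideal agent — which is in fact where good
performers sit empirically.  It also means a strongly perseverative
(high-`kappa`) agent can leak some bias into C12 (via the hole it just
exploited in C11), a contrast the empirical data report as stable; no
acceptance check depends on that contrast.

## Cohort construction

The default cohort is 24 sham and 20 irradiated subjects.  Irradiated
subjects split by exact quota into ~30 % *overtly sensitive* (impaired
in both sleep conditions: low `beta`/`alpha`, elevated omissions),
~50 % of the remainder *conditionally sensitive* (high-performer
parameters when rested, `kappa` raised from 0.2 to 4.0 and `alpha`
halved after sleep fragmentation), and the rest *refractory*
(mid-level, never impaired further).  Sham parameters are
sleep-invariant.  Per-subject log-normal jitter (σ = 0.25) multiplies
`beta` and `kappa`, identically in both sleep conditions (it is a
subject trait); jitter streams are split per subject index so
extending a cohort never perturbs existing subjects.

Presets were calibrated once against the published group-level
anchors — rested sham ≈ 70–75 % in C12 and ≈ 45–55 % in C13, overtly
sensitive subjects at or below the 50 % C12 chance level, roughly a
quarter to a third of each group clearing the high-performer filter,
and conditional subjects collapsing below the 25 % C13 chance level
with a perseverative hole-14 excess after sleep fragmentation.  The
presets are calibration targets, not claims about effect sizes, which
the source material does not quantify.

The simulated experiment mirrors the published design: familiarization
(5 days × 50 C11 presentations; warms values only, never scored), two
rested test days, the high-performer filter (strictly above chance +
20 points in both C12 (> 70 %) and C13 (> 45 %), rested), and one
post-sleep-fragmentation day for passing subjects only, with learning
state persisting across days.  SF group sizes always come out of the
filter; they are never hard-coded.

## Scoring conventions

* A stage *presentation* is a response or an omission; omissions count
  against success rates.  Premature touches are logged but are not
  presentations.
* Success rates pool presentations across a condition's days (C11 can
  appear more than once per sequence after restarts); a per-sequence
  first-try rate is reported alongside as an alternate view.
* Error taxonomy (C13, in session order, one subject-day per session):
  a correct trial carries no class; an incorrect choice repeated from
  the immediately preceding trial is *perseverative*; one made earlier
  in the session but not immediately before is *regressive*; a first
  occurrence is *initial*.  The rules speak of choices, so omission
  trials are excluded and adjacency is computed over response trials;
  `omissions_break_adjacency` optionally makes an omission interrupt
  the "immediately preceding" relation.
* Processing speed is the mean ± SEM (n − 1 denominator) of response
  latencies, omissions excluded; a single latency reports SEM 0 with a
  degeneracy flag.
* SFI = post-SF / rested success rate per stage (1 = SF-neutral).  A
  zero rested rate yields a flagged undefined value, never infinity.
  Note that the index is a ratio of small-sample estimates (the rested
  denominator rests on ~15–20 presentations), so even a truly
  SF-neutral subject has mean SFI slightly above 1, and early-session
  learning depresses the rested baseline further.  The neutrality
  check in the test suite therefore brings agents to behavioural
  steady state with two unscored warm-up sessions and uses the
  high-performing parameterisation — the only population for which the
  index is ever computed in the re-test design.

## Statistics

* **Mann–Whitney U** (two-sided): for `n1 + n2 ≤ 20` the null is
  enumerated exactly over all `C(n1+n2, n1)` assignments of the pooled
  mid-ranks, which handles ties by construction; the two-sided p is the
  doubled smaller tail capped at 1 (matching common commercial
  software), with a sum-of-both-tails alternative behind a flag.
  Larger samples use the tie-corrected, continuity-corrected normal
  approximation, and every result records which method produced it.
  With complete separation of two groups of four the exact p is
  2/70 ≈ 0.0286 — the resolution floor relevant to the 4-vs-4
  contrasts this pipeline emits.
* **Chance levels**: 50 % (C12), 25 % (C13); "below chance" is a
  strict inequality, and C11 has no chance level because both options
  are rewarded.
* **KDE**: Gaussian kernel, Silverman's rule-of-thumb bandwidth
  (`0.9 · min(sd, IQR/1.34) · n^(−1/5)`; the cited calculator does not
  state its rule), density evaluated on a grid spanning the data ± 5
  bandwidths; cumulative mass below a threshold is computed from the
  mixture CDF exactly rather than by grid integration.
* **Absolute risk**: per-group probability of below-chance performance
  (empirical proportion by default, KDE mass below chance as the
  smoothed variant), risk difference, and number needed to harm
  (1/|risk difference|, undefined at zero).  Both estimators are
  reported because the upstream description of how distributions fed
  the risk calculator is not specific.
* No multiplicity adjustment is applied by default, matching the
  source analysis; Holm-adjusted p-values are available behind a
  config flag.

## Determinism

A single master seed drives everything, split hierarchically
(cohort jitter → subject → day) with `numpy` `SeedSequence` spawn
keys, so `simulate → score → analyze` is bit-reproducible and editing
one subject never reshuffles another.  The run manifest records the
config hash, seed and package version needed to regenerate every
table.

## Problem sizes used in the checks

The test suite uses 10,000 presentations for chance reproduction,
5,000 C13 presentations for the perseverative-selection check, 500
paired sessions for SFI neutrality, 1,000 random sessions for the
error-taxonomy oracle, 2,000 replicates for the null calibration of
the exact test, and 20 seeds of the full 44-subject experiment for
phenotype recovery — sizes at which Monte-Carlo error is comfortably
inside each asserted tolerance while the whole suite stays fast.

## Known limitations

* The agent is a per-hole value learner; it has no representation of
  configuration context, so cross-stage interference is structural
  (see above) and C13 ceilings near 55 %.
* Effect sizes for "impaired" parameters are calibrated, not
  estimated from data; no likelihood-based fitting of agent parameters
  is provided.
* Sleep fragmentation is represented only as a parameter change; no
  sleep architecture is modelled.
* Synthetic cohorts reproduce group-level structure (chance
  performers, high performers, conditional collapse), not individual
  rat trajectories, and passing tests establish internal consistency
  of the pipeline — not claims about new animal data.
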