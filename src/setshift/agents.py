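"""Synthetic rat agents for the attentional set-shifting task.

The agent is an attention-weighted exemplar-value learner with softmax choice.
It maintains a value in [0, 1] for every exemplar it has encountered and a
single attention weight splitting the odor and medium dimensions.  Choice
compares the attention-weighted values of the two cups (novel exemplars
transiently capture extra attention weight); learning moves chosen exemplars'
values toward the reward outcome, and attention drifts toward the dimension
whose exemplar values currently discriminate reward best, damped by a
perseveration parameter.  This one mechanism produces the task's hallmark
phenomena:

* attentional-set formation — after several stages with one relevant
  dimension, attention is locked on it, so an intradimensional shift (ID) with
  brand-new exemplars is learned quickly;
* extradimensional-shift cost — at ED the locked attention must re-allocate,
  which is slow when perseveration is high;
* compound-discrimination cost — the novel irrelevant dimension introduced at
  CD transiently captures attention (novel stimuli are salient) and produces
  early errors; at ID and ED every exemplar is new, so the capture is
  symmetric and cancels;
* reversal cost — exemplar values carry over between stages and must be
  unlearned after a reversal.

Response latency is lognormal with a multiplicative elevation in stages that
introduce novel stimuli (CD, ID, ED) and a per-stage multiplicative decline as
the subject habituates to the procedure.

Strain presets (SHR, WKY, SD) and methylphenidate dose transforms encode the
behavioral profiles of a spontaneously-hypertensive-rat ADHD model and its
normoactive controls: SHR = fast, lapse-prone and perseverative; WKY/SD =
slow/intermediate, accurate, set-forming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .schedule import (
    MEDIUM,
    NOVEL_STAGES,
    ODOR,
    STAGE_ORDER,
    Exemplar,
    Schedule,
    StageSpec,
    TrialConfig,
    build_schedule,
    iter_trial_configs,
    latin_square_assignment,
)

CRITERION_RUN = 6  # consecutive correct trials ending a stage
SALIENCE_DECAY = 0.8  # per-sample decay of an exemplar's novelty salience


class AgentError(ValueError):
    pass


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of one simulated rat.

    attn_odor/attn_medium   initial attention split (nonnegative, sums to 1)
    learning_rate           value-update step in (0, 1]
    perseveration           [0, 1); damps attention re-allocation after a rule
                            change (1 would freeze attention entirely)
    lapse                   [0, 0.5); probability of a uniformly random choice
    inverse_temperature     softmax choice determinism (> 0)
    latency_mu/latency_sigma  lognormal location/scale of the first-dig
                            latency, in log-seconds
    novelty_latency_gain    >= 1 typical; latency multiplier in stages that
                            introduce new stimuli (CD, ID, ED)
    stage_decay             >= 0; per-stage multiplicative latency decline
    novelty_salience        >= 0; multiplies the attention weight of an
                            exemplar the agent has rarely sampled (the boost
                            decays geometrically per sample) — the source of
                            distraction by the novel irrelevant dimension
                            introduced at CD
    refuse_prob             [0, 1); per-trial probability of refusing to dig,
                            terminating the session (0 = disabled)
    """

    attn_odor: float = 0.5
    attn_medium: float = 0.5
    learning_rate: float = 0.5
    perseveration: float = 0.5
    lapse: float = 0.02
    inverse_temperature: float = 8.0
    latency_mu: float = 3.0
    latency_sigma: float = 0.35
    novelty_latency_gain: float = 1.5
    stage_decay: float = 0.06
    novelty_salience: float = 14.0
    refuse_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.attn_odor < 0 or self.attn_medium < 0:
            raise AgentError("attention weights must be nonnegative")
        if not math.isclose(self.attn_odor + self.attn_medium, 1.0, abs_tol=1e-9):
            raise AgentError("attention weights must sum to 1")
        if not (0 < self.learning_rate <= 1):
            raise AgentError("learning_rate must be in (0, 1]")
        if not (0 <= self.perseveration < 1):
            raise AgentError("perseveration must be in [0, 1)")
        if not (0 <= self.lapse < 0.5):
            raise AgentError("lapse must be in [0, 0.5)")
        if self.inverse_temperature <= 0:
            raise AgentError("inverse_temperature must be > 0")
        if self.latency_sigma <= 0:
            raise AgentError("latency_sigma must be > 0")
        if self.novelty_latency_gain < 0 or self.stage_decay < 0 or self.novelty_salience < 0:
            raise AgentError("novelty/stage-decay parameters must be >= 0")
        if not (0 <= self.refuse_prob < 1):
            raise AgentError("refuse_prob must be in [0, 1)")


@dataclass
class BeliefState:
    """Exemplar values, sample counts and the current attention split."""

    values: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    attn_odor: float = 0.5

    def value(self, exemplar: Exemplar) -> float:
        return self.values.get(exemplar.label, 0.5)

    def salience(self, exemplar: Exemplar, novelty_salience: float) -> float:
        """Novelty multiplier on attention, decaying geometrically per sample."""
        return 1.0 + novelty_salience * SALIENCE_DECAY ** self.counts.get(
            exemplar.label, 0
        )

    def attention(self, dimension: str) -> float:
        return self.attn_odor if dimension == ODOR else 1.0 - self.attn_odor


def initial_belief(params: AgentParams) -> BeliefState:
    return BeliefState(attn_odor=params.attn_odor)


def pretrained_belief(params: AgentParams, stage_spec: StageSpec) -> BeliefState:
    """Belief that already favors the stage's correct exemplar (no novelty)."""
    b = initial_belief(params)
    for e in stage_spec.exemplars():
        b.values[e.label] = 1.0 if e == stage_spec.correct_exemplar else 0.0
        b.counts[e.label] = 50
    b.attn_odor = (
        1.0 if stage_spec.relevant_dimension == ODOR else 0.0
    ) * 0.98 + 0.01  # near-locked attention
    return b


def _cup_value(params: AgentParams, belief: BeliefState, cup) -> float:
    """Attention-weighted cup value; novel exemplars capture extra weight."""
    exs = [e for e in cup if e is not None]
    raw = [
        belief.attention(e.dimension) * belief.salience(e, params.novelty_salience)
        for e in exs
    ]
    w_total = sum(raw)
    if w_total <= 0:
        weights = [1.0 / len(exs)] * len(exs)
    else:
        weights = [w / w_total for w in raw]
    return sum(w * belief.value(e) for w, e in zip(weights, exs))


def choice_probability_left(
    params: AgentParams, belief: BeliefState, config: TrialConfig
) -> float:
    """Closed-form P(choose left): lapse-mixed softmax over cup values."""
    v_l = _cup_value(params, belief, config.left_cup)
    v_r = _cup_value(params, belief, config.right_cup)
    d = params.inverse_temperature * (v_l - v_r)
    # numerically safe logistic
    p_soft = 1.0 / (1.0 + math.exp(-d)) if abs(d) < 500 else (1.0 if d > 0 else 0.0)
    return params.lapse * 0.5 + (1.0 - params.lapse) * p_soft


def latency_sample(
    params: AgentParams, stage_name: str, rng: np.random.Generator
) -> float:
    """First-dig latency in seconds: lognormal with novelty and stage decay."""
    stage_idx = STAGE_ORDER.index(stage_name)
    mu = params.latency_mu - params.stage_decay * stage_idx
    if stage_name in NOVEL_STAGES:
        mu += math.log(params.novelty_latency_gain)
    return math.exp(mu + params.latency_sigma * rng.standard_normal())


def choose(
    params: AgentParams,
    belief: BeliefState,
    config: TrialConfig,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """One choice: returns (chosen side, latency in seconds)."""
    if rng.random() < params.lapse:
        side = "L" if rng.random() < 0.5 else "R"
    else:
        p_left = (
            choice_probability_left(params, belief, config) - params.lapse * 0.5
        ) / (1.0 - params.lapse)
        side = "L" if rng.random() < p_left else "R"
    return side, latency_sample(params, config.stage_name, rng)


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one trial (carries its TrialConfig for downstream scoring)."""

    stage: str
    trial_index: int
    config: TrialConfig
    chosen_side: str
    correct: bool
    latency_s: float
    exploratory: bool

    @property
    def chosen_exemplars(self) -> list[Exemplar]:
        return self.config.cup_exemplars(self.chosen_side)


def update(
    params: AgentParams, belief: BeliefState, record: TrialRecord
) -> BeliefState:
    """Learning step after one trial (mutates and returns ``belief``).

    Chosen exemplars move toward the reward outcome by ``learning_rate``.  On
    exploratory trials (1-4) the rat digs both cups, so the unchosen cup's
    exemplars are also updated, toward the complementary outcome.  Attention
    then drifts toward the dimension whose exemplar values discriminate the
    two cups best, at a rate damped by ``perseveration``.
    """
    lr = params.learning_rate
    reward = 1.0 if record.correct else 0.0
    for e in record.chosen_exemplars:
        v = belief.values.get(e.label, 0.5)
        belief.values[e.label] = v + lr * (reward - v)
        belief.counts[e.label] = belief.counts.get(e.label, 0) + 1
    if record.exploratory:
        other = "R" if record.chosen_side == "L" else "L"
        for e in record.config.cup_exemplars(other):
            v = belief.values.get(e.label, 0.5)
            belief.values[e.label] = v + lr * ((1.0 - reward) - v)
            belief.counts[e.label] = belief.counts.get(e.label, 0) + 1

    # attention drift: only defined when both dimensions are present
    by_dim: dict[str, list[Exemplar]] = {}
    for side in "LR":
        for e in record.config.cup_exemplars(side):
            by_dim.setdefault(e.dimension, []).append(e)
    if len(by_dim) == 2:
        spreads = {
            dim: abs(belief.value(exs[0]) - belief.value(exs[1]))
            for dim, exs in by_dim.items()
        }
        total = spreads[ODOR] + spreads[MEDIUM]
        if total > 0:
            target = spreads[ODOR] / total
            eta = lr * (1.0 - params.perseveration)
            belief.attn_odor += eta * (target - belief.attn_odor)
            belief.attn_odor = min(1.0, max(0.0, belief.attn_odor))
    return belief


@dataclass
class SessionLog:
    """Per-trial records for one subject across the 7 stages."""

    subject_id: str
    strain: str
    treatment: float  # methylphenidate dose in mg/kg (0 = vehicle)
    schedule: Schedule
    trials: list[TrialRecord] = field(default_factory=list)
    completed: dict[str, bool] = field(default_factory=dict)
    group: str = ""  # cohort group label (defaults to strain at write time)

    def stage_trials(self, stage: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.stage == stage]


def run_session(
    params: AgentParams,
    schedule: Schedule,
    rng: np.random.Generator,
    max_trials_per_stage: int = 150,
    strain: str = "",
    treatment: float = 0.0,
    oracle: bool = False,
) -> SessionLog:
    """Simulate one full 7-stage session.

    Each stage runs until six consecutive correct responses or the trial cap;
    a capped stage is flagged incomplete but subsequent stages still run.
    Belief carries over between stages — this carry-over is what makes
    reversals and shifts costly.  With ``oracle=True`` the agent always
    chooses the baited cup (an error-free reference subject).
    """
    if max_trials_per_stage < CRITERION_RUN:
        raise AgentError(f"max_trials_per_stage must be >= {CRITERION_RUN}")
    belief = initial_belief(params)
    log = SessionLog(schedule.subject_id, strain, treatment, schedule)
    refused = False
    for spec in schedule.stages:
        if refused:
            log.completed[spec.name] = False
            continue
        streak = 0
        n = 0
        for config in iter_trial_configs(spec, rng):
            if params.refuse_prob > 0 and rng.random() < params.refuse_prob:
                refused = True
                break
            n += 1
            if oracle:
                side = config.baited_side
                latency = latency_sample(params, spec.name, rng)
            else:
                side, latency = choose(params, belief, config, rng)
            correct = side == config.baited_side
            record = TrialRecord(
                stage=spec.name,
                trial_index=config.trial_index,
                config=config,
                chosen_side=side,
                correct=correct,
                latency_s=latency,
                exploratory=config.exploratory,
            )
            log.trials.append(record)
            if not oracle:
                update(params, belief, record)
            streak = streak + 1 if correct else 0
            if streak >= CRITERION_RUN or n >= max_trials_per_stage:
                break
        log.completed[spec.name] = streak >= CRITERION_RUN
    return log


# --------------------------------------------------------------------------
# strain presets and methylphenidate dose transforms
# --------------------------------------------------------------------------

#: Default parameters per strain.  WKY and SD share the control behavioral
#: profile and differ only in speed; the SHR preset is fast (short latencies),
#: lapse-prone (attentional lapses at every stage) and strongly perseverative
#: (attention barely re-allocates, so no attentional set forms and the
#: extradimensional shift shows no extra cost over ID).  latency_mu values are
#: calibrated so that cohort grand-mean latencies land on the three strain
#: anchors (SHR ~14.7 s < SD ~26.9 s < WKY ~46.4 s).
STRAIN_PRESETS: dict[str, AgentParams] = {
    "SHR": AgentParams(
        learning_rate=0.30,
        perseveration=0.995,
        lapse=0.14,
        inverse_temperature=6.0,
        latency_mu=2.60,
        latency_sigma=0.35,
        novelty_salience=14.0,
    ),
    "WKY": AgentParams(
        learning_rate=0.5,
        perseveration=0.93,
        lapse=0.005,
        inverse_temperature=20.0,
        latency_mu=3.73,
        latency_sigma=0.35,
        novelty_salience=20.0,
    ),
    "SD": AgentParams(
        learning_rate=0.5,
        perseveration=0.93,
        lapse=0.005,
        inverse_temperature=20.0,
        latency_mu=3.19,
        latency_sigma=0.35,
        novelty_salience=20.0,
    ),
}


@dataclass(frozen=True)
class TreatmentEffect:
    """Additive deltas a methylphenidate dose applies to agent parameters."""

    dose_mg_per_kg: float
    d_lapse: float
    d_perseveration: float
    d_latency_mu: float


#: Dose transforms.  Both doses slow the animal down and reduce attentional
#: lapses; the perseveration reduction is larger at the low dose (the
#: inverted-U dose-response: high doses fail to release perseveration).
TREATMENT_EFFECTS: dict[float, TreatmentEffect] = {
    0.0: TreatmentEffect(0.0, 0.0, 0.0, 0.0),
    2.5: TreatmentEffect(2.5, -0.10, -0.45, +0.45),
    5.0: TreatmentEffect(5.0, -0.06, -0.15, +0.70),
}


def apply_treatment(preset: AgentParams, dose_mg_per_kg: float) -> AgentParams:
    """Return ``preset`` with the dose's parameter deltas applied."""
    try:
        eff = TREATMENT_EFFECTS[float(dose_mg_per_kg)]
    except KeyError:
        raise AgentError(
            f"unsupported dose {dose_mg_per_kg!r}; known doses: "
            f"{sorted(TREATMENT_EFFECTS)}"
        ) from None
    if eff.dose_mg_per_kg == 0.0:
        return preset
    return replace(
        preset,
        lapse=min(0.499, max(0.0, preset.lapse + eff.d_lapse)),
        perseveration=min(0.999, max(0.0, preset.perseveration + eff.d_perseveration)),
        latency_mu=preset.latency_mu + eff.d_latency_mu,
    )


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: a strain preset, a dose, and a group size."""

    name: str
    preset: str  # key into STRAIN_PRESETS
    dose_mg_per_kg: float = 0.0
    n: int = 8


#: Experiment-1 design: three strains, 8 subjects each, no drug.
EXPERIMENT_1 = (
    GroupSpec("SHR", "SHR", 0.0, 8),
    GroupSpec("WKY", "WKY", 0.0, 8),
    GroupSpec("SD", "SD", 0.0, 8),
)

#: Experiment-2 design: SHR cohorts under vehicle, 2.5 and 5 mg/kg
#: methylphenidate.
EXPERIMENT_2 = (
    GroupSpec("SHR-vehicle", "SHR", 0.0, 8),
    GroupSpec("MPH-L", "SHR", 2.5, 8),
    GroupSpec("MPH-H", "SHR", 5.0, 8),
)


def simulate_cohort(
    design: Sequence[GroupSpec],
    seed: int,
    max_trials_per_stage: int = 150,
    param_overrides: Optional[dict[str, dict]] = None,
) -> list[SessionLog]:
    """Simulate a full cohort with per-group counterbalancing.

    Subject-level generators are spawned deterministically from the master
    seed.  Within each group the pair->block latin square rotates across
    subjects and series 1/2 alternate, as in the standard counterbalanced
    design.  ``param_overrides`` maps group name -> AgentParams field dict.
    """
    root = np.random.SeedSequence(seed)
    logs: list[SessionLog] = []
    streams = iter(root.spawn(sum(g.n for g in design))) if design else iter(())
    for group in design:
        if group.preset not in STRAIN_PRESETS:
            raise AgentError(
                f"unknown preset {group.preset!r}; known: {sorted(STRAIN_PRESETS)}"
            )
        params = apply_treatment(STRAIN_PRESETS[group.preset], group.dose_mg_per_kg)
        if param_overrides and group.name in param_overrides:
            params = replace(params, **param_overrides[group.name])
        if group.n == 0:
            continue
        assignments = latin_square_assignment(group.n)
        for i in range(group.n):
            sched = build_schedule(
                subject_id=f"{group.name}_{i + 1:02d}",
                series=1 if i % 2 == 0 else 2,
                pair_assignment=assignments[i],
            )
            rng = np.random.default_rng(next(streams))
            log = run_session(
                params,
                sched,
                rng,
                max_trials_per_stage=max_trials_per_stage,
                strain=group.preset,
                treatment=group.dose_mg_per_kg,
            )
            log.group = group.name
            logs.append(log)
    return logs
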