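"""Scoring of set-shifting session logs.

Per stage: trials and errors to the criterion of six consecutive correct
responses, mean first-dig latency, and the three-way error taxonomy used in
rodent set-shifting work:

* perseverative — errors consistent with the previously rewarded rule while
  the subject is still responding under it.  Trials are partitioned into
  consecutive blocks of four from the first trial of the stage; while the
  subject is in the perseveration phase, a block with three or more errors
  (of any type) marks its old-rule-consistent errors perseverative.
* regressive — old-rule-consistent errors from the first block with two or
  fewer errors onward (the subject has begun disengaging from the old rule
  but fails to maintain the new one).
* never-reinforced — errors consistent with no previously rewarded rule.

Old-rule consistency in a two-choice compound task:

* reversal stages (CDR/IDR/EDR): every error chooses the previously correct
  exemplar (the only other option), so all errors are old-rule-consistent;
* acquisition stages (SD/CD/ID): the previous rule equals or contains the
  current one, so no error can be old-rule-consistent — all errors are
  never-reinforced;
* ED: all exemplars are new, so the old rule (the previously relevant
  dimension) is anchored to the previous-dimension exemplar in the cup chosen
  on the stage's first error; later errors choosing cups with that anchor are
  old-rule-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .agents import CRITERION_RUN, SessionLog, TrialRecord
from .schedule import REVERSAL_STAGES, StageSpec

BLOCK_SIZE = 4  # trials per scoring block
PERSEVERATION_THRESHOLD = 3  # errors per block that keep the perseveration phase


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class StageMetrics:
    stage: str
    trials_to_criterion: int  # includes the 6 criterion trials
    errors_to_criterion: int
    mean_latency_s: float
    completed: bool


@dataclass(frozen=True)
class ErrorBreakdown:
    perseverative: int
    regressive: int
    never_reinforced: int

    @property
    def total(self) -> int:
        return self.perseverative + self.regressive + self.never_reinforced


@dataclass(frozen=True)
class SetFormationContrasts:
    """Trial-count differences diagnosing an attentional set (positive = set)."""

    cd_minus_id: int
    ed_minus_id: int


def trials_to_criterion(stage_trials: Sequence[TrialRecord]) -> StageMetrics:
    """Locate the first run of six consecutive correct trials.

    Returns the 1-based index of the trial completing the run; errors and mean
    latency are computed over trials 1..that index.  If no run exists the
    stage is flagged incomplete and totals cover all trials.
    """
    if not stage_trials:
        raise ScoringError("empty stage trial list")
    stage = stage_trials[0].stage
    streak = 0
    end: Optional[int] = None
    for i, t in enumerate(stage_trials):
        streak = streak + 1 if t.correct else 0
        if streak >= CRITERION_RUN:
            end = i + 1
            break
    completed = end is not None
    upto = stage_trials[:end] if completed else list(stage_trials)
    errors = sum(1 for t in upto if not t.correct)
    mean_lat = float(np.mean([t.latency_s for t in upto]))
    return StageMetrics(
        stage=stage,
        trials_to_criterion=len(upto),
        errors_to_criterion=errors,
        mean_latency_s=mean_lat,
        completed=completed,
    )


def _old_rule_consistent(
    stage_trials: Sequence[TrialRecord], stage_spec: StageSpec
) -> list[bool]:
    """Tag each trial's error (True/False) as consistent with the old rule.

    Correct trials get False (they are not errors).  See the module docstring
    for the per-stage-role definition.
    """
    name = stage_spec.name
    if name in REVERSAL_STAGES:
        if stage_spec.previous_correct_exemplar is None:
            raise ScoringError(f"{name} stage spec lacks previous_correct_exemplar")
        return [not t.correct for t in stage_trials]
    if name == "ED":
        if stage_spec.previous_relevant_dimension is None:
            raise ScoringError("ED stage spec lacks previous_relevant_dimension")
        prev_dim = stage_spec.previous_relevant_dimension
        anchor: Optional[str] = None
        out = []
        for t in stage_trials:
            if t.correct:
                out.append(False)
                continue
            chosen_prev_dim = [
                e.label
                for e in t.config.cup_exemplars(t.chosen_side)
                if e.dimension == prev_dim
            ]
            if anchor is None:
                anchor = chosen_prev_dim[0] if chosen_prev_dim else None
                out.append(anchor is not None)
            else:
                out.append(anchor in chosen_prev_dim)
        return out
    # acquisition stages: no previously rewarded rule competes
    return [False for _ in stage_trials]


def classify_errors(
    stage_trials: Sequence[TrialRecord], stage_spec: StageSpec
) -> ErrorBreakdown:
    """Partition a stage's errors into perseverative / regressive / never-reinforced.

    Blocks of four trials are anchored at trial 1 (a final short block uses the
    same >=3 threshold, so a two-trial tail can never be perseverative).  The
    block that switches the phase already counts its old-rule-consistent errors
    as regressive.
    """
    if not stage_trials:
        return ErrorBreakdown(0, 0, 0)
    consistent = _old_rule_consistent(stage_trials, stage_spec)
    persev = regress = never = 0
    persev_phase = True
    for start in range(0, len(stage_trials), BLOCK_SIZE):
        block = stage_trials[start : start + BLOCK_SIZE]
        block_cons = consistent[start : start + BLOCK_SIZE]
        n_errors = sum(1 for t in block if not t.correct)
        if persev_phase and n_errors < PERSEVERATION_THRESHOLD:
            persev_phase = False
        for t, is_cons in zip(block, block_cons):
            if t.correct:
                continue
            if not is_cons:
                never += 1
            elif persev_phase:
                persev += 1
            else:
                regress += 1
    return ErrorBreakdown(persev, regress, never)


def stage_metrics_table(
    session_log: SessionLog,
) -> list[tuple[StageMetrics, ErrorBreakdown]]:
    """Score every stage of a session, in task order."""
    out = []
    for spec in session_log.schedule.stages:
        trials = session_log.stage_trials(spec.name)
        if not trials:
            raise ScoringError(
                f"session {session_log.subject_id} has no trials for stage {spec.name}"
            )
        metrics = trials_to_criterion(trials)
        scored = trials[: metrics.trials_to_criterion]
        out.append((metrics, classify_errors(scored, spec)))
    return out


def set_formation_contrasts(
    metrics_table: Sequence[tuple[StageMetrics, ErrorBreakdown]]
) -> SetFormationContrasts:
    """CD-ID and ED-ID trial differences; requires all three stages completed."""
    by_stage = {m.stage: m for m, _ in metrics_table}
    for s in ("CD", "ID", "ED"):
        if s not in by_stage:
            raise ScoringError(f"stage {s} missing from metrics table")
        if not by_stage[s].completed:
            raise ScoringError(f"stage {s} did not reach criterion")
    return SetFormationContrasts(
        cd_minus_id=by_stage["CD"].trials_to_criterion
        - by_stage["ID"].trials_to_criterion,
        ed_minus_id=by_stage["ED"].trials_to_criterion
        - by_stage["ID"].trials_to_criterion,
    )
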