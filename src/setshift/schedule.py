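"""Counterbalanced schedules for the seven-stage attentional set-shifting task.

The task is a sequence of two-choice digging discriminations over compound
stimuli (an odor crossed with a digging medium).  Stage order is fixed:

    SD   simple discrimination (one dimension only)
    CD   compound discrimination (irrelevant dimension introduced)
    CDR  reversal of CD
    ID   intradimensional shift (new exemplars, same relevant dimension)
    IDR  reversal of ID
    ED   extradimensional shift (new exemplars, relevant dimension flips)
    EDR  reversal of ED

Counterbalancing follows the standard design: three exemplar pairs rotate
through the three stage blocks via a latin square, half the subjects shift
odor->medium at ED (series 1) and half medium->odor (series 2), and within a
stage neither the exemplar combination nor the baited side repeats more than
twice in a row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

ODOR = "odor"
MEDIUM = "medium"
DIMENSIONS = (ODOR, MEDIUM)

STAGE_ORDER = ("SD", "CD", "CDR", "ID", "IDR", "ED", "EDR")
REVERSAL_STAGES = frozenset({"CDR", "IDR", "EDR"})
#: stages that introduce exemplars (or a whole dimension) the subject has not seen
NOVEL_STAGES = frozenset({"CD", "ID", "ED"})

#: the three stage blocks that share an exemplar pair
STAGE_BLOCKS = ("SD/CD/CDR", "ID/IDR", "ED/EDR")
MAX_RUN = 2  # neither combination nor side may repeat more than twice


class ScheduleError(ValueError):
    """Raised for invalid schedule construction requests."""


@dataclass(frozen=True)
class Exemplar:
    """One stimulus exemplar: an odor (O1..O6) or a digging medium (M1..M6)."""

    dimension: str
    label: str

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ScheduleError(f"unknown dimension {self.dimension!r}")
        prefix = "O" if self.dimension == ODOR else "M"
        if not self.label.startswith(prefix):
            raise ScheduleError(
                f"label {self.label!r} does not match dimension {self.dimension!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def _pair(dimension: str, index: int) -> tuple[Exemplar, Exemplar]:
    """Exemplar pair ``index`` (1-3) of a dimension: (O1,O2), (O3,O4), ..."""
    prefix = "O" if dimension == ODOR else "M"
    a, b = 2 * index - 1, 2 * index
    return (Exemplar(dimension, f"{prefix}{a}"), Exemplar(dimension, f"{prefix}{b}"))


@dataclass(frozen=True)
class StageSpec:
    """Contract for one discrimination stage."""

    name: str
    relevant_dimension: str
    correct_exemplar: Exemplar
    exemplar_pair_relevant: tuple[Exemplar, Exemplar]
    exemplar_pair_irrelevant: Optional[tuple[Exemplar, Exemplar]] = None
    previous_correct_exemplar: Optional[Exemplar] = None
    previous_relevant_dimension: Optional[str] = None

    def __post_init__(self) -> None:
        if self.name not in STAGE_ORDER:
            raise ScheduleError(f"unknown stage {self.name!r}")
        if self.correct_exemplar not in self.exemplar_pair_relevant:
            raise ScheduleError("correct exemplar not in the relevant pair")
        if self.name == "SD" and self.exemplar_pair_irrelevant is not None:
            raise ScheduleError("SD has no irrelevant dimension")
        if self.name in REVERSAL_STAGES and self.previous_correct_exemplar is None:
            raise ScheduleError(f"{self.name} requires previous_correct_exemplar")
        if self.name == "ED" and self.previous_relevant_dimension is None:
            raise ScheduleError("ED requires previous_relevant_dimension")

    @property
    def is_compound(self) -> bool:
        return self.exemplar_pair_irrelevant is not None

    def exemplars(self) -> list[Exemplar]:
        out = list(self.exemplar_pair_relevant)
        if self.exemplar_pair_irrelevant is not None:
            out.extend(self.exemplar_pair_irrelevant)
        return out


Cup = tuple[Optional[Exemplar], Optional[Exemplar]]  # (odor, medium)


@dataclass(frozen=True)
class TrialConfig:
    """One trial: the two cup compounds and which side is baited."""

    stage_name: str
    trial_index: int  # 1-based within stage
    left_cup: Cup
    right_cup: Cup
    baited_side: str  # "L" or "R"
    exploratory: bool

    def cup(self, side: str) -> Cup:
        return self.left_cup if side == "L" else self.right_cup

    def cup_exemplars(self, side: str) -> list[Exemplar]:
        return [e for e in self.cup(side) if e is not None]


@dataclass(frozen=True)
class Schedule:
    """Full per-subject task schedule: 7 stages in fixed order."""

    subject_id: str
    series: int  # 1: odor->medium at ED; 2: medium->odor
    pair_assignment: dict[int, str]  # exemplar pair index (1-3) -> stage block
    stages: tuple[StageSpec, ...]

    def stage(self, name: str) -> StageSpec:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)


def latin_square_assignment(n_subjects: int) -> list[dict[int, str]]:
    """Cycle pair->block assignments through the 3 rotations of a 3x3 latin square.

    Subject ``i`` receives rotation ``i % 3``; over any 3 consecutive subjects
    each exemplar pair serves each stage block exactly once.  Subject 0 gets the
    identity assignment (pair 1 -> SD/CD/CDR).
    """
    if n_subjects < 1:
        raise ScheduleError("n_subjects must be >= 1")
    out = []
    for i in range(n_subjects):
        r = i % 3
        out.append({p: STAGE_BLOCKS[(p - 1 + r) % 3] for p in (1, 2, 3)})
    return out


def _block_pairs(pair_assignment: dict[int, str]) -> dict[str, int]:
    """Invert a pair->block mapping, rejecting non-bijections."""
    if sorted(pair_assignment) != [1, 2, 3] or sorted(
        pair_assignment.values()
    ) != sorted(STAGE_BLOCKS):
        raise ScheduleError(
            "pair_assignment must be a bijection from pairs {1,2,3} onto "
            f"the stage blocks {STAGE_BLOCKS}"
        )
    return {block: pair for pair, block in pair_assignment.items()}


def build_stage_sequence(
    series: int, pair_assignment: dict[int, str]
) -> tuple[StageSpec, ...]:
    """Construct the 7 StageSpecs for one subject.

    Series 1 uses odor as the relevant dimension from SD through IDR and flips
    to medium at ED; series 2 is the mirror image.  Within each block the first
    exemplar of the relevant pair is correct at acquisition and the second
    after reversal.
    """
    if series not in (1, 2):
        raise ScheduleError("series must be 1 or 2")
    block_pair = _block_pairs(pair_assignment)
    dim1 = ODOR if series == 1 else MEDIUM  # relevant SD..IDR
    dim2 = MEDIUM if series == 1 else ODOR  # relevant ED/EDR

    def pairs_for(block: str) -> tuple[tuple[Exemplar, Exemplar], tuple[Exemplar, Exemplar]]:
        idx = block_pair[block]
        return _pair(dim1, idx), _pair(dim2, idx)

    acq_rel, acq_irr = pairs_for("SD/CD/CDR")
    id_rel, id_irr = pairs_for("ID/IDR")
    # at ED the previously irrelevant dimension becomes relevant
    ed_irr, ed_rel = pairs_for("ED/EDR")

    stages = (
        StageSpec("SD", dim1, acq_rel[0], acq_rel),
        StageSpec("CD", dim1, acq_rel[0], acq_rel, acq_irr),
        StageSpec("CDR", dim1, acq_rel[1], acq_rel, acq_irr,
                  previous_correct_exemplar=acq_rel[0]),
        StageSpec("ID", dim1, id_rel[0], id_rel, id_irr),
        StageSpec("IDR", dim1, id_rel[1], id_rel, id_irr,
                  previous_correct_exemplar=id_rel[0]),
        StageSpec("ED", dim2, ed_rel[0], ed_rel, ed_irr,
                  previous_relevant_dimension=dim1),
        StageSpec("EDR", dim2, ed_rel[1], ed_rel, ed_irr,
                  previous_correct_exemplar=ed_rel[0]),
    )
    return stages


def build_schedule(
    subject_id: str, series: int, pair_assignment: dict[int, str]
) -> Schedule:
    return Schedule(
        subject_id=subject_id,
        series=series,
        pair_assignment=dict(pair_assignment),
        stages=build_stage_sequence(series, pair_assignment),
    )


def _combinations(spec: StageSpec) -> list[tuple[Cup, Cup]]:
    """The cup compound configurations of a stage, as (correct cup, foil cup).

    Compound stages have exactly two: relevant/irrelevant exemplars aligned
    (a/a vs b/b) or crossed (a/b vs b/a).  SD has a single configuration.
    """
    r1, r2 = spec.exemplar_pair_relevant
    if spec.correct_exemplar == r2:
        r1, r2 = r2, r1  # r1 is the correct exemplar
    def cup(*exs: Exemplar) -> Cup:
        odor = next((e for e in exs if e.dimension == ODOR), None)
        medium = next((e for e in exs if e.dimension == MEDIUM), None)
        return (odor, medium)

    if not spec.is_compound:
        return [(cup(r1), cup(r2))]
    i1, i2 = spec.exemplar_pair_irrelevant
    return [(cup(r1, i1), cup(r2, i2)), (cup(r1, i2), cup(r2, i1))]


def _constrained_pick(rng: np.random.Generator, n_options: int, history: list[int]) -> int:
    """Pick an option uniformly among those not extending a run past MAX_RUN."""
    if len(history) >= MAX_RUN and len(set(history[-MAX_RUN:])) == 1:
        banned = history[-1]
        options = [o for o in range(n_options) if o != banned]
    else:
        options = list(range(n_options))
    if not options:  # unreachable with >=2 options; guard per contract
        raise ScheduleError("no feasible extension under the run-length constraint")
    return options[int(rng.integers(len(options)))] if len(options) > 1 else options[0]


def generate_trial_configs(
    stage_spec: StageSpec, rng: np.random.Generator, n_trials: int
) -> list[TrialConfig]:
    """Pseudorandom trial list for one stage under the run-length constraints.

    Exemplar combination and baited side are each drawn independently, with a
    per-trial feasibility check so that neither repeats more than twice in a
    row.  Reproducible from the generator's state.
    """
    if n_trials < 1:
        raise ScheduleError("n_trials must be >= 1")
    combos = _combinations(stage_spec)
    combo_hist: list[int] = []
    side_hist: list[int] = []
    configs = []
    for t in range(1, n_trials + 1):
        c = (
            _constrained_pick(rng, len(combos), combo_hist)
            if len(combos) > 1
            else 0
        )
        s = _constrained_pick(rng, 2, side_hist)
        combo_hist.append(c)
        side_hist.append(s)
        correct_cup, foil_cup = combos[c]
        side = "LR"[s]
        left, right = (correct_cup, foil_cup) if side == "L" else (foil_cup, correct_cup)
        configs.append(
            TrialConfig(
                stage_name=stage_spec.name,
                trial_index=t,
                left_cup=left,
                right_cup=right,
                baited_side=side,
                exploratory=t <= 4,
            )
        )
    return configs


def iter_trial_configs(
    stage_spec: StageSpec, rng: np.random.Generator
) -> Iterator[TrialConfig]:
    """Lazy, unbounded version of :func:`generate_trial_configs`."""
    combos = _combinations(stage_spec)
    combo_hist: list[int] = []
    side_hist: list[int] = []
    t = 0
    while True:
        t += 1
        c = _constrained_pick(rng, len(combos), combo_hist) if len(combos) > 1 else 0
        s = _constrained_pick(rng, 2, side_hist)
        combo_hist = (combo_hist + [c])[-MAX_RUN:]
        side_hist = (side_hist + [s])[-MAX_RUN:]
        correct_cup, foil_cup = combos[c]
        side = "LR"[s]
        left, right = (correct_cup, foil_cup) if side == "L" else (foil_cup, correct_cup)
        yield TrialConfig(
            stage_name=stage_spec.name,
            trial_index=t,
            left_cup=left,
            right_cup=right,
            baited_side=side,
            exploratory=t <= 4,
        )


@dataclass(frozen=True)
class Violation:
    kind: str  # shared_exemplar | bait_mismatch | combination_run | side_run
    trial_index: int
    message: str


def validate_schedule(
    configs: Sequence[TrialConfig], stage_spec: Optional[StageSpec] = None
) -> list[Violation]:
    """Check a stage's trial list against the counterbalancing contracts.

    Returns one record per violated constraint; an empty list means valid.
    Bait placement is checked only when ``stage_spec`` is supplied (it needs
    the stage's correct exemplar).  The combination run-length rule applies
    only to compound stages — a single-dimension stage has one configuration.
    """
    if not configs:
        raise ScheduleError("empty config list")
    out: list[Violation] = []
    combo_keys = []
    sides = []
    for cfg in configs:
        left = set(e.label for e in cfg.cup_exemplars("L"))
        right = set(e.label for e in cfg.cup_exemplars("R"))
        shared = left & right
        if shared:
            out.append(
                Violation("shared_exemplar", cfg.trial_index,
                          f"cups share exemplar(s) {sorted(shared)}")
            )
        if stage_spec is not None:
            lab = stage_spec.correct_exemplar.label
            holders = [s for s, cup in (("L", left), ("R", right)) if lab in cup]
            if len(holders) != 1 or holders[0] != cfg.baited_side:
                out.append(
                    Violation("bait_mismatch", cfg.trial_index,
                              f"baited side {cfg.baited_side} does not hold the "
                              f"correct exemplar {lab}")
                )
        combo_keys.append(frozenset({tuple(sorted(left)), tuple(sorted(right))}))
        sides.append(cfg.baited_side)

    compound = all(len(cfg.cup_exemplars("L")) == 2 for cfg in configs)
    if compound:
        for i in range(MAX_RUN, len(combo_keys)):
            if combo_keys[i] == combo_keys[i - 1] == combo_keys[i - 2]:
                out.append(
                    Violation("combination_run", configs[i].trial_index,
                              "same exemplar combination on 3 consecutive trials")
                )
    for i in range(MAX_RUN, len(sides)):
        if sides[i] == sides[i - 1] == sides[i - 2]:
            out.append(
                Violation("side_run", configs[i].trial_index,
                          "same baited side on 3 consecutive trials")
            )
    return out
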