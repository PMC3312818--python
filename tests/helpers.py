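"""Shared test helpers (kept out of conftest so tests can import them)."""

from setshift.agents import TrialRecord
from setshift.scoring import ErrorBreakdown
from setshift.schedule import generate_trial_configs


def make_trials(spec, pattern, rng, chooser=None):
    """Build TrialRecords for one stage from a correctness pattern.

    ``pattern``: string of 'C' (correct) / 'E' (error).  By default an error
    chooses the unbaited cup and a correct trial the baited one; ``chooser``
    overrides the chosen side per trial: (index, config, is_error) -> side.
    """
    configs = generate_trial_configs(spec, rng, len(pattern))
    out = []
    for i, (ch, cfg) in enumerate(zip(pattern, configs)):
        is_error = ch == "E"
        if chooser is not None:
            side = chooser(i, cfg, is_error)
        else:
            side = (
                ("R" if cfg.baited_side == "L" else "L")
                if is_error
                else cfg.baited_side
            )
        out.append(
            TrialRecord(
                stage=spec.name,
                trial_index=cfg.trial_index,
                config=cfg,
                chosen_side=side,
                correct=side == cfg.baited_side,
                latency_s=10.0,
                exploratory=cfg.exploratory,
            )
        )
    return out


def brute_force_classify(trials, spec):
    """Independent literal implementation of the error taxonomy (test oracle).

    Materializes the four-trial blocks and the perseveration phase explicitly,
    with its own old-rule tagging, so it shares no code with the package's
    classifier.
    """
    reversals = {"CDR", "IDR", "EDR"}
    consistent = []
    anchor = "unset"
    for t in trials:
        if t.correct:
            consistent.append(False)
            continue
        if spec.name in reversals:
            consistent.append(True)
        elif spec.name == "ED":
            prev = spec.previous_relevant_dimension
            chosen_prev = [
                e.label
                for e in t.config.cup_exemplars(t.chosen_side)
                if e.dimension == prev
            ]
            if anchor == "unset":
                anchor = chosen_prev[0] if chosen_prev else None
                consistent.append(anchor is not None)
            else:
                consistent.append(anchor is not None and anchor in chosen_prev)
        else:
            consistent.append(False)
    blocks = [
        list(range(i, min(i + 4, len(trials)))) for i in range(0, len(trials), 4)
    ]
    phase = "perseverating"
    p = r = n = 0
    for blk in blocks:
        errs = [i for i in blk if not trials[i].correct]
        if phase == "perseverating" and len(errs) <= 2:
            phase = "disengaged"
        for i in errs:
            if not consistent[i]:
                n += 1
            elif phase == "perseverating":
                p += 1
            else:
                r += 1
    return ErrorBreakdown(p, r, n)


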