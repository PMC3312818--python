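"""Flat-file I/O for trial logs and scored metrics.

Trial logs are UTF-8 comma-delimited tables, one row per trial, preceded by
``#``-prefixed header comments that record the seed and configuration hash of
the run that produced them.  Column dictionary in FORMATS.md.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .agents import CRITERION_RUN, SessionLog, TrialRecord
from .schedule import STAGE_BLOCKS, Exemplar, TrialConfig, build_schedule

TRIAL_LOG_COLUMNS = [
    "subject_id",
    "group",
    "strain",
    "treatment",
    "series",
    "pairs",
    "stage",
    "trial_index",
    "left_odor",
    "left_medium",
    "right_odor",
    "right_medium",
    "baited_side",
    "chosen_side",
    "correct",
    "latency_s",
    "exploratory",
]

METRICS_COLUMNS = [
    "subject_id",
    "group",
    "strain",
    "treatment",
    "stage",
    "trials_to_criterion",
    "errors_to_criterion",
    "mean_latency_s",
    "perseverative",
    "regressive",
    "never_reinforced",
    "completed",
]


class SchemaError(ValueError):
    pass


def _pairs_code(pair_assignment: dict[int, str]) -> str:
    """Encode a pair->block assignment as the pair index per block, in block order."""
    block_pair = {block: pair for pair, block in pair_assignment.items()}
    return "-".join(str(block_pair[b]) for b in STAGE_BLOCKS)


def _pairs_decode(code: str) -> dict[int, str]:
    idx = [int(p) for p in str(code).split("-")]
    return {pair: block for pair, block in zip(idx, STAGE_BLOCKS)}


def _label(e: Optional[Exemplar]) -> str:
    return "" if e is None else e.label


def session_to_frame(log: SessionLog) -> pd.DataFrame:
    rows = []
    pairs = _pairs_code(log.schedule.pair_assignment)
    for t in log.trials:
        c = t.config
        rows.append(
            {
                "subject_id": log.subject_id,
                "group": getattr(log, "group", "") or _default_group(log),
                "strain": log.strain,
                "treatment": log.treatment,
                "series": log.schedule.series,
                "pairs": pairs,
                "stage": t.stage,
                "trial_index": t.trial_index,
                "left_odor": _label(c.left_cup[0]),
                "left_medium": _label(c.left_cup[1]),
                "right_odor": _label(c.right_cup[0]),
                "right_medium": _label(c.right_cup[1]),
                "baited_side": c.baited_side,
                "chosen_side": t.chosen_side,
                "correct": int(t.correct),
                "latency_s": t.latency_s,
                "exploratory": int(t.exploratory),
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def _default_group(log: SessionLog) -> str:
    if log.treatment:
        return f"{log.strain}+MPH{log.treatment:g}"
    return log.strain


def logs_to_frame(logs: Sequence[SessionLog]) -> pd.DataFrame:
    if not logs:
        return pd.DataFrame(columns=TRIAL_LOG_COLUMNS)
    return pd.concat([session_to_frame(g) for g in logs], ignore_index=True)


def _write_with_header(
    df: pd.DataFrame, path, seed: Optional[int], config_hash: Optional[str]
) -> None:
    buf = _io.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    if config_hash is not None:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def write_trial_log(
    logs: Sequence[SessionLog],
    path,
    seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> None:
    _write_with_header(logs_to_frame(logs), path, seed, config_hash)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_trial_log(path) -> list[SessionLog]:
    """Read a trial-log CSV back into SessionLogs.

    Unknown columns are ignored (preserved in the file, not the objects);
    malformed rows and non-contiguous trial indices are rejected with their
    location.  A file holding only the header yields an empty list.
    """
    df = pd.read_csv(path, comment="#", dtype={"pairs": str})
    _require_columns(df, TRIAL_LOG_COLUMNS, path)
    logs: list[SessionLog] = []
    if df.empty:
        return logs
    for subject_id, sub in df.groupby("subject_id", sort=False):
        first = sub.iloc[0]
        schedule = build_schedule(
            str(subject_id), int(first["series"]), _pairs_decode(first["pairs"])
        )
        log = SessionLog(
            subject_id=str(subject_id),
            strain=str(first["strain"]),
            treatment=float(first["treatment"]),
            schedule=schedule,
        )
        log.group = str(first["group"])  # type: ignore[attr-defined]
        for stage, st in sub.groupby("stage", sort=False):
            st = st.sort_values("trial_index")
            idx = st["trial_index"].to_numpy()
            if idx[0] != 1 or (idx[1:] - idx[:-1] != 1).any():
                raise SchemaError(
                    f"{path}: non-contiguous trial indices for subject "
                    f"{subject_id}, stage {stage}"
                )
            streak = 0
            completed = False
            for _, row in st.iterrows():
                left = _cup(row["left_odor"], row["left_medium"])
                right = _cup(row["right_odor"], row["right_medium"])
                cfg = TrialConfig(
                    stage_name=str(stage),
                    trial_index=int(row["trial_index"]),
                    left_cup=left,
                    right_cup=right,
                    baited_side=str(row["baited_side"]),
                    exploratory=bool(int(row["exploratory"])),
                )
                rec = TrialRecord(
                    stage=str(stage),
                    trial_index=int(row["trial_index"]),
                    config=cfg,
                    chosen_side=str(row["chosen_side"]),
                    correct=bool(int(row["correct"])),
                    latency_s=float(row["latency_s"]),
                    exploratory=bool(int(row["exploratory"])),
                )
                log.trials.append(rec)
                streak = streak + 1 if rec.correct else 0
                if streak >= CRITERION_RUN:
                    completed = True
            log.completed[str(stage)] = completed
        logs.append(log)
    return logs


def _cup(odor, medium) -> tuple:
    o = None if pd.isna(odor) or odor == "" else Exemplar("odor", str(odor))
    m = None if pd.isna(medium) or medium == "" else Exemplar("medium", str(medium))
    return (o, m)


def write_metrics(
    df: pd.DataFrame, path, seed: Optional[int] = None, config_hash: Optional[str] = None
) -> None:
    _write_with_header(df, path, seed, config_hash)


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, METRICS_COLUMNS, path)
    return df
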