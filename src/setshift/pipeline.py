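"""End-to-end pipeline: simulate -> score -> analyze, with a manifest.

The analysis battery mirrors the standard treatment of set-shifting data:

* mixed repeated-measures ANOVA (group x stage) on trials to criterion, with
  sphericity-adjusted degrees of freedom;
* mixed ANOVA (group x error subtype) on summed error counts;
* per-stage one-way ANOVAs with Fisher LSD post-hocs on trials;
* paired t-tests CD-vs-ID and ID-vs-ED within each group (set formation);
* Pearson correlation between SD and ED trials within each group.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .agents import EXPERIMENT_1, EXPERIMENT_2, GroupSpec, SessionLog, simulate_cohort
from .io import METRICS_COLUMNS, write_metrics, write_trial_log
from .scoring import stage_metrics_table
from .schedule import STAGE_ORDER
from .stats import (
    StatsError,
    mixed_rm_anova,
    oneway_anova_lsd,
    paired_t,
    pearson_correlation,
)

log = logging.getLogger("setshift")

ERROR_TYPES = ("perseverative", "regressive", "never_reinforced")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration for a pipeline run (YAML-loadable)."""

    seed: int = 0
    design: tuple[GroupSpec, ...] = EXPERIMENT_1
    out_dir: str = "setshift_out"
    max_trials_per_stage: int = 150
    latency_aggregation: str = "trials"  # or "stage_means"
    holm: bool = False  # Holm-adjust LSD p-values (off: plain Fisher LSD)
    param_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.latency_aggregation not in ("trials", "stage_means"):
            raise ConfigError(
                "latency_aggregation must be 'trials' or 'stage_means'"
            )
        if self.max_trials_per_stage < 6:
            raise ConfigError("max_trials_per_stage must be >= 6")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        design = raw.pop("design", "experiment1")
        if design == "experiment1":
            groups: tuple[GroupSpec, ...] = EXPERIMENT_1
        elif design == "experiment2":
            groups = EXPERIMENT_2
        elif isinstance(design, (list, tuple)):
            groups = tuple(
                GroupSpec(
                    name=g["name"],
                    preset=g.get("preset", g["name"]),
                    dose_mg_per_kg=float(g.get("dose", 0.0)),
                    n=int(g.get("n", 8)),
                )
                for g in design
            )
        else:
            raise ConfigError(f"unrecognized design {design!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(design=groups, **raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload["design"] = [dataclasses.asdict(g) for g in self.design]
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def score_logs(logs: Sequence[SessionLog]) -> pd.DataFrame:
    """One row per subject x stage with metrics and the error breakdown."""
    rows = []
    for s in logs:
        table = stage_metrics_table(s)
        for metrics, errors in table:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group or s.strain,
                    "strain": s.strain,
                    "treatment": s.treatment,
                    "stage": metrics.stage,
                    "trials_to_criterion": metrics.trials_to_criterion,
                    "errors_to_criterion": metrics.errors_to_criterion,
                    "mean_latency_s": metrics.mean_latency_s,
                    "perseverative": errors.perseverative,
                    "regressive": errors.regressive,
                    "never_reinforced": errors.never_reinforced,
                    "completed": int(metrics.completed),
                }
            )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def grand_mean_latency(
    logs: Sequence[SessionLog], aggregation: str = "trials"
) -> float:
    """Cohort grand-mean first-dig latency.

    ``trials``: mean over every trial of every subject (the default);
    ``stage_means``: mean of per-stage mean latencies (each stage weighted
    equally).
    """
    if aggregation == "trials":
        lats = [t.latency_s for s in logs for t in s.trials]
        return float(pd.Series(lats).mean())
    if aggregation == "stage_means":
        means = [
            m.mean_latency_s for s in logs for m, _ in stage_metrics_table(s)
        ]
        return float(pd.Series(means).mean())
    raise ConfigError(f"unknown latency aggregation {aggregation!r}")


def _holm(pairs):
    """Holm step-down adjustment over a list of PairwiseResult."""
    order = sorted(range(len(pairs)), key=lambda i: pairs[i].p_lsd)
    m = len(pairs)
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * pairs[i].p_lsd))
        adj[i] = running
    return [dataclasses.replace(p, p_lsd=a) for p, a in zip(pairs, adj)]


def analyze_metrics(
    metrics: pd.DataFrame, holm: bool = False
) -> dict[str, pd.DataFrame]:
    """Run the full statistical battery on a scored per-stage table."""
    out: dict[str, pd.DataFrame] = {}
    long = metrics.rename(columns={"subject_id": "subject"})

    # group x stage mixed ANOVA on trials to criterion
    anova_rows = []
    try:
        for res in mixed_rm_anova(
            long, "group", "stage", dv="trials_to_criterion", subject="subject"
        ):
            anova_rows.append(
                {"response": "trials_to_criterion", **dataclasses.asdict(res)}
            )
    except StatsError:
        pass

    # group x error-subtype mixed ANOVA on whole-task error counts
    err_long = (
        long.groupby(["subject", "group"])[list(ERROR_TYPES)]
        .sum()
        .reset_index()
        .melt(
            id_vars=["subject", "group"],
            value_vars=list(ERROR_TYPES),
            var_name="error_type",
            value_name="count",
        )
    )
    try:
        for res in mixed_rm_anova(
            err_long, "group", "error_type", dv="count", subject="subject"
        ):
            anova_rows.append({"response": "error_count", **dataclasses.asdict(res)})
    except StatsError:
        pass
    out["anova"] = pd.DataFrame(anova_rows)

    # per-stage one-way ANOVA + Fisher LSD on trials
    lsd_rows = []
    for stage in STAGE_ORDER:
        st = long[long["stage"] == stage]
        groups = {
            g: sub["trials_to_criterion"].to_numpy()
            for g, sub in st.groupby("group", sort=False)
        }
        if len(groups) < 2:
            continue
        try:
            res = oneway_anova_lsd(groups)
        except StatsError:
            continue
        pairs = _holm(list(res.pairwise)) if holm else list(res.pairwise)
        for p in pairs:
            lsd_rows.append(
                {
                    "stage": stage,
                    "F": res.F,
                    "df_num": res.df_num,
                    "df_den": res.df_den,
                    "p_anova": res.p,
                    "group_a": p.group_a,
                    "group_b": p.group_b,
                    "mean_diff": p.mean_diff,
                    "p_lsd": p.p_lsd,
                }
            )
    out["posthoc"] = pd.DataFrame(lsd_rows)

    # set-formation paired contrasts within each group
    wide = long.pivot_table(
        index=["group", "subject"], columns="stage", values="trials_to_criterion"
    )
    contrast_rows = []
    for (a, b) in (("CD", "ID"), ("ED", "ID")):
        for g, sub in wide.groupby(level="group", sort=False):
            try:
                res = paired_t(sub[a].to_numpy(), sub[b].to_numpy())
            except StatsError:
                continue
            contrast_rows.append(
                {
                    "group": g,
                    "contrast": f"{a}-{b}",
                    "mean_diff": res.mean_diff,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                }
            )
    out["contrasts"] = pd.DataFrame(contrast_rows)

    # SD-vs-ED correlation within each group
    corr_rows = []
    for g, sub in wide.groupby(level="group", sort=False):
        try:
            res = pearson_correlation(sub["SD"].to_numpy(), sub["ED"].to_numpy())
        except StatsError:
            continue
        corr_rows.append(
            {"group": g, "stages": "SD~ED", "r": res.r, "p": res.p, "n": res.n}
        )
    out["correlations"] = pd.DataFrame(corr_rows)
    return out


def _report_text(
    metrics: pd.DataFrame, tables: dict[str, pd.DataFrame], config: RunConfig
) -> str:
    lines = [
        f"setshift {__version__} analysis report",
        f"seed={config.seed} config_hash={config.config_hash()}",
        "",
        "Group means (trials to criterion per stage):",
    ]
    piv = metrics.pivot_table(
        index="group", columns="stage", values="trials_to_criterion"
    ).reindex(columns=list(STAGE_ORDER))
    lines.append(piv.round(2).to_string())
    lines.append("")
    lines.append("Mixed repeated-measures ANOVA:")
    lines.append(tables["anova"].round(4).to_string(index=False))
    lines.append("")
    lines.append("Set-formation paired contrasts (positive diff = set formed):")
    lines.append(tables["contrasts"].round(4).to_string(index=False))
    lines.append("")
    lines.append("SD~ED correlations:")
    lines.append(tables["correlations"].round(4).to_string(index=False))
    return "\n".join(lines) + "\n"


def run_full_pipeline(config: RunConfig) -> dict:
    """simulate -> score -> analyze; writes all artifacts under out_dir.

    Returns a bundle with the logs, the metrics frame, the analysis tables and
    the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    log.info("simulating cohort: %s groups, seed=%d", len(config.design), config.seed)
    logs = simulate_cohort(
        config.design,
        config.seed,
        max_trials_per_stage=config.max_trials_per_stage,
        param_overrides=config.param_overrides or None,
    )
    write_trial_log(logs, out / "trial_log.csv", seed=config.seed, config_hash=chash)

    metrics = score_logs(logs)
    write_metrics(metrics, out / "stage_metrics.csv", seed=config.seed, config_hash=chash)
    for s in logs:
        done = sum(s.completed.values())
        log.info("%s: %d/7 stages completed, %d trials", s.subject_id, done, len(s.trials))

    tables = analyze_metrics(metrics, holm=config.holm)
    for name, df in tables.items():
        _df_with_header(df, out / f"{name}.csv", config.seed, chash)
    (out / "report.txt").write_text(_report_text(metrics, tables, config))

    manifest = {
        "seed": config.seed,
        "config_hash": chash,
        "setshift_version": __version__,
        "n_sessions": len(logs),
        "n_trials": int(sum(len(s.trials) for s in logs)),
        "n_metric_rows": int(len(metrics)),
        "groups": [dataclasses.asdict(g) for g in config.design],
        "grand_mean_latency_s": {
            g: grand_mean_latency(
                [s for s in logs if s.group == g], config.latency_aggregation
            )
            for g in sorted({s.group for s in logs})
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"logs": logs, "metrics": metrics, "tables": tables, "manifest": manifest}


def _df_with_header(df: pd.DataFrame, path, seed: int, chash: str) -> None:
    text = f"# seed={seed}\n# config_hash={chash}\n" + df.to_csv(index=False)
    Path(path).write_text(text)
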