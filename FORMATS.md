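# File formats

All files are UTF-8, comma-delimited, `.` decimal. Files written by the
pipeline start with `#`-prefixed comment lines recording the seed and the
configuration hash (`# seed=…`, `# config_hash=…`); readers skip them.

## trial_log.csv — one row per trial

| column | type | meaning |
|---|---|---|
| subject_id | str | unique subject identifier |
| group | str | cohort group label (e.g. `SHR`, `MPH-L`) |
| strain | str | strain preset name (`SHR`, `WKY`, `SD`) |
| treatment | float | methylphenidate dose in mg/kg (0 = vehicle) |
| series | int | 1 = odor→medium shift at ED, 2 = medium→odor |
| pairs | str | exemplar-pair index per stage block, in block order `SD/CD/CDR-ID/IDR-ED/EDR` (e.g. `2-3-1`) |
| stage | str | `SD`, `CD`, `CDR`, `ID`, `IDR`, `ED`, `EDR` |
| trial_index | int | 1-based within stage, contiguous |
| left_odor, left_medium | str | exemplar labels in the left cup (empty if the dimension is absent, as at SD) |
| right_odor, right_medium | str | same for the right cup |
| baited_side | `L`/`R` | side of the cup holding the reward |
| chosen_side | `L`/`R` | side of the first dig |
| correct | 0/1 | first dig in the baited cup |
| latency_s | float | door-opening-to-first-dig latency, seconds |
| exploratory | 0/1 | trial 1–4 of the stage (both-cup digging allowed) |

## stage_metrics.csv — one row per subject × stage

| column | type | meaning |
|---|---|---|
| subject_id, group, strain, treatment | | as above |
| stage | str | stage name |
| trials_to_criterion | int | trials up to and including the run of 6 consecutive correct (total trials if incomplete) |
| errors_to_criterion | int | errors within that range |
| mean_latency_s | float | mean latency over that range |
| perseverative, regressive, never_reinforced | int | error-subtype counts (sum = errors_to_criterion) |
| completed | 0/1 | criterion reached |

## Analysis tables

* `anova.csv` — mixed repeated-measures ANOVA effects (`response`, `effect`,
  `F`, `df_num`, `df_den`, `p_uncorrected`, `epsilon_gg`, `epsilon_hf`,
  `correction_used`, `p_corrected`).
* `posthoc.csv` — per-stage one-way ANOVA plus Fisher-LSD pairwise rows
  (`stage`, `F`, `df_num`, `df_den`, `p_anova`, `group_a`, `group_b`,
  `mean_diff`, `p_lsd`).
* `contrasts.csv` — paired t-tests CD−ID and ED−ID per group (`group`,
  `contrast`, `mean_diff`, `t`, `df`, `p`).
* `correlations.csv` — Pearson r between SD and ED trials per group
  (`group`, `stages`, `r`, `p`, `n`).
* `manifest.json` — seed, config hash, package version, session/trial/row
  counts, group specs, per-group grand-mean latency.

## Cohort configuration (YAML)

```yaml
seed: 1
design: experiment1          # or experiment2, or an explicit list:
# design:
#   - {name: SHR, preset: SHR, dose: 0.0, n: 8}
#   - {name: MPH-L, preset: SHR, dose: 2.5, n: 8}
out_dir: setshift_out
max_trials_per_stage: 150
latency_aggregation: trials   # or stage_means
holm: false                   # Holm-adjust LSD p-values
```
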