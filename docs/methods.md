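# Methods

## Task structure and schedules

A session is seven discrimination stages in fixed order — SD, CD, CDR, ID,
IDR, ED, EDR — each run to a criterion of six consecutive correct responses.
Stimuli are abstract exemplar labels O1–O6 (odors) and M1–M6 (digging media);
the physical identities are irrelevant to every computation, so no attempt is
made to model them. Three exemplar pairs per dimension rotate through the
three stage blocks (SD/CD/CDR, ID/IDR, ED/EDR) by cycling the three rotations
of a 3×3 latin square across subjects, so any three consecutive subjects use
each pair in each block exactly once. Half the subjects (alternating by
subject index, a choice this package makes since nothing mandates another
split) run series 1 (odor relevant until the extradimensional shift), half
series 2 (the mirror image).

Within a compound stage exactly two cup configurations exist — relevant and
irrelevant exemplars aligned (a/a vs b/b) or crossed (a/b vs b/a) — and a
trial draws one of them plus a baited side, each under its own constraint
that no value repeats on more than two consecutive trials. The generator
draws each trial with a per-trial feasibility check (a run-length-2 state
machine): with two options per constraint a feasible extension always exists,
so rejection cannot stall, but the guard is kept for safety.
`validate_schedule` re-checks every contract (no shared exemplar between
cups, bait on the cup holding the correct exemplar, both run-length rules)
and is itself exercised against a brute-force enumeration of all valid
length-6 side sequences.

The first four trials of every stage are exploratory: the subject may dig
both cups, an error is still scored on a wrong first dig, but the trial does
not end — so the agent observes both cups' outcomes there.

## The synthetic agent

No standard behavioral model exists for this task, so the package defines
one — an attention-weighted exemplar-value learner chosen because a single
mechanism set yields all four phenomena the task is built to expose. Any
model reproducing the same ordinal structure would do; this one is the
package's reference implementation.

State: a value `v(e) ∈ [0,1]` per exemplar (initialized 0.5), a sample count
per exemplar, and one attention weight `w` splitting odor vs medium.

* **Choice.** Each cup's utility is the attention-weighted mean of its
  exemplars' values, where an exemplar's weight is its dimension's attention
  multiplied by a novelty salience `1 + s·0.8^count`. Choice is softmax with
  inverse temperature β, mixed with a lapse probability of a uniformly random
  dig.
* **Learning.** Chosen exemplars move toward the outcome by learning rate α
  (`v ← v + α(r − v)`); on exploratory trials the other cup's exemplars move
  toward the complementary outcome, since the animal digs there too.
* **Attention.** After each compound trial, attention drifts toward the
  dimension whose two present exemplars' values are farther apart (the
  better reward predictor), with step `α(1 − perseveration)`. Perseveration
  is thus the inertia of re-allocation: at 1 attention would never move.
* **Latency.** Lognormal(μ, σ) seconds, multiplied by a novelty gain in the
  stages that introduce new stimuli (CD, ID, ED) and by a per-stage decay
  `e^(−d·stage_index)` capturing procedural habituation.

Why the phenomena follow: reversals are costly because exemplar values carry
over between stages and must be unlearned (belief is deliberately never reset
at stage boundaries). ID is fast once attention has locked onto the relevant
dimension during CD/CDR — new exemplars are learned mostly through the
attended dimension. ED is slow because the locked attention must re-allocate
at the damped rate. CD is slower than ID because the newly introduced
irrelevant dimension transiently captures attention weight through the
novelty-salience term; at ID and ED *all* exemplars are novel, so the capture
is symmetric and cancels. (An additive "exploration bonus" on cup value does
not work here: both cups always contain one equally novel irrelevant
exemplar, so an additive bonus is symmetric by construction and biases
nothing. The multiplicative attention-capture form is what produces the CD
cost.)

## Strain presets and dose transforms

| parameter | SHR | WKY | SD |
|---|---|---|---|
| learning rate α | 0.30 | 0.50 | 0.50 |
| perseveration | 0.995 | 0.93 | 0.93 |
| lapse | 0.14 | 0.005 | 0.005 |
| inverse temperature β | 6 | 20 | 20 |
| latency μ (log-s) | 2.60 | 3.73 | 3.19 |
| latency σ | 0.35 | 0.35 | 0.35 |
| novelty salience s | 14 | 20 | 20 |

WKY and SD share one control behavioral profile (the two control strains are
behaviorally indistinguishable in this task) and differ only in speed. The
SHR preset is the ADHD phenotype: short latencies with a high lapse rate
(impulsive, error-prone at *every* stage) and near-total attention inertia,
so no attentional set forms and ID ≈ ED. The latency locations are calibrated
so that an 8-subject cohort's grand-mean first-dig latency lands on the three
reference strain means (≈14.7 s SHR < ≈26.9 s SD < ≈46.4 s WKY); the
behavioral parameters are calibrated so that control cohorts of 8 show the
set-formation contrasts (CD−ID > 0 and ED−ID > 0, paired t, p < 0.05) in
≥95% of replicates while SHR cohorts reject ED-vs-ID at roughly the nominal
false-positive rate, and so that SHR cohorts exceed controls on perseverative
and regressive error counts in ≥95% of replicates.

Methylphenidate is a static transform of the preset (no pharmacokinetics —
the regimen being emulated is a fixed 14-day daily dose, not within-session
dynamics): both doses raise latency μ and lower lapse; the perseveration
reduction is larger at 2.5 mg/kg (−0.45) than at 5 mg/kg (−0.15), encoding
the inverted-U dose response in which high doses fail to release — and may
even entrench — perseverative responding. Whether the latency increase
reflects reduced impulsivity or sedation is deliberately left open; the
transform only asserts the direction.

Sessions cap at 150 trials per stage by default (an unbounded session is
untestable); a capped stage is flagged incomplete and later stages still run.
Refusal to dig (session termination) is supported via `refuse_prob` but
defaults to off.

## Scoring

`trials_to_criterion` returns the index of the trial completing the first run
of six consecutive correct responses; errors and mean latency are totals over
trials 1..that index (all trials, flagged incomplete, if no run exists).
Exploratory-trial errors count and break runs. Correctness is always the
first dig.

Error classification partitions the scored trials into consecutive blocks of
four anchored at trial 1 (a short final block uses the same threshold, so a
two-trial tail can never be perseverative). Scanning blocks in order: while
in the perseveration phase, a block with ≥3 errors of any type marks its
old-rule-consistent errors perseverative; the first block with ≤2 errors
switches the phase, and that block's and all later old-rule-consistent errors
are regressive (a ≤2-error block demonstrates disengagement has begun, so the
switch is inclusive). Errors not consistent with the old rule are
never-reinforced regardless of phase.

Old-rule consistency is not self-evident in a two-choice compound task, so
the package fixes a deterministic rule: at reversals every error chooses the
previously correct exemplar (the only alternative), so all errors are
old-rule-consistent and never-reinforced is structurally zero; at acquisition
stages (SD/CD/ID) the previous rule equals or contains the current one, so no
error can follow a defunct rule and all errors are never-reinforced; at ED
the old rule is the previously relevant *dimension*, anchored to the
old-dimension exemplar in the cup chosen on the stage's first error —
subsequent errors on cups containing the anchor are old-rule-consistent. The
classifier is verified against an independent brute-force implementation on
randomized sequences.

A historical phrasing sometimes attached to this taxonomy — that the subject
"is allowed" six perseverative responses per twelve trials — is a carry-over
from the maze procedure the taxonomy originated in and is inconsistent with
the block-of-four rule; it is not implemented.

## Statistics

The battery mirrors standard treatment of these designs:

* **Mixed (split-plot) ANOVA**, one between-subjects factor × one
  within-subjects factor, balanced designs only (the sums of squares are
  computed directly and the partition is property-tested to 1e−8 relative).
  Sphericity is tested with Mauchly's W on the pooled within-group
  covariance; if violated at α = 0.05, within and interaction p-values use
  ε-scaled degrees of freedom — Greenhouse–Geisser when ε_GG < 0.75,
  Huynh–Feldt otherwise (the usual "large vs small violation" reading).
  The standalone `sphericity_epsilons` uses the single-group HF correction;
  inside the mixed ANOVA the N−g version is used. The ε-adjustment is
  conservative (raises p) for effects with F > 1; for F < 1 the direction can
  reverse, which is why the property test pins the F > 1 case.
* **Per-stage one-way ANOVA with Fisher LSD** post-hocs on the pooled error
  term, unadjusted for multiplicity — that is what LSD is; a Holm flag exists
  for users who want protection, off by default.
* **Paired t-tests** for CD−ID and ED−ID (set formation), two-sided.
* **Pearson correlations** between stages (SD vs ED by default).

All tests are two-sided. Zero-variance degenerate inputs raise explicit
errors rather than returning NaN. The grand-mean latency aggregates over all
trials by default; a `stage_means` option weights stages equally instead,
since a single "mean latency" per subject is ambiguous between the two.

## What the synthetic generator does and does not emulate

It reproduces the ordinal and inferential structure of real cohorts —
trials-to-criterion orderings across stages and strains, error-subtype
profiles, latency orderings and their stage dynamics, dose effects — under
clean assumptions: stationary parameters within a session, no fatigue or
satiation, no side bias, no olfactory generalization between exemplars, no
inter-individual parameter variability within a group beyond sampling noise.
Passing recovery tests therefore shows the pipeline is correct and powered
for effects of the calibrated size, not that the agent is a complete model of
rat behavior. The printed F/t/r values of any real experiment are empirical
animal results and are not reproduction targets; only their qualitative
pattern is recovered.

## Numerical and design choices

* Simulation sizes in the test suite (200 cohort replicates for recovery
  properties, 2000 null datasets for the type-I check, 100 full-pipeline
  replicates) are chosen as the smallest sizes at which the binomial noise of
  the checked rates is well inside the asserted bands.
* Subject-level random streams are spawned from the master seed via
  `numpy.random.SeedSequence`, so cohorts are reproducible and individual
  subjects are independent.
* Softmax choice uses a numerically guarded logistic; criterion detection is
  a single left-to-right scan; ties cannot occur (choices are binary).
* `latin_square_assignment` for n not divisible by 3 leaves rotation counts
  differing by at most one — exact balance is only possible at multiples
  of 3.
* Output files embed the seed and a hash of the scientific configuration
  (output paths excluded), so equal hashes imply byte-identical reruns.

## Known limitations

* The SHR preset's never-reinforced error count is elevated alongside the
  other subtypes (its lapse rate raises all error kinds); real cohorts are
  reported to differ mainly in perseverative/regressive errors. The package's
  recovery guarantees cover the perseverative and regressive orderings only.
* Fisher LSD controls no family-wise error; with three groups this matches
  field practice but inflates error with more.
* The agent's attention is a single scalar over two dimensions; tasks with
  three or more dimensions would need a simplex-valued attention state.
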