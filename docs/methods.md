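# Methods

`digiphen` re-implements, as a tested pipeline over synthetic raw data, a
digital-phenotyping analysis of a two-group remote-monitoring cohort: adults
and adolescents with ADHD versus matched comparison participants, observed
24/7 for ten weeks through a smartphone passive-sensing app, a questionnaire
("active") app, and a wrist-worn activity tracker. Ten behavioural features
are derived from the raw event streams and compared between groups.

## Event model and sessionization

Raw data arrive as per-participant timestamped streams: phone status
transitions (STANDBY / UNLOCKED / SHUTDOWN / BOOTED), app events (with an
event type of OTHER, FOREGROUND, INTERACTION or BACKGROUND — an OTHER event
for a social or communication package marks an incoming notification),
ambient-light samples (lux), minute-level step counts, tracker-detected sleep
intervals, and questionnaire notification/start/finish timestamps. Timestamps
are epoch seconds, UTC; calendar days are assigned with a fixed per-cohort
UTC offset (default 0), so daily aggregates are reproducible.

An *active phone use session* is the half-open interval [unlock, next
standby). Conventions the raw event grammar leaves open, fixed here and
flagged because the source analysis does not specify them:

- SHUTDOWN also closes a session (powering off ends active use); BOOTED never
  opens one.
- Repeated UNLOCKED events without an intervening terminator extend the open
  session.
- A trailing unterminated UNLOCKED is dropped, not truncated to the end of
  the stream — an unknown true duration must not bias the duration feature —
  and counted in the log.
- Zero-length spans are discarded.

## The ten features

| # | Feature | Unit | Grain | Test |
|---|---------|------|-------|------|
| 1 | Questionnaire notification response latency | hours | questionnaire | LMM |
| 2 | SD of feature 1, pooled per participant | hours | participant | t-test |
| 3 | Mean interval between finishing one questionnaire and starting the next | hours | wave | LMM |
| 4 | SD of those intervals | hours | wave | LMM |
| 5 | Daily mean of social/communication notification response latency | s | day | LMM |
| 6 | Daily SD of the same latencies | s | day | LMM |
| 7 | SD of ambient light within each active session | lux | session | LMM |
| 8 | Steps during each active session | steps | session | LMM |
| 9 | Active session duration | s | session | LMM |
| 10 | New apps added per day | count | day | LMM |

Notification latency (features 5–6) is the time from a social/communication
OTHER event to the first UNLOCKED event strictly after it. Notifications
delivered during a sleep interval are excluded first (the participant could
not have seen them). Decisions the source analysis leaves open, all exposed
as configuration:

- several pending notifications may share one unlock, each keeping its own
  latency (no collapsing rule is stated; this is the simplest faithful
  reading);
- a latency cap of 24 h, beyond which a response is treated as unobserved —
  without a cap, overnight and multi-day gaps dominate the daily SDs;
- notifications arriving mid-session default to latency-to-next-unlock
  (`during_session_policy`: `next_unlock` | `zero` | `drop`);
- daily means/SDs need at least 2 responses (sample SD, n−1 denominator).

Questionnaire latency (feature 1) is analysed per questionnaire (a repeated
measure); feature 2 is its per-participant pooled SD, the single
time-aggregated feature. Questionnaires are available for 72 h after the
notification; ones never started within the window yield no latency
observation. Intervals (features 3–4) are computed within each assessment
wave, ordering questionnaires by start time; negative gaps (overlapping
questionnaires) clip to 0 with a warning. Feature 10 has no install sensor
behind it: a package is "new" on the first local day its name appears, after
a 1-day burn-in that absorbs pre-installed apps; days with zero new apps
count as 0 (this inclusion choice changes the mean and is therefore
explicit).

## Outlier handling

The IQR proximity rule suits these heavily right-skewed features: with Q1 and
Q3 the 25th/75th percentiles (numpy linear interpolation, fixed for
reproducibility), values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are removed
before the group comparison. Limits are computed per feature on the pooled
values of both groups (per-group limits are available via config). The
boundary is closed: a value exactly at a limit is retained. The rule is
applied once with fixed limits; re-applying with limits recomputed on the
retained subset would remove more.

A separate sensitivity analysis re-runs the statistics after dropping the two
participants with the highest mean ambient-light SD.

Note an instructive interaction with the synthetic data: session-level light
SDs are generated gamma with SD > mean, so the IQR rule removes a substantial
upper tail and can flatten the group contrast in feature 7 that the raw
observations carry. The acceptance checks therefore target the raw derived
means; the default end-to-end run still applies the rule, as the study did.

## Group comparison

Repeated features: a linear mixed model, `value ~ 1 + group` with a random
intercept per participant, fitted by REML (statsmodels `MixedLM`). The group
indicator is comparison = 1, ADHD = 0, so the coefficient and its Wald Z are
comparison-minus-ADHD (negative Z when the ADHD group is higher). P-values
for the group term use a Student-t reference with (participants − 2) degrees
of freedom rather than the normal: with 40 participants the difference is
cosmetic (<0.01 in p), but the normal reference is anti-conservative at small
cluster counts and would inflate the type-I error that the validation suite
measures at 10+10. A singular or non-convergent fit falls back to a t-test on
participant means, flagged in the result row.

Effect size for LMM features divides the fixed-effect group difference by the
square root of the summed variance components — random intercept variance per
participant, random intercept/slope variances per item, random slope variance
per participant, and residual variance. This design has no crossed item
factor and fits no random slopes by default, so those components are zero
(a config flag adds a random slope on day). The aggregated feature uses a
two-sample t-test and Cohen's d with the pooled SD. d is reported as a
magnitude; the direction is carried by Z. Descriptive group means (SD) are
computed over observations, matching the repeated-measures presentation
(per-participant aggregation is config-selectable). No multiple-testing
correction is applied, mirroring the exploratory design; the report notes
significance at P < .05.

Time trends for features 1, 3 and 4: `value ~ group + day + group:day` with
the participant random intercept, day = days since enrollment. Under
comparison coding a negative interaction coefficient means the per-day
increase is smaller in the comparison group.

## Synthetic cohort generator

The raw study data are not deposited, so a generator stands in, built so the
*derived* features — not the raw streams — match configured distributions.
Defaults are the study conditions: 20 participants per group, 10 weeks,
three assessment waves at weeks 2/6/10 with 5 questionnaires each, and the
published group mean (SD) per feature as targets.

Mechanics, per participant:

- **Positive skewed features** (latencies, durations, light SDs, steps per
  session) are moment-matched gammas: shape (mean/SD)², scale SD²/mean. This
  supports targets with SD > mean without negative draws. Daily new-app
  counts are Poisson with the target mean.
- **Hierarchy.** Each target SD is split in quadrature into a
  between-participant part (fraction `between_fraction`, default 0.6, of the
  SD — an intraclass correlation of 0.36, a mid-range value for behavioural
  phenotypes) and a within-participant part, so the mixed models have real
  variance components to estimate.
- **Stratified participant means.** Participant-level means are the
  conditional means of the between-participant gamma within equal-probability
  quantile slices, assigned by random permutation (independent permutations
  per feature). A 20-person group then tiles its configured spread and the
  average of its participant means equals the group mean exactly. For
  calibration studies this is switched off (`stratify_participants=False`):
  null-distribution properties of a mixed model are only meaningful when
  participant effects are random draws.
- **Day structure.** One nightly sleep interval (23:30 ± 0.5 h, 8 ± 0.5 h)
  per day. Waking time is a renewal process of notification-driven cycles:
  exponential wait, then a social/communication notification (an OTHER app
  event), then an unlock after a latency drawn from the group distribution,
  then a session of the group's duration distribution, closed by STANDBY.
  The stop rule depends only on the notification time, never on the drawn
  latency or duration, so retained draws are unbiased samples. Per-cycle
  waits are lengthened for participants with short latencies/sessions so the
  cycle rate is roughly participant-independent and pooled per-session means
  are not rate-weighted; the clamp at a 2-minute minimum wait leaves a small
  residual length bias (~2–4% low) in the pooled session-duration mean.
  A Poisson number (default 2/night) of notifications falls inside sleep
  intervals to exercise the exclusion stage.
- **Light traces** sample every 60 s (minimum two samples per session) as a
  constant base plus balanced ± deviations whose sample SD equals the drawn
  session-level SD exactly; illuminance stays non-negative by construction.
- **Step traces** split a drawn session total into minute records
  (multinomial); extra "walking" records are placed outside sessions only,
  so they exercise the containment join without contaminating totals.
- **Questionnaires.** Within a wave, the first questionnaire's start is
  notification + latency; subsequent starts chain as previous finish + a gap
  drawn from the interval target, with the notification time back-computed as
  start − latency. Latencies and gaps are then recovered exactly by the
  extraction stage. Latencies beyond the 72 h window become never-started
  records. The ADHD day slope (default +0.1 h/day, comparison 0) shifts wave
  means, centred on the middle wave so the overall group mean stays on
  target; 0.1 h/day amounts to a ~5.6 h drift across the wave span,
  comparable to the between-group difference, and is recoverable in sign by
  the interaction model in ≥90% of 10+10 cohorts.

What the generator does *not* emulate: features 2, 4 and 6 (within-
participant SD features) are not independently targetable once features 1, 3
and 5 fix the observation-level dispersion — indeed the published mean of
feature 2 exceeds the pooled SD of feature 1, which no i.i.d. hierarchy can
reproduce. These features emerge from the latency generation with smaller
between-participant spread than the real data showed, which inflates their
test statistics in the demo report. Similarly, daily new-app counts are
Poisson (variance = mean), giving feature 10 less dispersion than real
ecosystems; real circadian light physics, app-package ecosystems, weekday
structure and missing data (device off, non-wear) are out of scope. Passing
recovery tests therefore demonstrate the correctness of the extraction and
statistics on data with known ground truth, not realism of the raw streams.

## Validation studies

- **Parameter recovery** (`tests/test_acceptance.py`): a 20+20, 10-week
  cohort is generated under the default targets and pushed end-to-end; each
  targeted group mean (features 1, 5, 7, 8, 10) must come back within 3
  standard errors, with the SE computed cluster-aware (SE of the mean of
  per-participant means).
- **Type-I error**: 500 questionnaire-only cohorts of 10+10 over 2 weeks
  with identical group distributions; the LMM group test must reject at
  5% ± 1.5% at α = .05. Questionnaire-only generation is used because the
  passive streams are irrelevant to the group test's null calibration and
  would multiply runtime ~100-fold.
- **Interaction recovery**: 100 cohorts with the +0.1 h/day ADHD slope; the
  interaction coefficient must be negative in ≥90%.
- **Oracle equivalence**: the effect-size formula, Cohen's d, sample SDs and
  IQR limits match brute-force recomputations on 1000 random inputs to
  1e-10 relative tolerance.
- **Structural invariants**: disjoint sessions, no retained notification
  inside sleep, drop-count conservation at every stage, and byte-exact
  round-trip I/O, as property tests (hypothesis, derandomized).

Problem sizes (full cohort for recovery; 10+10 reduced cohorts for the
Monte-Carlo studies) keep the whole suite under a minute while leaving
standard errors far below the tolerance bands.

## Numerical choices and degenerate inputs

- Percentiles: numpy linear interpolation between order statistics.
- Sample SDs use the n−1 denominator throughout; aggregates requiring an SD
  are omitted (with a warning) below 2 observations.
- Interval membership is uniformly half-open [start, end); outlier limits are
  closed at both ends.
- Zero-variance data: t-test on identical groups reports t = 0, p = 1;
  Cohen's d on zero pooled variance is an error; a constant-data LMM falls
  back with effect size 0.
- Ties in event streams preserve input order (stable sorts keyed on
  participant and time).
- Gamma moment matching requires mean > 0; SD = 0 yields constants, which
  propagate to exact zeros in the SD features.

## Known limitations

- The Wald-t df correction is a pragmatic small-sample fix, not a full
  Satterthwaite/Kenward-Roger approximation.
- Feature 9's pooled mean carries the residual ~2–4% length bias noted above.
- The report's feature-6/10 statistics are exaggerated relative to real data
  (see generator notes); recovery targets deliberately exclude them.
- No missing-data mechanisms (non-wear, app death, permission revocation)
  are simulated; drop counters exist at every stage so adding them is
  mechanical.
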