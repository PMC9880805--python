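# Methods

## The prompting engine

The engine is a deterministic per-minute state machine over a participant's
waking day. Its policy constants live in `EngineConfig`:

| parameter | default | meaning |
| --- | --- | --- |
| `sedentary_step_cut` | 10 steps/min | a minute below this is sedentary |
| `low_threshold` | 60 min | bout threshold when all symptom severities < cut |
| `high_threshold` | 120 min | bout threshold when any severity ≥ cut |
| `severity_cut` | 7 (of 0–10) | symptom severity that switches thresholds |
| `default_threshold_when_unrated` | 120 min | conservative default with no rating |
| `response_window` | 15 min | window after a prompt in which steps count |
| `response_step_goal` | 30 steps | response (and feedback) criterion |

Semantics that the published description leaves open were fixed as explicit,
configuration-visible policies:

* **Reset-on-prompt re-arm.** The sedentary accumulator resets at prompt
  emission and must re-reach the full threshold before the next prompt. On a
  fully sedentary waking day of W minutes this gives exactly `floor(W / T)`
  prompts, which reproduces the observed inpatient prompt frequency at the
  120-minute threshold over a ~16-hour waking day.
* **Hard reset on activity.** Any minute with ≥ 10 steps zeroes the
  accumulator; "consecutive" is taken literally, with no partial credit.
* **Missing minutes are sedentary.** Inside the wake window, a minute with
  no recorded data is treated as zero steps: that is what the on-wrist app
  observes when the watch is idle or off the wrist. The multi-day driver
  skips a calendar day only when there is no recorded minute anywhere near
  its waking window (the app demonstrably was not running that day). The
  single-day entry point always imputes.
* **Threshold changes are live.** A new symptom report takes effect at its
  arrival minute and applies to the accumulation already in progress; it
  never resets the accumulator. Reports carry forward indefinitely.
* **Response windows do not pause accumulation**, and the window is the 15
  minutes strictly after the prompt minute, `(t, t+15]`; it may extend past
  bed time.

## Outcome metrics

* Wear time is a simple count of worn minutes per calendar day (consecutive
  wear is not required); days with ≥ 480 worn minutes enter activity
  analyses. The 8-hour filter counts all worn minutes, including sleep.
* Sedentary bouts are maximal sedentary runs inside the waking day. Sleep
  episodes are excised *before* run-finding, so sleep splits a bout; runs
  truncate at the wake-window boundaries. Mean bout per day averages over
  that day's bouts; phase means then average over wear-included days
  (mean-over-bouts-then-days, one of two readings of "mean bout"; the
  alternative is a configuration away by pooling the bout lists).
* Phase response fractions are pooled ratios of summed counts
  (Σ responses / Σ prompts), not means of daily percentages, and are flagged
  `None` rather than 0 when a phase saw no prompts.
* Percentages print with round-half-away-from-zero to integer; chi-square
  and bout means to one decimal.
* Setting `treat_missing_as_sedentary=False` breaks bouts at unrecorded
  minutes instead, the wear-time sensitivity direction.

## Trial statistics

`trial_stats` wraps scipy.stats behind the package's validated types: the
2×2 Pearson chi-square **without** continuity correction (the uncorrected
statistic is what reproduces the published readmission comparison; Yates is
a flag), and the two-sample t test from group summaries with pooled variance
by default (df = n₁+n₂−2, which reproduces the published usability P values;
Welch is a flag). Degenerate inputs are defined explicitly: zero row/column
margins make the chi-square undefined; two zero-variance groups give t = 0
when means agree and an error otherwise.

## The cohort simulator

Each participant gets three phases: preoperative duration drawn from a
truncated geometric on 8–47 days calibrated to mean 19.6, inpatient 5–24
days with mean 10.9 (surgery and discharge days inclusive), and a fixed 30
days post discharge. A uniform-integer duration spec is also available, but
a uniform law cannot carry those printed means, hence the skewed default.

Within the waking day (default 07:00–23:00), minute-level steps come from a
two-state Markov chain — the minimal structure that yields the
geometric-tailed bout distributions the extractor must handle. Active
minutes log `10 + Poisson(λ_phase)` steps; sedentary minutes log
`min(Poisson(µ), 9)` incidental steps. Nightly sleep (bed to wake) logs
zero. Wear is drawn per day: worn at all with `p_worn_day`; worn days get a
single device-off gap, short (≤ 4 h, stays above the 8-h filter) with
`p_full_wear_given_worn`, otherwise long (≥ 1000 min, guarantees
exclusion). Daily symptom reports appear 30 minutes after wake with
`p_report`; one designated dimension (fatigue) is drawn from a two-point
mixture so that P(any severity ≥ 7) equals `p_symptom_high` exactly, and the
other nine stay low — only the ≥ 7 indicator affects the engine.

For the intervention arm the engine runs **online** during generation. At
each prompt:

* if the device is off at that minute, nothing happens — the wearer never
  saw the prompt;
* otherwise the participant responds with the phase's `response_prob`,
  walking 30–80 steps over two adjacent minutes inside the response window;
* a non-responder stays seated through the window (its minutes are forced to
  low incidental stepping), so the engine's response indicator equals the
  Bernoulli draw, which is what makes exact parameter recovery possible.

Replaying the engine offline over the recorded streams reproduces the online
prompt sequence bit for bit (same deterministic rules, and injections only
ever touch minutes after the decision point).

`recover_parameters` re-runs the engine over a bundle and compares, per
phase, the empirical response fraction (denominator restricted to prompts
delivered while worn — the exposures the propensity governs), the empirical
P(any severity ≥ 7), and report adherence against their configured values,
each with an exact (Clopper–Pearson) 95% binomial interval.

### Calibration

Default `PhaseParams` were calibrated once against the published phase
statistics and then frozen: prompts per intervention participant-day near
3.3 / 7.8 / 6.2 (pre / in / post), response propensities 0.49 / 0.06 / 0.18,
rating adherence pooling to ~62% of days, wear pooling to ~77% of days worn
with ~91% of worn days above the 8-hour filter, and a pooled daily step mean
in the few-thousand range. Two caveats are deliberate: the *observable*
pooled response fraction over all sent prompts is lower than the configured
propensity, because device-off gaps generate long zero-step runs that prompt
into the void (the trial's own wear-confounding, reproduced rather than
hidden); and desk-scale cohorts do not pin the published step/bout
magnitudes, which are sensitive to the real cohort's behavior — a green
calibration test establishes neighborhoods, not reproduction.

## Numerical and testing notes

* All timestamps are timezone-naive minute-resolution local time; epoch
  arithmetic uses a naive 1970 epoch so datetime and numpy paths agree.
* Determinism: one seed feeds a `SeedSequence` spawned per participant;
  rerunning any command on the same inputs is byte-identical.
* The engine and the bout extractor are each verified against independent
  brute-force re-scans on 1000+ random synthetic days, and the fully
  sedentary closed form `floor(W/T)` is property-tested.
* Recovery coverage: the exact binomial interval's true coverage at the
  realized sample sizes is ~95.5–96.5%, so across 100 seeded replicates a
  per-row "≥ 93 in-interval" bar is appropriate for the headline response
  propensities but sits within ordinary binomial fluctuation for the
  auxiliary probabilities; those are asserted as pooled coverage plus a
  dispersion check instead.

## Known limitations

* No timezone or daylight-saving arithmetic; no vendor-API ingestion.
* Sleep is strictly nocturnal in the simulator (no naps inside the wake
  window), although the metrics handle in-window sleep correctly.
* Symptom trajectories have no autocorrelation; severities are day-iid.
* Readmissions are not modeled causally from activity; arm-level Bernoulli
  draws exist only to exercise the contingency statistics.
* The simulator's wake window must lie within a single calendar day (the
  stream model itself supports midnight-crossing windows).
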