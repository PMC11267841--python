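# Methods

## The exposure score

The score operationalises "the strategy was applied when it should have
been". Its ingredients, in the order they are evaluated per day inside
the Day 2–14 window:

1. **Observability.** A day with no recorded weight has unknown
   overload status and can never contribute a deviation; missing
   weights are penalised only through the weigh-in proportion factor.
2. **Overload.** Measured weight strictly above the day-indexed
   threshold (admission + 2 kg on Day 2, admission on Days 3–7,
   admission − 2 kg on Days 8–14). A weight exactly at the threshold is
   not overload.
3. **Contraindication.** Hypotension, Na > 155 mmol/L, K < 2.8 mmol/L
   (strict, as printed in the protocol) or RIFLE ≥ risk. A
   contraindicated overload day is never a deviation, whatever was or
   was not given, and absent labs never contraindicate.
4. **Compliant response.** Diuretics, any ultrafiltration, or intake
   ≤ 70 % of the previous day's intake (the 30 % boundary counts as
   compliant). With no previous-day record, or a previous intake of
   zero, the restriction branch is unevaluable and contributes false;
   the treatment branches still apply.

The raw score is 100 × (1 − deviations / window-days); the final score
multiplies it by the fraction of window days weighed. The window is
the *inclusive* Day 2–14 span — thirteen scored days for a long stay,
even though the protocol text labels it a 12-day period; shortening it
silently would change every denominator. The raw-score denominator is
the stay's days inside the window, not the full length of stay:
deviations are only defined inside the window, and a full-LOS
denominator would mechanically inflate scores of long stays. A config
switch (`ScoringRules.denominator = "full_los"`) restores the other
reading. Stays ending before Day 2 have no defined score and are
excluded from aggregation with a warning.

Albumin, although part of the clinical strategy, is not in the
compliant-response set: the score is defined by the
restriction/diuretics/ultrafiltration triad, and intake restriction is
compared on volumes only. Group aggregation uses the arithmetic mean
and the n−1 sample standard deviation; singleton groups report an
absent SD.

## Descriptive battery

*Reach* is 100 × included/expected enrolment per ICU × period. *Weekly
weigh-ins* are 7 × (weigh-ins)/LOS per patient, averaged over patients
(not patient-weeks). *Achieved/expected weighing* divides all weigh-ins
of the stay by a period-dependent expectation: the control period is
held to the weekly standard of care (one weigh-in per started 7-day
block of the stay), the intervention period to the daily protocol (one
per stay-day inside Day 2–14). This is the only expectation under
which control-period ratios of several hundred percent are
arithmetically possible, and both rules are overridable. *Hypotension*
uses at-least-one-episode-per-stay semantics. *Weight change* is
discharge minus admission weight, absent when no discharge weight
exists. Cohen's κ is the unweighted (nominal) statistic, delegated to
scikit-learn behind the package's own surface, with the degenerate
perfect-agreement/single-category case fixed to 1.

## Synthetic cohorts

The generator emulates the structure the scoring assumes, not ICU
physiology. Per (ICU, period) arm: lengths of stay are negative
binomial (mean 10, dispersion 4) truncated to ≥ 3 days, since patients
enter beyond 48 h after admission; admission weights are Normal(75, 15)
kg floored at 40; true weight performs a ±`overload_drift_kg_per_day`
(default 0.4 kg) walk — up after a day with no compliant response, down
after one — and measured weights add N(0, 0.3 kg) noise. Day 1 is
always weighed, later days with probability `p_weigh`. A response is
drawn only on *actionable* days (weighed, measured weight above
threshold, no contraindication drawn) with probability `p_adhere`, and
is restriction/diuretics/ultrafiltration with weights 0.6/0.3/0.1.
Generated restriction days cut intake to 65 % of the previous day, past
the 30 % compliance boundary; non-restriction intakes are baseline
2000 mL with ±10 % noise, which cannot cross the boundary by accident.
Contraindications arrive daily with probability `p_contra` (0.1),
uniformly typed; hypotension also arrives independently at
`p_hypo_day` (0.12). Contamination in the control arm is modelled
solely by that arm's non-zero weighing/adherence propensities.

Intake volumes, weight-noise level and the response mix have no
published distributional anchors; the defaults are nominal round
numbers at clinically plausible magnitudes. The default 12-ICU
calibration fixes planned enrolment at 60 patients per ICU-period;
realised sizes and per-arm weighing propensities were back-solved from
the trial's published per-ICU weekly weigh-in means, and adherence
propensities chosen so that control arms span wide contamination levels
while every intervention arm sits clearly higher. The generator is a
stand-in, not a fit: it reproduces the *directional* per-ICU pattern
(intervention score above control everywhere, control achieved/expected
far above 100 %, larger weight loss under the intervention) but not the
published per-ICU values, and its weight-change means are shifted
positive relative to a real ICU because the walk has no baseline
weight-loss trend. Passing tests therefore demonstrate the pipeline's
correctness and the mechanism's direction, not agreement with any real
cohort.

Determinism: each stay consumes an independent stream spawned from
`(seed, arm index, patient index)`, so enlarging one arm never perturbs
any other patient, and identical (config, seed) pairs yield
byte-identical CSV outputs (each output embeds the seed and a config
hash).

## Numerical and testing choices

All comparisons in the score are exact floating-point comparisons of
simple sums and ratios; no tolerance enters the implementation. The
test oracle for the scorer is an independently coded naive day-loop;
agreement is asserted exactly, not approximately.

The analytic stress check uses a degenerate generator in which every
weighed day is overloaded and deviations are independent Bernoulli
draws; the mean final score then converges to
100 (1 − p_weigh(1 − p_adhere)) p_weigh. That formula is the
infinite-window limit: over a window of n days the covariance between
the deviation rate and the weigh-in proportion shifts the expectation
by −100 (1 − p_adhere) p_weigh(1 − p_weigh)/n, about one point at the
clinical 13-day window and far larger than Monte-Carlo error at 2 000
patients. The harness therefore scores a 400-day synthetic window,
where the shift (< 0.04 points) is well below the 3-standard-error
resolution of the check. Problem sizes elsewhere (100-patient boundary
cohorts, 2 000-stay length-of-stay and analytic checks, the full
~1 360-stay default cohort) keep the whole suite under a minute of
compute while leaving Monte-Carlo error far below every asserted
margin.

## Known limitations

- No imputation of missing weights and no per-protocol causal
  estimation; the score is descriptive.
- The generator has no mortality, no discharge process linked to
  recovery, and no serial correlation in contraindications.
- Admission weight is taken as given per stay; whether it is a measured
  Day-1 weight or an estimated dry weight is outside the data model.
- `weekly_weighins` treats the stay as a single exposure period; a
  per-patient-week variant would weight long stays differently.
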