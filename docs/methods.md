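# Methods

## The energy-balance model

The predictor is the static 3500 kcal/lb rule expressed in kilograms.
Two constants define it and are used exactly as conventionally printed —
3500 kcal per pound of body mass and 0.454 kg per pound — so one kilogram
is equivalent to 3500/0.454 = 7709.25 kcal (conventionally rounded to
7700).  They are never recomputed from finer conversion factors
(0.45359...), keeping outputs bit-comparable with the published
arithmetic of this model family.  Energy unit conversion uses
4.1868 kJ/kcal with results rounded to the nearest 5 kJ, which reproduces
the protocol table's kJ cells up to the source's own rounding noise.

The model is linear in time and deficit, assumes the full deficit is met
from body-mass stores at a fixed energy density, and deliberately ignores
metabolic adaptation and physical activity.  It is a supervision
heuristic, not a physiological simulation: its value is an expected mass
at each follow-up examination, against which the measured mass is judged.

### Literal vs deficit mode

The staged per-examination update as conventionally written multiplies by
the phase *intake* EB_i, whereas the closed form multiplies by the
*deficit* ΔEB.  The two are dimensionally incompatible readings of the
same rule, so both are exposed:

* `mode="deficit"` (default): multiplier = `required_energy − intake`.
  This is the physically coherent reading; `required_energy` defaults to
  2300 kcal/day, a maintenance intake for a lightly active adult, and is
  configurable globally.
* `mode="literal"`: multiplier = the intake itself, reproducing the
  formula verbatim for comparison work.

The mode and required energy are echoed in every summary so reported
agreement is never ambiguous about which reading produced it.

## The phase state machine

Seven phases with intakes 800, 900, 1000, 1150, 1300, 1400 and 1500
kcal/day are gated by the progress fraction p = (W0 − W)/(W0 − Wd) at
thresholds 0, 0.48, 0.64, 0.80, 0.85, 0.90, 0.95.  Comparison is `>=`
with half-open intervals — the only monotone-consistent reading of
"reaching" a threshold.  The fourth-phase intake is 1300 kcal (the
operational flow value) rather than the 1350 midpoint of its permissible
1300–1400 kcal range; the table of permissible ranges is retained for
validation and the whole table can be replaced from a YAML/TOML file.

Design choices where the protocol prose was open:

* **Fast entry.** Overweight-but-not-obese subjects skip phase I.  The
  eligibility clause is operationalised as BMI < 30 kg/m² (boundary
  assigned to the obese side); during progress-based phase selection such
  subjects are never demoted below their entry phase — only an explicit
  relapse can do that.
* **Relapse.** Stagnation is operationalised as measured ≥ previous
  measured mass (no numeric stagnation band is defined by the protocol);
  the demotion is exactly one phase, floored at phase I.
* **Non-adherence.** Deviation is |expected − measured| / expected, i.e.
  relative to the expected *body mass*; the flag threshold defaults to
  5 %.
* **Time.** The simulation steps one day at a time, re-evaluating the
  phase daily; examinations land on integer days with day 0 the program
  start; the trajectory is clipped at the desired mass (no overshoot).
  Exam-driven phase updates, by contrast, hold the phase fixed across
  each interval — consequently the exam-driven path loses mass at least
  as fast as the daily-re-evaluated trajectory (early phases carry the
  larger deficits) and may run ahead of it by a phase or two.  Both
  views are exposed because both are used in practice: the daily
  trajectory for planning, the exam-driven update for supervision.

`days_to_threshold` provides the continuous-time closed form for each
phase segment; the discrete simulation reaches a threshold on the ceiling
of that value, and the two are cross-checked against each other in the
tests (they are independent code paths).

## The synthetic cohort generator

No raw cohort data accompany this package, so a generator emulates the
anthropometric structure of a 100-adult staged-diet study population
(69 % female) well enough to exercise every pipeline stage.

* **Marginals.** Each variable (age, height, mass, six circumferences) is
  a truncated normal whose *realized* mean and SD match the target
  summary statistics: the underlying normal parameters are solved
  numerically, because truncating at the printed ranges would otherwise
  inflate the mean (for female mass by ≈ 2.3 kg).  Where a printed SD
  exceeds what any truncated normal on the printed range can express
  (male age: the uniform limit caps the SD at (hi−lo)/√12 ≈ 11.0 < 11.8),
  the mean is matched exactly and the SD takes the closest achievable
  value.
* **Eligibility.** Baseline BMI must fall in the per-sex observed range
  (floor 25.3 female / 26.3 male): mass is drawn first — matched on the
  range of masses compatible with the BMI floor at the shortest height —
  and height is then drawn from its distribution truncated to the window
  that keeps BMI in range.  The mass marginal is exact; the height
  marginal is mildly compressed downward for light subjects.  A joint
  mass–height covariance is not modelled; the BMI constraint induces the
  necessary dependence.
* **Desired mass** is the midpoint of the normal-BMI (20–25 kg/m²) band,
  i.e. BMI 22.5, overridable per subject.
* **Dynamics.** The true mass evolves by the engine's own daily update
  with the phase held fixed between examinations and re-assessed at each
  examination by exactly the rules used for prediction.  With zero noise
  and full adherence, measured and predicted masses therefore coincide
  identically — the generator's closure property, asserted in the tests.
* **Measurement noise** is zero-mean Gaussian with SD 0.2 kg by default
  (clinical scale precision).  Because each prediction re-anchors on the
  previous *noisy* measurement, the paired difference
  predicted − measured equals ε_(j−1) − ε_j: its SD is √2·σ, not σ, and
  consecutive differences are negatively correlated.  The Bland–Altman
  bias remains zero-mean with standard error √2·σ/√n.
* **Violations.** Two per-interval episode types are injected
  independently: *non-adherence* (probability 0.10) models complete
  abandonment of the prescribed intake with rebound overeating, an
  intake excess of 3000 kcal/day above the phase prescription.  The
  excess must be this large for a reason that follows from the flag's
  own arithmetic: over a 14-day interval, merely eating back the whole
  deficit caps the deviation at the expected interval loss (≈ 2.7 kg,
  3–4 % of body mass), below the 5 %-of-expected-mass threshold, so only
  episodes producing net gain are detectable.  *Relapse* (probability
  0.05) models a mild regain — intake 300 kcal/day above maintenance —
  which trips the phase-demotion rule without necessarily exceeding the
  5 % flag.  Each exam row carries its ground-truth episode label so
  detection sensitivity can be scored.
* **Schedule.** Examinations every 14 days by default (optional Gaussian
  jitter, floored at one day); histories end at the goal or at a 365-day
  horizon.  One seeded generator stream drives every draw: one seed, one
  cohort, byte-identical CSVs.

What passing tests on this cohort do **not** show about real data: the
generator contains no metabolic adaptation, water-mass fluctuation,
activity, seasonal or weekday effects, no correlation between adherence
and subject covariates, and independent noise across visits.  Agreement
statistics recovered on it demonstrate the pipeline's internal
consistency and calibration under the model's own assumptions, not the
model's clinical accuracy.

## Numerical and interface choices

* Sample (n−1) standard deviations everywhere; limits of agreement use
  the two-sided 95 % normal quantile 1.96.  The `relative_error` field
  is the SD of the relative differences (predicted − measured)/measured —
  reported under that explicit name because "error" is otherwise
  ambiguous.  OLS is delegated to `scipy.stats.linregress` and
  cross-checked against hand-computed closed forms in the tests.
* Difference orientation is predicted − measured and is printed in every
  report.  Per-sex stratification is always computed alongside the
  pooled statistics; the Bland–Altman x-axis (pairwise mean) is stored
  for plotting but takes no part in the statistics.
* Mode of a series is the most frequent value, smallest on ties;
  relative frequencies are reported as percentages to two decimals.
* CSVs: decimal point, UTF-8, mandatory header, masses at six decimals
  in data files (lossless round-trip) and two decimals in human reports,
  BMI to one decimal.  Each run writes a JSON manifest with the full
  configuration and its SHA-256 hash; re-running from the same manifest
  reproduces outputs byte-identically.  The hash lives in the manifest
  rather than inside the CSVs to keep the schemas clean.
* Degenerate inputs raise typed errors (`InvalidInputError`,
  `InvalidConfigError`, `ModelRangeError`, `InsufficientDataError`,
  `DegenerateFitError`) rather than returning sentinel values; a
  non-terminating simulation configuration (non-positive deficit) is
  rejected before stepping.

## Problem sizes

The test suite evaluates the closed-form/stepping equivalence on 100
randomized subjects, the partition-consistency property on 1000 random
cases (to 1e-9 kg), agreement recovery on a 69-subject adherent cohort
(≈ 650 paired examinations), and detection sensitivity on 69-subject
cohorts at three intake-excess levels.  The full suite runs in well under
a minute on one core; the acceptance script in a few seconds.

## Known limitations

* The model is static: no metabolic adaptation, no activity, no
  body-composition distinction — final BMI of muscular subjects will be
  judged pessimistically.
* The "required" (maintenance) energy is a single configurable constant,
  not an individualized estimate (no Mifflin-St Jeor / Harris–Benedict);
  literal mode avoids the constant entirely at the cost of dimensional
  coherence.
* Repeated-measures corrections to the limits of agreement are not
  applied; all examinations are pooled, matching standard practice for
  this evaluation style.
* Multi-restart programs appear in data as relapse episodes; no
  automated restart policy is modelled.
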