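# Methods

This note documents the models and procedures implemented in `hiikit`, the
assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic-cohort experiments demonstrate.

## Labeling and feature extraction

Hemodynamic instability has no gold-standard annotation in routine ICU
databases, so the label is a treatment proxy: an encounter is **unstable**
if the patient received a qualifying intervention — a fluid bolus at a rate
strictly greater than 10 ml/kg/h, or the start of one of six vasoactive
drugs (dopamine, dobutamine, epinephrine, norepinephrine, neosynephrine,
vasopressin) — and **stable** if no qualifying intervention occurred during
the stay. The *onset* is the first qualifying intervention; only one
intervention per patient is considered, and only each patient's first
admission enters the analysis. Encounters unstable within 6 h of admission
are excluded (their deterioration predates the observable record), as are
encounters with no charted data or with age outside 1 month–20 years. Every
exclusion is counted in a ledger so that exclusions plus labeled encounters
always equal the input encounters.

Feature vectors take the **last value** of each of 36 charted variables in
the half-open 24-hour window `(ref − 24 h, ref]`; a variable never measured
in the window is missing. For unstable encounters the training reference
time is the onset, and evaluation vectors are additionally built at
`onset − L` for lead times L = 1…12 h. For stable encounters the reference
time is drawn uniformly at random (seeded) from `[admission + 24 h,
discharge]` so that a full window of history is available, falling back to
`[admission + 6 h, discharge]` for shorter stays; the random draw is made
once and reused across lead times.

Three composites are derived after extraction, with invasive systolic /
mean pressure preferred over cuff values: shock index SI = HR/SBP,
oxygenation index OI = MAP_aw·FiO2·100/PaO2 and oxygen-saturation index
OSI = MAP_aw·FiO2·100/SpO2 (MAP_aw = mean airway pressure in cmH2O, FiO2 a
fraction; FiO2 arriving as a percent is divided by 100 at ingest). A zero
denominator leaves the composite missing and is logged.

### Cleaning rules

* **Plausibility filter.** Each variable has a physiologic validity range
  (e.g. heart rate 20–350 bpm, systolic BP 30–300 mmHg, temperature
  25–45 °C, pH 6.5–8.0, FiO2 0.21–1.0, SpO2 5–100%); out-of-range values
  become missing. The full built-in table lives in
  `hiikit.features.CATALOGUE` and is overridable by config. The filter is
  idempotent and must cover every feature present.
* **Blood-pressure reconciliation.** When a cuff (noninvasive) reading of a
  BP component falls within 20 minutes of an arterial-line (invasive)
  reading of the same component, the cuff reading is discarded; invasive
  readings are never removed. The 20-minute default is the upper end of the
  plausible proximity range and is configurable.
* **Staleness horizons (runtime scoring only).** Blood-pressure and
  ventilator measurements expire 1 h after charting; laboratory values and
  other vitals expire after 24 h. Ventilator parameters are grouped with
  the 1-h class because they change on the same timescale as invasively
  monitored pressures; non-BP vitals default to 24 h. Training-time window
  extraction uses the single 24-h observation window for all features, per
  the labeling protocol above.
* Simultaneous duplicate measurements resolve to the last-read row
  (file order), which is logged as the tie-break convention.

## The learner

Weak classifiers are **age-conditioned decision stumps**: a lookup table
over five age bins (1–12 mo, 1–3, 3–6, 6–12, 12–20 y; configurable) holding
one threshold and vote direction per bin for a single feature. A stump
votes +1 (unstable) or −1 (stable) from its bin's threshold, and **abstains
(0)** when its feature is missing. Age is required for every example and is
never missing by construction.

Training is the confidence-rated construction for abstaining weak learners.
With weights D_t summing to 1, a candidate stump partitions the weight into
W₊ (voted correctly), W₋ (incorrectly) and W₀ (abstained), and is scored by
the exponential-loss normaliser

    Z = W₀ + 2·√(W₊·W₋).

Because the correct-minus-incorrect weight of an age-binned stump is a sum
of independent per-bin terms, the Z-optimal stump for a feature is found by
maximising that term bin by bin (orienting each bin so its correct weight
dominates, hence α ≥ 0) — this greedy-per-bin search provably equals the
exhaustive minimum over the full cross-product of per-bin candidates, and
the test suite checks that equivalence against a brute-force enumerator on
small instances. Candidate thresholds are midpoints between consecutive
distinct in-bin values, thinned evenly to 64 per bin; bins with too little
data inherit the nearest populated bin's candidates.

Per round: the Z-minimising candidate is selected (ties broken
deterministically by catalogue feature order, then lower threshold, then
high-is-unstable), given vote weight α_t = ½·ln((W₊+ε)/(W₋+ε)) with
ε = 1/(2N), and weights are updated D_{t+1}(i) ∝ D_t(i)·exp(−α_t·y_i·h_t(x_i))
and renormalised — abstained examples' weights are multiplied by exactly 1.
Training stops at `n_rounds` (default 100), when the best Z reaches
1 − 10⁻⁶ (no usable signal left), or when the best stump's α would be
non-positive. If no candidate is informative at round 1 the fit fails
loudly. Per-round Z, α, training error and exponential loss are recorded;
with ε = 0 the classic bound (empirical exp-loss ≤ Π_t Z_t) holds and is
asserted in tests.

The margin F(x) = Σ_t α_t·h_t(x) is mapped to a probability by the
additive-logistic view of boosting, p = 1/(1 + e^{−2F}). The margin is
deliberately **not** normalised by Σα, so the calibration map is part of the
model and is serialized with it; operating thresholds are therefore not
transferable between models trained under different conditions. Models
serialize to a versioned JSON text format carrying the stump list, the
calibration name, the operating threshold, and frozen copies of the feature
catalogue, plausibility table and staleness horizons; the loader refuses a
model whose catalogue digest does not match the running package's.

Feature selection is emergent: features whose candidates never win a round
simply never appear in the ensemble, and `selected_features` ranks the
chosen ones by summed vote weight. An always-missing feature can never be
selected, so adding one leaves the serialized model bit-for-bit identical —
a property the acceptance suite asserts.

## Runtime scoring

`score_stream` replays an encounter's events at a fixed cadence (default
1 min in principle; the bundled examples use coarser cadences for speed).
At each tick the staleness gate produces the current-value snapshot,
composites are re-derived, and the model emits the HII probability, which
is banded green / yellow / red. The red cutpoint defaults to the model's
break-even operating threshold and the yellow cutpoint to 0.1 below it
(clamped); both are configurable, and band boundaries are closed from
below. Heart rate and age are the minimum inputs — ticks without them (or
where every stump abstains) produce an explicit no-output record with a
reason, never a silent skip. Scoring is strictly causal; truncating the
event stream after a tick cannot change that tick, which is asserted in
tests. `explain` reports per-feature signed contributions (the sum of
α·vote over that feature's stumps), which sum exactly to the margin;
features whose stumps all abstained are flagged *missing* rather than
reported as zero.

## Evaluation protocol

* **AUROC** is computed by the Mann–Whitney statistic (ties counted ½),
  which equals trapezoidal ROC integration; it is cross-checked against a
  brute-force pairwise count and an independent library implementation in
  tests.
* **Operating point**: the break-even threshold minimises
  |sensitivity − precision| over the observed unique scores (classification
  rule: score ≥ threshold ⇒ unstable), ties toward the lower threshold.
  Exact equality is generally unattainable on a finite score set, so the
  search is over observed cutpoints only, without interpolation.
* **Prevalence adjustment**: PPV = sens·π/(sens·π + (1−spec)(1−π)) and
  NPV = spec·(1−π)/(spec·(1−π) + (1−sens)·π). At π equal to the sample
  prevalence these reproduce the raw confusion-matrix values exactly.
  The positive likelihood ratio is sens/(1−spec). Two published
  inconsistencies are noted here for the record and deliberately not
  asserted: an LR of 5.22 quoted alongside sens 0.66 / spec 0.78 (the
  standard formula gives 3.0), and a validation age-group SD quoted as 0.06
  where the five printed values give 0.065 (the printed table is treated as
  authoritative; only the means and extrema are checked).
* **Stratified analyses** cover the five age groups, ventilated vs not,
  encounters whose first intervention was vasoactive, and feature subsets
  (vitals / labs / ventilator). Feature subsets are evaluated by masking
  all other features to missing at predict time and re-deriving composites,
  letting abstention absorb the removal — no retraining — with a
  retrain-per-subset mode available as an option. Empty strata are skipped
  with a warning, never silently.
* **Baselines**: the identical learner restricted to systolic blood
  pressure (both sources) or to the shock index, evaluated on the same
  held-out split as the full model.
* Sample SD uses the n−1 denominator throughout.

## The cohort simulator

No patient-level dataset accompanies the modelled system, so the simulator
defines the study conditions. It emulates:

* **Age-dependent physiology** — built-in piecewise-linear reference curves
  (mean, SD vs age) for all 36 features, age-varying where physiology
  demands it (heart rate 140→70 bpm from infancy to late adolescence,
  respiratory rate 40→14, blood pressures rising, creatinine rising,
  weight-normalised urine output falling) and flat otherwise. The knots are
  pediatric-plausible textbook values, documented in
  `hiikit.cohort_sim.DEFAULT_CURVES` and fully configurable.
* **Recording behavior** — each feature is ever-recorded with the
  probability observed in the modelled population's recording table
  (heart rate 100%, cuff BP 98%, blood gases 63%, lactate 14%, …), and
  measured at Poisson-spaced intervals with feature-appropriate mean gaps
  (vitals hourly, blood gases ~8 h, chemistry ~12–24 h). Invasive BP is
  gated by a patient-level arterial-line Bernoulli (default 0.5), and both
  BP streams co-occur to exercise reconciliation. A small gross-error rate
  (0.1%) plants implausible values so the plausibility filter has work.
* **The cohort mix** — 42% instability prevalence by default; intervention
  types split 70% fluid bolus / 30% vasoactive; ventilation, mortality and
  length-of-stay distributions differ between the groups in the direction
  seen in real PICU cohorts (unstable patients: more ventilation, longer
  stays, higher mortality).
* **Pre-intervention deterioration** — unstable patients' feature means
  drift monotonically toward the shock direction (heart rate and lactate
  up, blood pressure, pH, base excess and urine output down, respiratory
  support escalating), scaled per feature in reference-SD units, ramping
  linearly over the `deterioration_duration` hours before onset and held
  constant afterwards. The default effect sizes (+2 SD heart rate and
  lactate, −1.5 SD pH/base excess/urine output, −0.8 SD systolic BP, …)
  were chosen once as a realistic compensated-shock picture in which heart
  rate moves early and strongly while blood pressure moves late and
  weakly — which also yields the expected ordering of the full model over
  the SI-only over the SBP-only baseline. The ramp duration defaults to
  **24 h** so that the deterioration signal spans the entire 1–12 h
  lead-time evaluation range; a ramp no longer than the longest evaluated
  lead time would make the 12-h stratum unlearnable by construction,
  contradicting the clearly above-chance 12-h performance the modelled
  system shows on real data.
* One qualifying intervention per unstable patient, always later than 8 h
  after admission (clear of the 6-h exclusion); fluid boluses draw rates
  uniformly in 11–40 ml/kg/h.

All randomness flows from a single seed through per-patient deterministic
substreams, so identical (config, seed) pairs reproduce byte-identical
tables, provenance header included.

### What the simulator does *not* model

No pharmacokinetics or therapy response (drift is held, not reversed, after
onset), no multi-intervention sequences, no pre-ICU interventions, no
cross-feature correlation beyond the shared deterioration ramp (a real
blood-gas panel is internally correlated; simulated features are
conditionally independent given age and the ramp), no informative-presence
effects (in real data the *existence* of an arterial line carries risk
information; here invasive monitoring is independent of the label beyond
the configured rates), and no terminology noise beyond a simple alias map.
Consequently, passing the signal-recovery checks shows that the pipeline
recovers the kind of structure it assumes — age-conditioned univariate
drifts under realistic missingness — not that it would achieve comparable
discrimination on real ICU data, where the published evidence comes from
retrospective cohorts.

## Numerical choices and degenerate inputs

* Weak-learner ties: 10⁻¹² slack when comparing weights and Z values so
  float summation order cannot break mathematical ties; the documented
  tie-break order (feature, threshold, direction) then applies.
* With ε = 0 on separable data α diverges; training raises rather than
  emitting a non-finite weight. The ε = 1/(2N) default keeps α finite.
* Probabilities can saturate to 1.0 in floating point for large margins;
  color-band construction clamps cutpoints into (0, 1).
* Division guards: SI/OI/OSI with a zero denominator are missing, logged.
* Examples the model cannot score (every stump abstains) get NaN scores in
  batch evaluation and are dropped with a logged count; the single-vector
  API raises instead.
* Stratified and lead-time reports skip empty strata with warnings;
  `summary_stats` returns NaN SD for a single value.

## Problem sizes

The bundled experiments use cohorts of 150–2000 patients (the
signal-recovery and age-adjustment studies at n = 2000, the null-calibration
study at n = 1000 with 10-fold cross-validation, unit fixtures at 100–400),
chosen so the whole suite and the acceptance script each run in minutes on
one core while leaving Monte-Carlo error well inside the asserted margins.
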