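# Methods

## Data model

A `GlucoseTrace` is one patient's CGM record: glucose concentrations in
mmol/L on a strict 5-minute grid, 288 samples per day, at least one whole
day, all values finite and positive. Incomplete days are not represented:
the reader drops a trailing partial day (with a warning) and rejects any
interior day with missing samples, unless linear interpolation of runs of
at most 3 samples (15 min) is explicitly enabled. Rationale: every
feature below assumes a complete grid, and silently imputing long gaps
would fabricate excursions.

Labels are +1 for type 1 diabetes and −1 for type 2 (stored as
`T1D`/`T2D` in files).

## The 17 features

All per-day features are computed day by day and averaged across the
record's days; MODD is computed on consecutive day pairs and averaged
(hence ≥ 2 days per patient). Canonical order: `mean_day`, six
pre-/post-meal means, `sdbg`, `lage`, `modd`, `auc`, `mage`, `th`, `tl`,
`hl`, `ll`, `wl`.

* **Means.** Whole-day mean x̄ = (1/288)Σxᵢ. Meal windows are fixed
  clock windows (defaults: breakfast 07:30, lunch 12:00, dinner 18:00;
  30 min before the meal, 120 min after, membership by slot midpoint).
  No meal log accompanies a CGM trace, so event-locked windows are not an
  option; the defaults are configurable and recorded in run manifests.
* **SDBG** is the *population* standard deviation (divisor n = 288), not
  the n−1 sample form — implemented exactly as the defining formula
  states.
* **LAGE** = x_max − x_min over the day.
* **MODD** = (1/287)·Σ_{i=1..288}|v₁(i) − v₂(i)| for two consecutive
  days. The defining formula sums 288 terms but divides by 287; the
  formula is implemented as printed. The divisor is internally
  inconsistent with a 288-term mean, so a `modd_denominator ∈ {287, 288}`
  switch exists (default 287).
* **AUC** is the excess area outside the band [lower, upper] in
  mmol/L·h: trapezoidal integration of max(x − upper, 0) plus
  max(lower − x, 0) at 1/12 h per step. The day is treated as a closed
  24 h interval — the last sample is held to midnight — so a constant
  excess of c integrates to exactly 24·c rather than 287/288 of it.
* **MAGE** follows the classical four-step procedure: (1) collect all
  local extrema; (2) find the first extreme point whose absolute
  difference to *both* adjacent extrema exceeds the day's SDBG; if none
  exists MAGE is 0; (3) collect the amplitudes of consecutive extremum
  pairs exceeding the SD, each counted once; (4) average them.
  Two conventions had to be fixed:
  * *Plateaus.* Strict sign-change extrema are undefined on runs of
    equal values; each run is collapsed to its midpoint sample before
    extremum detection, which eliminates tie-breaking.
  * *Direction.* The procedure's walking direction ("from the first
    valid point leftward, then over the remainder") is implemented as:
    all consecutive valid-pair amplitudes are included exactly once.
    This is the unique reading that makes the result independent of the
    starting point; it is isolated in one function (`features.mage`).
* **TH / TL** count excursion events beyond the band: local maxima above
  the upper threshold and local minima below the lower one (same
  extremum detector as MAGE). An alternative reading — counting maximal
  runs of samples beyond a threshold — is available via
  `th_tl_mode="crossings"` (default off). Multi-day aggregation averages
  the per-day integer counts, so the patient-level values may be
  fractional.
* **HL / LL / WL** are 100·#(x > upper)/288, 100·#(x < lower)/288 and
  the remainder; they sum to 100 by construction.

The lower threshold defaults to 3.9 mmol/L (the standard hypoglycemia
cut-off); only the upper threshold μ is swept (7–11 mmol/L).

## Boosting variants

Samples are 17-feature vectors with labels y ∈ {+1, −1}; weights start at
D₁(i) = 1/m. The final classifier is sign(Σ_t α_t h_t(g)), with
sign(0) → +1 as a fixed, deterministic tie rule.

* **Discrete AdaBoost.** Each round fits the weighted-error-minimizing
  decision stump over all features; candidate thresholds are midpoints
  between consecutive distinct sorted values, ties broken by (lowest
  feature index, lowest threshold, positive polarity). α_t =
  ½ln((1−ε_t)/ε_t); weights are multiplied by exp(−α_t yᵢ h_t(gᵢ)) and
  renormalized, so Σᵢ D(i) = 1 after every round. The polarity flip makes
  ε_t > ½ unreachable (asserted). A perfect round (ε_t = 0) takes its α
  through ε ← max(ε, 10⁻¹⁰) and stops training: the weight update would
  be degenerate afterwards.
* **Real AdaBoost.** Per feature the value range is partitioned once
  into up to 8 equal-frequency blocks (quantile edges from the training
  data). Each round computes the block class masses p±ʲ = Σ_{g∈Gⱼ,y=±1}
  D(i), picks the feature minimizing z = 2Σⱼ√(p₊ʲp₋ʲ), and emits
  ½log(p₊ʲ/p₋ʲ) per block with Schapire–Singer smoothing
  p ← (p + ε_s)/(1 + 2ε_s), ε_s = 1/(4m); an empty block therefore emits
  exactly 0. Weights update by exp(−yᵢh(gᵢ)) and renormalize.
* **Gentle AdaBoost.** The base learner is a regression stump fit by
  weighted least squares of y on g: each side outputs the weighted mean
  label, and the split maximizing the weighted sum-of-squares reduction
  wins (same tie-breaking as above). A side with zero weight outputs 0.
* **Modest AdaBoost.** Alongside D, the inverted distribution
  D̄ ∝ (1 − D) is maintained. Block responses are
  fⱼ = P₊ʲ(1−P̄₊ʲ) − P₋ʲ(1−P̄₋ʲ) with P from D and P̄ from D̄ — regions
  the ensemble already handles (large P̄) are damped, which is the
  variant's defining idea; responses are bounded in [−1, 1]. The feature
  maximizing the weighted margin gain Σᵢ D(i)yᵢf(gᵢ) = Σⱼ fⱼ(P₊ʲ−P₋ʲ) is
  kept; training stops when the best gain vanishes (the response would
  be identically ~0). No probability smoothing is applied here: the
  response contains no logarithms and is bounded with raw masses, and
  smoothing would bias the damping terms.

Training is fully deterministic given the inputs; models serialize to
versioned JSON and round-trip bit-exactly.

A structural note: boosted axis-aligned stumps provably cannot express
the canonical 4-point XOR pattern — every stump errs on exactly half the
uniform weight, so α₁ = 0 and the distribution never moves. The test
suite asserts this degenerate behaviour (ensemble error equals the
exhaustive-stump optimum of ½, and Modest refuses to add a zero-gain
learner) rather than pretending the pattern is learnable.

## Evaluation

Positive class = type 1 (+1). ACC = (TP+TN)/(P+N);
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) with the standard
convention MCC = 0 when the denominator vanishes. The hold-out protocol
shuffles with a seeded generator and trains on round(2/7 · n) samples
(the 300-of-1050 study ratio, applied as a ratio for other n). k-fold CV
is *stratified* (per-class round-robin dealing after a seeded shuffle):
plain random folds can lose a class entirely on small cohorts.
Early-stopped ensembles report staged-error curves of their actual
length; fold means extend shorter curves with their final value, which
is exact (an unchanged ensemble has constant error).

The threshold sweep re-extracts features at each μ and reuses one seeded
split across all (variant × μ) cells, so grid differences reflect the
threshold and the variant, not the partition.

## Synthetic cohorts

The generator emulates the structure of a hospital CGM cohort that is
not publicly deposited; it is first-class, tested code. Each day curve
is baseline + three meal-locked Gaussian excursions (peak ≈ 75 min after
the meal) + sinusoidal circadian drift + optional Poisson-placed
hypoglycemic dips + optional non-meal excursions ("snacks", stress) +
white sensor noise, clipped to the sensor range [2, 25] mmol/L. A master
seed derives an independent substream per patient
(`default_rng([seed, class, index])`), so cohorts are reproducible and
order-independent: removing a patient leaves every other trace
bit-identical.

Three presets define the study conditions:

* **default** — 525+525 patients, 2 days: type 1 with lower baseline
  (7.0 mmol/L), large excursions (4.5 mmol/L) and frequent hypoglycemia
  (0.5/day); type 2 with higher baseline (8.5), blunted excursions (2.0)
  and rare hypoglycemia (0.05/day); noise SD 0.3 mmol/L. This follows
  textbook CGM physiology of the two phenotypes.
* **null** — both classes draw from the midpoint phenotype; any
  classifier's held-out error concentrates at ½. Used as the no-signal
  control.
* **structured** — 150+150 patients built so the class signal lives
  below ~9.5 mmol/L: the contrast is a frequency-versus-amplitude
  tradeoff in non-meal-locked excursions (6/day of ≈1.7 mmol/L vs
  1.5/day of ≈3.0 mmol/L) with rate × amplitude² matched so whole-day
  mean and variance coincide (the residual mean gap is absorbed into the
  baseline), meal-locked bumps off, low-dispersion daily event counts
  (integer part + Bernoulli remainder) so day-level occupancy is stable,
  and a shared snack process whose amplitude range spans both phenotypes
  to blur the amplitude-sensitive threshold-free features (MAGE, LAGE).
  What remains separable is occupancy above 7–8 mmol/L (HL, TH, AUC),
  while both phenotypes stay essentially below 10 mmol/L — so sweeping μ
  to 10–11 discards the signal. This is the cohort on which the
  error-versus-threshold pattern (better classification at μ = 7–8 than
  at 10–11, for every variant) is demonstrated.

What the generator does **not** model: glucose–insulin dynamics (no
minimal-model ODEs), sensor artifacts (dropouts, compression lows,
calibration steps), meal-content or medication effects, demographics.
Passing tests on these cohorts therefore demonstrate the correctness and
internal consistency of the pipeline — feature fidelity, boosting
behaviour, protocol determinism, and sensitivity of the threshold sweep
to where the class signal sits — not clinical performance on real
patients.

## Problem sizes and determinism

The shipped evaluations use the default cohort at full study scale
(525+525 patients, 2 days, T = 100, 2/7 split; 750-patient test sets)
and the structured cohort at 150+150 patients across 10 seeds for the
threshold-sweep pattern — sizes chosen so the complete suite runs on a
single CPU in well under a minute per block. Every stochastic step
(cohort generation, splits, fold assignment) is driven by explicit
seeds; the end-to-end pipeline is bit-reproducible on a given platform,
and run manifests record config snapshots, seeds and input digests.

## Known limitations

* The MODD divisor (287 for a 288-term sum) is kept as defined; the
  self-consistent mean is one config switch away.
* TH/TL averaging across days can yield fractional counts.
* The MAGE direction convention and plateau handling are one defensible
  reading of an ambiguous procedure; both are isolated and documented.
* Scores are not calibrated probabilities; no multiclass support; stumps
  only (no deeper trees).
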