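# Methods

This note documents the models and procedures implemented in `eisrisk`,
the parameters that matter, and the design decisions taken where the
design was genuinely open.

## Spectral model and synthetic cohorts

Real oral-mucosa EIS spectra for this problem are confidential, so the
package generates synthetic cohorts whose spectral and sampling structure
emulates the clinical study design.

**Spectral model.** Each tissue class is parameterised by a
single-dispersion Cole model,

    Z(ω) = R_∞ + (R0 − R_∞) / (1 + (jωτ)^α),

the simplest standard bioimpedance form that reproduces the qualitative
features of mucosal spectra: a real part decreasing monotonically from the
DC limit `R0` to the high-frequency limit `R_∞`, and a single-peaked
reactive part centred near `ω = 1/τ`. Stored spectra follow the
convention `Z = Z_Re − j·Z_Im`, so the recorded reactive part is
non-negative for a passive capacitive tissue. The frequency grid is 14
binary (doubling) steps from 76 Hz, topping out at 622,592 Hz (the probe's
nominal 625 kHz).

**Disease effect.** Lesion classes differ from healthy tissue chiefly by a
reduced `R0` and a shortened `τ`, so their spectra leave the healthy band
most visibly at low frequency, with severity ordering the departure
(healthy `R0` = 4000 Ω down to cancer `R0` = 1500 Ω; the porcine
acid-treated class uses `R0` = 1800 Ω). No published numeric spectra
exist for this problem; these effect sizes are free presets calibrated
only to the qualitative published picture, and they produce *stronger*
class separation than clinical data (pooled synthetic test AUCs near 1.0
versus the reported clinical 0.90–0.98). Passing tests therefore
demonstrate that the pipeline recovers separable classes and sits at
chance on null data — not that clinical-grade accuracy is attainable.

**Sampling hierarchy.** A subject draws latent Cole parameters from its
class distribution — multiplicative log-normal with per-parameter log-SD
`subject_sd` (default 0.10), keeping parameters positive — and all of the
subject's readings share them. Reading-level measurement noise is
independent multiplicative Gaussian with SD `reading_sd` (default 0.03,
i.e. 3% of signal) on the real and reactive parts separately. Each
reading is treated as an independent observation downstream, matching the
clinical analysis.

**Cohort presets.**

* Human: 51 healthy subjects / 102 readings; 5 cancer / 10; 1 mild / 2;
  3 moderate / 4; 2 severe / 5. The moderate reading pattern is pinned to
  (2, 1, 1) with the two subjects holding 3 readings assigned high-risk,
  which reproduces the published binary split (2 low-risk subjects / 3
  readings; 9 high-risk / 18) exactly and deterministically. For
  non-default configurations, moderate dysplasia maps to high-risk with
  probability `moderate_to_highrisk_fraction` (default 2/3): binary risk
  grading is an independent histopathological assessment, not a function
  of the WHO grade.
* Porcine: 15 normal heads / 220 readings, 3 acid-treated heads / 80.
* Null calibration: 150 low-risk subjects / 300 readings and 30 high-risk
  subjects / 60 readings, with **zero class effect and zero
  between-subject variation**. Two deliberate departures from the human
  preset: the chance band of a pooled AUC must be resolvable, and the
  tiny clinical cohort cannot provide that — its pooled AUC is pinned to
  18 fixed high-risk readings (standard error ≈ 0.08), and latent
  per-subject spectra make single-trial AUCs swing between ~0.05 and
  ~0.85 purely through the subject lottery. Removing subject-level
  variation makes readings exchangeable, and the larger cohort brings the
  pooled null AUC standard error to ≈ 0.04, so the [0.4, 0.6] band is a
  meaningful bias check.

## Classifier family

`Model_xl_yc_z` denotes `x` ∈ {2, 3} fully connected hidden layers of
`z`-mapped {1 → 125, 2 → 250} ReLU neurons, preceded by `y` ∈ {0, 2} 1-D
convolutional layers. The mapping of the `z` suffix to the two published
neuron options follows their listed order and is configurable.

The convolutional variant views the 28-vector as 2 channels (real,
reactive) × 14 frequencies and applies two stride-1, same-padded
convolutions (kernel width 3; 8 then 16 channels) with ReLU before the
dense stack — convolution couples impedance at adjacent frequencies,
where the dispersion shape lives. The exact original convolutional
configuration is not published; these widths are this package's declared
choice and are configurable (`conv_channels`, `kernel_size`).

**Objective.**

    Obj = − Σ_c W_c y_c log(p_c) + (λ/2) Σ_i w_i²,

with per-class weights `W_c` (condition notation `W1:W2[:W3] λ`, ordered
normal/majority class first and high-risk last), λ ∈ {0.1, 0.01}, and the
L2 sum running over every weight *and* bias. The penalty is implemented
inside the loss, not as optimizer weight decay, so reported objective
values decompose exactly into cross-entropy + penalty. Probabilities are
clamped to [1e-12, 1] before the log. The cross-entropy term is averaged
over the mini-batch.

**Optimisation.** The original training schedule is unpublished; this
package uses Adam (learning rate 1e-3, β = 0.9/0.999), batch size 16, at
most 300 epochs, with early stopping on validation cross-entropy
(patience 30, best parameters restored) whenever a validation set is
supplied. Initialisation is He-normal for ReLU layers and
variance-1/fan-in for the output layer. Features are z-scored per feature
on the training data only (impedance magnitudes span decades across
frequency); the scaler travels with the fitted estimator. A fixed
`random_state` makes initialisation, batch order and hence the fitted
parameters bit-reproducible.

## Experimental design

Each trial: (1) carve a subject-disjoint test set; (2) split the
remainder into K = 3 reading-level folds, dealing each class round-robin
so rare classes spread across folds; (3) for every candidate model, train
on each 2-fold pool (SMOTE-augmented for the human tasks) and score the
held-out fold; (4) average validation AUC over folds and trials, select
the top models (ties broken by fewer parameters, then name); (5) retrain
the selected models on train+validation, fix the decision threshold on
training scores, and evaluate the test set. Per-trial seeds derive from
the master seed and trial index, so trials are independent and the whole
run is reproducible bit-for-bit.

**Test carve.** For the porcine task the test set is one fold-equivalent
(~1/(K+1) of each class's readings) assembled from whole subjects; with
only 3 treated heads of ~27 readings, the published 55/20 per-fold counts
cannot coexist with a subject-disjoint carve, so fold counts are
approximate (± one subject's readings) and the subject boundary wins.
For the human tasks the carve is constraint-based: exactly one lesional
low-risk subject, high-risk subjects totalling ~6 readings, and ~1/K of
the healthy subjects; splits are resampled (up to 100 attempts) until
every training pool contains every class.

**SMOTE.** Minority classes in a training pool are raised to the majority
count; each synthetic row is `x_i + δ(x_nn − x_i)` with `δ ~ U(0,1)` and
`x_nn` one of the `k = 3` nearest same-class neighbours (k is capped at
class size − 1). A class with a single training reading cannot be
interpolated and is instead duplicated with Gaussian jitter of SD 1e-6,
flagged in the trial result. Synthetic rows exist only inside training
folds — never in validation or test — and every trial records a leakage
audit (subject overlap, synthetic-row placement, scaler provenance).

**Cross-validation folds are reading-level.** Subject disjointness is
enforced at the test boundary only; within CV folds, readings of one
subject may straddle train and validation, mirroring the clinical
study's own constraint with few high-risk cases. Validation AUCs are
therefore slightly optimistic; test metrics are not.

## Decision thresholds

All thresholds are functions of training scores alone; score ties resolve
as "≥ threshold → positive" everywhere.

* **Youden (binary baseline).** Candidate thresholds are midpoints of
  consecutive sorted unique scores plus sentinels beyond both extremes;
  `T_Y` maximises `J = TPR − FPR`, ties toward the higher (more specific)
  threshold. `J` may be negative for worse-than-random orderings and is
  reported as such.
* **Three-class screening rule.** With class scores (z₁ normal, z₂
  low-risk, z₃ high-risk): call high-risk iff `z₃ ≥ T*`, else normal iff
  `z₁ ≥ z₂`, else low-risk. For any `T* ≤ 1/3` the rule's high-risk
  region contains the arg-max rule's, so high-risk sensitivity can only
  improve. "Balanced performance" over classes is operationalised as
  maximin per-class sensitivity over the sweep grid 0.5 → 0.15 (step
  0.05), ties toward the higher `T*`; a `fixed_Tstar` override (0.2 being
  the published operating choice) bypasses the selection.
* **α-scaled Youden rule.** Call high-risk iff `score ≥ α·T_Y`, sweeping
  α over 1.0 → 0.1 (step 0.1). "Satisfactory sensitivity with acceptable
  specificity" is operationalised as maximising training sensitivity
  subject to training specificity ≥ a floor (default 0.9), ties toward
  the larger α; if no α meets the floor the policy falls back to α = 1
  with an infeasibility flag. A `fixed_alpha` override is provided.

## Metrics

* Sensitivity/specificity with empty denominators return `nan`, an
  explicit "undefined" sentinel distinguishing "no cases" from "all
  missed"; accuracy on an empty matrix is an error.
* ROC AUC (scikit-learn's trapezoidal implementation) equals the
  tie-corrected pairwise probability `P(s_pos > s_neg) + ½P(=)`; the test
  suite asserts the equivalence against an independent brute-force oracle.
* Multi-class AUC is the unweighted mean of one-vs-rest AUCs, each using
  that class's own probability column as the score (the published
  definition does not fix the per-problem score; this choice is declared
  and configurable by construction). It reduces to binary AUC at K = 2.
  A class absent from a validation fold is skipped only when explicitly
  allowed — needed because 3 low-risk readings cannot occupy 3 folds.
* Wilcoxon signed-rank (two-sided) drops zero differences (Wilcoxon's
  prescription; the Pratt alternative changes p), uses the exact
  distribution for n ≤ 25 non-zero pairs and a normal approximation with
  continuity correction beyond; all-zero differences return p = 1 with a
  degeneracy flag.
* Pooling concatenates per-trial test decisions before computing
  per-true-class distributions and per-WHO-grade sensitivity within the
  high-risk class.

## Problem sizes

Full-scale runs (100 trials × 8 architectures × 4 conditions) are
supported but long on one CPU. The package's desk-scale defaults — used
by the test suite and `scripts/acceptance.py` — are 10–20 trials, one or
two candidate models, 25–60 training epochs at batch size 32. All
reported quantities are computed at these sizes and labelled with the
problem size used.

## Known limitations

* The Cole presets are not fitted to any real tissue; absolute impedance
  levels, effect sizes and noise structure are plausible but invented,
  and class overlap is milder than clinical reality.
* No electrode/device physics (contact pressure, probe placement,
  drift), no multi-dispersion spectra, no site-specific effects beyond a
  site label.
* CV folds are reading-level (see above); only the test boundary is
  subject-disjoint.
* Multi-class AUC convention and the convolutional stack are declared
  substitutes for unpublished details; both are configurable.
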