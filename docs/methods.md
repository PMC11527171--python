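# Methods

## The analysis problem

A two-scan differential FDG-PET design measures how regional brain glucose
metabolism changes with a behavioral event. Each subject receives a
baseline scan after a familiarization session (F1) and a second scan after
a contextual recall session (F3); the difference in normalized regional
uptake, ΔSUV = SUV(F3) − SUV(F1), isolates the task-associated metabolic
response. Two groups are compared: coherent responders (CON, e.g.
sham-operated controls) and a group with blunted, incoherent responses
(LS, e.g. long-sepsis survivors). Alongside imaging, freezing behavior is
scored from frame-wise video activity traces for the familiarization (F1),
conditioning (F2) and recall (F3) sessions.

`betapet` implements the full analysis as a library plus CLI: freezing
scoring, ΔSUV quantification, nested mixed-model group inference,
ΔSUV–behavior correlation, leave-one-out classification, and an
ordinal-trends canonical variates analysis (ORT) that validates the
region-of-interest findings with a voxel-level multivariate pattern.

## SUV normalization and ΔSUV

Each registered, skull-stripped volume is divided by its whole-brain mean,
so regional values are dimensionless and invariant to injected dose and
scanner gain (`roi.normalize_scan`). Region masks are per-slice footprints
over a common grid; bilateral regions are split at a configurable midline
x coordinate (x < midline → left; midline voxels go right by convention),
while the prefrontal regions PLC and ILC straddle the midline and are
scored as a single object per slice. Each (region, coronal slice,
hemisphere) cell yields one mean-SUV record; F3 − F1 differences are taken
record-wise, and per-subject region summaries are unweighted means over
slice/hemisphere records (voxel-weighted means are available as an
option). Slices where a mask∩hemisphere is empty are omitted with a
warning rather than zero-filled, which would bias region means.

## Group inference

Because each subject contributes many ΔSUV records per region, the group
test is a linear mixed model: fixed group effect, random intercept per
subject, record-level residual. Variance components are estimated by REML
(statsmodels `MixedLM`); the fixed effect and its standard error are then
computed in closed form by generalized least squares on subject means with
weights n_i/(σ̂²_e + n_i σ̂²_b). The standard error is scaled by the
empirical weighted between-subject residual variance rather than the
plug-in components: near the σ²_b = 0 boundary (common after whole-brain
normalization, which absorbs most subject-level intensity variation) the
plug-in Wald error is badly anticonservative, while the empirical scaling
makes the test reduce exactly to the two-sample t test on subject means in
balanced designs. The group effect is tested as F = (estimate/SE)² against
F(1, df) with the conservative between-subject denominator df =
n_subjects − 2 (a record-level "residual" df option exists). When every
subject has exactly one record the random intercept is unidentifiable and
the model collapses to the pooled t test (F = t² exactly).

Monte-Carlo calibration (200 simulated cohorts at the default noise
levels, 9 vs 15 subjects): type-I error at α = 0.05 stays within binomial
noise of nominal, and power for a planted BA-scale difference
(0.15 vs 0.049) exceeds 90%. No multiple-testing correction is applied
across the eight regions by default (raw per-region p values are
reported); a Holm adjustment helper is provided.

Per-subject ΔSUV–freezing coupling uses ordinary least squares and the
Pearson product-moment correlation; constant inputs yield an explicit
"undefined" result, never r = 0.

## Freezing scoring

A frame is inactive when its activity score is strictly below the
threshold (so a zero threshold gives zero freezing). The threshold has no
canonical value — it depends on camera and arena — and defaults to 10
score units, documented as arbitrary and configurable. Percent freezing is
computed on 10-s bins; the session value is the unweighted mean of
complete bins in the scoring window (trailing partial bins are reported
but excluded). Default windows: the conditioning session is scored over
the tone + trace intervals only; the recall session over its last 4
minutes. Bouts are maximal inactive runs of ≥ 2 s (boundary included),
taken from the unbinned flags with no smoothing or blip-merging. Bout
duration distributions are compared with the two-sample Kolmogorov-Smirnov
test (exact D, asymptotic p — appropriate for the hundreds of pooled
bouts).

## Classification

Subjects are classified CON (negative) vs LS (positive) from the 8-region
ΔSUV vector, evaluated by leave-one-out cross-validation: for each held-out
subject the model is trained on the others, with the regularization
hyperparameter tuned by an inner stratified 3-fold CV on those subjects
only and features standardized on the training fold. Models: ridge
logistic regression and linear SVM (scikit-learn; C tuned over
{0.01, 0.1, 1, 10}) and Gentle AdaBoost over weighted-least-squares
regression stumps (implemented here; the stump outputs are weighted class
means, the weight update is w ← w·exp(−y f), and the training exponential
loss is provably nonincreasing). A decision score of exactly 0 predicts
the positive class. Confusion rates come from hard predictions; the ROC
and AUC are computed on the pooled held-out scores, the only n scores that
exist.

The scrambled-label control permutes the labels **for training only** and
evaluates predictions against the true labels, which is what makes a
working model behave like a random classifier (mean AUC ≈ 0.5 over seeds).
Evaluating against the permuted labels instead would show the well-known
leave-one-out anti-learning bias (mean AUC well below 0.5) and would not
measure what the control is for.

## Ordinal-trends analysis

Scans are stacked subject-major (F1 row before F3 row) over in-mask
voxels, grand-mean centered column-wise, and decomposed by SVD. Candidate
patterns are every singleton {PCk} and every prefix {PC1..PCk}, scored by
OLS of the condition design (−1/+1) on their expression scores with
AIC = n·ln(RSS/n) + 2(k+1); the lowest AIC wins, ties favoring the smaller
set, and an RSS floor at machine epsilon guards the degenerate perfect
fit. Selected components are combined with their regression weights into a
unit-norm voxel pattern, sign-fixed so the majority of subjects increase
F1 → F3.

The candidate-set size is capped at min(8, rank, max(2, n_rows/6)). With
only ~18 scans, larger sets can fit *any* ±1 design nearly perfectly,
which both corrupts the AIC comparison and destroys the power of the
permutation test (the null statistic saturates); one predictor per six
scans keeps selection honest while still letting a non-leading component
(e.g. PC3) win as a singleton.

The ordinal trend is tested by within-subject label-flip permutation: each
subject's condition pair flips with probability ½ and the full pipeline
(selection + sign fix) is re-run; p = (1 + #{perm ≥ observed})/(1 + n_perm).
Because swapping a subject's two rows leaves the column means and the SVD
component vectors unchanged, the full re-run is computed exactly by
flipping that subject's design codes against the fixed decomposition — an
algebraic identity, not an approximation. A re-scoring mode that keeps the
observed pattern fixed is also available. Voxel-weight reliability uses a
subject-level pairs bootstrap (500 draws by default): each replicate
re-runs decomposition and selection, is sign-aligned to the original
pattern, and z_v = w_v / SD_boot(w_v); voxels with |z| > 1.645 in the
direction of the original sign are flagged (normal-quantile approximation;
a percentile option is deliberately out of scope). "Nodal expression" is a
scan's projection onto the pattern, z-scored across all scans in the
evaluation set (the reference-set choice is recorded in the output); its
F1→F3 change per subject is compared between groups by pooled t test.

## Synthetic cohorts

The generator (`betapet.synthetic`) emulates the study conditions so every
stage is testable without data downloads.

* **Geometry.** Default grid 32×48×32 voxels at 0.78×0.78×0.8 mm (the
  full 128×128×159 acquisition grid is supported via config). Region
  footprints are axis-aligned per-slice boxes — geometry is irrelevant to
  the statistics under test — in disjoint dorsoventral bands; BA spans 12
  coronal slices; PLC/ILC straddle the midline.
* **Planted effects.** F3 volumes carry per-region increments over the F1
  baseline. Group-level defaults (normalized-uptake units): CON
  BA 0.15, PLC 0.12, ILC 0.11, LEC 0.059, DH −0.043, VH 0.052, SB 0.016,
  MEC 0.0086; LS BA 0.049, PLC 0.032, ILC 0.046, LEC −0.012, DH −0.028,
  VH 0.023, SB −0.0024, MEC −0.00075. Each subject's realized increments
  are the group values times a per-subject response gain ~N(1, σ_gain)
  with σ_gain = 0.3 (CON) and 1.0 (LS): CON-like subjects respond
  coherently, LS-like responses are heterogeneous enough that an
  appreciable minority move against the group trend, which is what the
  increasing-expression contrast between groups measures. Realized
  increments are recorded per subject before noise.
* **Construction.** Region voxels are set to 1 + baseline + increment and
  the background solved so the whole-brain mean is exactly 1; with all
  noise off the downstream ΔSUV therefore equals the planted increment
  exactly, record by record — the pipeline's exact-recovery oracle.
* **Noise.** Additive Gaussian at four nesting levels, drawn per
  subject × session: whole-volume intercept (σ 0.012), hemisphere
  (σ 0.008), coronal slice (σ 0.010), voxel (σ 0.050). This matches the
  nesting the mixed model assumes and is sized so that planted effects of
  the printed magnitude are recoverable at n = 9 vs 15 with realistic
  uncertainty. Real PET data differ in ways the generator does not
  emulate — spatially correlated reconstruction noise, partial-volume
  effects, registration error — so passing tests demonstrate the
  statistics, not scanner realism.
* **Behavior.** Activity traces alternate mobility/immobility runs with
  gamma-distributed durations (shape 2), initialized from the equilibrium
  distribution of the alternating renewal process so the expected
  immobile-frame fraction equals the target exactly (no edge bias).
  Targets: freezing fractions 0.10/0.10 (F1), 0.3827/0.4022 (F2),
  0.7321/0.4537 (F3) for CON/LS, with longer CON bouts at recall (mean 8 s
  vs 5 s). Immobile frames score uniformly below half the default
  threshold; mobile frames at or above it.
* **Determinism.** One global seed; per-subject streams derive from
  stable hashing of (seed, subject index, stream), so outputs are
  bit-identical across runs and independent of generation order.

A reduced single-region configuration (16×24×16 grid, one bilateral
BA-like region) supports repeated-simulation calibration studies at a few
tenths of a second per cohort; the test suite uses it to run 200-cohort
calibration and power checks within minutes. ORT detection and
calibration tests use a separate phantom of directly constructed,
already-normalized volumes with a coherent planted block covering a
majority of a small test mask: routing a large block through the
generator's whole-brain-mean construction would create genuinely
anticorrelated background signal (not false positives), confounding the
specificity check.

## Numerical and design choices

* Hemisphere tie rule: voxels exactly on the midline go right.
* The t test is Student's (pooled variance), not Welch. Zero pooled
  variance returns T = 0, p = 1 for equal means and T = ±∞, p = 0
  otherwise.
* KS p values use the asymptotic two-sample Smirnov distribution; exact
  small-sample enumeration is unnecessary at bout-sample sizes.
* Bootstrap SDs are floored at 1e-12 (warned); AIC RSS is floored at
  machine epsilon (warned).
* Random-effects structure is subject intercept only; hemisphere/slice
  random effects are left to the configurable df options rather than
  modeled.
* LOOCV problem sizes: inner 3-fold CV over 4 (penalized models) or 3
  (boosting rounds) candidates; with 24 subjects a full LOOCV takes
  roughly a second (logistic/SVM) to a few seconds (GentleBoost).
* Reported simulation sizes (200 cohorts for calibration, 500
  permutations/bootstraps for ORT, 100 seeds for the scrambled control)
  are the package's default verification scale and complete in a few
  minutes on one core.

## Known limitations

* The mixed model's F reference distribution with the between-subject df
  is exact only for balanced designs; unbalanced nesting is handled by
  the GLS weighting but the df choice is then conservative.
* The ORT variant here fixes concrete choices (grand-mean centering,
  singleton+prefix candidates, count-of-increasing trend statistic,
  full-pipeline permutation) where the literature leaves latitude; all
  choices are stamped into results metadata so deviations are traceable.
* Pooled-score LOOCV ROC curves at n ≈ 24 are coarse (one score per
  subject) and degenerate for information-free constant features, where
  the intercept tracks the training-fold class prior.
* The synthetic generator's noise is spatially white within nesting
  levels; it cannot validate smoothing-dependent or cluster-level
  inference.
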