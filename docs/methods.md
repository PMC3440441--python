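# Methods

`coldheat` implements the two multivariate analyses used to discriminate the
Cold and Heat subtypes of rheumatoid arthritis patients — forced-classification
nonlinear PCA for questionnaire + clinical chemistry data, and double
cross-validated PLS-DA for urine/plasma LC-MS feature tables — together with
the preprocessing rules, the permutation-based validation, the metabolite
reporting layer, and a seeded synthetic-cohort generator that stands in for
patient data which were never deposited.

## Optimal-scaling nonlinear PCA

### Model

Given n subjects and m categorical variables (codes `1..k_j`), each variable
receives category quantifications `y_j` so that the quantified variable
`q_j = y_j[code]` (normalized to mean 0, sum of squares n) is maximally
explained by p principal components. With object scores `X` (n×p, columns
mean 0, `X'X = nI`) and loadings `a_j = X'q_j / n`, the per-variable VAF is
`‖a_j‖²` and the total VAF is the weight-averaged VAF. The alternating
least squares loop is:

1. object scores: `X ← orthonormalize(Σ_j w_j q_j a_j')` (polar/SVD
   orthonormalization after column centering);
2. loadings: `a_j = X'q_j / n`;
3. quantifications: the unconstrained update is the vector of category means
   of the rank-1 target `X a_j`; it is then projected onto the variable's
   analysis level and renormalized.

Every sweep weakly increases the total VAF; the fit asserts this invariant on
each iteration and stops when the gain drops below `tol` (default 1e-8,
maximum 500 iterations).

### Analysis levels

* **nominal** — free quantifications (the category means themselves);
* **ordinal** — monotone nondecreasing, via weighted pool-adjacent-violators
  with category frequencies as weights (pooled blocks carry weighted means;
  ties resolve deterministically through the left-to-right pooling order);
* **spline-nominal** — weighted least-squares projection onto a clamped
  B-spline basis of the requested degree (default 2) with interior knots
  (default 2) at frequency-weighted quantiles of the category distribution;
  rank `degree + knots + 1`.  When a variable has too few categories for the
  requested knots, the knot count is reduced and logged;
* **spline-ordinal** — monotone splines: right-tail cumulative sums of the
  B-spline partition of unity form an I-spline basis whose nonnegative
  combinations (plus a free intercept, profiled out) are nondecreasing;
  coefficients by NNLS;
* **numeric** — quantifications fixed at the standardized category codes; at
  this level the model reproduces classical PCA on standardized data (the
  equivalence is tested to 1e-8 against the top eigenvalue fraction).

The feasible sets nest (numeric ⊂ spline-ordinal ⊂ spline-nominal ⊂ nominal,
and 1-knot ⊂ 2-knot splines), so the achievable VAF is ordered accordingly;
the test suite asserts these inequalities.

### Forced classification

The binary subtype label enters as a nominal variable with weight 1000 while
every other variable has weight 1. One component then suffices: the huge
weight pins the component to the class contrast and the object scores
separate into two subclouds. The fit asserts *complete* separation of the
two classes' score intervals; if they overlap the class weight is doubled
(up to 1e6) and the model refit — if still unseparated the model is returned
flagged. The component sign is fixed so the Heat-coded class has positive
scores; negative quantifications therefore point toward Cold. Because the
weighted-mean VAF is ≈1 by construction under a weight of 1000, reports
quote the *substantive* VAF — the weighted mean over the non-class
variables.

### Prediction of held-out subjects

The source protocol predicts left-out subjects from the fitted model without
stating a rule, so one is defined here: a new subject's transformed values
are looked up from the trained quantifications (unseen ordinal/spline
categories interpolate linearly between neighbouring trained categories,
clamping at the ends; unseen nominal categories take the modal category's
quantification), the object score is the weighted least-squares estimate
over the non-class variables, `x̂ = Σ' w_j a_j q_j / Σ' w_j a_j²`, and the
predicted label is the class whose trained mean score is nearer, with exact
ties broken toward the Cold-coded class. Subjects missing more than half
the model variables are refused.

### Protocol

The full questionnaire/clinical protocol is: (1) optionally compare analysis
levels for the clinical variables via the total VAF of forced-classification
fits and attribute level-to-level gains to the variable with the largest
per-variable VAF difference; (2) select variables with VAF strictly above
0.20 (class variable always retained); (3) refit on the selection;
(4) leave-two-out cross-validation — disjoint stratified pairs, one subject
per class where possible, leftovers pairing within the larger class and an
odd last subject forming a singleton fold, so 39 subjects give 19 pairs plus
a singleton and 37 training subjects per fold; per fold the model is
refitted and the held-out pair predicted; (5) permutation testing —
labels permuted without replacement *before* selection (the conservative
ordering), the whole protocol re-run, and
`p = (1 + #{null ≤ observed}) / (n_permutations + 1)`.

Selection is performed once on the full data before cross-validation,
reproducing the published protocol even though it is optimistically biased;
a selection-inside-CV mode (`vaf_threshold=` in `leave_two_out_cv`) re-runs
selection inside every training fold for an unbiased estimate.

## PLS-DA with double cross-validation

The class coding is −1 (Cold) / +1 (Heat); prediction is the sign of the PLS
prediction, with exactly 0 assigned to Cold. The core is a deterministic
NIPALS PLS1 producing orthogonal score vectors and regression vectors
`b_a = W_a (P_a'W_a)^{-1} q_a` for every truncation `a = 1..A`; at
`A = rank(X)` the coefficients equal least squares (tested to 1e-8).

**Double CV.** Outer loop: stratified leave-two-out pairs (the detailed
description of the source protocol; a `n_folds` override gives true k-fold).
Per outer fold, an inner leave-two-out CV on the training remainder picks
the component count minimizing inner misclassification, ties toward fewer
components; the outer model is refit at that count and predicts the held-out
pair. Scaling (`center` for urine, `autoscale` for plasma) can be
recomputed inside every training fold to avoid information leak; the
pipelines scale once globally by default, matching the published procedure,
and the fold-wise mode is a flag.

**Jack-knife selection.** Regression vectors are collected across the outer
training folds; each feature's coefficient standard error is its standard
deviation over folds. Elimination is driven by the relative standard error
`SE/|mean b|`: a noise feature's coefficient is indistinguishable from zero
(relative SE large) while a discriminating feature's coefficient is stable.
(Thresholding the raw SE instead removes the informative features first —
large coefficients also have large absolute spread — and demonstrably
destroys recovery of planted features.) The threshold schedule walks
descending quantiles 1.0, 0.95, …, 0.5 of the relative-SE distribution,
re-running the double CV at each step; the full trace (threshold, retained
count, error) is recorded, the step where the error first starts increasing
is noted, and the selected step is the first error minimum. The final model
is refit on all samples with the selected features.

**Permutation test.** Labels are shuffled (class sizes preserved) and the
double CV re-run 250 times by default; the model is significant at the 95%
criterion when the observed error lies below the 5th percentile of the null
errors, and the p-value carries the +1 correction. Under the null the
cross-validated error centers on 50% for balanced classes; the suite checks
this and the approximate uniformity of null p-values.

## Preprocessing rules

* **Category merging** (categorical data, threshold 7 observations):
  ordinal variables merge a sparse category into the nearer adjacent
  observed category (code distance, ties toward the lower code), sparsest
  first; nominal variables pool sparse categories into one "other" category
  (folded into the smallest regular category if still sparse). Codes are
  re-indexed consecutively. Variables left with a single category are
  removed and listed. Merge→drop is idempotent.
* **Clinical binning**: equal-width binning into 19 categories over the
  observed range, half-open interior edges (a value on an edge goes right),
  closed rightmost bin, constant input → one bin. Rank order is preserved.
* **Presence filter** (80%): a feature is kept iff its nonzero fraction
  reaches the threshold in at least one class (QC samples excluded); an
  "all classes" mode is available behind a flag.
* **Zero replacement**: zeros are non-detects and become half the smallest
  nonzero value *of that feature* (a global-minimum convention would tie the
  imputed value to an unrelated feature's scale); after the presence filter
  this leaves no zeros.
* **Scaling**: urine mean-centered, plasma autoscaled; parameters computed
  on study samples and applied to QC samples; zero-variance features under
  autoscaling are dropped with a warning.
* **QC screen**: PCA on the scaled table; outliers are samples more than 4
  MADs (normal-consistent) from the median on PC1 or PC2 — a robust rule of
  this package's own choosing; stability is the QC/study score-dispersion
  ratio on PC1–2 (requires ≥3 QC samples, otherwise marked not assessable);
  the injection-order trend is the Spearman correlation of PC1 scores with
  injection order.

## Metabolite tools

* `log2_ratio`: base-2 log of the Cold/Heat ratio of arithmetic class means
  (geometric means behind a flag), antisymmetric under class swap.
* `flag_acylcarnitines`: a feature is acylcarnitine-like when some
  precursor−fragment difference is within 0.005 Da of the diagnostic 59.0747
  Da neutral loss; over the flagged set, retention time should increase with
  precursor mass (longer acyl chains are less polar), checked by Spearman
  correlation.
* `symptom_positive_summary`: a score above 1 on a 1–7 scale counts as
  positive; per class the table reports the percentage of subjects with
  exactly 0, ≥1, ≥2 and exactly-all positive symptoms (the "0" row is
  *exactly zero*, so it complements the ≥1 row to 100%), plus a tie-corrected
  two-sided Mann-Whitney U per symptom.
* `ttest_from_summary`: pooled-variance two-sample Student t-test from
  published mean ± sd and n.

## Synthetic cohorts

The generator emulates the study design: 20 Cold / 19 Heat subjects, 57
questionnaire items (15 constant, 8 with a sparse category, 10 informative),
40 clinical variables (4 monotone-informative, 2 quadratic), urine and
plasma feature tables with pooled-QC replicates. Specifics:

* **Questionnaire**: proportional-odds generation — a logistic latent
  variable with a per-item class shift (±2 on the latent scale for
  informative items) cut at fixed symmetric thresholds into categories 1–7.
  Designated non-sparse items have sparse realized categories collapsed so
  the constant/sparse column counts are exact by construction.
* **Clinical**: monotone variables shift class means by 1.5 sd; quadratic
  variables put the Heat class at ±2 (sd 0.5) and Cold at 0 (sd 0.5) — the
  "high as well as low" two-tailed pattern that motivates the nonmonotone
  spline level; the rest is standard normal noise.
* **LC-MS**: per-feature log2 base intensity uniform in [10, 20], within-class
  log2 sd 0.8; informative features are multiplied by `2^effect` in the Cold
  class so the empirical 2log Cold/Heat ratio of class means converges to
  the planted effect (default effects are the fifteen published urine values,
  −2.40…+0.42). Zeros are left-censoring below a detection limit placed at
  the `missing_rate` quantile of intensity (default 10%). QC samples are the
  cohort mean profile times `exp2(N(0, 0.05))` noise, scaled by
  `1 + drift_slope·injection_index` (default slope 0.004/injection); QC
  injection frequency and batch layout are free parameters since no layout
  is prescribed. An acylcarnitine-like family of up to 13 positive-mode
  urine features stores a fragment at exactly precursor − 59.0747 Da with
  retention time strictly increasing with mass.
* A single global seed fans out to per-table child seeds
  (`SeedSequence([seed, stream])`) so each table regenerates independently.

What the generator does **not** emulate: correlated feature blocks
(metabolites from shared pathways), isotope peaks and adducts beyond the one
stored fragment, retention-time drift within study samples, batch structure,
heavy-tailed intensity noise, and item–item correlation beyond the shared
class effect. Passing recovery/calibration tests therefore demonstrate the
correctness and calibration of the algorithms under the assumed model, not
performance on real cohorts; the published error rates (15% questionnaire
CV error, 14%/28% urine/plasma) are not reproducible because the patient
data were never deposited, and are not asserted anywhere.

## Numerical choices and degenerate inputs

* ALS initialization: seeded standard-normal object scores, orthonormalized;
  convergence when the total-VAF gain < 1e-8 or at 500 sweeps.
* A quantification update that collapses to a constant (normalization
  undefined) keeps the previous quantification for that sweep.
* Spline knots sit at frequency-weighted category quantiles, clipped
  strictly inside the range; knot counts reduce automatically when a
  variable has too few categories.
* PLS components are capped at `min(n−1, m)`; a fold whose training split
  loses a class is rebalanced with a logged note; a response explained
  exactly mid-extraction freezes the remaining components.
* Ties: PAVA pooling is deterministic left-to-right; inner-CV component
  choice prefers fewer components; jack-knife step choice takes the first
  error minimum; classification at exactly 0 (PLS) or equidistant scores
  (NLPCA) goes to Cold.
* Problem sizes in the test suite are chosen so the whole default run takes
  a few minutes on one core: calibration uses 60 null runs × 40
  permutations, jack-knife recovery 20 seeds, and the end-to-end run 1000
  urine features with 250 permutations.

## Known limitations

* Single-component (and generally p-component "single" rank-1) solutions
  only; no rotation, no missing-data imputation at fit time, no bootstrap
  confidence regions.
* The object-score normalization is variable-principal-like; packages that
  normalize on objects or symmetrically will print different loadings for
  the same data, so published loading tables are comparable only up to that
  convention.
* Leave-two-out composition (one subject per class) and the prediction rule
  are this package's own definitions where the source protocol is silent.
* The permutation test permutes labels before variable selection; permuting
  after selection would be anti-conservative.
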