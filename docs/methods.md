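# Methods

## Cohort representation and eligibility

A cohort is a long-format table, one row per subject-visit: visit month
(baseline = month 0, required), MMSE in [0, 30] (lower = worse), ADAS-13
in [0, 85] (higher = worse), an optional 78-region mean
cortical-thickness vector (mm, AAL-style ordering), and per-subject age,
sex, APOE4 allele count (0/1/2), diagnosis and source-cohort tag. Sex and
diagnosis are carried for reporting only and never enter a model. Missing
values are empty CSV cells, never sentinel numbers, so range checks stay
meaningful; partially missing thickness vectors are rejected rather than
silently accepted.

Eligibility for trajectory labeling requires at least three visits with a
score on the working scale spanning **strictly more than 12 months**; a
span of exactly 12 months is excluded. Both bounds are parameters
(`min_visits`, `min_span_months`) for protocols with different windows.
Whether a visit counts toward eligibility depends only on the score being
present; thickness availability is handled separately by follow-up
selection.

## Trajectory modeling

Complete cases (a score at every month of the visit grid) are clustered
by agglomerative clustering with **Ward's linkage on Euclidean distance**
between the score vectors (`scipy.cluster.hierarchy`), with the
dendrogram cut at *k* clusters. *k* is a design choice, not estimated
from data: the defaults are k = 2 for MMSE and k = 3 for ADAS-13, whose
larger dynamic range supports splitting decline into slow and fast
courses. Per-cluster means at each grid month form the template.

Classes are reordered canonically by final-month severity (least severe
first), which makes the `stable`/`decline` naming reproducible across
runs regardless of the arbitrary cluster numbering.

Assignment computes, for each class, the **unnormalized Euclidean
distance** between the subject's scores at its available grid months and
the template row restricted to those months; the label is the argmin.
Distances are not divided by the number of months: the comparison is
within-subject across classes, so the month count cancels. Ties break
toward the less severe class — deterministic and prognostically
conservative. Visits up to ±3 months off the grid snap to the nearest
grid month (scheduled-visit windows); farther off-grid visits are ignored
for assignment. Subjects used in clustering are re-assigned by proximity
like everyone else (uniform rule); with separation comfortably above the
within-cluster spread this reproduces their cluster labels, which the
tests assert on synthetic data.

## Longitudinal Siamese Network

Architecture (sizes searchable in the indicated ranges):

| module | structure |
|---|---|
| Siamese branch (shared) | 78 → 4 hidden ReLU layers of width 25–50 → linear embedding of 10–20 |
| distance embedding | e = b(x₁) − b(x₀) |
| multiplicative modulation | scalar gate g = σ(w·APOE4 + c), output g·e |
| head | [g·e ‖ score₀ ‖ score₁ ‖ age] → one hidden ReLU layer of 10–20 → softmax |

Defaults: branch width 35, embedding 15, head 15.

Design choices where the architecture description leaves room:

* **Signed difference, not absolute.** The embedding keeps the direction
  of change (thinning vs thickening), and antisymmetry
  e(x, y) = −e(y, x) holds by construction, giving a free structural
  test. Identical scans map to the zero vector exactly because one stored
  parameter set serves both branches.
* **Gate input is APOE4 alone.** The modulation module has a single node;
  a scalar logistic gate on the allele count multiplying the embedding
  elementwise is the minimal multiplicative interaction. The alternative
  (embedding concatenated into the gate input) is noted but not
  implemented. APOE4 enters as the raw ordinal count 0/1/2.
* **Standardization inside the model.** Thickness, scores and age are
  z-scored with training-set statistics stored in the parameter object.
  Thickness statistics are pooled per ROI **across both timepoints** so
  the shared branch sees both visits on one scale and the difference
  retains its meaning as change. Millimetre/score/year raw scales would
  otherwise destabilize training.
* **Training.** Joint minimization of cross-entropy with Adam
  (rate 1e-3, batch 32), early stopping on a stratified validation split
  (fraction 0.15, patience 20), binary tasks as 2-class softmax for code
  uniformity. Implemented in numpy with explicit backpropagation; the
  shared branch accumulates +∂e through the follow-up pass and −∂e
  through the baseline pass into the single parameter set.
* **Regularization.** Decoupled L2 weight decay (1e-3, weight matrices
  only) and inverted dropout 0.5 on the modulated embedding during
  training. Without these, the high-capacity branch memorizes
  measurement noise in the 2×78 thickness stream within a few epochs
  whenever the clinical scores carry most of the class signal, and early
  stopping alone recovers a mediocre compromise; with them the model
  matches clinical-only baselines when thickness is uninformative while
  keeping full sensitivity to planted structural change.
* **Seeding.** One config seed drives parameter init, the validation
  split, batch order and dropout masks through separate spawned streams;
  training is bit-deterministic given data and seed.

Follow-up selection: the model is agnostic to the exact interval, so the
second timepoint is the **latest visit within 12 months of baseline**
having both a score and a thickness vector; subjects lacking one are
excluded from two-timepoint analyses and reported with reasons. Missing
APOE4 is out of scope.

## Reference models and features

Feature design: {baseline, baseline+follow-up} × {CA, CT, CA+CT}, where
CA = score(s) + age + APOE4 and CT = 78 or 156 thickness values,
concatenated in the fixed order [scores, age, apoe4, ct₀, ct₁] (vector
lengths 3/4/78/156/81/160). Baselines: lasso logistic regression
(saga solver), SVM (RBF and linear kernels in the grid; ranking scores
from the decision function, which suffices for AUC/ROC without a
calibration layer), random forest, and a default feed-forward network
(scikit-learn's MLP). LR and SVM inputs are z-scored with training-fold
statistics; the forest is scale-invariant and left raw; the MLP also
receives z-scored input for trainability — a documented deviation from
the scale-sensitive-models-only rule. Hyperparameter grids (LR penalty
1e-3…1e2; SVM C 1e-2…1e2; forest 100/500 trees, depth ∅/5/10; MLP one or
two hidden layers of 25/50) are selected by mean inner-fold accuracy,
ties toward the smaller model; a reduced single-point grid is provided
for smoke runs.

## Evaluation harness

Outer k-fold (default 10) stratified jointly on source-cohort tag ×
class; inner folds (default 5) nested inside each outer training set with
the same stratification. Metrics: accuracy; AUC (binary = probability a
random positive outscores a random negative, ties half; 3-class =
macro one-vs-rest, an extension beyond accuracy-only three-way
reporting); confusion matrices (rows = true classes, pooled across folds
by summation); ROC points. Single-class truths yield a missing AUC, not
zero. Model contrasts use the two-sided Mann-Whitney U over per-fold
samples (exact null for n ≤ 10 per side without ties, otherwise normal
approximation with tie correction); both accuracy and AUC samples are
exposed.

Subject-group stratifications:

* **BE / FE / CC** clinical-workflow groups: baseline edge-cases
  (baseline score outside [low, high]), follow-up edge-cases (marked
  short-term change ≥ cutoff), cognitively consistent (the rest). The
  shipped cutoffs (MMSE 24/29, change 2; ADAS-13 10/30, change 4) are
  illustrative placeholders — the stratification demonstrates a clinical
  use case and any deployment must choose its own values.
* **Near/distant future** by the last visit used for the ground-truth
  label: ≤ 36 months vs ≥ 48 months; subjects in the 36–48 gap are
  flagged rather than forced into a band, since the two bands as defined
  are not exhaustive.

A replication-style mode (train folds on cohort A, test the 10 fold
models on cohort B, average) is supported by the cohort tag plus the
stored fold models' predictions; an 18-month-grid MMSE-only preset
emulates the replication cohort's design.

## Synthetic cohorts

The generator emulates the structure of an ADNI-like study: the
nine-visit grid {0, 6, 12, 18, 24, 36, 48, 60, 72} months; per class a
parametric mean score curve (linear, or logistic decline with start/end
level, midpoint and steepness) plus i.i.d. Gaussian noise clamped to the
scale range; per-ROI baseline thickness ~ Normal(2.5 mm, 0.25 mm)
truncated positive, declining linearly at a class-specific annual rate in
a signature ROI set (background rate elsewhere) with Gaussian measurement
noise, floored at 0.1 mm; APOE4 drawn from class-conditional mixtures
skewed toward carriers among decliners (stable ≈ 0.65/0.29/0.06,
decline ≈ 0.37/0.45/0.18); age ~ Normal per class; non-baseline visits
dropped independently (baseline always kept) and thickness vectors
additionally dropped at a second rate. Everything is deterministic given
the config seed.

Default magnitudes are chosen at clinically plausible values — MMSE
noise ≈ 1 point (test–retest scale), decliners losing ~13 points over six
years along a sigmoid, signature atrophy of a few hundredths of mm/year
against 0.05 mm measurement noise — but no quantitative atrophy or noise
figures are claimed from data; they are testing conditions, not
biological estimates. The generator reproduces qualitative structure
only: no score covariances, no scanner effects, no informative
missingness (dropout is independent of severity, unlike real attrition).
Passing tests therefore certify the machinery — recovery of planted
structure, correct accounting, absence of leakage — not clinical
performance on real cohorts.

Two special mixes isolate modalities for attribution tests:
`ct_signal_only_spec` (identical score/age/APOE4 distributions, classes
differ only in signature atrophy rate, default 0.15 mm/yr vs 0 against
0.05 mm noise — three times the per-measurement noise over a 12-month
interval) and `score_signal_only_spec` (identical thickness dynamics,
classes offset by 4 MMSE points).

## Numerical choices and degenerate inputs

Ward clustering is deterministic for fixed input; continuous synthetic
scores make ties measure-zero. Zero-variance feature columns standardize
to 0 with a warning. Proportions must sum to 1 within 1e-9. Non-finite
training loss raises with diagnostics rather than returning a broken
model. Model files are JSON with base64 little-endian float64 blocks, so
saved models reload bit-exactly. Report JSON is sorted-key serialized,
making end-to-end bit-reproducibility a string comparison.

## Problem sizes

The test suite and the acceptance script run the pipeline at reduced but
non-trivial sizes chosen to exercise every code path with stable
statistics: 69-subject complete-case clustering cohorts (mirroring the
size regime of a single-study complete-case sample), 600 subjects for
modality-attribution cross-validation, 200 subjects × 10 permutation
seeds for null calibration, and a 120-subject five-model smoke pipeline
run twice for bit-identity.

## Known limitations

* The LSN requires both timepoints complete (thickness, score, APOE4);
  it does not handle missing modalities.
* When thickness is pure noise and the cohort is small, the jointly
  trained branch can still cost a few AUC points relative to a
  clinical-only linear model despite regularization; at the zero-change
  limit (identical scans) the embedding vanishes structurally and the
  model reduces to its clinical stream.
* Feature importance over ROIs is not provided; hierarchical weight
  sharing makes per-region attribution non-identifiable.
* No growth-mixture or latent-class alternatives to the clustering; no
  automatic selection of k.
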