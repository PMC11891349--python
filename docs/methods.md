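# Methods

## Conformal machinery

**P-values.** All inductive p-values use the non-smoothed, (+1)-corrected
rank `p = (#{αᵢ ≥ α_test} + 1)/(n_cal + 1)` with ties counted as ≥; the
value lies in `[1/(n_cal+1), 1]` and is super-uniform for the true
label under exchangeability. Determinism was preferred over smoothed
(randomised-tie) p-values so that identical configs reproduce
byte-identical outputs; smoothing would only matter for heavily tied
score distributions.

**Transductive prediction** retrains the adapter once per candidate
label on the training set augmented with the new instance and ranks
the instance's score among all `n+1` scores of the retrained model —
the augmented instance counts itself, so the denominator is `n+1` with
no further correction. The API takes a `confidence` in (0,1) and
derives the significance level `ε = 1 − confidence` everywhere;
"confidence 0.95" always means a target error rate of 5%.

**Regions and flags.** `region = {y : p(y) > ε}`. Exactly-one-label
regions are *singletons*; everything else — including the empty set —
is *uncertain* (UNC). Empty regions therefore count toward both the
error rate and the UNC rate; this double-counting is intentional
(an empty region is both a miss and a flag for expert review) and all
conservation identities in `CoverageReport` hold under it.

**Regression intervals** use the absolute residual on a calibration
split; the half-width is the `k = ⌈(n_cal+1)·confidence⌉`-th smallest
residual, shared by every test sample. When `k > n_cal` the requested
confidence is not supportable by the calibration size and the interval
is returned as unbounded (±∞ sentinels) rather than clamped to the
largest residual — clamping would silently void the coverage
guarantee.

**Mondrian (label-conditional) classification** ranks a candidate
label's score only against calibration scores of that true label,
giving per-class validity under label shift at the cost of requiring
every class in the calibration set (an explicit error otherwise).
Label order is everywhere the lexicographic order of category names.

## Non-conformity measures

`inverse_probability` and `hinge` are both `1 − p̂(y|x)`; they are kept
as distinct names because the conformal literature distinguishes them,
but no numerical difference exists in this implementation.
`class_mean_distance` (Euclidean distance to the candidate class
centroid, paired with the nearest-centroid adapter) is exact and
enumerable, which makes transductive prediction on small cohorts
auditable by hand. `absolute_error` serves regression.

A practical finding that shaped the test design: **how the UNC rate
responds to covariate shift depends on the measure.** Distance-based
scores grow for *every* candidate label as points move off the
training support, so prediction regions empty out and the UNC rate
rises monotonically with shift magnitude (variance inflation of the
features is the cleanest such shift). Softmax/margin-based scores can
do the opposite — a point far from the decision boundary receives a
*more* confident probability, so variance inflation can lower the UNC
rate of a gradient-boosted or logistic model even as its coverage
degrades. A mean shift that moves points across decision boundaries
does inflate hinge-based uncertainty. The shift-behaviour suite uses
the distance measure with a variance-inflation grid (monotone per
seed); the pipeline-level check uses a mean shift with the hinge
measure.

## Synthetic cohorts

The generator draws class-conditional Gaussians with equal spherical
covariance: non-informative features are standard normal; the first
`n_informative` features get class centroids built from ±1 sign
patterns scaled by `separation·noise_sd/√n_informative`, so two
generic classes sit ≈ `separation·√2` within-class SDs apart. Sign
patterns are redrawn until every informative feature separates at
least one class pair (otherwise a feature could be nominally
informative but carry no signal) and until all classes are pairwise
distinct. An `overlap_pair` places its second class at
`0.7·separation` from the first — at the default 3-SD separation the
pair is 2.1 SD apart, a visible partial overlap that produces a
base-model error near 16% and an UNC rate near 36% at 95% confidence,
the regime the package's multiclass demonstration targets.

`structure_seed` decouples the centroid draw from the sampling draw:
two specs sharing a `structure_seed` are *sibling cohorts* — fresh
samples from the same class-conditional distributions — which is what
an external validation series from the same population means. Without
this, cohorts at different seeds differ in class structure and any
cross-cohort evaluation measures cohort mismatch, not covariate shift.

Regression responses are `Σ(informative features) + N(0, noise_sd²)`,
exponentiated when `response_skew` is set. The default drug-response
cohort uses 4 informative features and `noise_sd = 0.5`, giving a
log-response SD ≈ 2 and a response spanning roughly 0.003–900 across
765 draws — five orders of magnitude, like IC50 concentrations. The
base random forest predicts the raw (not log) response and is
accordingly weak in the heavy right tail (R² ≈ 0.3–0.4 at this scale);
this is deliberate: the demonstration's point is that the conformal
interval keeps its coverage regardless of the base model's quality,
with wide intervals honestly reflecting that weakness.

What the generator does **not** model: probe-level microarray
artifacts, normalisation or batch structure, gene–gene correlation
beyond the shared class centroids, and label noise. Passing tests
therefore certify the conformal machinery's distribution-free
properties and the pipelines' plumbing, not performance on real microarray or
drug-screen data.

## Default study conditions

* Binary TCP: 78 samples (39/39 at the default seed), 200 features
  (20 informative), MRMR top 30, 80/20 stratified split, SVM with
  sigmoid-calibrated probabilities tuned over a small grid
  (C ∈ {0.1, 1, 10} × {linear, rbf}) by seeded 5-fold CV on the
  training split only.
* Multiclass ICP: 1,032 samples in proportions 345/517/170 with the
  first two classes overlapping, 200 features (20 informative), MRMR
  top 20, 60/20/20 stratified split, XGBoost (50 trees, depth 3,
  hist), hinge non-conformity; external sibling of 789 samples with
  half the features translated by 0.5 SD — a shift the MMD permutation
  test (B = 199) detects while coverage stays roughly nominal.
  Samples labelled `UNC` are excluded from training/calibration and
  tabulated separately.
* Regression ICP: 765 cell lines, 100 features (4 informative), log-IQR
  outlier fencing (3×IQR on the log response), MRMR top 10, 60/20/20
  split, random forest (100 trees), absolute-error measure, confidence
  levels 0.85/0.90/0.95.

Feature counts are scaled down from probe-level arrays (tens of
thousands) to a few hundred; the conformal guarantees are
dimension-free and the pipelines' behaviour is unchanged, while the
whole analysis remains desk-sized. Validity suites use a multinomial
logistic learner where the learner is not the object under test.

## Numerical and design choices

* MRMR is the greedy difference variant (MRMR-D): relevance is the
  ANOVA F-statistic (categorical outcome) or |Pearson r| (continuous),
  redundancy the mean |Pearson r| against already-selected features.
  The two relevance scales differ (F is unbounded); no rescaling is
  applied, matching the common FCD formulation. Constant features get
  zero relevance and zero redundancy contribution. Ties break toward
  the lower feature index.
* The outlier fence (3×IQR on the log response) is a documented
  stand-in for unspecified preprocessing; on a clean log-normal
  response it removes nothing, and it is idempotent whenever the
  surviving fences contain all survivors.
* Splits use per-class largest-remainder allocation, so stratified
  parts preserve class proportions within ±1 sample; a zero fraction
  yields an empty part (transductive mode has no calibration set).
* MMD uses the biased V-statistic (non-negative by construction) with
  a Gaussian kernel and the pooled median-heuristic bandwidth computed
  once — the pooled bandwidth is permutation-invariant, so holding it
  fixed keeps the permutation test exact. The p-value
  `(1 + #{perm ≥ obs})/(B + 1)` never falls below `1/(B+1)`.
* The exchangeability diagnostic is the median MMD permutation p-value
  over random half-splits of one cohort — a reuse of the same kernel
  machinery rather than a second test family. It is a diagnostic, not
  a calibrated test: a small median is evidence against
  exchangeability; a large one is not proof of it.
* Grid search is restricted to the training split (seeded 5-fold
  stratified CV); calibration and test data never influence model or
  hyperparameter choice, and train/calibration overlap raises an
  explicit leakage error.

## Known limitations

* Marginal, not conditional, coverage: guarantees hold on average over
  exchangeable draws, not per subgroup; SSC and repeated-split
  coverage are diagnostics, not certificates.
* Under covariate shift the coverage guarantee is void; the MMD audit
  detects the shift but the package deliberately does not implement
  likelihood-ratio-weighted CP to correct for it.
* Split-conformal coverage fluctuates around its target with the
  Beta(n_cal+1−⌊ε(n_cal+1)⌋, ⌊ε(n_cal+1)⌋) law; with a 200-sample
  calibration set the per-split coverage SD at 90% confidence is ≈ 2
  percentage points, which any single-split reading should keep in
  mind.
* The regression interval is symmetric with a single global
  half-width; it does not adapt its width per sample (no Mondrian or
  normalised conformal regression).
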