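# cpgen — conformal prediction pipelines for genomic medicine

Predictive models in genomic medicine — who responds to a drug, which
molecular subtype a lymphoma belongs to, how resistant a cell line is
to a compound — make point predictions whose errors can carry clinical
cost. `cpgen` wraps such models in **conformal prediction (CP)**:
instead of a single label or number, each patient receives a
*prediction region* (a set of labels) or a *prediction interval* that
contains the truth with a user-chosen probability, under no assumption
beyond exchangeability. Cases where the region is not a single label
are flagged **UNC** (uncertain) and routed to an expert instead of
being decided by the model.

The package is organised as an analysis project: the library under
`src/cpgen/` implements every step, the numbered scripts under
`analysis/` run the three study designs end to end on synthetic
cohorts whose statistical structure mimics clinical expression data
(a small binary responder cohort; a three-subtype cohort with two
overlapping subtypes and a covariate-shifted external sibling; a
cell-line cohort with an IC50-like, five-orders-of-magnitude response).

## The statistics in brief

Given training data {(xᵢ, yᵢ)} and a fitted model, a **non-conformity
score** α measures how strange an instance is: `1 − p̂(y|x)` (inverse
probability / hinge) for classifiers, `|y − ŷ|` for regressors, or the
distance to the candidate class centroid. For a new instance and
candidate label y, the **conformal p-value** is the corrected rank

    p(y) = (#{αᵢ ≥ α_new} + 1) / (n + 1),

and the region at confidence 1 − ε keeps every label with p(y) > ε.
Two schemes are implemented:

* **TCP** (transductive): the model is retrained once per candidate
  label on the data augmented with the new instance — exact, suited to
  small cohorts, no calibration split needed.
* **ICP** (inductive): one fit on a training split; a held-out
  calibration split supplies the reference scores. The **Mondrian**
  label-conditional variant ranks each candidate label only against
  calibration samples of that label, restoring per-class validity
  under label shift.

For regression, the interval is `ŷ ± q` where `q` is the
`⌈(n_cal+1)·(1−ε)⌉`-th smallest calibration residual. Cohort-level
shift is audited with the **maximum mean discrepancy** (Gaussian
kernel, median-heuristic bandwidth, permutation p-value); features are
selected by greedy **MRMR** (F-statistic or correlation relevance
minus mean absolute correlation redundancy).

## Worked example

```sh
python analysis/01_simulate_cohorts.py --seed 0
python analysis/03_multiclass_icp_shift.py --seed 0
```

prints, for the 1,032-sample three-subtype cohort (60/20/20
train/calibration/test, XGBoost + hinge non-conformity, 95%
confidence) and its 789-sample external sibling with half the features
translated by 0.5 SD:

```
[internal]
n_test:             206
empirical coverage: 99.03%
error rate:         0.97%
UNC rate:           36.41%
error detection:    90.00%
[external]
n_test:             789
empirical coverage: 95.69%
error rate:         4.31%
UNC rate:           41.57%
error detection:    78.57%
MMD shift audit: statistic=0.0437205, p=0.005 (B=199, bandwidth=6.85)
```

Reading: on held-out internal data the conformal layer covers the true
subtype in 99% of cases and flags 36% as uncertain — including 90% of
the samples the bare XGBoost misclassifies. On the shifted external
cohort the MMD test rejects "same distribution" (p = 0.005); coverage
is nonetheless roughly preserved (95.7%) at the cost of a higher UNC
rate (41.6%), and most uncertain regions are the {C0,C1} pair — the
two overlapping subtypes. `analysis/02_binary_tcp.py` and
`analysis/04_regression_icp.py` run the transductive binary and the
regression-interval designs the same way.

A `cpgen` command line mirrors the scripts
(`cpgen simulate | binary-tcp | multiclass-icp | regression-icp | mmd | evaluate`);
every run writes a config echo, a prediction table (TSV), a coverage
report (JSON) and a log, and reruns with the same config and seed are
byte-identical.

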