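# Methods

This note documents the models and procedures implemented in `rdpredict`,
the assumptions behind them, the parameters that matter, and the places
where the design was genuinely open and a choice had to be made.

## The prediction task

At a *decision point* — a consultation date on which a patient's eGFR is
measured — the model predicts whether a *rapid-decline (RD) indication*
will occur within the following year (the *event window*, 365 days), using
only laboratory data from the preceding 54 weeks (the *input window*,
378 days). The two horizons are deliberately different: the input window is
kept at exactly 54 weeks so it tiles into 27 two-week bins, while "one
year" elsewhere is 365 days. Multiple decision points per patient are kept;
prediction stops at the first RD indication.

## RD labeling

RD at test date *t* means: smoothed eGFR ŝ(t) < 60 mL/min/1.73 m², and
ŝ(t − 365 d) − ŝ(t) ≥ 5 mL/min/1.73 m². Smoothing uses LOWESS (tricube
local linear regression) with span `lowess_fraction` (default 0.5) and
`lowess_iterations` robustifying passes (default 3), evaluated at the
observed dates. The one-year-back reference is linear interpolation of the
smoothed curve between the bracketing observed dates; nearest-measurement
alternatives were rejected because they reintroduce the visit-timing bias
the smoothing exists to remove. Dates with no observation at or before
t − 365 d are classified `insufficient_lookback` and are never RD. No
minimum number of eGFR tests is required; series with fewer than 3 points
bypass smoothing (the local fit is degenerate) and the criterion applies to
raw values.

Numerical notes:

- The span is clamped to at least 2/n so every local window supports a
  linear fit.
- Robustifying iterations assume noisy data. When the non-outlying points
  lie *exactly* on a line the median absolute residual is 0 and the robust
  weights degenerate (any point off the line is fully ignored — including
  the genuine beginning of a decline episode). Deterministic, noise-free
  analyses should set `lowess_iterations=0`; the smoothed fit is then an
  exact identity on straight-line series.
- `RdCriteria(on_smoothed=False)` applies the criterion to raw values, used
  for exact-agreement checks against an analytic oracle.

## Decision-point cohort

Candidates are all eGFR test dates inside the admissible decision period
(which should end one event window before the end of observation).
Exclusions, in order: dialysis or kidney transplant strictly before the
date; the date on or after the patient's first RD indication; no further
eGFR test within (t, t + 365 d], which would leave the label unverifiable.
The label is positive iff an RD indication date falls in (t, t + 365 d].
Censoring events are used only to truncate data; they do not themselves
define labels. Requiring lab data in the input window is automatic: the
decision date is itself an eGFR test date.

## Space features

For each decision point and lab test code, observations with day offset
d = decision_date − observation_date in [0, 377] are nearest-neighbour
interpolated to daily values between the first and last observed offset —
no extrapolation, so days outside the observed span stay missing, and a
test never observed in the window contributes 27 missing values.
Equidistant ties resolve to the more recent observation (a fixed,
deterministic rule; recency is the clinically salient side). The 378 days
partition into 27 spaces of 14 days; space k covers d ∈ [14(k−1), 14k−1],
so the decision date itself (d = 0) belongs to the 1st space. Each space is
represented by the natural log of the mean of its non-missing daily values;
an empty space, or a non-positive mean, stays missing rather than being
shifted, because shifting would silently distort every test's scale. The
order is interpolate → average → log.

The production matrix builder uses a prefix-sum shortcut: the global
nearest-neighbour daily series of a patient-test pair agrees with the
per-window one on all days between the first and last in-window
observation (interior days are bracketed by in-window observations), so
per-space means can be read from cumulative sums. Its exact equivalence to
the reference interpolate-then-quantize route is property-tested.

## Model and feature elimination

The learner is LightGBM — a leaf-wise gradient-boosted tree ensemble with
native missing-value routing, so missingness acts as signal rather than
requiring imputation. Fixed regime: learning rate 0.05, max depth 10, 50
leaves, min 100 samples per leaf, up to 1000 boosting rounds with
cross-entropy loss, early stopping after 50 rounds without validation
PR-AUC improvement, decision threshold 0.5, gain importance. Five
parameters are tunable (bagging_fraction, bagging_freq, feature_fraction,
lambda_l1, lambda_l2) via a seeded random search (default 100 trials,
trial 0 = the incoming defaults) maximizing mean PR-AUC over
patient-grouped cross-validation. No class rebalancing is applied: with
~17 % positive decision points, up/down-sampling trades imbalance for
overfitting risk, so the imbalance is left to the loss and reflected
honestly in PR-AUC/F1.

Recursive feature elimination removes, per iteration, the lowest
gain-importance features — a constant floor(5 % of the starting feature
count, at least 1) per step while more than 40 remain, then exactly one per
step down to a single feature (the fractional-step semantics of standard
RFE implementations). Importance ties break by stable column order so runs
are reproducible. At each visited size the six metrics are recorded by
patient-grouped, patient-level-stratified 5-fold cross-validation
(`cv_keep_every` thins this for large paths; `cv=0` records the selection
path only). Grouping by patient everywhere — CV folds, the early-stopping
split (20 % of training patients), and the 70/30 holdout — prevents
within-patient leakage, since decision points of one patient are strongly
correlated. The CV fold count, grouping and early-stopping split size are
package choices; they mirror the patient-level holdout.

## Evaluation

The holdout assigns ceil(30 % · n) patients to the test side (3438
patients → 2406/1032). Metrics: ROC-AUC (trapezoidal over thresholds),
PR-AUC (area under the precision-recall curve), accuracy, recall,
precision and F1 at threshold 0.5. Uncertainty comes from a percentile
bootstrap: test decision points are resampled with replacement to the
original size B = 1000 times; each metric reports its bootstrap mean and
2.5/97.5 percentiles. Resamples lacking a class are redrawn for the AUC
metrics and counted. The resampling unit is the decision point; because
decision points within a patient are correlated, `unit="patient"` offers a
cluster bootstrap as a sensitivity option. Percentile intervals (rather
than BCa) are the simplest reproducible choice.

Multicollinearity of a selected feature set is diagnosed by VIF_j =
1/(1 − R²_j), with R²_j from least-squares regression of feature j on the
others plus an intercept, on complete cases only; VIF > 10 flags strong
multicollinearity. The characteristics table compares RD and not_RD
decision points per feature: mean (SD) with a two-sided Mann-Whitney U
p-value, missing counts and configured bins with Fisher exact p-values. For
2×k bins the Freeman–Halton extension is computed by exact enumeration of
tables with the observed margins when k ≤ 5 and the enumeration is small,
otherwise a chi-square fallback with a logged warning. No multiple-testing
correction is applied to this descriptive table.

## Synthetic cohort generator

The generator emulates the structure of a hospital EHR lab table, not its
clinical content. Per patient: visits follow a homogeneous Poisson process
(`visit_rate`, default 6/year — routine diabetes follow-up every two
months); the noise-free eGFR trajectory is baseline + slope·t, with the
slope switching from `slow_slope` (−1.5/year, ordinary DKD drift) to
`rapid_slope` (−12/year) at a planted episode start for an `rd_fraction`
(default 0.3) of patients; i.i.d. Gaussian noise (SD 3 mL/min/1.73 m²) is
added and values truncated at 1 so logs stay defined. Baselines are
N(75, 15²) clipped at 15. The first visit whose noise-free eGFR falls
below 7 mL/min/1.73 m² (a typical dialysis-initiation range) triggers a
dialysis event; no labs are emitted after censoring. Episode starts are
drawn at least 6 months after study start and a year before study end so
planted episodes are in principle observable.

Serum creatinine is derived from the noisy eGFR by inverting the Japanese
Society of Nephrology 3-variable equation eGFR = 194 · Cr⁻¹·⁰⁹⁴ ·
age⁻⁰·²⁸⁷ (× 0.739 for women) — adopted because the emulated cohort is
Japanese; the labels "eGFR" are only as meaningful as this monotone link,
and any monotone alternative would serve testing equally. Informative
non-renal tests shift their mean by up to `informative_shift` (default 10,
against observation noise SD 10), ramping linearly over the year before the
episode and staying elevated after it, so *when* a test is informative is
recoverable, not just *whether*. All remaining codes are pure N(100, 10²)
noise, independent of ground truth. Identical configs and seeds reproduce
identical tables.

What the generator does **not** emulate: real lab-test correlation
structure, ICD-coded comorbidity, treatment effects, informative visit
scheduling (sicker patients visiting more often), assay changes, or the
~1200-test heterogeneity of a real panel. Passing tests therefore
demonstrate that the pipeline recovers signal it is pointed at under
realistic sparsity, noise and censoring — not that the clinical performance
figures transfer to any real population.

## Reference experiment sizes

The study-condition experiments (tests and `scripts/acceptance.py`) use the
generator defaults — 500 patients, 50 test codes, 3 informative,
rd_fraction 0.3, noise SD 3 — with 20 seeds for the end-to-end medians, 200
noise-free piecewise trajectories for the labeling oracle, 100 synthetic
test sets of 250 decision points (B = 1000) for bootstrap coverage, and
width scaling compared at 300 vs 600 points. The elimination-schedule check
runs from 100 features at a reduced tree count, which changes which
features are eliminated but not the visited sizes or nesting, the
properties under test.

## Known limitations

- LOWESS edge bias: at a series' left edge the local fit can extrapolate
  the later trend backwards; early smoothed values are less trustworthy,
  though they rarely matter (early dates fail the lookback requirement
  anyway).
- The bootstrap treats test decision points as exchangeable; within-patient
  correlation makes the default intervals somewhat anti-conservative (the
  patient-unit option exists for sensitivity analysis).
- The Freeman–Halton implementation enumerates tables and is only intended
  for the small bin counts of a characteristics table.
- `run_pipeline` with full RFECV over tens of thousands of columns is
  computationally serious; `cv_keep_every` and reduced tree counts are the
  supported ways to scale it down.
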