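# Methods

## The prognostic model

The parametric engine is a cause-specific competing-risks survival model
for two causes, breast-cancer death and other-cause death.  For cause
*c* the cumulative hazard is H_c(t | x) = H0_c(t) · exp(π_c(x)) with a
fractional-polynomial baseline H0_c(t) = exp(Σ_k γ_ck b_k(t)), where each
basis term b_k is 1, ln t, or t^p with p in {−2, −1, −0.5, 0.5, 1, 2, 3}.
The shipped stand-in baselines are Weibull-equivalent (intercept + ln t,
with a zero-coefficient √t term available to the fine-tuner).

The breast-cancer prognostic index uses: two fractional-polynomial age
terms centered at 65 years ((age/10)^−2 and (age/10)^−2·ln(age/10)),
ln(size/15 mm), ln(nodes + 1), grade-2/3 indicators, ER− and PR−
indicators, and indicators for HER2+, Ki-67+, screen detection and
micrometastases; treatment effects (chemotherapy, trastuzumab,
radiotherapy, bisphosphonates) act on the same cause.  The other-cause
index uses linear age per decade, smoking, heart-dose category (only when
radiotherapy was given) and a calendar-year offset.  All transforms are
centered so a reference patient (65 y, 15 mm, node-negative, grade 1,
ER+/PR+, untreated, no extended risk factors) has both indices equal to 0.

**Parameter provenance.** The deployed tool's coefficient values are not
published in a recoverable form, so the repository ships a *stand-in*
vector of 26 named parameters with plausible magnitudes and correct effect
directions for postmenopausal HR+ disease.  Its covariate-effect values
mirror the synthetic generator's hazard coefficients, so on default
synthetic cohorts the engine is approximately calibrated — a deliberate
choice that lets miscalibration be introduced in controlled, known
directions.  The loader accepts any parameter file in the same JSON
dialect (names, values, group assignment, baseline basis, mandatory-input
list), so an externally published set can be dropped in.

**Five-year combination.** Predictions use an annual grid: per year the
cause-specific cumulative-hazard increments are computed, all-cause
survival is S(j) = exp(−ΣH_c(j)), and the death mass S(j−1)(1 − e^(−ΣΔH))
is apportioned to causes proportionally to their increments.  The
telescoping sum makes F_bc + F_oth + S_all = 1 exact on the grid.  The
horizon is fixed at 5 years; longer horizons are out of scope.

**Invalid predictions.** Mandatory inputs default to {age, size, nodes,
grade, ER}; the set is configurable in the parameter file.  A record
missing any of them after the assumption layer yields an explicit invalid
result carrying the missing-field list — never an exception and never an
imputed number.  Optional covariates missing at the record level (e.g. PR)
contribute at their reference level.

**Assumption layer.** Inputs the source cohort never recorded (HER2,
Ki-67, detection mode, smoking, diagnosis year, micrometastases,
chemotherapy generation, bisphosphonates, heart dose) are filled at the
dataset level by scenario: *default* uses standard-of-care-circa-2003
constants and infers HER2+ from trastuzumab use; *optimistic* and
*pessimistic* move every fill to its risk-lowering or risk-raising value.
Scenarios differ only in fill values, never in which fields are filled,
so prediction spread across scenarios isolates assumption sensitivity.

## Fine-tuning (parameter-based transfer learning)

The 26 parameters are re-estimated on a target cohort by minimizing the
5-year ICI of the engine's predictions, starting from the pretrained
values.  The objective is non-smooth through the calibration smoother, so
the default optimizer is derivative-free Nelder-Mead (`max_iter` 2000,
`tol` 1e-5); Powell is available, as are per-parameter box bounds (useful
for identifiable single-parameter recovery experiments — a scalar
calibration objective cannot pin down 26 free parameters uniquely, and
unrestricted runs legitimately redistribute a baseline shift across
covariate terms).  Records invalid under the mandatory-input rule are
excluded from the objective per evaluation; validity depends only on
missingness, not on parameter values, so the excluded set is constant.
Fine-tuning never returns a vector worse than its initialization: on
optimizer failure or non-improvement the pretrained vector is returned
with a warning.  Covariates are not re-standardized, so parameter vectors
from repeated runs share a scale and element-wise averaging is meaningful.

## Tree learners

Cause-specific (breast-cancer death as event, competing death censored)
random survival forest (scikit-survival) and gradient boosting (xgboost,
Cox-form survival objective — chosen over the AFT variant for coherence
with the proportional-hazards framing).  XGBoost routes missing values
along learned default directions; the RSF backend has no native missing
support, so missing cells are encoded with a large out-of-range sentinel
(−9999) that split search isolates, applied identically at train and
predict time.  XGBoost risk scores map to probabilities through a Breslow
baseline estimated on the training partition.  Default grids (RSF: trees
{250, 500, 1000}, min leaf {5, 15, 50}; XGB: depth {2, 3, 4}, rate
{0.01, 0.05, 0.1}, rounds {100, 300}) are desk-scale choices; tests use
compact grids.  Hyperparameters are selected by exhaustive evaluation on
the held-out partition (ICI minimized, or AUROC maximized), ties to the
first grid point, and aggregated across runs by per-parameter majority
vote with ties toward the smaller value.  Rebalancing hooks (event
oversampling, inverse-prevalence weights) are wired but off by default.

## Stacking

The ensemble is a convex combination of the fine-tuned parametric model,
RSF and XGB.  Weights are fitted by exhaustive search over the simplex
grid (default step 0.05; deterministic and exactly testable against
enumeration, which is why grid search was preferred to constrained
continuous optimization at three components), minimizing the ICI of the
combined prediction; ties break to the first point in lexicographic grid
order.  When the parametric component is invalid for a record, its weight
is renormalized over the valid components — an inference from the
ensemble's requirement to predict for every patient, and the simplex
constraint is what keeps every combined output a probability.

## Evaluation

* **ICI**: mean |p_i − ô(p_i)| at 5 years, where ô comes from a
  proportional-hazards calibration model on a 4-knot restricted cubic
  spline of cloglog(p) (knots at the 5/35/65/95 percentiles, standardized
  columns, ridge 1e-6).  This spline-PH smoother is this package's stand-in
  for hazard-regression calibration smoothing; it is validated in tests
  against binned Kaplan-Meier estimates on large synthetic data and its
  internal Newton/L-BFGS Cox fit is cross-checked against lifelines.
  Constant predictions degrade the smoother, triggering a single-bin KM
  fallback with a warning.
* **IPCW AUROC**: cumulative-case/dynamic-control AUROC at 5 years.
  Cases (breast-cancer deaths by the horizon) are weighted 1/Ĝ(T−) with Ĝ
  the Kaplan-Meier censoring-survival estimate evaluated left-continuously;
  event-free records are weighted 1/Ĝ(5); competing-cause deaths before
  the horizon count as controls weighted 1/Ĝ(T−).  Prediction ties earn
  half credit.  Uncensored, it reduces exactly to Mann-Whitney pair
  counting (asserted in tests).
* **Calibration plots**: predictions trimmed to the 10th–90th percentile
  band, quartiles of predicted probability, per-bin mean predicted vs
  KM-observed event probability with SDs (Greenwood for the observed).
  Pooling across runs is done by concatenating before binning.
* **Bootstrap**: percentile CIs (2.5/97.5) from record resampling; the
  interval is widened if necessary to bracket the full-sample point
  estimate; failed resamples are skipped and counted.
* All metrics exclude invalid predictions and report the exclusion count.

## Decision curves

Net benefit at threshold P_t uses the KM cumulative event probability F̂ at
5 years within the flagged stratum {p ≥ P_t}: NB = TP/n − (FP/n)·P_t/(1−P_t)
with TP = n_high·F̂, FP = n_high·(1−F̂); the odds weight P_t/(1−P_t) is the
standard decision-curve exchange rate of false for true positives (Vickers
& Elkin, Med Decis Making 2006).  The default grid spans 1%–10%, the
clinically plausible band for 5-year mortality in this population; an
empty flagged set gives NB = 0, and ≥ is used at the threshold.

## Monte-Carlo Shapley attribution

Model-agnostic sampled-permutation Shapley values over the ten patient-level
inputs: per draw, a random permutation and background record define a walk
from background to instance; each feature's contribution is the prediction
change at its step.  Contributions telescope, so efficiency
(Σφ = f(x) − baseline) holds up to MC error shrinking as 1/√m.  Defaults:
m = 200 draws per record, background of 100 training records, fixed seeds.
Missing values are a legitimate feature state, since all models accept
them.  The cohort summary ranks features by mean |φ|.

## The synthetic generator

The generator emulates the *structure* of the study cohorts, not their
records: skew-normal age (calibrated to median 64.2, IQR 58.2–71.2),
categorical nodal stage with within-category count ranges, lognormal tumor
size, grade/laterality/receptor categoricals, logistic treatment
assignment depending on risk covariates (confounding by indication, so
attribution rankings face realistic correlation), cause-specific Weibull
proportional-hazards event times, administrative censoring from uniform
accrual over 2.4 years with cutoff 5.365 years, and per-variable
missingness (MCAR/MAR/MNAR).  Grade is masked MNAR (grade-2 ambiguity
masked most), PR MNAR with negatives masked more — with the latent PR
prevalence set to 0.8157 so the *observed* positive share is 82%.

Calibration targets (event rate 2.5% within 5 years as observed under
censoring, median follow-up 4.1 y, treatment prevalences 30.8%/71.1%/3.5%)
were solved once offline by iterated simulation and root-finding; the
resulting constants are frozen in `default_config`.  Missingness rates for
grade (21.9%), nodes (1.4%), PR (2.0%) and trastuzumab (74.7%) are backed
out of the source cohort's characteristics-table denominators; the tumor
size rate (2.5%) is calibrated so the mandatory-input failure fraction
falls in the reported 23.8–25.8% invalid-prediction band, and is labeled
calibrated, not observed.

The `team_like` scenario shifts the covariate mix to the adverse profile
(39.3% node-negative, larger, higher grade) **and** adds a +0.4 log-hazard
cohort-level excess not attributable to measured covariates.  Without that
term, a correctly specified model transported from the trial-like scenario
would remain calibrated under pure covariate shift; the uplift is what
makes transported models overestimate survival, emulating the documented
generalizability failure on higher-risk external cohorts.  `seer_like` is
the same population at registry scale with thinner missingness.

What the generator does **not** emulate: real trial records, correlations
beyond those induced by the treatment and hazard models, informative
(outcome-dependent) censoring, calendar-time trends, site effects, or
measurement error.  Passing tests therefore demonstrate the pipeline's
internal correctness and directional behavior under known truth — not
clinical performance on real cohorts.

## Protocol

60/20/20 stratified split (stratified on the binary 5-year
breast-cancer-death indicator; events after the horizon stratify as
non-events — a convention, since the stratification variable at the
horizon is otherwise underdetermined).  Within each stratum the first
k−1 partitions get floor(fraction·stratum) records and the last the
remainder; this floor rule reproduces a 6049/1514 development/validation
split on 7563 records with 187 events.  Per run: fine-tune and train on A;
select hyperparameters and stack weights on B; refit on A∪B; evaluate the
five models on C; reoptimize weights on C; refit on A∪B∪C.  Runs use
independent seeds derived from one master seed and are isolated — a failed
run is flagged and skipped.  Internal results are medians/IQRs across runs
(default 10); the final bundle averages fine-tuned vectors and weights and
majority-votes hyperparameters, then refits learners on the full cohort.

## Problem sizes in tests

Tests and the acceptance checks run at deliberately compact sizes chosen
as sufficient for their assertions: generator calibration at the study
size n = 7563 over 25 seeds; metric oracles at n = 200–20000; fine-tuning
recovery at n = 5000 with 400 objective evaluations; the directional
pipeline at n ≈ 5000 with 2 runs, 25-tree forests and singleton grids; the
bootstrap-coverage simulation scaled to 30 replicates at n = 500.

## Known limitations

* The stand-in parameters are not the deployed tool's coefficients;
  absolute predictions are only meaningful relative to the synthetic truth.
* The exact membership and grouping of the 26 fine-tuned parameters is a
  convention of this package.
* The calibration smoother is a spline-PH stand-in for hazard-regression
  smoothing; ICI values can differ in the third decimal from other
  smoother choices.
* Competing-cause-death handling in the IPCW AUROC (competing events as
  dynamic controls) is one of several defensible conventions.
* No interval censoring, left truncation, time-varying covariates, 10/15-
  year horizons, or genomic covariates.
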