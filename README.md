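# prognostack

Five-year breast-cancer survival prognostication for postmenopausal,
hormone-receptor-positive disease: a pretrained fractional-polynomial
competing-risks model, calibration-targeted parameter fine-tuning (transfer
learning), de-novo tree-based survival learners, an ICI-optimized stacked
ensemble, and the survival-specific evaluation suite needed to compare them
— together with a synthetic cohort generator so that every stage of the
pipeline runs and is testable without access to confidential trial data.

## Who this is for

Biostatisticians and clinical-ML researchers who want to (a) apply or adapt
a pretrained parametric prognostic model to a new cohort, (b) benchmark it
against tree-based survival learners that tolerate missing inputs, and
(c) evaluate everything with censoring-aware calibration and discrimination
metrics, decision-curve analysis, and model-agnostic Shapley attribution.

## The model

The parametric engine is a cause-specific competing-risks model for breast-
cancer death (`bc`) and other-cause death (`oth`).  Each cause has a
prognostic index — a Cox-style linear predictor over transformed
covariates (log tumor size, log(nodes + 1), fractional-polynomial age
terms, grade and receptor indicators, treatment effects) — and a
fractional-polynomial baseline cumulative hazard

    H0_c(t) = exp( Σ_k γ_ck · b_k(t) ),    b_k(t) ∈ { 1, ln t, t^p },
    p ∈ {−2, −1, −0.5, 0.5, 1, 2, 3}

On the annual grid t = 1..5 the cause-specific increments
ΔH_c(t) = H0_c(t)·e^{π_c} − H0_c(t−1)·e^{π_c} are combined by proportional
apportionment of the all-cause death mass, giving the 5-year cumulative
incidence of breast-cancer death F_bc(5), with
F_bc + F_oth + S_all = 1 on the grid.  The engine has 26 named
parameters in five groups (two baselines, two covariate blocks, treatment
effects), loaded from a JSON parameter file.  The repository ships a
documented **stand-in** parameter set with plausible magnitudes and correct
signs; externally published coefficient sets in the same dialect load
identically.

Records missing a mandatory input (default: age, tumor size, nodes, grade,
ER status) receive an explicit *invalid* prediction rather than a number.
Fine-tuning (`prognostack.finetune`) re-estimates the 26 parameters on a
new cohort by derivative-free local optimization of the 5-year integrated
calibration index (ICI), initialized at the pretrained values.  The random
survival forest and gradient-boosted learners (`prognostack.trees`) predict
for every record regardless of missingness, and the stacked ensemble
(`prognostack.stacking`) combines all three on the probability simplex,
renormalizing over the components that produced a value.

Metrics (`prognostack.metrics`): ICI from a spline-smoothed hazard-based
calibration curve; IPCW time-dependent AUROC with a Kaplan-Meier censoring
model; quartile calibration-plot data with 10th–90th percentile trimming;
bootstrap percentile CIs.  `prognostack.dca` implements time-to-event net
benefit, `prognostack.shapley` Monte-Carlo Shapley attribution, and
`prognostack.protocol` the full repeated 60/20/20 development protocol.

## Worked example

```python
from prognostack import (PatientRecord, load_params, predict_5y,
                         default_config, generate_cohort, batch_predict,
                         ici, ipcw_auroc)

params = load_params()                      # shipped stand-in parameter set
patient = PatientRecord(id="example", age=58.0, nodes=2, size_mm=22.0,
                        grade=3, er_positive=True, pr_positive=False,
                        chemotherapy=True, radiotherapy=True,
                        time_years=5.0, event="censored")
res = predict_5y(patient, params)
print(f"5-year breast-cancer death risk: {res.p_bc_death_5y:.3f}")
print(f"5-year breast-cancer survival:   {res.p_surv_5y:.3f}")

cohort = generate_cohort(default_config("ma27_like", n=7563, seed=1))
preds = batch_predict(cohort, params)
print(f"invalid predictions: {preds.attrs['invalid_fraction']:.1%}")
p = preds["p_bc_death_5y"].to_numpy()
print(f"ICI:   {ici(p, cohort).point:.4f}")
print(f"AUROC: {ipcw_auroc(p, cohort).point:.3f}")
```

Output:

```
5-year breast-cancer death risk: 0.084
5-year breast-cancer survival:   0.916
invalid predictions: 25.0%
ICI:   0.0015
AUROC: 0.684
```

The 58-year-old node-positive, grade-3, PR-negative patient has an 8.4%
predicted 5-year breast-cancer mortality.  On a full synthetic trial-like
cohort, a quarter of records lack a mandatory input (matching the
missingness the generator emulates), the stand-in engine is nearly
calibrated to the generator's truth (ICI 0.0015), and discrimination is
moderate (IPCW AUROC 0.68).

A command-line interface mirrors the library:

```bash
prognostack simulate --scenario ma27_like --n 7563 --seed 1 --out cohort.csv
prognostack fit --cohort cohort.csv --runs 10 --seed 1 --out results/
prognostack dca --cohort cohort.csv --out dca.csv
prognostack explain --cohort cohort.csv --m 200 --out shap.csv
```

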