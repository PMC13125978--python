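"""Experimental protocol orchestration.

The development protocol splits the cohort 60/20/20 into training (A),
testing (B) and internal-validation (C) partitions and repeats the whole
cycle across independent runs:

1. fine-tune the pretrained parametric model and train the tree learners
   on A;
2. select tree hyperparameters and stacking weights on B;
3. refit everything on A∪B with the selections from B;
4. evaluate the pretrained model, the fine-tuned model, RSF, XGB and the
   stacked ensemble on the held-out C;
5. reoptimize the ensemble weights on C;
6. refit on A∪B∪C for the final specification.

Across runs, tree hyperparameters are aggregated by majority vote, and the
fine-tuned parameter vectors and ensemble weights by averaging; the final
bundle is refit on the full cohort under those aggregates.  Internal
results are reported as medians with IQRs across runs; external validation
reports point estimates with bootstrap percentile CIs.  A failed run is
flagged and skipped rather than aborting the experiment.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .cohort import Cohort, SplitSpec, stratified_split
from .engine import ParamVector, batch_predict, load_params, make_scenario
from .finetune import FinetuneConfig, average_param_vectors, finetune
from .metrics import MetricResult, bootstrap_ci, ici, ipcw_auroc, km_survival
from .stacking import COMPONENTS, StackWeights, average_weights, \
    ensemble_predict, fit_weights
from .trees import DEFAULT_GRIDS, FittedLearner, fit_learner, majority_vote, \
    predict_5y_surv, select_hyperparameters

logger = logging.getLogger(__name__)

MODELS = ("predict", "f_predict", "rsf", "xgb", "ensemble")


@dataclasses.dataclass
class ExperimentConfig:
    fractions: tuple[float, ...] = (0.6, 0.2, 0.2)
    runs: int = 10
    seed: int = 0
    grids: dict = dataclasses.field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_GRIDS.items()})
    finetune: FinetuneConfig = dataclasses.field(default_factory=FinetuneConfig)
    stack_resolution: float = 0.05
    criterion: str = "ici"
    assumption_scenario: str = "default"
    bootstrap_B: int = 200
    learners: tuple[str, ...] = ("rsf", "xgb")

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        SplitSpec(self.fractions)  # validates


@dataclasses.dataclass
class FinalBundle:
    """The final model specification: averaged fine-tuned parameters,
    majority-vote hyperparameters, averaged ensemble weights, and learners
    refit on the full cohort."""

    pretrained: ParamVector
    finetuned: ParamVector
    hyper: dict[str, dict]
    weights: StackWeights
    learners: dict[str, FittedLearner]
    scenario_name: str = "default"


@dataclasses.dataclass
class ExperimentResult:
    report: pd.DataFrame
    bundle: FinalBundle
    run_details: list[dict]
    failures: list[tuple[int, str]]


def _concat(cohorts: list[Cohort]) -> Cohort:
    return Cohort(pd.concat([c.df for c in cohorts], ignore_index=True),
                  provenance=cohorts[0].provenance)


def bundle_predictions(bundle: FinalBundle, cohort: Cohort) -> dict[str, np.ndarray]:
    """Per-model 5-year event probabilities on a cohort.  Parametric models
    carry NaN at invalid records; the ensemble renormalizes over valid
    components and therefore covers every record."""
    scenario = make_scenario(bundle.scenario_name)
    out = {}
    out["predict"] = batch_predict(cohort, bundle.pretrained, scenario)["p_bc_death_5y"].to_numpy()
    out["f_predict"] = batch_predict(cohort, bundle.finetuned, scenario)["p_bc_death_5y"].to_numpy()
    for kind, learner in bundle.learners.items():
        out[kind] = predict_5y_surv(learner, cohort)
    mat = np.column_stack([out["f_predict"]] +
                          [out[k] for k in bundle.learners])
    out["ensemble"] = ensemble_predict(mat, bundle.weights)
    return out


def _metric_pair(p: np.ndarray, cohort: Cohort) -> dict:
    return {"ici": ici(p, cohort), "auroc": ipcw_auroc(p, cohort)}


def _one_run(cohort: Cohort, pretrained: ParamVector, cfg: ExperimentConfig,
             run_seed: int) -> dict:
    scenario = make_scenario(cfg.assumption_scenario)
    A, B, C = stratified_split(cohort, SplitSpec(cfg.fractions, seed=run_seed))
    # 1: fine-tune and train on A
    f_A = finetune(pretrained, A, cfg.finetune, scenario)
    hyper = {k: select_hyperparameters(k, cfg.grids[k], A, B, cfg.criterion,
                                       seed=run_seed)
             for k in cfg.learners}
    # 2: stack weights on B
    comp_B = [batch_predict(B, f_A, scenario)["p_bc_death_5y"].to_numpy()]
    for k in cfg.learners:
        comp_B.append(predict_5y_surv(fit_learner(k, A, hyper[k], seed=run_seed), B))
    names = ("f_predict",) + tuple(cfg.learners)
    w_B = fit_weights(np.column_stack(comp_B), B, cfg.criterion,
                      cfg.stack_resolution, components=names)
    # 3: refit on A∪B
    AB = _concat([A, B])
    f_AB = finetune(pretrained, AB, cfg.finetune, scenario)
    learners_AB = {k: fit_learner(k, AB, hyper[k], seed=run_seed)
                   for k in cfg.learners}
    # 4: internal validation on C
    preds_C = {"predict": batch_predict(C, pretrained, scenario)["p_bc_death_5y"].to_numpy(),
               "f_predict": batch_predict(C, f_AB, scenario)["p_bc_death_5y"].to_numpy()}
    for k in cfg.learners:
        preds_C[k] = predict_5y_surv(learners_AB[k], C)
    mat_C = np.column_stack([preds_C["f_predict"]] + [preds_C[k] for k in cfg.learners])
    preds_C["ensemble"] = ensemble_predict(mat_C, w_B)
    metrics = {name: _metric_pair(p, C) for name, p in preds_C.items()}
    # 5: reoptimize weights on C
    w_C = fit_weights(mat_C, C, cfg.criterion, cfg.stack_resolution,
                      components=names)
    # 6: final specification on A∪B∪C
    f_full = finetune(pretrained, cohort, cfg.finetune, scenario)
    return {"seed": run_seed, "hyper": hyper, "weights": w_C,
            "params": f_full, "metrics": metrics,
            "invalid_C": {"predict": int(np.isnan(preds_C["predict"]).sum()),
                          "f_predict": int(np.isnan(preds_C["f_predict"]).sum())},
            "n_C": len(C)}


def run_internal_experiment(cohort: Cohort, cfg: ExperimentConfig | None = None,
                            pretrained: ParamVector | None = None) -> ExperimentResult:
    """Full internal development/validation protocol (steps 1-6 per run)."""
    cfg = cfg or ExperimentConfig()
    pretrained = pretrained or load_params()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.runs) % (2**31 - 1)
    details, failures = [], []
    for r in range(cfg.runs):
        try:
            details.append(_one_run(cohort, pretrained, cfg, int(seeds[r])))
        except Exception as exc:
            logger.warning("run %d failed: %s", r, exc)
            failures.append((r, str(exc)))
    if not details:
        raise RuntimeError("every run failed; see log")

    rows = []
    for model in ("predict", "f_predict") + tuple(cfg.learners) + ("ensemble",):
        for metric in ("ici", "auroc"):
            vals = np.array([d["metrics"][model][metric].point for d in details])
            rows.append({"model": model, "metric": metric,
                         "median": float(np.median(vals)),
                         "iqr_lo": float(np.percentile(vals, 25)),
                         "iqr_hi": float(np.percentile(vals, 75)),
                         "n_runs": len(vals)})
    report = pd.DataFrame(rows)

    hyper = {k: majority_vote([d["hyper"][k] for d in details])
             for k in cfg.learners}
    finetuned = average_param_vectors([d["params"] for d in details])
    weights = average_weights([d["weights"] for d in details])
    learners = {k: fit_learner(k, cohort, hyper[k], seed=cfg.seed)
                for k in cfg.learners}
    bundle = FinalBundle(pretrained=pretrained, finetuned=finetuned,
                         hyper=hyper, weights=weights, learners=learners,
                         scenario_name=cfg.assumption_scenario)
    return ExperimentResult(report=report, bundle=bundle,
                            run_details=details, failures=failures)


def run_external_validation(bundle: FinalBundle, cohort: Cohort,
                            B: int = 2000, seed: int = 0) -> pd.DataFrame:
    """ICI and AUROC with bootstrap percentile CIs per model on an external
    cohort, plus invalid-prediction fractions for the parametric models."""
    preds = bundle_predictions(bundle, cohort)
    rows = []
    for model, p in preds.items():
        for metric, fn in (("ici", ici), ("auroc", ipcw_auroc)):
            r = bootstrap_ci(fn, p, cohort, B=B, seed=seed)
            rows.append({"model": model, "metric": metric, "point": r.point,
                         "ci_lo": r.ci[0], "ci_hi": r.ci[1],
                         "n_used": r.n_used, "n_invalid": r.n_excluded})
    return pd.DataFrame(rows)


def stratify_high_risk(cohort: Cohort):
    """Split a cohort into the adverse-prognosis subgroup (node-positive,
    tumor >= 2 cm, grade 3) and the rest.

    Records missing any defining variable are excluded from both parts.
    Returns (high, rest, n_excluded); an empty part is returned as None.
    """
    df = cohort.df
    defined = df["nodes"].notna() & df["size_mm"].notna() & df["grade"].notna()
    high = defined & (df["nodes"] >= 1) & (df["size_mm"] >= 20.0) & (df["grade"] == 3)
    rest = defined & ~high
    n_excluded = int((~defined).sum())
    high_c = cohort.subset(df.index[high.fillna(False)]) if high.any() else None
    rest_c = cohort.subset(df.index[rest.fillna(False)]) if rest.any() else None
    return high_c, rest_c, n_excluded


def run_sensitivity(bundle: FinalBundle, cohort: Cohort,
                    scenarios: tuple[str, ...] = ("optimistic", "default",
                                                  "pessimistic")) -> dict:
    """Impact of the dataset-level input assumptions.

    Re-evaluates every model under each assumption scenario and reports the
    per-model metric table alongside the per-record prediction spread
    (max − min across scenarios); the tree learners use no assumption fills,
    so their spread is structurally zero.
    """
    metric_rows, spreads = [], {}
    for name in scenarios:
        alt = dataclasses.replace(bundle, scenario_name=name)
        preds = bundle_predictions(alt, cohort)
        for model, p in preds.items():
            m = _metric_pair(p, cohort)
            metric_rows.append({"scenario": name, "model": model,
                                "ici": m["ici"].point, "auroc": m["auroc"].point})
            spreads.setdefault(model, []).append(p)
    import warnings as _warnings
    with _warnings.catch_warnings():
        # records invalid under every scenario yield all-NaN rows; keep NaN
        _warnings.simplefilter("ignore", RuntimeWarning)
        spread = pd.DataFrame({
            model: np.nanmax(np.column_stack(ps), axis=1) -
                   np.nanmin(np.column_stack(ps), axis=1)
            for model, ps in spreads.items()})
    spread.insert(0, "id", cohort.df["id"].to_numpy())
    return {"metrics": pd.DataFrame(metric_rows), "spread": spread}


def mean_survival_gap(bundle: FinalBundle, cohort: Cohort, model: str = "f_predict",
                      horizon: float = 5.0) -> float:
    """Mean predicted 5-year survival minus KM-observed survival — positive
    values flag systematic survival overestimation (the failure mode on a
    higher-risk external cohort)."""
    preds = bundle_predictions(bundle, cohort)[model]
    valid = ~np.isnan(preds)
    km = km_survival(cohort.subset(cohort.df.index[valid]), horizon)
    return float(np.mean(1.0 - preds[valid]) - km)
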