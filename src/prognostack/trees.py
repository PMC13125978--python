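"""De-novo tree-based survival learners.

Two cause-specific learners predict the 5-year breast-cancer-death
probability directly from the covariates, tolerating record-level missing
values so that — unlike the parametric engine — they can predict for every
patient:

* **RSF** — random survival forest (scikit-survival).  The backend has no
  native missing-value routing, so missing cells are encoded with a large
  out-of-range sentinel that the split search isolates as its own branch
  (documented adapter; identical encoding at train and predict time).
* **XGB** — gradient boosting with the Cox-form survival objective
  (xgboost), which routes missing values along learned default directions.
  Risk scores are mapped to probabilities through a Breslow baseline hazard
  estimated on the training partition.

Hyperparameters are chosen by exhaustive grid evaluation on a held-out
partition under the ICI (or AUROC) criterion, and aggregated across
repeated runs by per-parameter majority vote.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter
from typing import Mapping

import numpy as np
import pandas as pd
import xgboost as xgb
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model.coxph import BreslowEstimator
from sksurv.util import Surv

from .cohort import Cohort
from .metrics import HORIZON, ici, ipcw_auroc

FEATURES = ("age", "nodes", "size_mm", "grade", "er_positive", "pr_positive",
            "laterality_code", "radiotherapy", "chemotherapy", "trastuzumab")

_SENTINEL = -9999.0

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rsf": {"n_estimators": [250, 500, 1000], "min_samples_leaf": [5, 15, 50]},
    "xgb": {"max_depth": [2, 3, 4], "learning_rate": [0.01, 0.05, 0.1],
            "n_rounds": [100, 300]},
}


def feature_matrix(df: pd.DataFrame) -> np.ndarray:
    """Numeric design matrix with NaN marking missing cells."""
    lat = df["laterality"].map({"left": 0.0, "right": 1.0, "bilateral": 2.0})
    cols = {
        "age": pd.to_numeric(df["age"], errors="coerce"),
        "nodes": pd.to_numeric(df["nodes"], errors="coerce"),
        "size_mm": pd.to_numeric(df["size_mm"], errors="coerce"),
        "grade": pd.to_numeric(df["grade"], errors="coerce"),
        "er_positive": pd.to_numeric(df["er_positive"], errors="coerce"),
        "pr_positive": pd.to_numeric(df["pr_positive"], errors="coerce"),
        "laterality_code": lat,
        "radiotherapy": pd.to_numeric(df["radiotherapy"], errors="coerce"),
        "chemotherapy": pd.to_numeric(df["chemotherapy"], errors="coerce"),
        "trastuzumab": pd.to_numeric(df["trastuzumab"], errors="coerce"),
    }
    return pd.DataFrame(cols).to_numpy(dtype=float)


def _surv_outcome(df: pd.DataFrame):
    event = (df["event"] == "bc_death").to_numpy(dtype=bool)
    time = df["time_years"].to_numpy(dtype=float)
    return event, time


@dataclasses.dataclass
class FittedLearner:
    """A fitted survival learner able to produce a 5-year breast-cancer-death
    probability for any record, including records with missing covariates."""

    model_kind: str                 # "rsf" | "xgb"
    model: object
    hyper: dict
    seed: int
    n_train: int
    n_events: int
    breslow: BreslowEstimator | None = None

    def metadata(self) -> dict:
        return {"model_kind": self.model_kind, "hyper": self.hyper,
                "seed": self.seed, "n_train": self.n_train,
                "n_events": self.n_events}


def fit_learner(kind: str, train: Cohort, hyper: Mapping | None = None,
                weights: np.ndarray | None = None, seed: int = 0) -> FittedLearner:
    """Fit an RSF or XGB survival learner on a cohort (cause-specific:
    breast-cancer death is the event, competing deaths are censored)."""
    if kind not in DEFAULT_GRIDS:
        raise ValueError(f"unknown learner kind {kind!r}")
    hyper = dict(hyper or {k: v[0] for k, v in DEFAULT_GRIDS[kind].items()})
    event, time = _surv_outcome(train.df)
    if not event.any():
        raise ValueError("training cohort has no breast-cancer deaths")
    X = feature_matrix(train.df)
    if kind == "rsf":
        Xs = np.nan_to_num(X, nan=_SENTINEL)
        model = RandomSurvivalForest(
            n_estimators=int(hyper.get("n_estimators", 250)),
            min_samples_leaf=int(hyper.get("min_samples_leaf", 15)),
            max_features="sqrt", n_jobs=1, random_state=seed)
        model.fit(Xs, Surv.from_arrays(event, time), sample_weight=weights)
        breslow = None
    elif kind == "xgb":
        # survival:cox label convention: +time for events, -time for censored
        label = np.where(event, time, -time)
        dtrain = xgb.DMatrix(X, label=label, weight=weights,
                             missing=float("nan"))
        params = {"objective": "survival:cox",
                  "max_depth": int(hyper.get("max_depth", 3)),
                  "eta": float(hyper.get("learning_rate", 0.05)),
                  "subsample": float(hyper.get("subsample", 1.0)),
                  "lambda": 1.0, "nthread": 1, "seed": seed}
        model = xgb.train(params, dtrain,
                          num_boost_round=int(hyper.get("n_rounds", 100)))
        lp = model.predict(dtrain, output_margin=True)
        breslow = BreslowEstimator().fit(lp, event, time)
    else:
        raise ValueError(f"unknown learner kind {kind!r}")
    return FittedLearner(model_kind=kind, model=model, hyper=hyper, seed=seed,
                         n_train=len(train), n_events=int(event.sum()),
                         breslow=breslow)


def predict_5y_surv(model: FittedLearner, cohort: Cohort,
                    horizon: float = HORIZON) -> np.ndarray:
    """Per-record probability of breast-cancer death by the horizon, from
    the learner's survival function at t = horizon."""
    X = feature_matrix(cohort.df)
    if model.model_kind == "rsf":
        Xs = np.nan_to_num(X, nan=_SENTINEL)
        times = model.model.unique_times_
        surv = model.model.predict_survival_function(Xs, return_array=True)
        mask = times <= horizon
        s5 = surv[:, mask][:, -1] if mask.any() else np.ones(len(Xs))
        return 1.0 - s5
    lp = model.model.predict(xgb.DMatrix(X, missing=float("nan")),
                             output_margin=True)
    chf = model.breslow.get_cumulative_hazard_function(lp)
    h5 = np.array([fn(min(horizon, fn.domain[1])) for fn in chf])
    return 1.0 - np.exp(-h5)


def select_hyperparameters(kind: str, grid: Mapping[str, list], train: Cohort,
                           test: Cohort, criterion: str = "ici",
                           weights: np.ndarray | None = None,
                           seed: int = 0) -> dict:
    """Exhaustive grid evaluation on the held-out partition; returns the
    candidate minimizing ICI (or maximizing AUROC), ties broken by first
    occurrence in grid order."""
    if criterion not in ("ici", "auroc"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be non-empty")
    keys = list(grid)
    best, best_score = None, np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        hyper = dict(zip(keys, combo))
        learner = fit_learner(kind, train, hyper, weights=weights, seed=seed)
        p = predict_5y_surv(learner, test)
        score = (ici(p, test).point if criterion == "ici"
                 else -ipcw_auroc(p, test).point)
        if score < best_score - 1e-12:
            best, best_score = hyper, score
    return best


def majority_vote(choices: list[Mapping]) -> dict:
    """Per-hyperparameter modal value across runs; ties break toward the
    smaller value (simpler model under the natural ordering)."""
    if not choices:
        raise ValueError("need at least one choice")
    keys = list(choices[0])
    out = {}
    for k in keys:
        counts = Counter(c[k] for c in choices)
        top = max(counts.values())
        out[k] = min(v for v, c in counts.items() if c == top)
    return out
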