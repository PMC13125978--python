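"""Model-agnostic Monte-Carlo Shapley attribution for 5-year predictions.

Per-prediction feature attributions are estimated by the sampled-permutation
scheme: for each of ``m`` draws, a random feature permutation and a random
background record are taken, and each feature's marginal contribution is the
change in prediction when that feature switches from the background value to
the instance value, with the features preceding it in the permutation
already switched.  Summed over one draw the contributions telescope to
f(instance) − f(background), so the efficiency property Σφ = f(x) − baseline
holds up to Monte-Carlo error that shrinks as 1/√m.

Missing covariate values are a legitimate feature state here — the models
accept missingness — so coalitions may carry missing values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import Cohort

#: Features attributed by default: the patient-level model inputs.
SHAP_FEATURES = ("age", "nodes", "laterality", "er_positive", "pr_positive",
                 "size_mm", "grade", "radiotherapy", "chemotherapy",
                 "trastuzumab")


@dataclasses.dataclass
class ShapResult:
    values: pd.DataFrame          # records x features
    baseline: float
    m: int
    seed: int


def _batched(predict_fn, df: pd.DataFrame) -> np.ndarray:
    out = np.asarray(predict_fn(df), dtype=float)
    if out.shape != (len(df),):
        raise ValueError("predict_fn must return one probability per row")
    return out


def mc_shap(predict_fn, instance, background: Cohort, m: int = 200,
            seed: int = 0, features: tuple[str, ...] = SHAP_FEATURES) -> pd.Series:
    """Per-feature Shapley attributions for one record.

    ``predict_fn`` maps a cohort-layout DataFrame to a probability per row;
    ``instance`` is a PatientRecord or a single-row DataFrame.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if hasattr(instance, "to_row"):
        inst = Cohort.from_records([instance]).df.iloc[0]
    else:
        inst = instance.iloc[0] if isinstance(instance, pd.DataFrame) else instance
    bg = background.df
    rng = np.random.default_rng(seed)
    p = len(features)
    bg_rows = bg.iloc[rng.integers(0, len(bg), size=m)].reset_index(drop=True)
    perms = np.array([rng.permutation(p) for _ in range(m)])

    # coalition rows, vectorized: per draw d, rows k = 0..p walk from pure
    # background to pure instance along permutation d; feature j comes from
    # the instance exactly when k > position of j in the permutation
    pos = np.argmax(perms[:, :, None] == np.arange(p)[None, None, :], axis=1)  # (m, p)
    k_grid = np.arange(p + 1)
    frame = bg_rows.loc[bg_rows.index.repeat(p + 1)].reset_index(drop=True)
    frame["id"] = [f"shap-{d}-{k}" for d in range(m) for k in k_grid]
    for j, f in enumerate(features):
        from_inst = (k_grid[None, :] > pos[:, j][:, None]).ravel()   # (m*(p+1),)
        col = frame[f].copy()
        col[from_inst] = inst[f]
        frame[f] = col
    preds = _batched(predict_fn, frame)
    preds = preds.reshape(m, p + 1)
    deltas = np.diff(preds, axis=1)          # (m, p) contribution per step
    phi = np.array([deltas[np.arange(m), pos[:, j]].mean() for j in range(p)])
    return pd.Series(phi, index=list(features))


def shap_summary(predict_fn, cohort: Cohort, background: Cohort | None = None,
                 m: int = 200, seed: int = 0,
                 features: tuple[str, ...] = SHAP_FEATURES,
                 background_size: int = 100) -> pd.DataFrame:
    """Cohort-level attribution summary, ranked by mean |SHAP|.

    Returns one row per feature with the mean absolute attribution (the
    ranking statistic), the mean signed attribution, and the rank — enough
    to reconstruct a beeswarm-style summary together with
    :func:`shap_values`."""
    res = shap_values(predict_fn, cohort, background, m=m, seed=seed,
                      features=features, background_size=background_size)
    vals = res.values
    out = pd.DataFrame({
        "feature": vals.columns,
        "mean_abs_shap": vals.abs().mean().to_numpy(),
        "mean_shap": vals.mean().to_numpy(),
    }).sort_values("mean_abs_shap", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def shap_values(predict_fn, cohort: Cohort, background: Cohort | None = None,
                m: int = 200, seed: int = 0,
                features: tuple[str, ...] = SHAP_FEATURES,
                background_size: int = 100) -> ShapResult:
    """Per-record, per-feature attributions for a whole cohort."""
    rng = np.random.default_rng(seed)
    bg = background or cohort
    if len(bg) > background_size:
        pick = rng.choice(len(bg), size=background_size, replace=False)
        bg = bg.subset(bg.df.index[np.sort(pick)])
    baseline = float(np.mean(_batched(predict_fn, bg.df)))
    rows = {}
    for i, (_, rec) in enumerate(cohort.df.iterrows()):
        rows[rec["id"]] = mc_shap(predict_fn, rec, bg, m=m,
                                  seed=int(rng.integers(0, 2**31 - 1)),
                                  features=features)
    values = pd.DataFrame(rows).T
    values.index.name = "id"
    return ShapResult(values=values, baseline=baseline, m=m, seed=seed)
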