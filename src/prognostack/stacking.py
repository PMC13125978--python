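"""Weighted linear stacking of the parametric and tree-based predictions.

Final predictions are a convex combination of the component models'
5-year event probabilities.  Weights live on the probability simplex and
are fitted by exhaustive search over a simplex grid, minimizing the ICI (or
maximizing the IPCW AUROC) of the combined prediction on a held-out
partition.  When the parametric component is invalid for a record, its
weight is renormalized over the components that did predict, which is what
lets the ensemble cover every record.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .metrics import ici, ipcw_auroc

COMPONENTS = ("f_predict", "rsf", "xgb")


@dataclasses.dataclass
class StackWeights:
    components: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if len(self.w) != len(self.components):
            raise ValueError("one weight per component required")
        if (self.w < -1e-12).any() or abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        self.w = np.clip(self.w, 0.0, None)
        self.w = self.w / self.w.sum()

    def as_dict(self) -> dict[str, float]:
        return {c: float(v) for c, v in zip(self.components, self.w)}


def simplex_grid(k: int, resolution: float):
    """Lexicographically ordered grid on the k-simplex with the given step."""
    steps = int(round(1.0 / resolution))
    for combo in itertools.product(range(steps + 1), repeat=k - 1):
        if sum(combo) <= steps:
            last = steps - sum(combo)
            yield np.array(combo + (last,), dtype=float) / steps


def ensemble_predict(preds, weights: StackWeights) -> np.ndarray:
    """Row-wise convex combination over the valid components.

    ``preds`` is an (n, k) array with NaN marking invalid entries; weights
    are renormalized per record over the valid subset.  A record where every
    component is invalid raises (cannot occur while the tree learners are in
    the stack)."""
    P = np.asarray(preds, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    valid = ~np.isnan(P)
    if (~valid.any(axis=1)).any():
        raise ValueError("a record has no valid component prediction")
    W = np.where(valid, weights.w[None, :], 0.0)
    wsum = W.sum(axis=1)
    if (wsum <= 0).any():
        # all weight sat on invalid components: fall back to equal weights
        # over the valid subset
        zero = wsum <= 0
        W[zero] = valid[zero].astype(float)
        wsum = W.sum(axis=1)
    combined = np.nansum(W * P, axis=1) / wsum
    return combined


def fit_weights(component_preds, samples, criterion: str = "ici",
                resolution: float = 0.05,
                components: tuple[str, ...] = COMPONENTS) -> StackWeights:
    """Exhaustive simplex-grid search for the stacking weights.

    ``component_preds`` is (n, k) with NaN for invalid entries; the
    objective is evaluated on the combined prediction over records where at
    least one component is valid.  Ties break toward the first point in
    lexicographic grid order."""
    P = np.asarray(component_preds, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("need an (n, k>=2) prediction matrix")
    if P.shape[0] == 0:
        raise ValueError("empty predictions")
    if not (~np.isnan(P)).all(axis=1).any():
        raise ValueError("no record has all components valid")
    if criterion not in ("ici", "auroc"):
        raise ValueError(f"unknown criterion {criterion!r}")
    best, best_score = None, np.inf
    for w in simplex_grid(P.shape[1], resolution):
        sw = StackWeights(components, w)
        combined = ensemble_predict(P, sw)
        if criterion == "ici":
            score = ici(combined, samples).point
        else:
            score = -ipcw_auroc(combined, samples).point
        if score < best_score - 1e-12:
            best, best_score = sw, score
    return best


def average_weights(weight_list: list[StackWeights]) -> StackWeights:
    """Element-wise mean, renormalized onto the simplex."""
    if not weight_list:
        raise ValueError("need at least one weight vector")
    comp = weight_list[0].components
    for w in weight_list[1:]:
        if w.components != comp:
            raise ValueError("mismatched component order")
    mean = np.mean([w.w for w in weight_list], axis=0)
    return StackWeights(comp, mean / mean.sum())
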