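"""Decision-curve analysis for 5-year breast-cancer mortality.

Net benefit of using a risk model to trigger an intervention at threshold
probability P_t, against the treat-all and treat-none defaults.  Because the
outcome is time-to-event, the event probability within the high-risk stratum
is estimated by Kaplan-Meier at the horizon rather than by raw counts, and
true/false positives are derived from it:

    NB(P_t) = TP/n − (FP/n) · P_t / (1 − P_t)

with TP = n_high·F̂ and FP = n_high·(1 − F̂), where F̂ is the KM cumulative
event probability at 5 years among records with predicted risk ≥ P_t.  The
weighting term P_t/(1−P_t) encodes the cost of a false positive relative to
the benefit of a true positive implied by the chosen threshold.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .metrics import HORIZON, as_samples, km_event_prob


@dataclasses.dataclass
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    n_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "nb_model": self.nb_model,
            "nb_all": self.nb_all, "nb_none": self.nb_none,
            "n_high": self.n_high})


def net_benefit(pred, samples, p_t: float, horizon: float = HORIZON) -> float:
    """Net benefit at one threshold; empty high-risk set → 0."""
    if not (0.0 < p_t < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    time, event = as_samples(samples)
    p = np.asarray(pred, dtype=float)
    valid = ~np.isnan(p)
    p, time, event = p[valid], time[valid], event[valid]
    n = len(p)
    high = p >= p_t
    n_high = int(high.sum())
    if n_high == 0:
        return 0.0
    f_hat = km_event_prob((time[high], event[high]), horizon)
    tp = n_high * f_hat
    fp = n_high * (1.0 - f_hat)
    return tp / n - (fp / n) * p_t / (1.0 - p_t)


def decision_curve(pred, samples, grid=None, horizon: float = HORIZON) -> DecisionCurve:
    """Net benefit across a threshold grid (default 1%-10%) for the model,
    treat-all and treat-none strategies."""
    if grid is None:
        grid = np.round(np.arange(0.01, 0.1001, 0.005), 4)
    grid = np.asarray(grid, dtype=float)
    if (np.diff(grid) <= 0).any() or (grid <= 0).any() or (grid >= 1).any():
        raise ValueError("threshold grid must be strictly increasing within (0, 1)")
    p = np.asarray(pred, dtype=float)
    all_pred = np.ones_like(p)
    nb_model, nb_all, n_high = [], [], []
    for t in grid:
        nb_model.append(net_benefit(p, samples, t, horizon))
        nb_all.append(net_benefit(all_pred, samples, t, horizon))
        n_high.append(int((p[~np.isnan(p)] >= t).sum()))
    return DecisionCurve(thresholds=grid, nb_model=np.array(nb_model),
                         nb_all=np.array(nb_all), nb_none=np.zeros_like(grid),
                         n_high=np.array(n_high))
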