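"""Survival-specific evaluation suite.

All metrics target the fixed 5-year horizon and account for right-censoring:

* **ICI** — integrated calibration index: the mean absolute difference
  between predicted event probabilities and smoothed observed probabilities
  from a flexible hazard-based calibration curve (a proportional-hazards
  model on a restricted-cubic-spline basis of cloglog(p)).
* **IPCW AUROC** — cumulative-case / dynamic-control time-dependent AUROC
  with inverse-probability-of-censoring weights from the Kaplan-Meier
  estimate of the censoring distribution.
* Quartile calibration-plot data with percentile trimming, bootstrap
  percentile confidence intervals, and the Kaplan-Meier machinery behind
  all of the above.

Invalid (NaN) predictions are excluded everywhere and the exclusion count is
reported on the result object.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

HORIZON = 5.0


@dataclasses.dataclass
class MetricResult:
    point: float
    ci: tuple[float, float] | None = None
    n_used: int = 0
    n_excluded: int = 0

    def __post_init__(self):
        if self.ci is not None:
            lo, hi = self.ci
            if not (lo <= hi):
                raise ValueError("CI endpoints out of order")

    def __float__(self) -> float:
        return float(self.point)


def as_samples(samples) -> tuple[np.ndarray, np.ndarray]:
    """Normalize cohort-like input to (time, event-code) arrays.

    Accepts a Cohort, a DataFrame with ``time_years``/``event`` columns, or a
    (time, event) tuple where event is either a string code array or a
    binary indicator (1 = breast-cancer death).
    """
    if hasattr(samples, "df"):
        samples = samples.df
    if isinstance(samples, pd.DataFrame):
        time = samples["time_years"].to_numpy(dtype=float)
        event = samples["event"].astype(str).to_numpy()
        return time, event
    time, event = samples
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if event.dtype.kind in "biu":
        event = np.where(event.astype(bool), "bc_death", "censored")
    else:
        event = event.astype(str)
    if (time <= 0).any():
        raise ValueError("follow-up times must be positive")
    return time, event


# ---------------------------------------------------------------------------
# Kaplan-Meier machinery

def km_curve(time: np.ndarray, observed: np.ndarray):
    """Product-limit estimate.  Returns (event_times, S at those times,
    Greenwood variance terms)."""
    order = np.argsort(time, kind="mergesort")
    t, d = time[order], observed[order].astype(bool)
    uniq, first = np.unique(t, return_index=True)
    n = len(t)
    at_risk = n - first
    deaths = np.add.reduceat(d.astype(int), first)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - deaths / at_risk
        green = deaths / (at_risk * (at_risk - deaths))
    keep = deaths > 0
    s = np.cumprod(frac[keep])
    gv = np.cumsum(np.where(np.isfinite(green[keep]), green[keep], 0.0))
    return uniq[keep], s, gv


def km_survival(samples, t: float, observed: np.ndarray | None = None,
                left: bool = False) -> float:
    """Kaplan-Meier survival probability at ``t``.

    ``observed`` overrides the event indicator (e.g. flipped, to estimate
    the censoring distribution Ĝ).  ``left=True`` evaluates the
    left-continuous version S(t−), needed for IPCW case weights.
    """
    time, event = as_samples(samples)
    if t < 0:
        raise ValueError("t must be >= 0")
    if observed is None:
        observed = event == "bc_death"
    et, s, _ = km_curve(time, np.asarray(observed, dtype=bool))
    if len(et) == 0:
        return 1.0
    mask = (et < t) if left else (et <= t)
    return float(s[mask][-1]) if mask.any() else 1.0


def censoring_survival(samples, t, left: bool = False):
    """Ĝ(t) = P(censoring time > t), KM on the flipped indicator (deaths of
    any cause are the censored observations)."""
    time, event = as_samples(samples)
    observed = event == "censored"
    et, s, _ = km_curve(time, observed)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.ones_like(t)
    if len(et):
        for i, ti in enumerate(t):
            mask = (et < ti) if left else (et <= ti)
            if mask.any():
                out[i] = s[mask][-1]
    return out if out.size > 1 else float(out[0])


def km_event_prob(samples, t: float) -> float:
    """1 − KM survival for breast-cancer death by ``t`` (competing deaths
    censored), the binned 'observed probability' used in calibration plots
    and decision curves."""
    return 1.0 - km_survival(samples, t)


# ---------------------------------------------------------------------------
# Internal Cox fit (calibration smoother backbone)

def _cox_negloglik(beta, X, first, at_risk_idx, deaths, event_rows, ridge):
    eta = X @ beta
    e = np.exp(eta - eta.max())
    rev = np.cumsum(e[::-1])[::-1]            # Σ_{t_j >= t_i} exp(eta)
    denom = rev[first]                        # per tie group
    ll = eta[event_rows].sum() - np.sum(deaths * (np.log(denom) + eta.max()))
    xe = X * e[:, None]
    rev_x = np.cumsum(xe[::-1], axis=0)[::-1]
    grad = X[event_rows].sum(axis=0) - (deaths[:, None] * rev_x[first] / denom[:, None]).sum(axis=0)
    ll -= ridge * (beta @ beta)
    grad -= 2 * ridge * beta
    return -ll, -grad


def _fit_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray, ridge: float = 1e-6):
    """Breslow-ties Cox partial-likelihood fit via L-BFGS with analytic
    gradient; returns (beta, baseline cumulative hazard evaluator)."""
    order = np.argsort(time, kind="mergesort")
    X, time, event = X[order], time[order], event[order].astype(bool)
    uniq, first = np.unique(time, return_index=True)
    deaths = np.add.reduceat(event.astype(int), first)
    event_rows = np.flatnonzero(event)
    res = optimize.minimize(
        _cox_negloglik, np.zeros(X.shape[1]), jac=True,
        args=(X, first, None, deaths.astype(float), event_rows, ridge),
        method="L-BFGS-B", options={"maxiter": 200})
    beta = res.x
    eta = X @ beta
    shift = eta.max()
    e = np.exp(eta - shift)
    rev = np.cumsum(e[::-1])[::-1]
    with np.errstate(divide="ignore"):
        dh0 = deaths / (rev[first] * np.exp(shift))
    keep = deaths > 0
    bt, bh = uniq[keep], np.cumsum(dh0[keep])

    def cumhaz0(t: float) -> float:
        mask = bt <= t
        return float(bh[mask][-1]) if mask.any() else 0.0

    return beta, cumhaz0


def _rcs_basis(u: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear-tail constrained), k knots →
    k−1 columns including the linear term."""
    k = knots
    scale = (k[-1] - k[0]) ** 2
    cols = [u]
    for j in range(len(k) - 2):
        cj = (np.clip(u - k[j], 0, None) ** 3
              - np.clip(u - k[-2], 0, None) ** 3 * (k[-1] - k[j]) / (k[-1] - k[-2])
              + np.clip(u - k[-1], 0, None) ** 3 * (k[-2] - k[j]) / (k[-1] - k[-2]))
        cols.append(cj / scale)
    return np.column_stack(cols)


def smoothed_calibration(pred: np.ndarray, samples, horizon: float = HORIZON,
                         n_knots: int = 4) -> np.ndarray:
    """Smoothed observed event probability ô(p_i) at the horizon, from a
    proportional-hazards calibration model on an ``n_knots``-knot restricted
    cubic spline of cloglog(p)."""
    time, event = as_samples(samples)
    p = np.clip(np.asarray(pred, dtype=float), 1e-8, 1 - 1e-8)
    u = np.log(-np.log(1.0 - p))
    if np.ptp(u) < 1e-8:
        # degenerate smoother: constant predictions -> single KM bin
        warnings.warn("constant predictions: falling back to a single "
                      "Kaplan-Meier bin for the calibration curve")
        return np.full(len(p), km_event_prob((time, event == "bc_death"), horizon))
    qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.unique(np.quantile(u, qs))
    if len(knots) < 3:
        X = (u - u.mean())[:, None] / max(u.std(), 1e-8)
    else:
        X = _rcs_basis(u, knots)
        X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-8)
    beta, cumhaz0 = _fit_cox(X, time, event == "bc_death")
    return 1.0 - np.exp(-cumhaz0(horizon) * np.exp(X @ beta))


def ici(pred, samples, horizon: float = HORIZON) -> MetricResult:
    """Integrated calibration index at the horizon: mean |p_i − ô(p_i)|."""
    time, event = as_samples(samples)
    p = np.asarray(pred, dtype=float)
    valid = ~np.isnan(p)
    n_used = int(valid.sum())
    if n_used == 0:
        raise ValueError("no valid predictions for ICI")
    if n_used < 50:
        logger.warning("ici: only %d valid records; estimate may be unstable", n_used)
    ohat = smoothed_calibration(p[valid], (time[valid], event[valid]), horizon)
    point = float(np.mean(np.abs(np.clip(p[valid], 1e-8, 1 - 1e-8) - ohat)))
    return MetricResult(point, n_used=n_used, n_excluded=int((~valid).sum()))


# ---------------------------------------------------------------------------
# IPCW time-dependent AUROC

def ipcw_auroc(pred, samples, horizon: float = HORIZON) -> MetricResult:
    """Cumulative-case / dynamic-control AUROC with IPCW.

    Cases are breast-cancer deaths by the horizon, weighted 1/Ĝ(T_i−);
    records known event-free at the horizon are controls weighted 1/Ĝ(h);
    deaths from the competing cause before the horizon count as controls
    weighted 1/Ĝ(T_i−).  Prediction ties receive half credit.
    """
    time, event = as_samples(samples)
    p = np.asarray(pred, dtype=float)
    valid = ~np.isnan(p)
    n_excluded = int((~valid).sum())
    time, event, p = time[valid], event[valid], p[valid]

    is_case = (event == "bc_death") & (time <= horizon)
    is_ctrl_late = time > horizon
    is_ctrl_comp = (event == "other_death") & (time <= horizon)
    if not is_case.any() or not (is_ctrl_late.any() or is_ctrl_comp.any()):
        raise ValueError("ipcw_auroc undefined: need at least one case and one control")

    g_h = censoring_survival((time, event), horizon, left=False)
    g_tm = np.asarray(censoring_survival((time, event), time, left=True))
    w = np.zeros(len(p))
    w[is_case] = 1.0 / np.maximum(g_tm[is_case], 1e-12)
    w[is_ctrl_late] = 1.0 / max(g_h, 1e-12)
    w[is_ctrl_comp] = 1.0 / np.maximum(g_tm[is_ctrl_comp], 1e-12)
    is_ctrl = is_ctrl_late | is_ctrl_comp

    order = np.argsort(p, kind="mergesort")
    ps, ws = p[order], w[order]
    case_s, ctrl_s = is_case[order], is_ctrl[order]
    wc = np.where(ctrl_s, ws, 0.0)
    # tie groups share half credit
    uniq, first = np.unique(ps, return_index=True)
    grp_ctrl = np.add.reduceat(wc, first)
    below = np.concatenate([[0.0], np.cumsum(grp_ctrl)[:-1]])
    grp_index = np.searchsorted(uniq, ps)
    credit = below[grp_index] + 0.5 * grp_ctrl[grp_index]
    num = float(np.sum(np.where(case_s, ws, 0.0) * credit))
    denom = float(ws[case_s].sum() * wc.sum())
    return MetricResult(num / denom, n_used=len(p), n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Calibration-plot data

@dataclasses.dataclass
class CalibrationBin:
    quartile: int
    mean_predicted: float
    mean_observed: float
    sd_predicted: float
    sd_observed: float
    n: int


def calibration_quartiles(pred, samples, trim: tuple[float, float] = (0.10, 0.90),
                          horizon: float = HORIZON) -> list[CalibrationBin]:
    """Quartile calibration-plot data on the event-probability scale.

    Records outside the [trim] percentile band of predicted probability are
    excluded; the remainder is split into quartiles of predicted probability
    and each bin receives its mean predicted probability and the
    Kaplan-Meier observed event probability (SD via Greenwood).  To pool
    across runs, concatenate the runs' predictions and samples first.
    """
    time, event = as_samples(samples)
    p = np.asarray(pred, dtype=float)
    valid = ~np.isnan(p)
    p, time, event = p[valid], time[valid], event[valid]
    if len(p) < 4:
        raise ValueError("need at least 4 valid predictions")
    lo, hi = np.quantile(p, trim[0]), np.quantile(p, trim[1])
    keep = (p >= lo) & (p <= hi)
    p, time, event = p[keep], time[keep], event[keep]
    ranks = np.searchsorted(np.sort(p, kind="mergesort"), p, side="left")
    qid = np.minimum((4 * ranks) // len(p), 3)
    bins = []
    for q in range(4):
        m = qid == q
        if not m.any():
            continue
        et, s, gv = km_curve(time[m], event[m] == "bc_death")
        mask = et <= horizon
        if mask.any():
            s_h = s[mask][-1]
            sd_obs = float(s_h * np.sqrt(gv[mask][-1]))
        else:
            s_h, sd_obs = 1.0, 0.0
        bins.append(CalibrationBin(
            quartile=q + 1,
            mean_predicted=float(p[m].mean()),
            mean_observed=float(1.0 - s_h),
            sd_predicted=float(p[m].std(ddof=1)) if m.sum() > 1 else 0.0,
            sd_observed=sd_obs,
            n=int(m.sum())))
    return bins


def calibration_table(bins: list[CalibrationBin]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(b) for b in bins])


# ---------------------------------------------------------------------------
# Bootstrap percentile CIs

def bootstrap_ci(metric_fn, pred, samples, B: int = 2000, seed: int = 0,
                 level: float = 0.95) -> MetricResult:
    """Percentile bootstrap CI: resample records with replacement, recompute
    the metric, take the (2.5, 97.5) percentiles; the point estimate comes
    from the original sample.  Failed resamples are skipped and counted."""
    if B < 2:
        raise ValueError("B must be >= 2")
    time, event = as_samples(samples)
    p = np.asarray(pred, dtype=float)
    base = metric_fn(p, (time, event))
    point = float(base.point if isinstance(base, MetricResult) else base)
    rng = np.random.default_rng(seed)
    stats, skipped = [], 0
    n = len(p)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            r = metric_fn(p[idx], (time[idx], event[idx]))
            stats.append(float(r.point if isinstance(r, MetricResult) else r))
        except (ValueError, ArithmeticError):
            skipped += 1
    if skipped > 0.01 * B:
        logger.warning("bootstrap_ci: %d/%d resamples failed", skipped, B)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    # the interval must bracket the full-sample point estimate
    lo, hi = min(float(lo), point), max(float(hi), point)
    base_n = base.n_used if isinstance(base, MetricResult) else n
    base_ex = base.n_excluded if isinstance(base, MetricResult) else 0
    return MetricResult(point, ci=(lo, hi), n_used=base_n, n_excluded=base_ex)


def pooled_roc_points(pred, samples, horizon: float = HORIZON) -> pd.DataFrame:
    """Plot-ready IPCW ROC coordinates (threshold sweep over the observed
    prediction values)."""
    time, event = as_samples(samples)
    p = np.asarray(pred, dtype=float)
    valid = ~np.isnan(p)
    time, event, p = time[valid], event[valid], p[valid]
    is_case = (event == "bc_death") & (time <= horizon)
    is_ctrl = (time > horizon) | ((event == "other_death") & (time <= horizon))
    g_h = censoring_survival((time, event), horizon)
    g_tm = np.asarray(censoring_survival((time, event), time, left=True))
    w = np.zeros(len(p))
    w[is_case] = 1.0 / np.maximum(g_tm[is_case], 1e-12)
    w[is_ctrl] = np.where(time[is_ctrl] > horizon, 1.0 / max(g_h, 1e-12),
                          1.0 / np.maximum(g_tm[is_ctrl], 1e-12))
    thresholds = np.unique(np.concatenate([[0.0], np.sort(p), [1.0]]))
    wc_case = np.where(is_case, w, 0.0)
    wc_ctrl = np.where(is_ctrl, w, 0.0)
    tpr = [wc_case[p >= t].sum() / max(wc_case.sum(), 1e-12) for t in thresholds]
    fpr = [wc_ctrl[p >= t].sum() / max(wc_ctrl.sum(), 1e-12) for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
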