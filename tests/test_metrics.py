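"""Evaluation suite: Kaplan-Meier, ICI, IPCW AUROC, calibration bins,
bootstrap CIs — each against an independent oracle."""

import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
import pandas as pd

from prognostack import (bootstrap_ci, calibration_quartiles,
                         censoring_survival, ici, ipcw_auroc, km_survival)
from prognostack.metrics import MetricResult, _fit_cox, smoothed_calibration


def test_km_no_censoring():
    time = np.array([1, 2, 3, 6, 7, 8, 9, 10, 11, 12], dtype=float)
    event = np.full(10, "bc_death")
    assert km_survival((time, event), 5.0) == pytest.approx(0.7)


def test_km_all_censored():
    time = np.linspace(1, 10, 8)
    event = np.full(8, "censored")
    assert km_survival((time, event), 7.0) == 1.0


def test_km_hand_computed_product_limit():
    # times 1, 2+, 3, 4+, 5, 6 with events at 1, 3, 5, 6:
    # S(5) = 5/6 * 3/4 * 1/2 = 0.3125
    time = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    event = np.array(["bc_death", "censored", "bc_death", "censored",
                      "bc_death", "bc_death"])
    assert km_survival((time, event), 5.0) == pytest.approx(0.3125)


def test_km_matches_lifelines_on_random_data():
    rng = np.random.default_rng(12)
    T = rng.exponential(4, 400)
    C = rng.uniform(0, 8, 400)
    time = np.minimum(T, C)
    event = np.where(T <= C, "bc_death", "censored")
    kmf = KaplanMeierFitter().fit(time, T <= C)
    for t in (1.0, 2.5, 5.0):
        assert km_survival((time, event), t) == pytest.approx(float(kmf.predict(t)), abs=1e-10)


def test_censoring_survival_left_continuity():
    time = np.array([1.0, 2.0, 3.0])
    event = np.array(["censored", "bc_death", "censored"])
    g_at = censoring_survival((time, event), 1.0)
    g_before = censoring_survival((time, event), 1.0, left=True)
    assert g_before == 1.0 and g_at < 1.0


def test_internal_cox_matches_lifelines():
    rng = np.random.default_rng(3)
    n = 600
    X = rng.normal(size=(n, 2))
    eta = 0.7 * X[:, 0] - 0.4 * X[:, 1]
    T = rng.exponential(np.exp(-eta) * 5)
    C = rng.uniform(0, 10, n)
    time, obs = np.minimum(T, C), T <= C
    beta, _ = _fit_cox(X, time, obs)
    df = pd.DataFrame({"t": time, "e": obs, "x1": X[:, 0], "x2": X[:, 1]})
    ref = CoxPHFitter().fit(df, "t", "e").params_.values
    np.testing.assert_allclose(beta, ref, atol=1e-4)


def test_ici_perfect_calibration_near_zero(uncensored_calibrated):
    p, time, event = uncensored_calibrated
    r = ici(p, (time, event))
    assert r.point < 0.005
    assert r.n_used == len(p) and r.n_excluded == 0


def test_ici_detects_constant_shift(uncensored_calibrated):
    p, time, event = uncensored_calibrated
    r = ici(np.clip(p + 0.05, 0, 1), (time, event))
    assert r.point == pytest.approx(0.05, abs=0.012)


def test_ici_invariant_to_record_order(uncensored_calibrated):
    p, time, event = uncensored_calibrated
    perm = np.random.default_rng(0).permutation(len(p))
    assert ici(p, (time, event)).point == pytest.approx(
        ici(p[perm], (time[perm], event[perm])).point, abs=1e-12)


def test_ici_constant_predictions_fallback(uncensored_calibrated):
    p, time, event = uncensored_calibrated
    with pytest.warns(UserWarning, match="constant predictions"):
        r = ici(np.full(len(p), 0.03), (time, event))
    observed = 1 - km_survival((time, event), 5.0)
    assert r.point == pytest.approx(abs(0.03 - observed), abs=1e-9)


def test_ici_excludes_invalid_predictions(uncensored_calibrated):
    p, time, event = uncensored_calibrated
    p2 = p.copy()
    p2[:100] = np.nan
    r = ici(p2, (time, event))
    assert r.n_excluded == 100 and r.n_used == len(p) - 100


def test_ipcw_equals_pair_counting_when_uncensored():
    rng = np.random.default_rng(5)
    n = 200
    p = np.round(rng.random(n), 2)           # include ties
    T = rng.exponential(6, n)
    time, event = T, np.full(n, "bc_death")
    got = ipcw_auroc(p, (time, event)).point
    y = time <= 5.0
    num = sum((p[i] > p[j]) + 0.5 * (p[i] == p[j])
              for i in np.flatnonzero(y) for j in np.flatnonzero(~y))
    assert got == pytest.approx(num / (y.sum() * (~y).sum()), abs=1e-12)


def test_ipcw_null_and_perfect_discrimination():
    rng = np.random.default_rng(6)
    n = 4000
    T = rng.exponential(6, n)
    time, event = np.minimum(T, 20.0), np.where(T <= 20, "bc_death", "censored")
    assert ipcw_auroc(rng.random(n), (time, event)).point == pytest.approx(0.5, abs=0.03)
    perfect = np.where(T <= 5.0, 0.9, 0.1)
    assert ipcw_auroc(perfect, (time, event)).point == 1.0


def test_ipcw_matches_sksurv_under_censoring():
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv
    rng = np.random.default_rng(8)
    n = 500
    x = rng.normal(size=n)
    T = rng.exponential(np.exp(-0.8 * x) * 6)
    C = rng.uniform(1, 10, n)
    time, obs = np.minimum(T, C), T <= C
    pred = x  # risk score
    event = np.where(obs, "bc_death", "censored")
    ours = ipcw_auroc(pred, (time, event)).point
    y = Surv.from_arrays(obs, time)
    ref, _ = cumulative_dynamic_auc(y, y, pred, times=[5.0])
    assert ours == pytest.approx(float(ref[0]), abs=1e-6)


def test_ipcw_requires_both_classes():
    time = np.full(5, 1.0)
    event = np.full(5, "bc_death")
    with pytest.raises(ValueError):
        ipcw_auroc(np.linspace(0, 1, 5), (time, event))


def test_calibration_trimming_and_bins():
    p = np.round(np.linspace(0.01, 1.00, 100), 2)
    time = np.where(p > 0.5, 2.0, 9.0)
    event = np.where(p > 0.5, "bc_death", "censored")
    bins = calibration_quartiles(p, (time, event))
    assert sum(b.n for b in bins) == 80
    assert [b.quartile for b in bins] == [1, 2, 3, 4]
    assert all(b2.mean_predicted > b1.mean_predicted
               for b1, b2 in zip(bins, bins[1:]))


def test_calibration_four_records_one_per_bin():
    p = np.array([0.1, 0.2, 0.3, 0.4])
    bins = calibration_quartiles(p, (np.full(4, 6.0), np.full(4, "censored")),
                                 trim=(0.0, 1.0))
    assert [b.n for b in bins] == [1, 1, 1, 1]


def test_calibration_diagonal_when_calibrated(uncensored_calibrated):
    p, time, event = uncensored_calibrated
    bins = calibration_quartiles(p, (time, event))
    for b in bins:
        assert b.mean_observed == pytest.approx(b.mean_predicted, abs=0.02)


def test_bootstrap_constant_metric_collapses():
    p = np.linspace(0.1, 0.9, 50)
    samples = (np.full(50, 6.0), np.full(50, "censored"))
    r = bootstrap_ci(lambda *_: MetricResult(0.42), p, samples, B=25, seed=1)
    assert r.ci == (0.42, 0.42) and r.point == 0.42


def test_bootstrap_ci_orders_and_brackets(uncensored_calibrated):
    p, time, event = uncensored_calibrated
    sl = slice(0, 800)
    r = bootstrap_ci(ici, p[sl], (time[sl], event[sl]), B=60, seed=2)
    assert r.ci[0] <= r.point <= r.ci[1]


def test_bootstrap_ici_coverage_scaled_down():
    """Percentile-CI coverage for the ICI under repeated sampling from a
    known constant-shift miscalibration (scaled-down simulation: 30
    replicates, n=500, B=120; the true ICI is the 0.03 shift)."""
    rng = np.random.default_rng(42)
    hits = 0
    reps = 30
    for r in range(reps):
        n = 500
        p = rng.beta(2, 20, n)
        lam = -np.log(1 - p) / 5.0
        T = rng.exponential(1 / np.maximum(lam, 1e-12))
        time = np.minimum(T, 30.0)
        event = np.where(T <= 30, "bc_death", "censored")
        shifted = np.clip(p + 0.03, 0, 1)
        res = bootstrap_ci(ici, shifted, (time, event), B=120, seed=r)
        if res.ci[0] - 0.01 <= 0.03 <= res.ci[1] + 0.01:
            hits += 1
    assert hits / reps >= 0.8


def test_smoothed_calibration_tracks_binned_km(uncensored_calibrated):
    """The spline calibration curve agrees with decile-binned KM estimates
    on large well-behaved data."""
    p, time, event = uncensored_calibrated
    ohat = smoothed_calibration(p, (time, event))
    qs = np.quantile(p, np.linspace(0, 1, 11))
    for lo, hi in zip(qs[2:-3], qs[3:-2]):       # interior deciles
        m = (p >= lo) & (p < hi)
        km = 1 - km_survival((time[m], event[m]), 5.0)
        assert np.mean(ohat[m]) == pytest.approx(km, abs=0.02)
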