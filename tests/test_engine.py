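"""Parametric engine: assumption layer, prognostic indices, baselines,
competing-risks combination and invalid-prediction semantics."""

import numpy as np
import pytest

from prognostack import (Cohort, batch_predict, baseline_cumhaz, load_params,
                         make_scenario, predict_5y, prognostic_index,
                         survival_curve)
from prognostack.engine import apply_assumptions, _predict_frame
from conftest import make_cohort, make_record


def test_param_vector_shape(params):
    assert len(params.names) == 26
    assert len(set(params.names)) == 26
    assert set(params.groups.values()) <= {
        "baseline_bc", "baseline_oth", "covariate_bc", "covariate_oth",
        "treatment_effect"}


def test_her2_inferred_from_trastuzumab():
    rec = make_record(0, trastuzumab=True)
    out = apply_assumptions(rec, make_scenario("default"))
    assert out.extended["her2_positive"] is True or out.extended["her2_positive"] == 1
    rec2 = make_record(1, trastuzumab=False)
    out2 = apply_assumptions(rec2, make_scenario("default"))
    assert not out2.extended["her2_positive"]


def test_assumptions_do_not_touch_core_fields():
    rec = make_record(0, grade=None, pr_positive=None)
    out = apply_assumptions(rec, make_scenario("pessimistic"))
    assert out.grade is None and out.pr_positive is None


def test_scenarios_fill_same_fields():
    df = make_cohort(5, 1).df
    filled = {name: apply_assumptions(df, make_scenario(name))
              for name in ("optimistic", "default", "pessimistic")}
    for name, f in filled.items():
        assert not f[["her2_positive", "ki67_positive", "smoker"]].isna().any().any()
    # they differ only in fill values, never in which cells are filled
    assert (filled["optimistic"].isna() == filled["pessimistic"].isna()).all().all()


def test_reference_patient_has_zero_index(params):
    rec = make_record(0, age=65.0)
    pi_bc, pi_oth = prognostic_index(rec, params)
    assert pi_bc == pytest.approx(0.0, abs=1e-12)
    assert pi_oth == pytest.approx(0.0, abs=1e-12)


def test_index_linear_in_coefficients(params):
    rec = make_record(0, nodes=3)
    pi0, _ = prognostic_index(rec, params)
    doubled = params.with_shift("bc_log_nodes", params["bc_log_nodes"])
    pi1, _ = prognostic_index(rec, doubled)
    contribution = params["bc_log_nodes"] * np.log1p(3)
    assert pi1 - pi0 == pytest.approx(contribution, rel=1e-9)


def test_index_hand_evaluation(params):
    """Spreadsheet-style evaluation of the linear predictor for one record."""
    rec = make_record(0, age=55.0, nodes=2, size_mm=22.0, grade=3,
                      er_positive=True, pr_positive=False, chemotherapy=True)
    u, r = 5.5, 6.5
    expected = (params["bc_age_fp1"] * (u**-2 - r**-2)
                + params["bc_age_fp2"] * (u**-2 * np.log(u) - r**-2 * np.log(r))
                + params["bc_log_size"] * np.log(22.0 / 15.0)
                + params["bc_log_nodes"] * np.log(3.0)
                + params["bc_grade3"]
                + params["bc_pr_negative"]
                + params["tx_chemotherapy"])
    pi_bc, _ = prognostic_index(rec, params)
    assert pi_bc == pytest.approx(expected, rel=1e-9)


def test_baseline_cumhaz_identities():
    t = np.array([0.5, 1.0, 2.0, 5.0])
    # single ln t term with unit coefficient -> H0(t) = t
    np.testing.assert_allclose(baseline_cumhaz(t, [0.0, 1.0], ["intercept", "log"]), t)
    # intercept shift scales multiplicatively
    h0 = baseline_cumhaz(t, [-2.0, 1.3], ["intercept", "log"])
    h1 = baseline_cumhaz(t, [-1.5, 1.3], ["intercept", "log"])
    np.testing.assert_allclose(h1, h0 * np.exp(0.5))
    with pytest.raises(ValueError):
        baseline_cumhaz([0.0], [1.0], ["intercept"])
    with pytest.raises(ValueError):
        baseline_cumhaz([1.0], [1.0], ["p4"])   # outside the FP family


def test_shipped_baselines_nondecreasing(params):
    grid = np.arange(1, 6, dtype=float)
    for cause in ("bc", "oth"):
        names = params.group_names(f"baseline_{cause}")
        h = baseline_cumhaz(grid, [params[n] for n in names], params.basis[cause])
        assert (np.diff(h) >= 0).all()


def test_missing_mandatory_input_yields_invalid(params):
    res = predict_5y(make_record(0, grade=None), params)
    assert res.status == "invalid" and res.invalid_reason == ["grade"]
    res2 = predict_5y(make_record(1, grade=None, size_mm=None), params)
    assert res2.invalid_reason == ["grade", "size_mm"]


def test_single_risk_limit(params):
    """With the other-cause hazard switched off, the annual-grid combination
    collapses to 1 − exp(−H_bc(5))."""
    v = params.values.copy()
    for name in params.group_names("baseline_oth"):
        v[params.names.index(name)] = -50.0 if "intercept" in name else 0.0
    p2 = params.replace_values(v)
    rec = make_record(0, nodes=4, size_mm=30.0, grade=3)
    res = predict_5y(rec, p2)
    pi_bc, _ = prognostic_index(rec, p2)
    names = p2.group_names("baseline_bc")
    h5 = baseline_cumhaz(np.array([5.0]), [p2[n] for n in names], p2.basis["bc"])[0]
    assert res.p_bc_death_5y == pytest.approx(1 - np.exp(-h5 * np.exp(pi_bc)), abs=1e-9)


def test_predict_matches_annual_grid_hand_computation(params):
    """Year-by-year spreadsheet evaluation of the competing-risks
    apportionment for a toy record."""
    rec = make_record(0, age=58.0, nodes=1, size_mm=18.0, grade=2)
    scenario = make_scenario()
    df = apply_assumptions(Cohort.from_records([rec]).df, scenario)
    pi_bc, pi_oth = prognostic_index(df, params)
    bc_names = params.group_names("baseline_bc")
    oth_names = params.group_names("baseline_oth")
    H_bc_prev = H_oth_prev = 0.0
    S_prev, F = 1.0, 0.0
    for j in range(1, 6):
        H_bc = baseline_cumhaz(np.array([float(j)]), [params[n] for n in bc_names],
                               params.basis["bc"])[0] * np.exp(pi_bc[0])
        H_oth = baseline_cumhaz(np.array([float(j)]), [params[n] for n in oth_names],
                                params.basis["oth"])[0] * np.exp(pi_oth[0])
        d_bc, d_oth = H_bc - H_bc_prev, H_oth - H_oth_prev
        d = d_bc + d_oth
        F += S_prev * (1 - np.exp(-d)) * (d_bc / d)
        S_prev *= np.exp(-d)
        H_bc_prev, H_oth_prev = H_bc, H_oth
    res = predict_5y(rec, params)
    assert res.p_bc_death_5y == pytest.approx(F, abs=1e-12)


def test_curve_conservation_and_monotonicity(params):
    rec = make_record(0, age=70.0, nodes=5, size_mm=35.0, grade=3)
    c = survival_curve(rec, params)
    np.testing.assert_allclose(c.F_bc + c.F_oth + c.S_all, 1.0, atol=1e-9)
    assert (np.diff(c.F_bc) >= 0).all() and (np.diff(c.S_all) <= 0).all()


@pytest.mark.parametrize("field,values", [("nodes", [0, 1, 3, 8, 15]),
                                          ("size_mm", [5.0, 10.0, 20.0, 40.0, 80.0])])
def test_risk_monotone_in_burden(params, field, values):
    preds = [predict_5y(make_record(i, **{field: v}), params).p_bc_death_5y
             for i, v in enumerate(values)]
    assert all(b > a for a, b in zip(preds, preds[1:]))


def test_batch_predict_invalid_fractions(params, ma27_complete):
    out = batch_predict(ma27_complete, params)
    assert out.attrs["invalid_fraction"] == 0.0
    assert out["p_bc_death_5y"].between(0, 1).all()
    nosize = Cohort(ma27_complete.df.assign(size_mm=np.nan).iloc[:50])
    out2 = batch_predict(nosize, params)
    assert out2.attrs["invalid_fraction"] == 1.0
    assert (out2["invalid_reason"] == "size_mm").all()


def test_default_missingness_invalid_band(params, ma27_small):
    out = batch_predict(ma27_small, params)
    assert 0.19 <= out.attrs["invalid_fraction"] <= 0.32


def test_scenarios_bracket_default(params, ma27_complete):
    """Optimistic and pessimistic fills bracket the default predictions for
    records affected by the fills."""
    sub = Cohort(ma27_complete.df.iloc[:300])
    p = {name: batch_predict(sub, params, make_scenario(name))["p_bc_death_5y"].to_numpy()
         for name in ("optimistic", "default", "pessimistic")}
    assert (p["optimistic"] <= p["default"] + 1e-12).all()
    assert (p["pessimistic"] >= p["default"] - 1e-12).all()
    assert (p["pessimistic"] > p["optimistic"]).mean() > 0.95
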