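"""Parametric competing-risks prognostic engine.

Re-implementation of a pretrained fractional-polynomial competing-risks
survival model for 5-year breast-cancer mortality: cause-specific prognostic
indices (breast-cancer death and other-cause death), fractional-polynomial
baseline cumulative hazards, an annual-grid competing-risks combination, a
dataset-level assumption layer for inputs the source cohort never recorded,
and explicit invalid-prediction semantics when mandatory record-level inputs
are missing.

The engine is fully configurable through a JSON parameter file carrying the
26 named parameters, the fractional-polynomial basis of each cause's
baseline, and the mandatory-input list.  The repository ships a documented
stand-in parameter set (``params/standin_v1.json``) with plausible effect
magnitudes and correct signs; externally published coefficient sets in the
same dialect load identically.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord

N_PARAMS = 26
GROUPS = ("baseline_bc", "baseline_oth", "covariate_bc", "covariate_oth",
          "treatment_effect")

#: Fractional-polynomial powers allowed for baseline time transforms.
FP_POWERS = (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 3.0)

_REF_AGE_U = 6.5  # reference age 65, on the age/10 scale


@dataclasses.dataclass
class ParamVector:
    """The pretrained model's 26 named parameters, their group assignment,
    the baseline basis, and the mandatory-input list."""

    names: list[str]
    values: np.ndarray
    groups: dict[str, str]                 # name -> group
    basis: dict[str, list[str]]            # cause -> basis term labels
    mandatory_inputs: list[str]
    version: str = "unversioned"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != N_PARAMS or len(self.values) != N_PARAMS:
            raise ValueError(f"parameter vector must have exactly {N_PARAMS} entries")
        if len(set(self.names)) != N_PARAMS:
            raise ValueError("parameter names must be unique")
        bad = {g for g in self.groups.values()} - set(GROUPS)
        if bad or set(self.groups) != set(self.names):
            raise ValueError("every parameter must belong to exactly one known group")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def replace_values(self, values: np.ndarray) -> "ParamVector":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float).copy())

    def with_shift(self, name: str, delta: float) -> "ParamVector":
        v = self.values.copy()
        v[self.names.index(name)] += delta
        return self.replace_values(v)

    def group_names(self, group: str) -> list[str]:
        return [n for n in self.names if self.groups[n] == group]

    def to_dict(self) -> dict:
        return {
            "format": "prognostack-params",
            "version": self.version,
            "basis": self.basis,
            "mandatory_inputs": self.mandatory_inputs,
            "parameters": [{"name": n, "group": self.groups[n], "value": float(v)}
                           for n, v in zip(self.names, self.values)],
        }

    def save(self, path, provenance: Mapping | None = None) -> None:
        d = self.to_dict()
        if provenance:
            d["provenance"] = dict(provenance)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def load_params(path=None) -> ParamVector:
    """Load a parameter file; with no argument, the shipped stand-in set."""
    if path is None:
        text = (resources.files("prognostack") / "params/standin_v1.json").read_text()
        d = json.loads(text)
    else:
        with open(path) as fh:
            d = json.load(fh)
    names = [p["name"] for p in d["parameters"]]
    return ParamVector(
        names=names,
        values=np.array([p["value"] for p in d["parameters"]], dtype=float),
        groups={p["name"]: p["group"] for p in d["parameters"]},
        basis={k: list(v) for k, v in d["basis"].items()},
        mandatory_inputs=list(d["mandatory_inputs"]),
        version=str(d.get("version", "unversioned")),
    )


# ---------------------------------------------------------------------------
# Assumption layer

@dataclasses.dataclass
class AssumptionScenario:
    """Constant fills (or simple rules) for model inputs that the dataset
    never recorded.  Fills apply only where the extended input is missing;
    record-level missing *mandatory* inputs are never filled."""

    name: str
    fills: dict

    def __post_init__(self):
        recognized = {"her2_positive", "ki67_positive", "screen_detected",
                      "smoker", "year_of_diagnosis", "micrometastases",
                      "chemo_generation", "bisphosphonates", "heart_dose_category"}
        unknown = set(self.fills) - recognized
        if unknown:
            raise ValueError(f"assumption fills target unknown inputs: {sorted(unknown)}")


#: ``her2_positive`` uses a rule, not a constant: inferred positive when
#: trastuzumab was given, otherwise the scenario's fallback constant.
HER2_FROM_TRASTUZUMAB = "her2_from_trastuzumab"

_SCENARIOS = {
    "default": {
        "her2_positive": HER2_FROM_TRASTUZUMAB,
        "ki67_positive": False, "screen_detected": False, "smoker": False,
        "year_of_diagnosis": 2003, "micrometastases": False,
        "chemo_generation": 2, "bisphosphonates": False,
        "heart_dose_category": 1,
    },
    "optimistic": {
        "her2_positive": HER2_FROM_TRASTUZUMAB,
        "ki67_positive": False, "screen_detected": True, "smoker": False,
        "year_of_diagnosis": 2003, "micrometastases": False,
        "chemo_generation": 3, "bisphosphonates": True,
        "heart_dose_category": 0,
    },
    "pessimistic": {
        "her2_positive": HER2_FROM_TRASTUZUMAB,
        "ki67_positive": True, "screen_detected": False, "smoker": True,
        "year_of_diagnosis": 2003, "micrometastases": True,
        "chemo_generation": 1, "bisphosphonates": False,
        "heart_dose_category": 2,
    },
}


def make_scenario(name: str = "default") -> AssumptionScenario:
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    return AssumptionScenario(name=name, fills=dict(_SCENARIOS[name]))


def apply_assumptions(data, scenario: AssumptionScenario):
    """Fill dataset-level-absent extended inputs per scenario.

    Accepts a :class:`PatientRecord` (returns a record) or a DataFrame in
    cohort layout (returns a filled copy).  Core covariates are untouched:
    a record-level missing mandatory input stays missing and will surface as
    an invalid prediction downstream.
    """
    if isinstance(data, PatientRecord):
        df = Cohort.from_records([data]).df
        out = apply_assumptions(df, scenario)
        from .cohort import record_from_row
        return record_from_row(out.iloc[0])
    df = data.copy()
    for field, fill in scenario.fills.items():
        if field not in df.columns:
            df[field] = pd.NA
        missing = df[field].isna()
        if not missing.any():
            continue
        if fill == HER2_FROM_TRASTUZUMAB:
            tras = df["trastuzumab"].fillna(False).astype(bool)
            df.loc[missing, field] = tras[missing]
        elif field == "heart_dose_category":
            # a heart dose only exists where radiotherapy was given
            radio = df["radiotherapy"].fillna(False).astype(bool)
            df.loc[missing, field] = np.where(radio[missing], fill, 0)
        else:
            df.loc[missing, field] = fill
    return df


# ---------------------------------------------------------------------------
# Linear predictors

def _col(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        return np.full(len(df), np.nan)
    return pd.to_numeric(df[name], errors="coerce").astype(float).to_numpy()


def _bool_col(df: pd.DataFrame, name: str, default: float = 0.0) -> np.ndarray:
    x = _col(df, name)
    return np.where(np.isnan(x), default, x)


def design_terms(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Covariate transforms entering the prognostic indices.  All transforms
    are centered so that a reference patient (age 65, 15 mm, node-negative,
    grade 1, ER+/PR+, no treatment, no extended risk factors) has index 0."""
    age = _col(df, "age")
    u = age / 10.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fp1 = u ** -2.0 - _REF_AGE_U ** -2.0
        fp2 = u ** -2.0 * np.log(u) - _REF_AGE_U ** -2.0 * np.log(_REF_AGE_U)
        log_size = np.log(_col(df, "size_mm") / 15.0)
    grade = _col(df, "grade")
    radio = _bool_col(df, "radiotherapy")
    heart = _bool_col(df, "heart_dose_category") * radio
    return {
        "bc_age_fp1": fp1,
        "bc_age_fp2": fp2,
        "bc_log_size": log_size,
        "bc_log_nodes": np.log1p(_col(df, "nodes")),
        "bc_grade2": (grade == 2).astype(float) + np.where(np.isnan(grade), np.nan, 0.0),
        "bc_grade3": (grade == 3).astype(float) + np.where(np.isnan(grade), np.nan, 0.0),
        "bc_er_negative": 1.0 - _col(df, "er_positive"),
        # optional covariates: record-level missing -> reference level 0
        "bc_pr_negative": 1.0 - _bool_col(df, "pr_positive", default=1.0),
        "bc_her2_positive": _bool_col(df, "her2_positive"),
        "bc_ki67_positive": _bool_col(df, "ki67_positive"),
        "bc_screen_detected": _bool_col(df, "screen_detected"),
        "bc_micrometastases": _bool_col(df, "micrometastases"),
        "oth_age_dec": (age - 65.0) / 10.0,
        "oth_smoker": _bool_col(df, "smoker"),
        "oth_heart_dose": heart,
        "oth_year_offset": np.where(np.isnan(_col(df, "year_of_diagnosis")), 0.0,
                                    _col(df, "year_of_diagnosis") - 2003.0),
        "tx_chemotherapy": _bool_col(df, "chemotherapy"),
        "tx_trastuzumab": _bool_col(df, "trastuzumab"),
        "tx_radiotherapy": radio,
        "tx_bisphosphonates": _bool_col(df, "bisphosphonates"),
    }


def missing_mandatory(df: pd.DataFrame, params: ParamVector) -> pd.DataFrame:
    """Boolean frame (records x mandatory inputs) of record-level absences."""
    out = {}
    for field in params.mandatory_inputs:
        out[field] = df[field].isna() if field in df.columns else np.ones(len(df), bool)
    return pd.DataFrame(out, index=df.index)


def prognostic_index(data, params: ParamVector):
    """Cause-specific linear predictors (pi_bc, pi_oth).

    For a DataFrame returns two float arrays with NaN where a mandatory
    input is missing (the invalid-prediction condition — not an exception).
    For a single extended :class:`PatientRecord`, returns a scalar pair.
    """
    if isinstance(data, PatientRecord):
        pi_bc, pi_oth = prognostic_index(Cohort.from_records([data]).df, params)
        return float(pi_bc[0]), float(pi_oth[0])
    terms = design_terms(data)
    n = len(data)
    pi_bc = np.zeros(n)
    pi_oth = np.zeros(n)
    for name, value in zip(params.names, params.values):
        group = params.groups[name]
        if group in ("baseline_bc", "baseline_oth"):
            continue
        x = terms[name]
        x = np.where(np.isnan(x), 0.0, x) if group != "covariate_bc" else x
        if group == "covariate_oth":
            pi_oth = pi_oth + value * x
        else:  # covariate_bc and treatment_effect act on the bc hazard
            pi_bc = pi_bc + value * x
    invalid = missing_mandatory(data, params).any(axis=1).to_numpy()
    pi_bc = np.where(invalid, np.nan, pi_bc)
    pi_oth = np.where(invalid, np.nan, pi_oth)
    return pi_bc, pi_oth


# ---------------------------------------------------------------------------
# Baselines and competing-risks combination

def _basis_value(term: str, t: np.ndarray) -> np.ndarray:
    if term == "intercept":
        return np.ones_like(t)
    if term == "log":
        return np.log(t)
    if term.startswith("p"):
        p = float(term[1:])
        if p not in FP_POWERS:
            raise ValueError(f"power {p} outside the fractional-polynomial family")
        return t ** p
    raise ValueError(f"unknown basis term {term!r}")


def baseline_cumhaz(t, coeffs: Iterable[float], basis: Iterable[str]) -> np.ndarray:
    """Fractional-polynomial baseline cumulative hazard
    H0(t) = exp(Σ_k c_k · b_k(t)) with b_k drawn from the powers
    {−2,−1,−0.5,0.5,1,2,3} or ln t."""
    t = np.asarray(t, dtype=float)
    if (t <= 0).any():
        raise ValueError("baseline cumulative hazard requires t > 0")
    coeffs = list(coeffs)
    basis = list(basis)
    if len(coeffs) != len(basis):
        raise ValueError("one coefficient per basis term required")
    log_h = np.zeros_like(t)
    for c, term in zip(coeffs, basis):
        log_h = log_h + c * _basis_value(term, t)
    return np.exp(log_h)


@dataclasses.dataclass
class SurvivalCurve:
    """Annual-grid competing-risks decomposition over years 1..5."""

    years: np.ndarray
    H_bc: np.ndarray
    H_oth: np.ndarray
    S_all: np.ndarray
    F_bc: np.ndarray
    F_oth: np.ndarray


@dataclasses.dataclass
class PredictionResult:
    """A 5-year breast-cancer-death probability or an explicit INVALID marker."""

    status: str                      # "valid" | "invalid"
    p_bc_death_5y: float | None = None
    p_surv_5y: float | None = None
    invalid_reason: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        if self.status == "valid":
            assert self.p_bc_death_5y is not None and not self.invalid_reason
        elif self.status == "invalid":
            assert self.p_bc_death_5y is None and self.invalid_reason
        else:
            raise ValueError(f"unknown status {self.status!r}")


def _curve_arrays(pi_bc: np.ndarray, pi_oth: np.ndarray, params: ParamVector,
                  horizon: int = 5):
    """Vectorized annual-grid combination.  Per year j the cause-specific
    increments ΔH are apportioned proportionally within the all-cause death
    mass S(j−1)(1 − exp(−ΣΔH))."""
    years = np.arange(1, horizon + 1, dtype=float)
    h0_bc = baseline_cumhaz(years, [params[n] for n in params.group_names("baseline_bc")],
                            params.basis["bc"])
    h0_oth = baseline_cumhaz(years, [params[n] for n in params.group_names("baseline_oth")],
                             params.basis["oth"])
    H_bc = np.outer(np.exp(pi_bc), h0_bc)          # (n, horizon)
    H_oth = np.outer(np.exp(pi_oth), h0_oth)
    dH_bc = np.diff(np.concatenate([np.zeros((len(H_bc), 1)), H_bc], axis=1), axis=1)
    dH_oth = np.diff(np.concatenate([np.zeros((len(H_oth), 1)), H_oth], axis=1), axis=1)
    dH = dH_bc + dH_oth
    S = np.exp(-(H_bc + H_oth))
    S_prev = np.concatenate([np.ones((len(S), 1)), S[:, :-1]], axis=1)
    death_mass = S_prev * (1.0 - np.exp(-dH))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_bc = np.where(dH > 0, dH_bc / dH, 0.0)
    F_bc = np.cumsum(death_mass * frac_bc, axis=1)
    F_oth = np.cumsum(death_mass * (1.0 - frac_bc), axis=1)
    # telescoping: F_bc + F_oth = 1 - S exactly, so conservation holds
    S_all = 1.0 - F_bc - F_oth
    return years, H_bc, H_oth, S_all, F_bc, F_oth


def survival_curve(record: PatientRecord, params: ParamVector,
                   scenario: AssumptionScenario | None = None) -> SurvivalCurve:
    scenario = scenario or make_scenario()
    df = apply_assumptions(Cohort.from_records([record]).df, scenario)
    pi_bc, pi_oth = prognostic_index(df, params)
    if np.isnan(pi_bc[0]):
        miss = missing_mandatory(df, params).iloc[0]
        raise ValueError(f"record {record.id}: mandatory inputs missing: "
                         f"{sorted(miss[miss].index)}")
    years, H_bc, H_oth, S_all, F_bc, F_oth = _curve_arrays(pi_bc, pi_oth, params)
    return SurvivalCurve(years=years, H_bc=H_bc[0], H_oth=H_oth[0],
                         S_all=S_all[0], F_bc=F_bc[0], F_oth=F_oth[0])


def predict_5y(record: PatientRecord, params: ParamVector,
               scenario: AssumptionScenario | None = None) -> PredictionResult:
    """5-year breast-cancer-death probability for one patient, or an invalid
    result naming the missing mandatory inputs."""
    scenario = scenario or make_scenario()
    df = apply_assumptions(Cohort.from_records([record]).df, scenario)
    p, invalid, reasons = _predict_frame(df, params)
    if invalid[0]:
        return PredictionResult(status="invalid", invalid_reason=reasons[0])
    return PredictionResult(status="valid", p_bc_death_5y=float(p[0]),
                            p_surv_5y=1.0 - float(p[0]))


def _predict_frame(df: pd.DataFrame, params: ParamVector, horizon: int = 5):
    """Vectorized prediction on an assumption-filled frame.  Returns
    (probabilities with NaN at invalid rows, invalid mask, per-row reasons)."""
    pi_bc, pi_oth = prognostic_index(df, params)
    invalid = np.isnan(pi_bc)
    missing = missing_mandatory(df, params)
    reasons = [sorted(missing.columns[missing.iloc[i]]) if invalid[i] else []
               for i in range(len(df))]
    p = np.full(len(df), np.nan)
    if (~invalid).any():
        _, _, _, _, F_bc, _ = _curve_arrays(pi_bc[~invalid], pi_oth[~invalid],
                                            params, horizon)
        p[~invalid] = F_bc[:, -1]
    return p, invalid, reasons


def batch_predict(cohort: Cohort, params: ParamVector,
                  scenario: AssumptionScenario | None = None) -> pd.DataFrame:
    """Element-wise 5-year prediction over a cohort.

    Returns a frame (id, status, p_bc_death_5y, invalid_reason) whose
    ``attrs["invalid_fraction"]`` records the share of invalid predictions.
    """
    scenario = scenario or make_scenario()
    df = apply_assumptions(cohort.df, scenario)
    p, invalid, reasons = _predict_frame(df, params)
    out = pd.DataFrame({
        "id": cohort.df["id"].to_numpy(),
        "status": np.where(invalid, "invalid", "valid"),
        "p_bc_death_5y": p,
        "invalid_reason": [";".join(r) for r in reasons],
    })
    out.attrs["invalid_fraction"] = float(invalid.mean())
    return out


def predictions_to_results(frame: pd.DataFrame) -> list[PredictionResult]:
    out = []
    for _, row in frame.iterrows():
        if row["status"] == "valid":
            out.append(PredictionResult("valid", float(row["p_bc_death_5y"]),
                                        1.0 - float(row["p_bc_death_5y"])))
        else:
            out.append(PredictionResult("invalid",
                                        invalid_reason=row["invalid_reason"].split(";")))
    return out
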