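"""Patient cohorts: domain types, CSV I/O, stratified splitting, summaries,
and optional outcome-rebalancing utilities.

A :class:`Cohort` wraps a :class:`pandas.DataFrame` with one row per patient
and a fixed set of typed clinicopathological columns.  Missing covariate
values are first-class (``pd.NA``); follow-up time and the event code are
never missing.  Records with zero follow-up are rejected at load time,
mirroring the usual trial convention that patients must be followed beyond
the day of enrollment.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized event codes.  ``bc_death`` is the event of interest (death from
#: breast cancer); ``other_death`` is the competing cause; everything else is
#: administratively censored.
EVENT_CODES = ("censored", "bc_death", "other_death")

LATERALITY_CODES = ("left", "right", "bilateral")

#: Canonical covariate columns, in order.  Booleans use pandas' nullable
#: ``boolean`` dtype so that missingness is explicit.
CORE_COLUMNS: dict[str, str] = {
    "id": "string",
    "age": "float64",
    "nodes": "Int64",
    "laterality": "string",
    "er_positive": "boolean",
    "pr_positive": "boolean",
    "size_mm": "Float64",
    "grade": "Int64",
    "radiotherapy": "boolean",
    "chemotherapy": "boolean",
    "trastuzumab": "boolean",
    "time_years": "float64",
    "event": "string",
}

#: Optional extended inputs used by the parametric engine's assumption layer.
EXTENDED_COLUMNS: dict[str, str] = {
    "her2_positive": "boolean",
    "ki67_positive": "boolean",
    "screen_detected": "boolean",
    "smoker": "boolean",
    "year_of_diagnosis": "Int64",
    "micrometastases": "boolean",
    "chemo_generation": "Int64",
    "bisphosphonates": "boolean",
    "heart_dose_category": "Int64",
}

#: Plausibility bounds applied at load time.
BOUNDS = {"age": (18.0, 110.0), "nodes": (0, 60), "size_mm": (0.1, 300.0)}


class SchemaError(ValueError):
    """Raised for malformed input files or unrecognized codes."""


@dataclasses.dataclass
class PatientRecord:
    """One patient's covariates, follow-up and event code."""

    id: str
    age: float
    time_years: float
    event: str
    nodes: int | None = None
    laterality: str | None = None
    er_positive: bool | None = None
    pr_positive: bool | None = None
    size_mm: float | None = None
    grade: int | None = None
    radiotherapy: bool | None = None
    chemotherapy: bool | None = None
    trastuzumab: bool | None = None
    extended: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.time_years <= 0:
            raise ValueError(f"record {self.id}: time_years must be > 0")
        if self.event not in EVENT_CODES:
            raise SchemaError(f"record {self.id}: unknown event code {self.event!r}")

    def to_row(self) -> dict:
        row = {k: getattr(self, k) for k in CORE_COLUMNS}
        for k in EXTENDED_COLUMNS:
            row[k] = self.extended.get(k, None)
        return row


class Cohort:
    """An ordered collection of patient records backed by a DataFrame."""

    def __init__(self, df: pd.DataFrame, provenance: str = "unknown",
                 schema_version: str = "1"):
        if len(df) == 0:
            raise ValueError("cohort must be non-empty")
        df = _coerce_types(df.copy())
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate patient id {dup!r}")
        _validate(df)
        self.df = df.reset_index(drop=True)
        self.provenance = provenance
        self.schema_version = schema_version

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        n_ev = int((self.df["event"] == "bc_death").sum())
        return (f"Cohort(n={len(self)}, bc_deaths={n_ev}, "
                f"provenance={self.provenance!r})")

    @classmethod
    def from_records(cls, records: Iterable[PatientRecord], provenance: str = "memory") -> "Cohort":
        rows = [r.to_row() for r in records]
        return cls(pd.DataFrame(rows), provenance=provenance)

    def records(self) -> list[PatientRecord]:
        out = []
        for _, row in self.df.iterrows():
            out.append(record_from_row(row))
        return out

    def subset(self, mask_or_index, provenance: str | None = None) -> "Cohort":
        sub = self.df.loc[mask_or_index]
        return Cohort(sub, provenance=provenance or self.provenance,
                      schema_version=self.schema_version)

    def event_indicator(self, horizon: float = 5.0) -> np.ndarray:
        """Binary breast-cancer-death-by-horizon indicator (events after the
        horizon count as non-events)."""
        df = self.df
        return ((df["event"] == "bc_death") & (df["time_years"] <= horizon)).to_numpy()


def record_from_row(row: pd.Series) -> PatientRecord:
    def _opt(key):
        v = row.get(key, None)
        return None if v is None or pd.isna(v) else v

    extended = {k: _opt(k) for k in EXTENDED_COLUMNS if _opt(k) is not None}
    return PatientRecord(
        id=str(row["id"]), age=float(row["age"]),
        time_years=float(row["time_years"]), event=str(row["event"]),
        nodes=None if pd.isna(row.get("nodes")) else int(row["nodes"]),
        laterality=_opt("laterality"),
        er_positive=_opt("er_positive"), pr_positive=_opt("pr_positive"),
        size_mm=None if pd.isna(row.get("size_mm")) else float(row["size_mm"]),
        grade=None if pd.isna(row.get("grade")) else int(row["grade"]),
        radiotherapy=_opt("radiotherapy"), chemotherapy=_opt("chemotherapy"),
        trastuzumab=_opt("trastuzumab"), extended=extended)


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    for col, dtype in {**CORE_COLUMNS, **EXTENDED_COLUMNS}.items():
        if col not in df.columns:
            if col in CORE_COLUMNS and col in ("id", "age", "time_years", "event"):
                raise SchemaError(f"mandatory column {col!r} absent")
            df[col] = pd.Series([pd.NA] * len(df), dtype=dtype)
        else:
            try:
                if dtype == "boolean":
                    df[col] = _to_boolean(df[col])
                elif dtype in ("Int64",):
                    df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
                elif dtype in ("Float64",):
                    df[col] = pd.to_numeric(df[col], errors="raise").astype("Float64")
                elif dtype == "float64":
                    df[col] = pd.to_numeric(df[col], errors="raise").astype("float64")
                else:
                    df[col] = df[col].astype("string")
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"column {col!r}: {exc}") from exc
    order = list(CORE_COLUMNS) + list(EXTENDED_COLUMNS)
    extra = [c for c in df.columns if c not in order]
    return df[order + extra]


def _to_boolean(s: pd.Series) -> pd.Series:
    if s.dtype == bool or str(s.dtype) == "boolean":
        return s.astype("boolean")
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False, "t": True, "f": False}
    out = []
    for v in s:
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            out.append(pd.NA)
        elif isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        elif isinstance(v, (int, float, np.integer, np.floating)):
            out.append(bool(int(v)))
        else:
            key = str(v).strip().lower()
            if key in ("", "na", "nan", "none"):
                out.append(pd.NA)
            elif key in mapping:
                out.append(mapping[key])
            else:
                raise SchemaError(f"unrecognized boolean value {v!r}")
    return pd.Series(out, dtype="boolean", index=s.index)


def _validate(df: pd.DataFrame) -> None:
    if (df["time_years"] <= 0).any():
        bad = df.loc[df["time_years"] <= 0, "id"].iloc[0]
        raise ValueError(f"record {bad!r}: time_years must be > 0")
    unknown = set(df["event"].dropna()) - set(EVENT_CODES)
    if unknown:
        raise SchemaError(f"unknown event code(s): {sorted(unknown)}")
    if df["event"].isna().any():
        raise SchemaError("event code may not be missing")
    lat = set(df["laterality"].dropna()) - set(LATERALITY_CODES)
    if lat:
        raise SchemaError(f"unknown laterality code(s): {sorted(lat)}")
    for col, (lo, hi) in BOUNDS.items():
        vals = df[col].dropna()
        if len(vals) and ((vals < lo) | (vals > hi)).any():
            raise ValueError(f"column {col!r} outside plausibility bounds [{lo}, {hi}]")
    grades = df["grade"].dropna()
    if len(grades) and (~grades.isin([1, 2, 3])).any():
        raise SchemaError("grade must be in {1,2,3}")


# ---------------------------------------------------------------------------
# CSV I/O

def read_cohort(path, schema: Mapping | None = None, provenance: str | None = None) -> Cohort:
    """Read a cohort from CSV.

    ``schema`` may provide ``columns`` (a file-column → canonical-name map),
    ``event_codes`` (file-value → canonical event code), and
    ``size_unit`` ("mm", the default, or "cm" for automatic conversion).
    Empty cells and "NA" are missing.  Rows with non-positive follow-up are
    dropped and counted in the log.
    """
    schema = dict(schema or {})
    try:
        raw = pd.read_csv(path, dtype="object", keep_default_na=False,
                          na_values=["", "NA", "NaN", "nan"])
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed CSV {path}: {exc}") from exc
    colmap = schema.get("columns", {})
    raw = raw.rename(columns=dict(colmap))
    for col in ("id", "time_years", "event"):
        if col not in raw.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    event_map = schema.get("event_codes", {})
    if event_map:
        bad = set(raw["event"].dropna()) - set(event_map)
        if bad:
            raise SchemaError(f"event code(s) {sorted(bad)} not in schema mapping")
        raw["event"] = raw["event"].map(event_map)
    else:
        bad = set(raw["event"].dropna()) - set(EVENT_CODES)
        if bad:
            raise SchemaError(f"unknown event code(s) in {path}: {sorted(bad)}")
    if schema.get("size_unit", "mm") == "cm" and "size_mm" in raw.columns:
        raw["size_mm"] = pd.to_numeric(raw["size_mm"], errors="raise") * 10.0

    raw["time_years"] = pd.to_numeric(raw["time_years"], errors="raise")
    n_drop = int((raw["time_years"] <= 0).sum())
    if n_drop:
        logger.info("read_cohort(%s): excluded %d record(s) with time-to-event <= 0",
                    path, n_drop)
        raw = raw[raw["time_years"] > 0]
    if len(raw) == 0:
        raise ValueError(f"{path}: no records with positive follow-up")
    return Cohort(raw, provenance=provenance or str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV with empty cells for missing values."""
    df = cohort.df.copy()
    for col, dtype in {**CORE_COLUMNS, **EXTENDED_COLUMNS}.items():
        if dtype == "boolean":
            df[col] = df[col].map({True: "true", False: "false"})
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Splitting

@dataclasses.dataclass
class SplitSpec:
    """Proportions for a stratified random partition of a cohort.

    Stratification is on the binary breast-cancer-death-by-horizon indicator.
    Within each stratum the first k−1 partitions receive
    ``floor(fraction * stratum size)`` records each and the last partition
    receives the remainder, so partitions are exhaustive.
    """

    fractions: Sequence[float]
    seed: int = 0
    horizon: float = 5.0

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if len(f) == 0 or (f <= 0).any() or (f > 1).any():
            raise ValueError("each fraction must lie in (0, 1]")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError(f"fractions must sum to 1, got {f.sum()}")


def stratified_split(cohort: Cohort, spec: SplitSpec) -> list[Cohort]:
    """Split a cohort into outcome-stratified random partitions.

    Reproducible under ``spec.seed``; the union of the partitions is a
    permutation of the input.
    """
    fractions = list(spec.fractions)
    rng = np.random.default_rng(spec.seed)
    strata = cohort.event_indicator(spec.horizon)
    parts: list[list[np.ndarray]] = [[] for _ in fractions]
    for value in (False, True):
        idx = np.flatnonzero(strata == value)
        if len(idx) == 0:
            continue
        idx = rng.permutation(idx)
        sizes = [int(np.floor(f * len(idx))) for f in fractions[:-1]]
        sizes.append(len(idx) - sum(sizes))
        start = 0
        for k, size in enumerate(sizes):
            parts[k].append(idx[start:start + size])
            start += size
    out = []
    for k, chunks in enumerate(parts):
        idx = np.concatenate(chunks) if chunks else np.array([], dtype=int)
        if len(idx) == 0:
            raise ValueError(f"partition {k} received no records; "
                             "fractions too fine for this cohort")
        out.append(cohort.subset(cohort.df.index[np.sort(idx)],
                                 provenance=f"{cohort.provenance}/part{k}"))
    return out


# ---------------------------------------------------------------------------
# Summaries

def summarize(cohort: Cohort, horizon: float = 5.0) -> pd.DataFrame:
    """Descriptive summary: median/IQR for continuous variables, counts and
    percentages (excluding missing values) for categorical ones."""
    df = cohort.df
    rows = []

    def cont(name, series):
        s = pd.to_numeric(series, errors="coerce").dropna().astype(float)
        if len(s) == 0:
            rows.append((name, "median (IQR)", np.nan, np.nan, np.nan))
            return
        rows.append((name, "median (IQR)", float(s.median()),
                     float(s.quantile(0.25)), float(s.quantile(0.75))))

    def cat(name, mask_series):
        obs = mask_series.dropna()
        n, k = len(obs), int(obs.sum()) if len(obs) else 0
        pct = 100.0 * k / n if n else np.nan
        rows.append((name, "n (%)", k, pct, np.nan))

    cont("age", df["age"])
    cont("size_cm", df["size_mm"].astype("Float64") / 10.0)
    cont("follow_up_years", df["time_years"])
    nodes = df["nodes"].dropna()
    for label, lo, hi in (("N0", 0, 0), ("N1", 1, 3), ("N2", 4, 9), ("N3", 10, 10**6)):
        k = int(((nodes >= lo) & (nodes <= hi)).sum())
        pct = 100.0 * k / len(nodes) if len(nodes) else np.nan
        rows.append((f"nodal_{label}", "n (%)", k, pct, np.nan))
    grades = df["grade"].dropna()
    for g in (1, 2, 3):
        k = int((grades == g).sum())
        pct = 100.0 * k / len(grades) if len(grades) else np.nan
        rows.append((f"grade_{g}", "n (%)", k, pct, np.nan))
    for name in ("er_positive", "pr_positive", "radiotherapy",
                 "chemotherapy", "trastuzumab"):
        cat(name, df[name])
    ev = cohort.event_indicator(horizon)
    rows.append(("bc_death_by_horizon", "n (%)", int(ev.sum()),
                 100.0 * ev.mean(), np.nan))
    return pd.DataFrame(rows, columns=["variable", "statistic", "value", "q25_or_pct", "q75"])


# ---------------------------------------------------------------------------
# Rebalancing (off by default throughout the pipeline)

def oversample_events(cohort: Cohort, target_event_fraction: float,
                      perturbation: float = 0.0, seed: int = 0,
                      horizon: float = 5.0) -> Cohort:
    """Random oversampling of event records until the event fraction meets
    the target.  Continuous covariates of duplicated rows may be jittered by
    a Gaussian with relative scale ``perturbation``.  Outcome labels are
    never altered."""
    ev = cohort.event_indicator(horizon)
    n, n_ev = len(cohort), int(ev.sum())
    if n_ev == 0:
        raise ValueError("cannot oversample a cohort with no events")
    current = n_ev / n
    if target_event_fraction <= current:
        logger.warning("oversample_events: target %.3f not above current %.3f; "
                       "returning input unchanged", target_event_fraction, current)
        return cohort
    # after adding k copies: (n_ev + k) / (n + k) >= target
    t = target_event_fraction
    k = int(np.ceil((t * n - n_ev) / (1.0 - t)))
    rng = np.random.default_rng(seed)
    pick = rng.choice(np.flatnonzero(ev), size=k, replace=True)
    dup = cohort.df.iloc[pick].copy()
    dup["id"] = [f"{v}_os{j}" for j, v in enumerate(dup["id"])]
    if perturbation > 0:
        for col in ("age", "size_mm"):
            vals = pd.to_numeric(dup[col], errors="coerce").astype(float)
            scale = perturbation * np.nanstd(pd.to_numeric(cohort.df[col], errors="coerce").astype(float))
            noise = rng.normal(0.0, scale if np.isfinite(scale) and scale > 0 else 0.0, len(dup))
            jittered = vals + np.where(np.isnan(vals), 0.0, noise)
            lo, hi = BOUNDS["age"] if col == "age" else BOUNDS["size_mm"]
            dup[col] = pd.array(np.clip(jittered, lo, hi), dtype=cohort.df[col].dtype)
    out = pd.concat([cohort.df, dup], ignore_index=True)
    return Cohort(out, provenance=f"{cohort.provenance}/oversampled")


def case_weights(cohort: Cohort, scheme: str = "none", horizon: float = 5.0) -> np.ndarray:
    """Per-record weights: ``none`` → all 1; ``inverse_prevalence`` → events
    weighted n/(2·n_event), non-events n/(2·n_nonevent)."""
    n = len(cohort)
    if scheme == "none":
        return np.ones(n)
    if scheme == "inverse_prevalence":
        ev = cohort.event_indicator(horizon)
        n_ev = int(ev.sum())
        if n_ev == 0 or n_ev == n:
            raise ValueError("inverse_prevalence weights need both classes present")
        w = np.where(ev, n / (2.0 * n_ev), n / (2.0 * (n - n_ev)))
        return w
    raise ValueError(f"unknown weighting scheme {scheme!r}")
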