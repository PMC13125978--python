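"""Cohort I/O, stratified splitting, summaries and rebalancing."""

import math

import numpy as np
import pandas as pd
import pytest

from prognostack import (Cohort, SplitSpec, case_weights, oversample_events,
                         read_cohort, stratified_split, summarize, write_cohort)
from prognostack.cohort import SchemaError
from conftest import make_cohort, make_record


def test_csv_round_trip(tmp_path):
    cohort = make_cohort(10, 3)
    path = tmp_path / "c.csv"
    write_cohort(cohort, path)
    back = read_cohort(path)
    assert len(back) == 10
    pd.testing.assert_frame_equal(back.df, cohort.df, check_dtype=False)
    # summaries identical after the round trip
    pd.testing.assert_frame_equal(summarize(back), summarize(cohort))


def test_zero_followup_rows_dropped(tmp_path, caplog):
    cohort = make_cohort(5, 1)
    path = tmp_path / "c.csv"
    write_cohort(cohort, path)
    text = path.read_text().replace("p4,60.0", "p4x,60.0").splitlines()
    # append a record with zero follow-up
    extra = text[1].replace("p0", "pz").replace("2.0", "0.0")
    path.write_text("\n".join(text + [extra]) + "\n")
    with caplog.at_level("INFO"):
        back = read_cohort(path)
    assert len(back) == 5
    assert any("excluded 1" in r.message for r in caplog.records)


def test_unknown_event_code_rejected(tmp_path):
    cohort = make_cohort(4, 1)
    path = tmp_path / "c.csv"
    write_cohort(cohort, path)
    path.write_text(path.read_text().replace("bc_death", "dead"))
    with pytest.raises(SchemaError):
        read_cohort(path)


def test_cm_to_mm_schema_conversion(tmp_path):
    cohort = make_cohort(3, 1, size_mm=15.0)
    path = tmp_path / "c.csv"
    df = cohort.df.copy()
    df["size_mm"] = 1.5  # written in cm
    Cohort(df).df.to_csv(path, index=False)
    back = read_cohort(path, schema={"size_unit": "cm"})
    assert (back.df["size_mm"] == 15.0).all()


def test_duplicate_ids_rejected():
    df = make_cohort(3, 1).df.copy()
    df.loc[2, "id"] = df.loc[0, "id"]
    with pytest.raises(ValueError, match="duplicate"):
        Cohort(df)


def _floor_rule(n_stratum, fractions):
    sizes = [math.floor(f * n_stratum) for f in fractions[:-1]]
    return sizes + [n_stratum - sum(sizes)]


def test_split_reproduces_published_partition_sizes():
    """The per-stratum floor rule on 7563 records with 187 events at 80/20
    yields exactly 6049 development and 1514 validation records."""
    n, n_ev = 7563, 187
    recs = [make_record(i, event="bc_death", time_years=2.0) for i in range(n_ev)]
    recs += [make_record(i + n_ev) for i in range(n - n_ev)]
    cohort = Cohort.from_records(recs)
    dev, val = stratified_split(cohort, SplitSpec((0.8, 0.2), seed=0))
    assert (len(dev), len(val)) == (6049, 1514)


@pytest.mark.parametrize("fractions", [(1.0,), (0.6, 0.2, 0.2), (0.8, 0.2)])
def test_split_matches_floor_rule_and_partitions(fractions):
    cohort = make_cohort(10, 2)
    parts = stratified_split(cohort, SplitSpec(fractions, seed=3))
    ev_sizes = _floor_rule(2, fractions)
    non_sizes = _floor_rule(8, fractions)
    for part, ne, nn in zip(parts, ev_sizes, non_sizes):
        assert int(part.event_indicator().sum()) == ne
        assert len(part) == ne + nn
    ids = sorted(i for p in parts for i in p.df["id"])
    assert ids == sorted(cohort.df["id"])


def test_split_seed_reproducible_and_disjoint():
    cohort = make_cohort(40, 8)
    a1 = stratified_split(cohort, SplitSpec((0.6, 0.2, 0.2), seed=9))
    a2 = stratified_split(cohort, SplitSpec((0.6, 0.2, 0.2), seed=9))
    b = stratified_split(cohort, SplitSpec((0.6, 0.2, 0.2), seed=10))
    for p1, p2 in zip(a1, a2):
        assert list(p1.df["id"]) == list(p2.df["id"])
    assert any(list(p1.df["id"]) != list(p3.df["id"]) for p1, p3 in zip(a1, b))
    seen = [i for p in a1 for i in p.df["id"]]
    assert len(seen) == len(set(seen)) == 40


def test_invalid_fractions_rejected():
    with pytest.raises(ValueError):
        SplitSpec((0.5, 0.4))
    with pytest.raises(ValueError):
        SplitSpec((1.2, -0.2))


def test_summarize_median_age_and_pr_share():
    recs = [make_record(0, age=60.0), make_record(1, age=64.0), make_record(2, age=70.0)]
    table = summarize(Cohort.from_records(recs))
    med = table.loc[table.variable == "age", "value"].iloc[0]
    assert med == 64.0
    # PR missing in 1 of 4; 2 of the remaining 3 positive -> 66.7%
    recs = [make_record(i, pr_positive=v) for i, v in
            enumerate([True, True, False, None])]
    table = summarize(Cohort.from_records(recs))
    row = table.loc[table.variable == "pr_positive"].iloc[0]
    assert row["value"] == 2
    assert row["q25_or_pct"] == pytest.approx(66.7, abs=0.05)


def test_summarize_matches_generator_targets(ma27_small):
    table = summarize(ma27_small).set_index("variable")
    assert table.loc["age", "value"] == pytest.approx(64.2, abs=1.5)
    assert table.loc["nodal_N0", "q25_or_pct"] == pytest.approx(71.9, abs=4.0)
    assert table.loc["size_cm", "value"] == pytest.approx(1.5, abs=0.15)


def test_oversample_counts_and_labels():
    cohort = make_cohort(100, 2)
    out = oversample_events(cohort, 0.5, seed=1)
    ev = out.event_indicator()
    assert ev.mean() >= 0.5 - 1.0 / len(out)
    assert abs(len(out) - 196) <= 2
    # original records retained, labels never altered
    assert set(cohort.df["id"]) <= set(out.df["id"])
    dup = out.df[out.df["id"].str.contains("_os")]
    assert (dup["event"] == "bc_death").all()


def test_oversample_exact_copies_without_perturbation():
    cohort = make_cohort(20, 4)
    out = oversample_events(cohort, 0.5, perturbation=0.0, seed=2)
    dup = out.df[out.df["id"].str.contains("_os")]
    src = cohort.df[cohort.df["event"] == "bc_death"].iloc[0]
    assert (dup["age"] == src["age"]).all() and (dup["size_mm"] == src["size_mm"]).all()


def test_oversample_noop_and_errors():
    cohort = make_cohort(10, 5)
    assert oversample_events(cohort, 0.5, seed=0) is cohort
    with pytest.raises(ValueError):
        oversample_events(make_cohort(5, 0), 0.5)


def test_case_weights():
    cohort = make_cohort(10, 1)
    assert (case_weights(cohort, "none") == 1.0).all()
    w = case_weights(cohort, "inverse_prevalence")
    ev = cohort.event_indicator()
    assert w[ev][0] == pytest.approx(5.0)
    assert w[~ev][0] == pytest.approx(10 / 18, abs=1e-9)
    assert w.sum() == pytest.approx(10.0)
    with pytest.raises(ValueError):
        case_weights(make_cohort(5, 0), "inverse_prevalence")
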