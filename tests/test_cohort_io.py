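"""Cohort CSV round-trip, validation, summary and complete-case filtering."""

import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

from rionntcp.cohort import (Cohort, complete_case_filter, covariate_frame,
                             read_cohort, summarize_cohort, write_cohort)
from rionntcp.stats import fisher_exact_test, rank_sum_test

from conftest import make_record


def test_round_trip_identity(toy_cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    write_cohort(toy_cohort, path)
    back = read_cohort(path)
    assert back.n == toy_cohort.n
    for a, b in zip(toy_cohort, back):
        for field in a.__dataclass_fields__:
            assert getattr(a, field) == getattr(b, field), field


def test_round_trip_preserves_missing_token(toy_cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    write_cohort(toy_cohort, path)
    text = path.read_text()
    assert "NA" in text
    back = read_cohort(path)
    assert back.records[3].hypertension is None
    assert back.records[7].hypertension is None


def test_empty_cohort_round_trip(tmp_path):
    path = tmp_path / "empty.csv"
    write_cohort(Cohort([], provenance="empty"), path)
    assert read_cohort(path).n == 0


def test_row_below_dose_inclusion_rejected(tmp_path):
    recs = [make_record("A"), make_record("B", optic_dmax=40.0, optic_d1=38.0,
                                          optic_dmean=30.0)]
    path = tmp_path / "c.csv"
    write_cohort(Cohort(recs), path)
    back = read_cohort(path)
    assert back.n == 1
    (row, reasons), = back.meta["rejected_rows"]
    assert row == 1
    assert any("45" in r for r in reasons)


def test_missing_required_column_raises(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("patient_id,age\nP1,50\n")
    with pytest.raises(KeyError):
        read_cohort(path)


def test_summary_counts_sum_to_n(toy_cohort):
    summary = summarize_cohort(toy_cohort)
    for var, entry in summary.entries.items():
        if entry["kind"] == "categorical":
            assert sum(c for _, c, _ in entry["counts"]) == toy_cohort.n, var


def test_summary_degenerate_range():
    recs = [make_record(f"P{i}", age=47.0) for i in range(5)]
    s = summarize_cohort(Cohort(recs))
    e = s.entries["age"]
    assert e["median"] == e["min"] == e["max"] == 47.0


def test_grouped_summary_has_p_values(toy_cohort):
    s = summarize_cohort(toy_cohort, group_by_institution=True)
    assert 0 <= s.entries["age"]["p_value"] <= 1
    assert 0 <= s.entries["sex"]["p_value"] <= 1


def test_rank_sum_exact_complete_separation():
    # n=3 vs 3, fully separated: 2 of the 20 equally likely rank splits are
    # as extreme, so the exact two-sided p is 0.1
    assert rank_sum_test([1, 2, 3], [101, 102, 103]) == pytest.approx(0.1)


def test_fisher_matches_hypergeometric_enumeration():
    # two-sided Fisher on 2x2 equals summing hypergeometric probabilities of
    # tables no more probable than observed, for all margins here
    rng = np.random.default_rng(5)
    for _ in range(30):
        a, b, c, d = rng.integers(0, 9, size=4)
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        n = a + b + c + d
        dist = hypergeom(n, a + b, a + c)
        p_obs = dist.pmf(a)
        expected = sum(dist.pmf(k) for k in range(max(0, a + c - c - d), min(a + b, a + c) + 1)
                       if dist.pmf(k) <= p_obs * (1 + 1e-9))
        assert fisher_exact_test(np.array([[a, b], [c, d]])) == pytest.approx(expected, rel=1e-8)


def test_complete_case_filter_counts():
    recs = [make_record(f"P{i}", hypertension=None if i < 16 else "no")
            for i in range(289)]
    filtered = complete_case_filter(Cohort(recs), ["hypertension"])
    assert filtered.n == 273


def test_complete_case_filter_identity_and_empty(toy_cohort):
    assert complete_case_filter(toy_cohort, []).n == toy_cohort.n
    recs = [make_record(f"P{i}", hypertension=None) for i in range(4)]
    assert complete_case_filter(Cohort(recs), ["hypertension"]).n == 0


def test_complete_case_filter_idempotent_monotone(toy_cohort):
    once = complete_case_filter(toy_cohort, ["hypertension"])
    twice = complete_case_filter(once, ["hypertension"])
    assert [r.patient_id for r in once] == [r.patient_id for r in twice]
    superset = complete_case_filter(toy_cohort, ["hypertension", "age"])
    ids_once = {r.patient_id for r in once}
    assert {r.patient_id for r in superset} <= ids_once


def test_unknown_variable_raises(toy_cohort):
    with pytest.raises(KeyError):
        complete_case_filter(toy_cohort, ["not_a_field"])


def test_covariate_frame_encoding(toy_cohort):
    frame = covariate_frame(toy_cohort)
    assert frame.loc["P000", "rion"] == 1.0
    assert frame.loc["P001", "rion"] == 0.0
    assert np.isnan(frame.loc["P003", "hypertension"])
    assert frame.loc["P000", "sex"] == 1.0
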