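"""Risk-group segmentation and threshold sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rionntcp.cohort import Cohort
from rionntcp.stats import FittedLogisticModel
from rionntcp.stratification import (DEFAULT_GRID, stratify, threshold_sweep)

from conftest import make_record


def _score_cohort(scores, outcomes):
    """Cohort whose NTCP under the identity-on-age model equals ``scores``.

    Uses a logit-linear model over an auxiliary age covariate so arbitrary
    probability vectors can be realized exactly.
    """
    recs = []
    for i, (s, y) in enumerate(zip(scores, outcomes)):
        # choose age so that sigmoid(age - 50) == s under beta=(−50, 1)
        age = 50.0 + np.log(s / (1 - s))
        recs.append(make_record(f"P{i:04d}", age=max(age, 18.0),
                                rion_grade=1 if y else 0))
    model = FittedLogisticModel(["age"], np.array([-50.0, 1.0]),
                                log_likelihood=-1.0, n_obs=len(recs), n_params=2)
    return model, Cohort(recs)


def test_separable_toy_perfect_classification():
    model, cohort = _score_cohort([0.02, 0.07, 0.10, 0.03], [0, 1, 1, 0])
    s = stratify(model, cohort, 0.06)
    assert (s.sensitivity, s.specificity) == (1.0, 1.0)
    assert (s.tp, s.fp, s.tn, s.fn) == (2, 0, 2, 0)


def test_boundary_thresholds():
    model, cohort = _score_cohort([0.02, 0.07, 0.10, 0.03], [0, 1, 1, 0])
    low = stratify(model, cohort, 1e-9)
    assert low.sensitivity == 1.0 and low.specificity == 0.0
    assert low.proportion_high == 1.0
    high = stratify(model, cohort, 1 - 1e-9)
    assert high.proportion_high == 0.0 and high.specificity == 1.0


def test_threshold_equality_is_high_risk():
    model, cohort = _score_cohort([0.06, 0.02], [1, 0])
    s = stratify(model, cohort, 0.06)
    # due to float solving the first score is within 1e-12 of 0.06; nudge
    t = float(s.ntcp[0])
    s2 = stratify(model, cohort, t)
    assert bool(s2.high_risk[0])


def test_invalid_threshold():
    model, cohort = _score_cohort([0.1, 0.2], [1, 0])
    with pytest.raises(ValueError):
        stratify(model, cohort, 0.0)


def test_missing_covariate_excluded():
    recs = [make_record("A", hypertension="yes"), make_record("B", hypertension=None,
                                                              rion_grade=1)]
    model = FittedLogisticModel(["hypertension"], np.array([-2.0, 1.0]),
                                log_likelihood=-1.0, n_obs=2, n_params=2)
    s = stratify(model, Cohort(recs), 0.1)
    assert s.excluded_ids == ["B"]
    assert s.n == 1


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_confusion_identities_and_monotone_sweep(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 60))
    scores = rng.uniform(0.005, 0.3, size=n)
    outcomes = rng.integers(0, 2, size=n)
    model, cohort = _score_cohort(scores, outcomes)
    grid = np.linspace(0.01, 0.25, 13)
    rows = threshold_sweep(model, cohort, grid)
    prev_prop, prev_sens, prev_spec = 2.0, 2.0, -1.0
    for row in rows:
        total = row["tp"] + row["fp"] + row["tn"] + row["fn"]
        assert total == n
        assert row["tp"] + row["fn"] == outcomes.sum()
        assert row["proportion_high"] <= prev_prop + 1e-12
        if not np.isnan(row["sensitivity"]):
            assert row["sensitivity"] <= prev_sens + 1e-12
            prev_sens = row["sensitivity"]
        if not np.isnan(row["specificity"]):
            assert row["specificity"] >= prev_spec - 1e-12
            prev_spec = row["specificity"]
        prev_prop = row["proportion_high"]


def test_sweep_single_point_equals_stratify():
    model, cohort = _score_cohort([0.02, 0.07, 0.10, 0.03], [0, 1, 1, 0])
    row, = threshold_sweep(model, cohort, np.array([0.06]))
    s = stratify(model, cohort, 0.06)
    assert (row["tp"], row["fp"], row["tn"], row["fn"]) == (s.tp, s.fp, s.tn, s.fn)


def test_default_grid_spans_one_to_twenty_percent():
    assert DEFAULT_GRID[0] == pytest.approx(0.01)
    assert DEFAULT_GRID[-1] == pytest.approx(0.20)
    steps = np.diff(DEFAULT_GRID)
    assert np.allclose(steps, 0.005)
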