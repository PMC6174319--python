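"""Left-truncated Kaplan-Meier, log-rank, conditioning, and RMST."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flosskit import (
    ConditioningError,
    SurvivalCurve,
    SurvivalRecord,
    condition_curve,
    km_left_truncated,
    logrank,
    rmst,
)


def rec(entry, exit_, event, label=""):
    return SurvivalRecord(entry, exit_, event, label)


def brute_force_km(records):
    """Enumerate risk sets record by record: the independent oracle."""
    times = sorted({r.exit_age for r in records if r.event})
    surv = []
    s = 1.0
    for t in times:
        at_risk = sum(1 for r in records if r.entry_age < t <= r.exit_age)
        deaths = sum(1 for r in records if r.event and r.exit_age == t)
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    return times, surv


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_hand_oracle_with_common_entry():
    """Entries at 80; deaths at 81, 83, 86 with a censoring at 84 give
    survival 0.75, 0.50, 0.0 (risk sets 4, 3, 1)."""
    records = [
        rec(80, 81, True),
        rec(80, 83, True),
        rec(80, 84, False),
        rec(80, 86, True),
    ]
    curve = km_left_truncated(records)
    assert curve.ages.tolist() == [81, 83, 86]
    np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.0])
    assert curve.evaluate(80.5) == 1.0
    assert curve.evaluate(84) == 0.5


def test_km_single_event_steps_to_zero():
    curve = km_left_truncated([rec(0, 5, True)])
    assert curve.evaluate(4.9) == 1.0
    assert curve.evaluate(5.0) == 0.0


def test_km_staggered_entry_matches_brute_force():
    records = [
        rec(80, 85, True),
        rec(82, 83, True),  # enters after the first record, dies early
        rec(82, 90, False),
        rec(84, 88, True),
        rec(80, 86, False),
    ]
    curve = km_left_truncated(records)
    times, surv = brute_force_km(records)
    assert curve.ages.tolist() == times
    np.testing.assert_allclose(curve.survival, surv)


@settings(deadline=None, max_examples=200)
@given(
    raw=st.lists(
        st.tuples(
            st.integers(0, 6),  # entry
            st.integers(1, 8),  # duration
            st.booleans(),
        ),
        min_size=1,
        max_size=10,
    )
)
def test_km_exhaustive_oracle_small_records(raw):
    """On every generated set of <= 10 records the vectorized estimator
    equals direct risk-set enumeration."""
    records = [rec(e, e + d, ev) for e, d, ev in raw]
    curve = km_left_truncated(records)
    times, surv = brute_force_km(records)
    assert curve.ages.tolist() == times
    np.testing.assert_allclose(curve.survival, surv, atol=1e-12)


def test_km_no_entry_and_no_censoring_is_empirical_survival():
    rng = np.random.default_rng(3)
    exits = rng.integers(1, 30, 20).astype(float)
    curve = km_left_truncated([rec(0, x, True) for x in exits])
    for t in np.arange(0, 31, 0.5):
        assert curve.evaluate(t) == pytest.approx((exits > t).mean(), abs=1e-12)


def test_km_against_lifelines_with_delayed_entry():
    """Independent cross-check: lifelines' KaplanMeierFitter with entry."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(8)
    entry = rng.uniform(0, 3, 200)
    exit_ = entry + rng.exponential(5, 200)
    event = rng.random(200) < 0.8
    curve = km_left_truncated(
        [rec(e, x, bool(v)) for e, x, v in zip(entry, exit_, event)]
    )
    kmf = lifelines.KaplanMeierFitter()
    kmf.fit(exit_, event_observed=event, entry=entry)
    ours = curve.evaluate(curve.ages)
    theirs = kmf.survival_function_at_times(curve.ages).to_numpy()
    np.testing.assert_allclose(ours, theirs, atol=1e-10)


def test_km_discards_zero_length_records_with_warning():
    with pytest.warns(UserWarning, match="zero-length"):
        curve = km_left_truncated([rec(5, 5, True), rec(0, 9, True)])
    assert curve.ages.tolist() == [9]


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_toy_two_group_oracle():
    """Deaths at {1,2} vs {3,4}: O-E = 7/6, V = 17/36, so the chi-square is
    49/17 = 2.8824 with p about 0.0896."""
    a = [rec(0, 1, True), rec(0, 2, True)]
    b = [rec(0, 3, True), rec(0, 4, True)]
    res = logrank(a, b)
    assert res.statistic == pytest.approx(49 / 17, abs=5e-5)
    assert res.df == 1
    assert res.p_value == pytest.approx(0.0896, abs=2e-3)


def test_logrank_identical_groups_and_label_symmetry():
    a = [rec(0, 2, True), rec(0, 5, False), rec(0, 7, True)]
    res = logrank(a, list(a))
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    b = [rec(0, 3, True), rec(0, 4, True), rec(0, 9, False)]
    assert logrank(a, b).statistic == pytest.approx(logrank(b, a).statistic)


def test_logrank_no_events_warns_and_returns_null():
    with pytest.warns(UserWarning, match="no events"):
        res = logrank([rec(0, 2, False)], [rec(0, 3, False)])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_logrank_single_event_time_closed_form():
    """With all deaths at one age the statistic reduces to the standard
    2x2 hypergeometric chi-square."""
    a = [rec(0, 5, True)] * 3 + [rec(0, 9, False)] * 2
    b = [rec(0, 9, False)] * 5
    res = logrank(a, b)
    # t=5: n=10, n_a=5, d=3; O-E = 3 - 1.5; V = 3*.5*.5*7/9
    expected = 1.5**2 / (3 * 0.25 * 7 / 9)
    assert res.statistic == pytest.approx(expected, rel=1e-12)


def test_logrank_against_lifelines_without_truncation():
    lifelines = pytest.importorskip("lifelines")
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(12)
    xa = rng.exponential(5, 80)
    xb = rng.exponential(7, 90)
    ea = rng.random(80) < 0.85
    eb = rng.random(90) < 0.85
    ours = logrank(
        [rec(0, x, bool(v)) for x, v in zip(xa, ea)],
        [rec(0, x, bool(v)) for x, v in zip(xb, eb)],
    )
    theirs = logrank_test(xa, xb, event_observed_A=ea, event_observed_B=eb)
    assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)
    assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-9)


# ---------------------------------------------------------------------------
# conditioning and RMST
# ---------------------------------------------------------------------------

def _step_curve(ages, survival, start=0.0):
    n = len(ages)
    return SurvivalCurve(
        np.asarray(ages, float),
        np.asarray(survival, float),
        np.zeros(n),
        np.zeros(n),
        start_age=start,
    )


def test_condition_curve_rescales_and_restricts():
    curve = _step_curve([70, 80, 90], [0.8, 0.5, 0.25])
    cond = condition_curve(curve, 80)
    assert cond.start_age == 80
    assert cond.ages.tolist() == [90]
    assert cond.evaluate(85) == pytest.approx(1.0)
    assert cond.evaluate(90) == pytest.approx(0.5)
    # output is itself a valid survival curve (invariants enforced in ctor)
    assert cond.survival.max() <= 1.0


def test_condition_at_first_age_is_identity():
    curve = _step_curve([70, 80], [0.5, 0.25], start=60)
    cond = condition_curve(curve, 60)
    np.testing.assert_allclose(cond.survival, curve.survival)


def test_condition_at_zero_survival_errors():
    curve = _step_curve([70], [0.0])
    with pytest.raises(ConditioningError):
        condition_curve(curve, 75)


def test_conditioning_equals_estimating_on_late_entrants():
    """For records entering at or after the conditioning age, rescaling the
    pooled curve equals estimating directly on those records."""
    records = [
        rec(80, 84, True),
        rec(81, 88, True),
        rec(80, 86, False),
        rec(83, 91, True),
    ]
    direct = km_left_truncated(records)
    cond = condition_curve(direct, 80)
    np.testing.assert_allclose(cond.evaluate(direct.ages), direct.evaluate(direct.ages))


def test_rmst_rectangle_and_step():
    flat = _step_curve([], [], start=80)
    assert rmst(flat, 80, 90) == pytest.approx(10.0)
    step = _step_curve([85], [0.5], start=80)
    assert rmst(step, 80, 90) == pytest.approx(7.5)


def test_rmst_window_guards():
    step = _step_curve([85], [0.5], start=80)
    with pytest.raises(ValueError):
        rmst(step, 90, 85)
    with pytest.raises(ValueError):
        rmst(step, 70, 90)


@settings(deadline=None, max_examples=100)
@given(
    drops=st.lists(st.floats(0.01, 0.3), min_size=1, max_size=8),
    shrink=st.floats(0.1, 1.0),
)
def test_rmst_monotone_under_pointwise_dominance(drops, shrink):
    """Scaling a survival curve down pointwise can only decrease its RMST."""
    surv = np.cumprod(1.0 - np.asarray(drops))
    ages = 80 + np.arange(1, len(drops) + 1, dtype=float)
    hi = _step_curve(ages, surv, start=80)
    lo = _step_curve(ages, surv * shrink, start=80)
    assert rmst(lo, 80, 95) <= rmst(hi, 80, 95) + 1e-12
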