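"""Unit and property tests for the four chart evaluators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scanspc import (
    ChartFamily,
    ChartSpec,
    QuarterlySeries,
    bernoulli_cusum_evaluate,
    cusum_weights,
    evaluate,
    ewma_evaluate,
    pchart_evaluate,
    run_length,
    wb_cusum_evaluate,
)
from conftest import make_series


# ---------------------------------------------------------------------------
# series container
# ---------------------------------------------------------------------------


def test_series_validation_rejects_bad_counts():
    with pytest.raises(ValueError):
        QuarterlySeries(n=[26, 26], x=[27, 0])
    with pytest.raises(ValueError):
        QuarterlySeries(n=[26], x=[-1])
    with pytest.raises(ValueError):
        QuarterlySeries(n=[2, 2], x=[1, 1], stream_events=[1, 0, 0, 0], stream_periods=[1, 1, 2, 2])


def test_series_csv_round_trip(tmp_path):
    s = make_series([3, 0, 5], practice_id="P01", quarter_labels=["2014Q1", "2014Q2", "2014Q3"])
    path = tmp_path / "series.csv"
    s.to_csv(path)
    back = QuarterlySeries.from_csv(path)
    assert np.array_equal(back.n, s.n)
    assert np.array_equal(back.x, s.x)
    assert back.practice_id == "P01"
    assert list(back.quarter_labels) == list(s.quarter_labels)


# ---------------------------------------------------------------------------
# p-chart
# ---------------------------------------------------------------------------


def test_pchart_closed_form_limit_and_strict_signal():
    # p0=0.5, n=25, L=3: UCL = 0.5 + 3*sqrt(0.25/25) = 0.8
    s = make_series([21, 20], n=25)
    res = pchart_evaluate(s, p0=0.5, L=3.0)
    assert res.ucl == pytest.approx([0.8, 0.8])
    assert res.signal.tolist() == [True, False]  # 0.84 > 0.8 signals; 0.80 does not
    assert res.first_signal_period == 1


def test_pchart_all_zero_counts_never_signal(design):
    s = make_series(np.zeros(20, dtype=int))
    res = pchart_evaluate(s, p0=design["p0"], L=3.0)
    assert not res.signal.any()
    assert run_length(res) is None


def test_pchart_zero_volume_period_skipped():
    s = QuarterlySeries(n=[26, 0, 26], x=[1, 0, 1])
    res = pchart_evaluate(s, p0=0.059, L=3.0)
    assert res.skipped.tolist() == [False, True, False]
    assert not res.signal[1]
    assert np.isnan(res.ucl[1])


def test_pchart_two_sided_lower_signal():
    s = make_series([0], n=100)
    res = pchart_evaluate(s, p0=0.5, L=3.0, sidedness="two_sided")
    assert res.signal[0]


# ---------------------------------------------------------------------------
# CUSUM weights
# ---------------------------------------------------------------------------


def test_cusum_weights_reference_design(design):
    w_event, w_nonevent = cusum_weights(design["p0"], design["p1"])
    assert w_event == pytest.approx(math.log(0.114 / 0.059))
    assert w_event == pytest.approx(0.6587, abs=1e-4)
    assert w_nonevent == pytest.approx(math.log(0.886 / 0.941))
    assert w_nonevent == pytest.approx(-0.0602, abs=1e-4)


def test_cusum_weights_reverse_shift_flips_signs():
    we, wn = cusum_weights(0.114, 0.059)
    assert we < 0 < wn


def test_cusum_weights_degenerate_design_rejected():
    with pytest.raises(ValueError):
        cusum_weights(0.5, 0.5)


# ---------------------------------------------------------------------------
# weighted binomial CUSUM
# ---------------------------------------------------------------------------


def test_wb_cusum_zero_floor_absorbs_quiet_series(design):
    s = make_series(np.zeros(15, dtype=int))
    res = wb_cusum_evaluate(s, design["p0"], design["p1"], h=2.0)
    assert np.all(res.statistic == 0.0)
    assert run_length(res) is None


def test_wb_cusum_single_period_crossing(design):
    we, wn = cusum_weights(design["p0"], design["p1"])
    x = 10
    increment = x * we + (26 - x) * wn
    s = make_series([x])
    res = wb_cusum_evaluate(s, design["p0"], design["p1"], h=increment - 1e-9)
    assert res.first_signal_period == 1
    res2 = wb_cusum_evaluate(s, design["p0"], design["p1"], h=increment + 1e-9)
    assert res2.first_signal_period is None


def test_wb_cusum_par_score_display_statistic():
    # x_t == n_t * p0 exactly: observed-minus-expected stays at zero
    s = make_series([13, 13, 13], n=26)
    res = wb_cusum_evaluate(s, p0=0.5, p1=0.7, h=5.0)
    assert res.display_statistic == pytest.approx([0.0, 0.0, 0.0])


def test_wb_cusum_rejects_nonpositive_h(design):
    with pytest.raises(ValueError):
        wb_cusum_evaluate(make_series([0]), design["p0"], design["p1"], h=0.0)


# ---------------------------------------------------------------------------
# Bernoulli CUSUM
# ---------------------------------------------------------------------------


def test_bernoulli_cusum_quiet_stream_stays_at_zero(design):
    events = np.zeros(52, dtype=int)
    periods = np.repeat([1, 2], 26)
    res = bernoulli_cusum_evaluate(events, design["p0"], design["p1"], h=2.0, periods=periods)
    assert np.all(res.stream_statistic == 0.0)
    assert run_length(res) is None


def test_bernoulli_cusum_consecutive_events_to_cross(design):
    # w_event ~ 0.6587, h=2: ceil(2/0.6587) = 4 consecutive events needed
    we, _ = cusum_weights(design["p0"], design["p1"])
    assert math.ceil(2.0 / we) == 4
    events = np.array([1, 1, 1, 1] + [0] * 22)
    periods = np.ones(26, dtype=int)
    res = bernoulli_cusum_evaluate(events, design["p0"], design["p1"], h=2.0, periods=periods)
    assert np.flatnonzero(res.stream_signal)[0] == 3  # 4th patient
    short = events.copy()
    short[3] = 0
    res2 = bernoulli_cusum_evaluate(short, design["p0"], design["p1"], h=2.0, periods=periods)
    assert not res2.stream_signal.any()


def test_bernoulli_alarm_maps_to_containing_quarter(design):
    # alarm at patient 53 of a fixed-26-per-quarter stream -> quarter 3
    we, _ = cusum_weights(design["p0"], design["p1"])
    events = np.zeros(78, dtype=int)
    events[49:53] = 1  # patients 50..53 are events; crossing at patient 53
    periods = np.repeat([1, 2, 3], 26)
    res = bernoulli_cusum_evaluate(events, design["p0"], design["p1"], h=4 * we - 1e-9, periods=periods)
    assert np.flatnonzero(res.stream_signal)[0] == 52
    assert run_length(res) == 3 == math.ceil(53 / 26)


@given(
    outcomes=st.lists(st.integers(0, 1), min_size=1, max_size=60),
    p0=st.floats(0.02, 0.4),
    shift=st.floats(1.2, 4.0),
    h=st.floats(0.2, 6.0),
)
@settings(max_examples=60, deadline=None)
def test_wb_cusum_with_unit_periods_equals_bernoulli(outcomes, p0, shift, h):
    """With n_t = 1 the aggregated and per-patient CUSUMs coincide exactly."""
    p1 = min(0.95, p0 * shift)
    x = np.asarray(outcomes)
    series = QuarterlySeries(n=np.ones(x.size, dtype=int), x=x)
    wb = wb_cusum_evaluate(series, p0, p1, h)
    bern = bernoulli_cusum_evaluate(x, p0, p1, h, periods=np.arange(1, x.size + 1))
    np.testing.assert_allclose(wb.statistic, bern.stream_statistic, atol=1e-12)
    assert wb.first_signal_period == bern.first_signal_period


@given(
    counts=st.lists(st.integers(0, 26), min_size=1, max_size=40),
    p0=st.floats(0.02, 0.4),
    h=st.floats(0.5, 8.0),
)
@settings(max_examples=60, deadline=None)
def test_cusum_statistic_never_negative(counts, p0, h):
    series = make_series(counts)
    res = wb_cusum_evaluate(series, p0, min(0.95, 2 * p0), h)
    assert np.all(res.statistic >= 0.0)


# ---------------------------------------------------------------------------
# EWMA
# ---------------------------------------------------------------------------


def test_ewma_fixed_point_at_center():
    s = make_series([13, 13, 13, 13], n=26)  # p-hat identically 0.5
    res = ewma_evaluate(s, p0=0.5, lam=0.3, L=3.0)
    assert res.statistic == pytest.approx([0.5] * 4)
    assert not res.signal.any()


def test_ewma_asymptotic_variance_limit():
    lam, p0, n, L = 0.2, 0.059, 26, 2.5
    s = make_series(np.zeros(400, dtype=int), n=n)
    res = ewma_evaluate(s, p0=p0, lam=lam, L=L)
    asymptotic = p0 + L * math.sqrt(p0 * (1 - p0) * lam / (2 - lam) / n)
    assert res.ucl[-1] == pytest.approx(asymptotic, rel=1e-9)
    # early limits are strictly tighter than the asymptote
    assert res.ucl[0] < res.ucl[5] < res.ucl[-1]


@given(
    counts=st.lists(st.integers(0, 26), min_size=1, max_size=40),
    p0=st.floats(0.02, 0.9),
    L=st.floats(0.5, 5.0),
)
@settings(max_examples=80, deadline=None)
def test_ewma_lambda_one_reduces_to_pchart(counts, p0, L):
    """λ = 1 makes Z_t = p̂_t and Var_t = p0(1−p0)/n_t: identical signals."""
    series = make_series(counts)
    ew = ewma_evaluate(series, p0, 1.0, L)
    pc = pchart_evaluate(series, p0, L)
    np.testing.assert_allclose(ew.statistic, pc.statistic, atol=1e-12)
    np.testing.assert_allclose(ew.ucl, pc.ucl, atol=1e-12)
    assert ew.signal.tolist() == pc.signal.tolist()


def test_ewma_rejects_bad_lambda():
    s = make_series([1])
    with pytest.raises(ValueError):
        ewma_evaluate(s, 0.059, 0.0, 2.0)
    with pytest.raises(ValueError):
        ewma_evaluate(s, 0.059, 1.1, 2.0)


# ---------------------------------------------------------------------------
# cross-cutting properties
# ---------------------------------------------------------------------------


@given(
    counts=st.lists(st.integers(0, 26), min_size=3, max_size=30),
    base=st.floats(0.5, 3.0),
    bump=st.floats(0.1, 2.0),
)
@settings(max_examples=60, deadline=None)
def test_raising_the_limit_never_signals_earlier(counts, base, bump):
    series = make_series(counts)
    for family, kwargs in [
        (ChartFamily.P_CHART, {}),
        (ChartFamily.WB_CUSUM, {"p1": 0.114}),
        (ChartFamily.EWMA, {"lam": 0.2}),
    ]:
        lo = ChartSpec(family=family, p0=0.059, limit=base, **kwargs)
        hi = ChartSpec(family=family, p0=0.059, limit=base + bump, **kwargs)
        rl_lo = run_length(evaluate(series, lo))
        rl_hi = run_length(evaluate(series, hi))
        if rl_hi is not None:
            assert rl_lo is not None and rl_lo <= rl_hi


def test_evaluation_is_deterministic_and_stateless(design):
    rng = np.random.default_rng(5)
    series = make_series(rng.binomial(26, 0.1, size=25))
    spec = ChartSpec(family="ewma", p0=design["p0"], lam=0.2, limit=2.5)
    first = evaluate(series, spec)
    second = evaluate(series, spec)
    np.testing.assert_array_equal(first.statistic, second.statistic)
    assert first.first_signal_period == second.first_signal_period


def test_run_length_reports_first_flagged_period():
    s = make_series([0, 0, 0, 0, 0, 0, 26, 0, 26, 0])
    res = pchart_evaluate(s, p0=0.059, L=3.0)
    assert np.flatnonzero(res.signal).tolist() == [6, 8]
    assert run_length(res) == 7
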