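"""First 2-SD excursion detection and the latency summary."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arrestnirs.detect import DetectionResult, first_change_time, latency_table
from arrestnirs.timeseries import TimeSeries

from conftest import brute_force_first_crossing


def _step_trace(marker=60.0, step_at=4.0, level=-10.0, seed=0, post=60.0):
    # bounded baseline noise (clipped at 1.5 SD): a 2-SD rule is only
    # meaningful when baseline variability does not itself cross the threshold
    rng = np.random.default_rng(seed)
    n = int((marker + post) * 10)
    t = np.arange(n) / 10.0
    x = np.clip(rng.standard_normal(n), -1.5, 1.5)
    x[t >= marker + step_at] = level
    return TimeSeries(x, fs=10.0)


def test_constructed_step_latency():
    res = first_change_time(_step_trace(), marker=60.0)
    assert res.latency == pytest.approx(4.0, abs=0.1)
    assert res.detected


def test_threshold_definition_falling_and_rising():
    ts = _step_trace()
    falling = first_change_time(ts, 60.0, direction="falling", k=2.5)
    assert falling.threshold == pytest.approx(
        falling.baseline_mean - 2.5 * falling.baseline_sd
    )
    rising = first_change_time(ts, 60.0, direction="rising", k=2.5)
    assert rising.threshold == pytest.approx(
        rising.baseline_mean + 2.5 * rising.baseline_sd
    )


def test_no_crossing_reports_threshold_without_latency():
    rng = np.random.default_rng(1)
    ts = TimeSeries(np.clip(rng.standard_normal(1200), -1.5, 1.5), fs=10.0)
    res = first_change_time(ts, marker=60.0)
    assert res.latency is None
    assert not res.detected
    assert np.isfinite(res.threshold)


def test_tie_at_threshold_does_not_trigger():
    base = np.tile([1.0, -1.0], 600).astype(float)  # 120 s at 10 Hz
    ts = TimeSeries(base, fs=10.0)
    mean = base[:600].mean()
    sd = base[:600].std(ddof=1)
    ts.data[700] = mean - 2.0 * sd  # exactly at threshold: must not trigger
    ts.data[800] = mean - 2.0 * sd - 1e-9  # strictly below: triggers
    res = first_change_time(ts, marker=60.0)
    assert res.latency == pytest.approx(20.0, abs=0.01)


def test_latency_matches_brute_force_oracle_on_noisy_trace():
    for seed in range(8):
        ts = _step_trace(seed=seed, step_at=3.0 + seed * 0.7)
        res = first_change_time(ts, 60.0)
        oracle = brute_force_first_crossing(ts, 60.0, res.threshold)
        assert res.latency == pytest.approx(oracle, abs=1e-9)


def test_degenerate_baseline_and_bad_marker_rejected():
    with pytest.raises(ValueError, match="degenerate baseline"):
        first_change_time(TimeSeries(np.ones(1200), fs=10.0), marker=60.0)
    with pytest.raises(ValueError, match="marker"):
        first_change_time(_step_trace(), marker=1e5)


def test_persistence_requires_sustained_excursion():
    ts = _step_trace()
    thr = first_change_time(ts, 60.0).threshold
    # single-sample blip before the real step
    blip = ts.copy()
    blip.data[int(61.0 * 10)] = thr - 5.0
    strict = first_change_time(blip, 60.0, persistence=1)
    sustained = first_change_time(blip, 60.0, persistence=3)
    assert strict.latency == pytest.approx(1.0, abs=0.01)
    assert sustained.latency == pytest.approx(4.0, abs=0.1)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(k_lo=st.floats(0.5, 2.0), k_hi=st.floats(2.0, 4.0), seed=st.integers(0, 100))
def test_lowering_k_never_increases_latency(k_lo, k_hi, seed):
    ts = _step_trace(seed=seed)
    lo = first_change_time(ts, 60.0, k=k_lo).latency
    hi = first_change_time(ts, 60.0, k=k_hi).latency
    if hi is not None:
        assert lo is not None and lo <= hi + 1e-9


def test_noiseless_exponential_matches_closed_form_crossing():
    """Detector latency equals the analytic crossing of mean - 2 SD."""
    marker, tau, fs = 120.0, 20.0, 10.0
    rng = np.random.default_rng(3)
    n = int((marker + 200.0) * fs)
    t = np.arange(n) / fs
    x = np.where(t < marker, 0.0, -50.0 * (1 - np.exp(-(t - marker) / tau)))
    x[t < marker] = 0.3 * rng.standard_normal((t < marker).sum())
    ts = TimeSeries(x, fs=fs)
    res = first_change_time(ts, marker)
    # closed form: -50 (1 - exp(-dt/tau)) = threshold
    expected = -tau * np.log(1.0 + res.threshold / 50.0)
    assert res.latency == pytest.approx(expected, abs=1.0 / fs)


def _result(animal, channel, latency):
    return DetectionResult(
        channel=channel, latency=latency, threshold=0.0, baseline_mean=0.0,
        baseline_sd=1.0, k=2.0, direction="falling", persistence=1, animal_id=animal,
    )


def test_latency_table_reproduces_constructed_cohort():
    """Channel means match programmed latencies; constant shift -> closed-form t."""
    rng = np.random.default_rng(0)
    base = rng.normal(10.43, 1.0, size=6)
    results = []
    for i, b in enumerate(base):
        results.append(_result(f"a{i}", "MAP", b))
        results.append(_result(f"a{i}", "TSI", b + 1.61))  # constant offset
    summary, pairs = latency_table(results)
    sm = summary.set_index("channel")
    assert sm.loc["MAP", "mean"] == pytest.approx(base.mean())
    assert sm.loc["TSI", "mean"] == pytest.approx(base.mean() + 1.61)
    # a pure constant shift is the closed-form limit of the paired t
    row = pairs.iloc[0]
    assert row["n"] == 6
    assert row["mean_diff_s"] == pytest.approx(-1.61)
    assert np.isinf(row["t"]) and row["t"] < 0
    assert row["p"] == 0.0


def test_latency_table_trivial_statistics():
    results = [_result(f"a{i}", "MAP", v) for i, v in enumerate([1.0, 2.0, 3.0])]
    summary, _ = latency_table(results)
    assert summary.loc[0, "mean"] == pytest.approx(2.0)
    assert summary.loc[0, "sd"] == pytest.approx(1.0)


def test_latency_table_identical_channels_give_zero_differences():
    results = []
    for i in range(4):
        results.append(_result(f"a{i}", "MAP", 5.0 + i))
        results.append(_result(f"a{i}", "TSI", 5.0 + i))
    _, pairs = latency_table(results)
    assert pairs.iloc[0]["mean_diff_s"] == 0.0
    assert pairs.iloc[0]["t"] == 0.0
    assert pairs.iloc[0]["p"] == 1.0
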