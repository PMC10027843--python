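"""STFT pulse-rate and pulse-amplitude estimation."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.signal import get_window

from arrestnirs import pipeline, synth
from arrestnirs.pulse import (
    StftSpec,
    pulse_amplitude,
    pulse_rate,
    spectrogram,
    three_window_analysis,
)
from arrestnirs.timeseries import TimeSeries

SPEC = StftSpec()


def _tone(freq: float, duration: float = 120.0, amp: float = 1.0) -> TimeSeries:
    t = np.arange(0, duration, 0.1)
    return TimeSeries(amp * np.sin(2 * np.pi * freq * t), fs=10.0, units="s.d.u.")


def test_spec_hop_and_bin_width():
    assert SPEC.hop == 401  # round(528 * 0.76)
    assert SPEC.noverlap == 127
    assert SPEC.bin_width == pytest.approx(10.0 / 528)


def test_spec_validation():
    with pytest.raises(ValueError, match="overlap"):
        StftSpec(overlap=1.0)
    with pytest.raises(ValueError, match="band"):
        StftSpec(band=(0.5, 6.0))


def test_tone_dominates_every_frame_within_one_bin():
    freqs, _, power = spectrogram(_tone(1.44, 300.0), SPEC)
    mask = (freqs >= 0.5) & (freqs <= 4.0)
    for frame in power[mask].T:
        peak = freqs[mask][np.argmax(frame)]
        assert abs(peak - 1.44) <= SPEC.bin_width


def test_zero_signal_gives_zero_matrix_and_no_pulse():
    ts = TimeSeries(np.zeros(1200), fs=10.0)
    freqs, _, power = spectrogram(ts, SPEC)
    assert np.all(power == 0.0)
    rate, ci, _ = pulse_rate(freqs, power, SPEC)
    assert (rate, ci) == (0.0, 0.0)
    assert pulse_amplitude(freqs, power, SPEC) == -np.inf


def test_parseval_identity_per_frame():
    """Summed PSD x bin width equals windowed time energy / sum(w^2)."""
    rng = np.random.default_rng(0)
    ts = TimeSeries(rng.standard_normal(2500), fs=10.0)
    freqs, _, power = spectrogram(ts, SPEC)
    w = get_window(SPEC.window_fn, SPEC.nfft)
    df = SPEC.fs / SPEC.nfft
    for k in range(power.shape[1]):
        frame = ts.data[k * SPEC.hop : k * SPEC.hop + SPEC.nfft] * w
        assert power[:, k].sum() * df == pytest.approx(
            np.sum(frame**2) / np.sum(w**2), rel=1e-9
        )


def test_trace_shorter_than_one_frame_rejected():
    with pytest.raises(ValueError, match="shorter"):
        spectrogram(TimeSeries(np.zeros(100), fs=10.0), SPEC)


def test_noiseless_tone_rate_and_ci():
    freqs, _, power = spectrogram(_tone(1.44, 600.0), SPEC)
    rate, ci, n = pulse_rate(freqs, power, SPEC)
    assert rate == pytest.approx(1.44, abs=SPEC.bin_width)
    assert ci == pytest.approx(0.0, abs=1e-9)
    assert n > 1


def test_noise_below_floor_reports_pulseless():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        ts = TimeSeries(rng.standard_normal(1200), fs=10.0)
        freqs, _, power = spectrogram(ts, SPEC)
        assert pulse_rate(freqs, power, SPEC) == (0.0, 0.0, power.shape[1])


def test_chirp_rates_increase_frame_by_frame():
    t = np.arange(0, 600, 0.1)
    f0, f1 = 1.3, 1.9
    phase = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * t[-1]))
    ts = TimeSeries(np.sin(phase), fs=10.0)
    freqs, _, power = spectrogram(ts, SPEC)
    mask = (freqs >= 0.5) & (freqs <= 4.0)
    framewise = freqs[mask][np.argmax(power[mask], axis=0)]
    assert np.all(np.diff(framewise) >= 0)
    assert framewise[-1] > framewise[0]


def test_halving_amplitude_lowers_result_by_6dB():
    f, _, p1 = spectrogram(_tone(1.44, 300.0, amp=1.0), SPEC)
    _, _, p2 = spectrogram(_tone(1.44, 300.0, amp=0.5), SPEC)
    assert pulse_amplitude(f, p1, SPEC) - pulse_amplitude(f, p2, SPEC) == pytest.approx(
        20 * np.log10(2), abs=1e-6
    )


def test_equal_waveforms_give_equal_amplitude():
    a = _tone(2.0, 300.0)
    b = a.copy()
    fa, _, pa = spectrogram(a, SPEC)
    _, _, pb = spectrogram(b, SPEC)
    assert pulse_amplitude(fa, pa, SPEC) == pulse_amplitude(fa, pb, SPEC)


def test_amplitude_invariant_to_dc_offset_after_zscore():
    from arrestnirs.preprocess import zscore

    base = _tone(1.7, 300.0)
    shifted = TimeSeries(base.data + 37.0, fs=10.0)
    f, _, p1 = spectrogram(zscore(base, (0.0, 60.0)), SPEC)
    _, _, p2 = spectrogram(zscore(shifted, (0.0, 60.0)), SPEC)
    assert pulse_amplitude(f, p1, SPEC) == pytest.approx(pulse_amplitude(f, p2, SPEC))


# --- three-window analysis on full synthetic animals -----------------------

def test_three_windows_on_steady_preset_animal(preset_cohort, geometry):
    """Animal #1 (1.44 Hz steady) reports 1.44 Hz pre-euthanasia on both channels."""
    recordings, _ = preset_cohort
    sess = pipeline.process_recording(recordings[0], geometry)
    table = pipeline.pulse_table(sess).set_index(["window", "channel"])
    for ch in ("ABP", "O2Hb"):
        assert table.loc[("pre", ch), "rate_hz"] == pytest.approx(1.44, abs=SPEC.bin_width)
    # ABP- and O2Hb-derived rates agree within one bin pre and during
    for win in ("pre", "during"):
        assert abs(
            table.loc[(win, "ABP"), "rate_hz"] - table.loc[(win, "O2Hb"), "rate_hz"]
        ) <= SPEC.bin_width + 1e-9


def test_pulseless_post_window_reports_zero(geometry):
    """With no residual pulsation the post window matches the 0 +/- 0 row."""
    cfg = synth.AnimalConfig(seed=13, residual_frac=0.0)
    sess = pipeline.process_recording(synth.simulate_animal(cfg, geometry), geometry)
    table = pipeline.pulse_table(sess).set_index(["window", "channel"])
    for ch in ("ABP", "O2Hb"):
        assert table.loc[("post", ch), "rate_hz"] == 0.0
        assert table.loc[("post", ch), "rate_ci95"] == 0.0


def test_tachycardia_raises_during_window_rate(geometry):
    cfg = synth.AnimalConfig(seed=17)
    assert cfg.tachycardia is not None
    sess = pipeline.process_recording(synth.simulate_animal(cfg, geometry), geometry)
    table = pipeline.pulse_table(sess).set_index(["window", "channel"])
    assert (
        table.loc[("during", "ABP"), "rate_hz"] > table.loc[("pre", "ABP"), "rate_hz"]
    )


def test_abp_amplitude_stronger_than_nirs(default_session):
    """Pressure-derived pulse power exceeds the O2Hb-derived power."""
    table = pipeline.pulse_table(default_session).set_index(["window", "channel"])
    for win in ("pre", "during"):
        assert table.loc[(win, "ABP"), "amp_db"] > table.loc[(win, "O2Hb"), "amp_db"]


def test_window_out_of_range_rejected(default_session):
    with pytest.raises(ValueError, match="out of range"):
        three_window_analysis(
            default_session.channels["ABP_z"],
            default_session.channels["O2Hb_z"],
            default_session.marker,
            post_offset=10_000.0,
        )
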