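"""Resampling, artifact-based stream alignment, z-scoring and windowing.

Streams recorded by independent acquisition systems share no clock; they are
aligned offline by maximizing the normalized cross-correlation of high-pass
filtered traces, exploiting motion-artifact transients common to both.  All
channels are then brought to a common 10-Hz grid and cut to the analysis
window (10 min before the infusion marker to 5 min after).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .timeseries import TimeSeries

__all__ = [
    "resample",
    "regrid",
    "align_streams",
    "zscore",
    "AlignedSession",
    "AlignmentError",
]


class AlignmentError(ValueError):
    """Raised when the cross-correlation peak is too weak to trust."""


def resample(ts: TimeSeries, target_fs: float) -> TimeSeries:
    """Resample to ``target_fs`` spanning the same interval.

    Upsampling uses linear interpolation; downsampling applies a zero-phase
    low-pass at 0.45 × target rate first so that the timing of downstream
    detection statistics is preserved.
    """
    if target_fs <= 0:
        raise ValueError(f"target rate must be positive, got {target_fs}")
    if ts.n == 0:
        raise ValueError("cannot resample an empty series")
    if np.isclose(target_fs, ts.fs):
        return ts.copy()

    data = ts.data
    if target_fs < ts.fs:  # decimation: anti-alias protect
        nyq = ts.fs / 2.0
        cutoff = 0.45 * target_fs
        if cutoff < nyq:
            sos = signal.butter(8, cutoff / nyq, output="sos")
            padlen = min(data.size - 1, 3 * 8 * 10)
            data = signal.sosfiltfilt(sos, data, padlen=padlen)
    n_out = max(int(round(ts.n * target_fs / ts.fs)), 1)
    t_new = ts.t0 + np.arange(n_out) / target_fs
    out = np.interp(t_new, ts.times, data)
    return replace(ts, data=out, fs=target_fs)


def regrid(ts: TimeSeries, fs: float, t_start: float, t_end: float) -> TimeSeries:
    """Linear interpolation of ``ts`` onto the grid ``t_start + k/fs < t_end``."""
    n = int(round((t_end - t_start) * fs))
    t_new = t_start + np.arange(n) / fs
    out = np.interp(t_new, ts.times, ts.data)
    return replace(ts, data=out, fs=fs, t0=t_start)


def _highpass(data: np.ndarray, fs: float, corner_hz: float) -> np.ndarray:
    nyq = fs / 2.0
    if corner_hz >= nyq:
        return data - data.mean()
    sos = signal.butter(2, corner_hz / nyq, btype="highpass", output="sos")
    padlen = min(data.size - 1, 600)
    return signal.sosfiltfilt(sos, data, padlen=padlen)


def _transient_envelope(data: np.ndarray, fs: float, highpass_hz: float) -> np.ndarray:
    """High-pass, rectify and smooth: emphasizes shared artifact bursts.

    Correlating raw high-passed traces locks onto continuous periodic
    physiology (respiration, the beat comb) whose phase carries no timing
    information across sensors; the rectified envelope instead peaks at the
    brief motion transients common to both streams.
    """
    hp = _highpass(data, fs, highpass_hz)
    env = np.abs(hp)
    nyq = fs / 2.0
    if 2.0 < nyq:
        sos = signal.butter(2, 2.0 / nyq, output="sos")
        env = signal.sosfiltfilt(sos, env, padlen=min(env.size - 1, 300))
    return env - env.mean()


def align_streams(
    a: TimeSeries,
    b: TimeSeries,
    search_s: float = 10.0,
    min_corr: float = 0.2,
    highpass_hz: float = 0.5,
) -> float:
    """Offset (s) that, added to ``b``'s timestamps, aligns it with ``a``.

    Both streams are high-pass filtered (default 0.5 Hz, above the
    respiration band), rectified into transient envelopes, and
    cross-correlated over lags within ``±search_s``; the peak locates the
    shared motion artifacts.  If the normalized peak falls below
    ``min_corr``, the alignment is declared ambiguous.

    A stream ``b`` that lags ``a`` by 3 s yields an offset of −3 s.
    """
    fs = a.fs
    if not np.isclose(b.fs, fs):
        b = resample(b, fs)
    ah = _transient_envelope(a.data, fs, highpass_hz)
    bh = _transient_envelope(b.data, fs, highpass_hz)
    a_sd, b_sd = ah.std(), bh.std()
    if a_sd == 0 or b_sd == 0:
        raise AlignmentError("cannot align: one stream is constant after filtering")
    ah, bh = ah / a_sd, bh / b_sd

    c = signal.correlate(ah, bh, mode="full")
    lags = signal.correlation_lags(ah.size, bh.size, mode="full")
    max_lag = int(round(search_s * fs))
    keep = np.abs(lags) <= max_lag
    c, lags = c[keep], lags[keep]
    norm = np.sqrt(np.sum(ah**2) * np.sum(bh**2))
    peak_idx = int(np.argmax(c))
    peak = c[peak_idx] / norm
    if peak < min_corr:
        raise AlignmentError(
            f"alignment ambiguous: normalized correlation peak {peak:.3f} < {min_corr}"
        )
    return float(lags[peak_idx] / fs)


def zscore(ts: TimeSeries, reference: tuple[float, float]) -> TimeSeries:
    """Normalize to standard-deviation units of a reference window.

    ``reference`` is a half-open time window ``(t_start, t_end)`` that must
    lie inside the series; the output has mean 0 and SD 1 over it.
    """
    ref = ts.window(*reference)
    mean = float(ref.data.mean())
    sd = float(ref.data.std(ddof=1))
    if sd == 0:
        raise ValueError(
            f"degenerate baseline: reference window of {ts.label or 'series'} has zero SD"
        )
    return replace(ts, data=(ts.data - mean) / sd, units="s.d.u.")


@dataclass
class AlignedSession:
    """Channels on a common rate and time base, cut to the analysis window.

    The analysis window is ``[marker − 600 s, marker + 300 s]``; shorter
    recordings are processed with a warning and a truncated window.
    """

    channels: dict[str, TimeSeries]
    marker_time: float
    alignment_offset: float = 0.0
    fs: float = 10.0

    @property
    def analysis_window(self) -> tuple[float, float]:
        return (self.marker_time - 600.0, self.marker_time + 300.0)

    @classmethod
    def build(
        cls,
        channels: dict[str, TimeSeries],
        marker_time: float,
        fs: float = 10.0,
        alignment_offset: float = 0.0,
        pre_s: float = 600.0,
        post_s: float = 300.0,
    ) -> "AlignedSession":
        t_lo = marker_time - pre_s
        t_hi = marker_time + post_s
        start = max(t_lo, max(c.t0 for c in channels.values()))
        end = min(t_hi, min(c.t_end for c in channels.values()))
        if start > t_lo or end < t_hi:
            warnings.warn(
                "recording shorter than the 15-min analysis window; truncating",
                stacklevel=2,
            )
        gridded = {name: regrid(c, fs, start, end) for name, c in channels.items()}
        return cls(
            channels=gridded,
            marker_time=marker_time,
            alignment_offset=alignment_offset,
            fs=fs,
        )
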