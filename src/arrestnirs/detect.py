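"""Arrest-onset detection: first 2-SD excursion beyond baseline.

The detection statistic is the time from the infusion marker to the first
post-marker sample (or run of samples) strictly beyond
``baseline_mean ± k·baseline_sd``, where the baseline statistics come from
the 60-s window immediately preceding the marker.  Ties at exactly the
threshold do not trigger.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries import TimeSeries

__all__ = ["DetectionResult", "first_change_time", "latency_table"]


@dataclass
class DetectionResult:
    """Outcome of the first-change scan on one channel."""

    channel: str
    latency: float | None  # s from marker; None when no crossing occurred
    threshold: float
    baseline_mean: float
    baseline_sd: float
    k: float
    direction: str
    persistence: int
    animal_id: str = ""

    @property
    def detected(self) -> bool:
        return self.latency is not None


def first_change_time(
    ts: TimeSeries,
    marker: float,
    direction: str = "falling",
    k: float = 2.0,
    persistence: int = 1,
    baseline_s: float = 60.0,
    post_s: float = 300.0,
    animal_id: str = "",
) -> DetectionResult:
    """Latency (s) from ``marker`` to the first k-SD excursion.

    ``persistence`` requires that many *consecutive* samples beyond the
    threshold before the first of them is reported; the default of 1 is the
    strict "first drop" reading, exposed because a single-sample rule is
    noise-sensitive.  The baseline SD is measured over the same 60-s window
    as the baseline mean.
    """
    if direction not in ("falling", "rising"):
        raise ValueError(f"direction must be 'falling' or 'rising', got {direction!r}")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    if not (ts.t0 <= marker < ts.t_end):
        raise ValueError(f"marker {marker} s lies outside the recording")
    baseline = ts.window(marker - baseline_s, marker)
    mean = float(np.nanmean(baseline.data))
    sd = float(np.nanstd(baseline.data, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate baseline: zero (or undefined) SD over the baseline window")

    threshold = mean - k * sd if direction == "falling" else mean + k * sd
    seg = ts.window(marker, min(marker + post_s, ts.t_end))
    beyond = seg.data < threshold if direction == "falling" else seg.data > threshold
    beyond = beyond & np.isfinite(seg.data)

    latency = None
    if persistence == 1:
        hits = np.flatnonzero(beyond)
        if hits.size:
            latency = float(seg.times[hits[0]] - marker)
    else:
        run = 0
        for i, flag in enumerate(beyond):
            run = run + 1 if flag else 0
            if run >= persistence:
                latency = float(seg.times[i - persistence + 1] - marker)
                break
    return DetectionResult(
        channel=ts.label or "channel",
        latency=latency,
        threshold=threshold,
        baseline_mean=mean,
        baseline_sd=sd,
        k=k,
        direction=direction,
        persistence=persistence,
        animal_id=animal_id,
    )


def latency_table(results) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-channel latency summary plus pairwise paired t-tests.

    ``results`` is an iterable of :class:`DetectionResult`.  The summary has
    one row per channel (n, mean, sample SD of the detected latencies); the
    pairwise table compares each channel pair with a paired t-test restricted
    to animals in which both channels produced a detection.
    """
    rows = [
        {"animal": r.animal_id, "channel": r.channel, "latency_s": r.latency}
        for r in results
    ]
    frame = pd.DataFrame(rows).dropna(subset=["latency_s"])
    if frame.empty:
        raise ValueError("no detections to summarize")
    summary = (
        frame.groupby("channel")["latency_s"]
        .agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    wide = frame.pivot(index="animal", columns="channel", values="latency_s")
    pairs = []
    for a, b in itertools.combinations(sorted(wide.columns), 2):
        both = wide[[a, b]].dropna()
        if len(both) < 2:
            continue
        diff = both[a] - both[b]
        if float(diff.std(ddof=1)) == 0.0:
            # degenerate pairs: identical vectors give t = 0, p = 1; a pure
            # constant shift gives the closed-form limit |t| -> inf, p -> 0
            mean = float(diff.mean())
            t = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
            p = 1.0 if mean == 0.0 else 0.0
        else:
            t, p = stats.ttest_rel(both[a], both[b])
        pairs.append(
            {
                "channel_a": a,
                "channel_b": b,
                "n": len(both),
                "mean_diff_s": float(diff.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    return summary, pd.DataFrame(pairs)
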