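"""Mean arterial pressure and the baseline/euthanasia summary table.

MAP is the classic weighted average ``systolic/3 + 2·diastolic/3``, taken
from sliding beat-scale window extrema of the pressure waveform; the
pre/post summary compares a 60-s pre-marker baseline with the final 10 s of
the 5-min post window, per animal and channel, with cohort Mean and sample-SD
rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .preprocess import resample
from .timeseries import TimeSeries

__all__ = ["PrePostSummary", "map_trace", "pre_post_summary", "cohort_table"]


def map_trace(
    abp: TimeSeries, window_s: float = 1.0, target_fs: float = 10.0
) -> TimeSeries:
    """Mean arterial pressure (mmHg) from the ABP waveform.

    Per sliding window of ``window_s`` (default 1 s, on the beat scale):
    systolic = window max, diastolic = window min, MAP = sys/3 + 2·dia/3.
    Sliding extrema rather than beat segmentation keep the estimate defined
    when pulsation vanishes post-arrest: the extrema converge and MAP tends
    to the instantaneous pressure, which is the physically correct limit.
    Output is on the common ``target_fs`` grid.
    """
    if abp.n == 0:
        raise ValueError("empty ABP input")
    if abp.fs < 10.0:
        raise ValueError(f"ABP rate must be >= 10 Hz, got {abp.fs}")
    size = max(int(round(abp.fs * window_s)), 1)
    systolic = maximum_filter1d(abp.data, size=size, mode="nearest")
    diastolic = minimum_filter1d(abp.data, size=size, mode="nearest")
    m = systolic / 3.0 + 2.0 * diastolic / 3.0
    out = TimeSeries(m, fs=abp.fs, t0=abp.t0, units="mmHg", label="MAP")
    if not np.isclose(target_fs, abp.fs):
        out = resample(out, target_fs)
        out.label, out.units = "MAP", "mmHg"
    return out


@dataclass
class PrePostSummary:
    """Baseline vs euthanasia means for one channel of one animal."""

    channel: str
    baseline_mean: float
    post_value: float
    animal_id: str = ""

    @property
    def delta(self) -> float:
        """Signed change, euthanasia − baseline."""
        return self.post_value - self.baseline_mean


def pre_post_summary(
    ts: TimeSeries,
    marker: float,
    baseline_s: float = 60.0,
    post_window_s: float = 300.0,
    last_s: float = 10.0,
    animal_id: str = "",
) -> PrePostSummary:
    """Baseline (60 s pre-marker) vs final-10-s-of-post-window means."""
    baseline = ts.window(marker - baseline_s, marker)
    post = ts.window(marker + post_window_s - last_s, marker + post_window_s)
    return PrePostSummary(
        channel=ts.label or "channel",
        baseline_mean=float(np.nanmean(baseline.data)),
        post_value=float(np.nanmean(post.data)),
        animal_id=animal_id,
    )


def cohort_table(summaries) -> pd.DataFrame:
    """Cohort summary with per-animal rows plus ``Mean`` and ``SD`` footers.

    ``summaries`` is an iterable of :class:`PrePostSummary`.  Columns form a
    2-level index ``(channel, field)`` with fields baseline / euthanasia /
    delta; the SD row uses the sample (n−1) estimator and animals missing a
    channel are excluded channel-wise.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries supplied")
    channels = sorted({s.channel for s in summaries})
    for ch in channels:
        if sum(1 for s in summaries if s.channel == ch) < 2:
            raise ValueError(f"channel {ch!r} needs >= 2 animals for Mean/SD rows")
    cells: dict[str, dict] = {}
    for s in summaries:
        row = cells.setdefault(s.animal_id, {})
        row[(s.channel, "baseline")] = s.baseline_mean
        row[(s.channel, "euthanasia")] = s.post_value
        row[(s.channel, "delta")] = s.delta
    body = pd.DataFrame.from_dict(cells, orient="index")
    body = body[
        [(ch, f) for ch in channels for f in ("baseline", "euthanasia", "delta")]
    ]
    body.columns = pd.MultiIndex.from_tuples(body.columns, names=["channel", "field"])
    body.index.name = "animal"
    footer = pd.DataFrame(
        [body.mean(axis=0), body.std(axis=0, ddof=1)], index=["Mean", "SD"]
    )
    return pd.concat([body, footer])
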