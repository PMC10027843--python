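"""Reference per-animal values from the eight-animal porcine euthanasia cohort.

These are the published worked-example inputs: per-animal carotid MAP, spinal
cord PO2 and hindlimb TSI at pre-euthanasia baseline (60-s average) and 5 min
post euthanasia (last-10-s average), the per-animal STFT pulse rates for the
three analysis windows, and the cohort first-change latencies.  They seed the
"cohort" simulator preset and serve as direct inputs to the summary-table and
statistics modules.

Missing entries reflect the experiments themselves: MAP from one animal was
excluded for poor post-infusion signal quality (n = 7) and PO2 was unavailable
in two animals (n = 6).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "prepost_reference",
    "pulse_rate_reference",
    "LATENCY_MEAN_S",
    "LATENCY_SD_S",
    "MAP_COLLAPSE_TIME_S",
]

_NA = np.nan

# animal #: MAP baseline/euthanasia, PO2 baseline/euthanasia, TSI baseline/euthanasia
_PREPOST = [
    # animal, map_b,  map_e,  po2_b, po2_e, tsi_b, tsi_e
    (1, 109.08, 31.02, 15.74, 0.87, 56.35, 49.27),
    (2, 67.32, 11.55, 25.26, 0.79, 61.52, 45.00),
    (3, 75.69, 10.86, 32.40, 0.48, 65.26, 51.36),
    (4, 65.71, 15.53, 72.91, 0.38, 70.96, 52.61),
    (5, 95.94, 11.15, 45.96, 0.32, 73.50, 60.34),
    (6, 60.21, 7.76, _NA, _NA, 69.55, 55.43),
    (7, 77.09, 10.38, _NA, _NA, 64.40, 45.01),
    (8, _NA, _NA, 40.26, 0.70, 76.08, 62.63),
]

# Pre-euthanasia ABP pulse rates per animal (Hz); the matched NIRS O2Hb rates
# are identical at this precision.
_PULSE = {
    "pre": {
        "ABP": [1.44, 1.51, 1.56, 2.67, 1.33, 1.08, 1.64, 2.25],
        "O2Hb": [1.44, 1.51, 1.56, 2.67, 1.33, 1.08, 1.64, 2.25],
    },
    "during": {
        "ABP": [1.47, 1.47, 1.46, 2.18, 1.94, 1.92, 1.98, 1.59],
        "O2Hb": [1.45, 1.46, 1.37, 2.18, 1.98, 1.92, 1.96, 1.74],
    },
    "post": {
        "ABP": [0.0] * 8,
        "O2Hb": [0.0] * 8,
    },
}

#: Cohort mean first-change latency (s from infusion marker) per channel.
LATENCY_MEAN_S = {"MAP": 10.43, "TSI": 12.04, "PO2": 25.02}
#: Cohort SD of the first-change latency (s) per channel.
LATENCY_SD_S = {"MAP": 4.73, "TSI": 1.85, "PO2": 9.237}

#: Mean time (s) for pentobarbital-induced MAP to fall to undetectable levels,
#: from the canine literature; used to size the default MAP decay constant.
MAP_COLLAPSE_TIME_S = 52.6


def prepost_reference() -> pd.DataFrame:
    """Per-animal baseline / euthanasia / delta values, one row per animal.

    Columns are a 2-level index ``(channel, field)`` with channels
    ``MAP``/``PO2``/``TSI`` and fields ``baseline``/``euthanasia``/``delta``
    (delta is signed, euthanasia − baseline).
    """
    rows = []
    for animal, mb, me, pb, pe, tb, te in _PREPOST:
        rows.append(
            {
                ("MAP", "baseline"): mb,
                ("MAP", "euthanasia"): me,
                ("MAP", "delta"): me - mb,
                ("PO2", "baseline"): pb,
                ("PO2", "euthanasia"): pe,
                ("PO2", "delta"): pe - pb,
                ("TSI", "baseline"): tb,
                ("TSI", "euthanasia"): te,
                ("TSI", "delta"): te - tb,
            }
        )
    frame = pd.DataFrame(rows, index=[a for a, *_ in _PREPOST])
    frame.index.name = "animal"
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["channel", "field"])
    return frame


def pulse_rate_reference() -> pd.DataFrame:
    """Published pulse rates (Hz) per animal × analysis window × channel."""
    records = []
    for window, chans in _PULSE.items():
        for channel, rates in chans.items():
            for animal, rate in enumerate(rates, start=1):
                records.append(
                    {"animal": animal, "window": window, "channel": channel, "rate_hz": rate}
                )
    return pd.DataFrame.from_records(records)
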