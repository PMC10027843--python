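"""End-to-end processing of one recorded (or simulated) animal.

Glue between the raw streams and the analysis modules: derive MAP from the
pressure waveform, invert the optics to TSI and relative O2Hb, realign the
independently clocked NIRS stream via shared artifacts, bring everything to
the common 10-Hz grid over the 15-min analysis window, and z-score the
pulse-analysis channels to the first 5 min of that window.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .detect import DetectionResult, first_change_time
from .hemodynamics import PrePostSummary, map_trace, pre_post_summary
from .optics import OpticalGeometry, mbll_delta, srs_tsi
from .preprocess import AlignmentError, align_streams, regrid, resample, zscore
from .pulse import StftSpec, three_window_analysis
from .synth import AnimalRecording
from .timeseries import TimeSeries

__all__ = ["ProcessedSession", "process_recording", "detect_all", "pulse_table"]

TARGET_FS = 10.0


@dataclass
class ProcessedSession:
    """Derived 10-Hz channels of one animal over the analysis window."""

    animal_id: str
    marker: float
    channels: dict[str, TimeSeries]  # MAP, TSI, PO2 (optional), ABP_z, O2Hb_z
    alignment_offset: float
    has_map: bool
    has_po2: bool


def process_recording(
    rec: AnimalRecording,
    geometry: OpticalGeometry | None = None,
    align: bool = True,
    max_lag_s: float = 5.0,
) -> ProcessedSession:
    """Raw streams → aligned, derived, z-scored 10-Hz channels."""
    geometry = geometry or OpticalGeometry()
    marker = rec.marker_time
    t_lo = max(marker - 600.0, rec.abp.t0)
    t_hi = min(marker + 300.0, rec.abp.t_end)
    zwin = (t_lo, t_lo + 300.0)  # first 5 min of the analysis window

    abp10 = resample(rec.abp, TARGET_FS) if rec.abp.fs != TARGET_FS else rec.abp

    # Align the NIRS clock to the pressure clock using shared artifacts.
    offset = 0.0
    if align:
        od = rec.optics.channel(rec.optics.wavelengths[0], rec.optics.distances_mm[0])
        try:
            offset = align_streams(abp10, od, search_s=max_lag_s)
        except AlignmentError:
            offset = 0.0
    optics = rec.optics.shifted(offset) if offset else rec.optics

    tsi = srs_tsi(optics, geometry)
    chrom = mbll_delta(
        optics, geometry, optics.distances_mm[0],
        reference_window=(max(zwin[0], optics.t0), zwin[1]),
    )

    channels: dict[str, TimeSeries] = {}
    channels["MAP"] = regrid(map_trace(rec.abp), TARGET_FS, t_lo, t_hi)
    channels["TSI"] = regrid(tsi, TARGET_FS, t_lo, t_hi)
    channels["TSI"].label, channels["TSI"].units = "TSI", "%"
    if rec.po2 is not None:
        channels["PO2"] = regrid(resample(rec.po2, TARGET_FS), TARGET_FS, t_lo, t_hi)
        channels["PO2"].label = "PO2"
    abp_win = regrid(abp10, TARGET_FS, t_lo, t_hi)
    abp_win.label = "ABP"
    o2hb_win = regrid(chrom.o2hb, TARGET_FS, t_lo, t_hi)
    o2hb_win.label = "O2Hb"
    channels["ABP_z"] = zscore(abp_win, zwin)
    channels["ABP_z"].label = "ABP"
    channels["O2Hb_z"] = zscore(o2hb_win, zwin)
    channels["O2Hb_z"].label = "O2Hb"

    return ProcessedSession(
        animal_id=rec.config.animal_id,
        marker=marker,
        channels=channels,
        alignment_offset=offset,
        has_map=rec.has_map,
        has_po2=rec.has_po2,
    )


def detect_all(
    session: ProcessedSession, k: float = 2.0, persistence: int = 1
) -> list[DetectionResult]:
    """First-change detection on the falling channels (MAP, TSI, PO2)."""
    out = []
    for name in ("MAP", "TSI", "PO2"):
        if name == "MAP" and not session.has_map:
            continue
        if name not in session.channels:
            continue
        out.append(
            first_change_time(
                session.channels[name],
                session.marker,
                direction="falling",
                k=k,
                persistence=persistence,
                animal_id=session.animal_id,
            )
        )
    return out


def prepost_all(session: ProcessedSession) -> list[PrePostSummary]:
    out = []
    for name in ("MAP", "TSI", "PO2"):
        if name == "MAP" and not session.has_map:
            continue
        if name not in session.channels:
            continue
        out.append(
            pre_post_summary(
                session.channels[name], session.marker, animal_id=session.animal_id
            )
        )
    return out


def pulse_table(session: ProcessedSession, spec: StftSpec = StftSpec()) -> pd.DataFrame:
    frame = three_window_analysis(
        session.channels["ABP_z"], session.channels["O2Hb_z"], session.marker, spec
    )
    frame.insert(0, "animal", session.animal_id)
    return frame
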