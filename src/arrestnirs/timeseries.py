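"""Uniformly sampled physiological time series.

A :class:`TimeSeries` is the universal currency of the pipeline: one channel
sampled at a fixed rate, with units, a start offset and a label.  All
operations (resampling, z-scoring, windowing, detection, STFT) consume and
produce these objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """One uniformly sampled channel.

    Parameters
    ----------
    data:
        1-D array of samples.
    fs:
        Sampling rate in Hz (> 0).
    t0:
        Time of the first sample in seconds.
    units:
        Physical units of the samples (e.g. ``"mmHg"``, ``"%"``, ``"s.d.u."``).
    label:
        Channel name (e.g. ``"ABP"``, ``"TSI"``).
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("data must be one-dimensional")
        if not (self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.data.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def t_end(self) -> float:
        """Time just past the last sample (``t0 + n/fs``)."""
        return self.t0 + self.n / self.fs

    @property
    def duration(self) -> float:
        return self.n / self.fs

    # -- slicing -----------------------------------------------------------
    def _index_range(self, t_start: float, t_end: float) -> tuple[int, int]:
        i0 = int(math.ceil((t_start - self.t0) * self.fs - 1e-9))
        i1 = int(math.ceil((t_end - self.t0) * self.fs - 1e-9))
        return max(i0, 0), min(i1, self.n)

    def window(self, t_start: float, t_end: float) -> "TimeSeries":
        """Samples with ``t_start <= t < t_end`` as a new series."""
        i0, i1 = self._index_range(t_start, t_end)
        if i1 <= i0:
            raise ValueError(
                f"window [{t_start}, {t_end}) s contains no samples of "
                f"{self.label or 'series'} spanning [{self.t0}, {self.t_end}) s"
            )
        return replace(self, data=self.data[i0:i1].copy(), t0=self.t0 + i0 / self.fs)

    def values_in(self, t_start: float, t_end: float) -> np.ndarray:
        i0, i1 = self._index_range(t_start, t_end)
        return self.data[i0:i1]

    def shifted(self, dt: float) -> "TimeSeries":
        """Same samples with all timestamps moved by ``dt`` seconds."""
        return replace(self, data=self.data.copy(), t0=self.t0 + dt)

    def copy(self) -> "TimeSeries":
        return replace(self, data=self.data.copy())

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path, animal_id: str | None = None) -> None:
        """Write ``time_s,value`` rows with a commented metadata header."""
        with open(path, "w", newline="") as fh:
            fh.write(f"# channel={self.label}\n")
            fh.write(f"# units={self.units}\n")
            fh.write(f"# fs={self.fs!r}\n")
            fh.write(f"# t0={self.t0!r}\n")
            if animal_id is not None:
                fh.write(f"# animal_id={animal_id}\n")
            fh.write("time_s,value\n")
            for t, v in zip(self.times, self.data):
                fh.write(f"{t:.6f},{v:.9g}\n")

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            frame = pd.read_csv(fh)
        fs = float(meta.get("fs", 0)) or None
        if fs is None:
            # fall back to the median sample spacing
            fs = 1.0 / float(np.median(np.diff(frame["time_s"].to_numpy())))
        return cls(
            data=frame["value"].to_numpy(dtype=float),
            fs=fs,
            t0=float(meta.get("t0", frame["time_s"].iloc[0])),
            units=meta.get("units", ""),
            label=meta.get("channel", ""),
        )
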