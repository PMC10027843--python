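"""Synthetic porcine euthanasia physiology with ground truth.

Each simulated animal produces the three recorded streams of the experiment:

* a pulsatile arterial blood pressure waveform (10 or 100 Hz),
* dual-wavelength, three-distance NIRS attenuation (10 Hz) generated through
  the same forward optical model the optics module inverts, and
* a 1-Hz tissue PO2 trace.

Pre-arrest the animal is stationary.  At the infusion marker each channel
collapses along a single exponential after a channel-specific onset lag
(modelling IV drug circulation time), the pulse envelope decays with the
pressure, an optional transient tachycardia perturbs the instantaneous rate,
and a low-amplitude residual pulsation may persist after clinical death.
Gaussian measurement noise is per channel; shared biphasic motion artifacts
are injected into independently clocked streams with a configurable
inter-stream offset so that artifact-based alignment is testable.

Default parameters are calibrated so the full pipeline lands on the study's
printed summary figures: a mean arterial pressure that falls below 5 mmHg
about 52.6 s post-infusion, 2-SD first-change latencies near 10.4 s (MAP),
12.0 s (TSI) and 25.0 s (PO2), a 14.5 % TSI drop at 5 min, and pre-arrest
pulse rates matching the published per-animal grid under the "cohort"
preset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import cohort_data
from .optics import OpticalGeometry, OpticalRecording, forward_attenuation, srs_tsi
from .timeseries import TimeSeries

__all__ = [
    "Tachycardia",
    "ArtifactEvent",
    "AnimalConfig",
    "AnimalRecording",
    "CohortTruth",
    "simulate_abp",
    "simulate_optics",
    "simulate_po2",
    "simulate_animal",
    "simulate_cohort",
    "noiseless",
    "write_cohort",
]

TWO_PI = 2.0 * np.pi
TEMPLATE_MEAN = 2.0 / np.pi  # mean of the rectified-sinusoid beat template


@dataclass(frozen=True)
class Tachycardia:
    """Transient post-infusion rate increase (Gaussian bump)."""

    peak_hz: float = 0.45
    duration_s: float = 60.0


@dataclass(frozen=True)
class ArtifactEvent:
    """One shared biphasic motion transient."""

    time_s: float
    amplitude: float = 1.0
    width_s: float = 0.4


def _default_artifacts() -> tuple[ArtifactEvent, ...]:
    return (
        ArtifactEvent(120.0),
        ArtifactEvent(300.0, amplitude=0.8),
        ArtifactEvent(480.0, amplitude=1.2),
    )


def _default_noise() -> dict[str, float]:
    return {"abp": 0.3, "od": 1e-4, "po2": 0.10}


def _default_resp_amp() -> dict[str, float]:
    # Ventilator-locked oscillation amplitude per channel (mmHg, %, mmHg).
    # Bounded quasi-periodic physiology dominates baseline variability, which
    # is what makes a 2-SD threshold meaningful: a sinusoid of amplitude a has
    # SD a/sqrt(2) and never exceeds 1.41 SD on its own.
    return {"map": 1.5, "tsi": 0.45, "po2": 1.2}


def _default_artifact_gain() -> dict[str, float]:
    return {"abp": 40.0, "od": 0.05, "po2": 0.0}


def _default_detection_noise() -> dict[str, float]:
    # Effective baseline SD of the *derived* 10-Hz channels under default
    # measurement noise and respiration; used only to define ground-truth
    # 2-SD crossings on noiseless traces.
    return {"MAP": 1.15, "TSI": 0.33, "PO2": 0.87}


@dataclass
class AnimalConfig:
    """Everything that defines one synthetic animal.

    Baselines default to the reference-cohort means; decay constants and
    onset lags are free parameters calibrated to the printed collapse and
    first-change latencies.  ``seed`` makes every derived stream
    reproducible.
    """

    animal_id: str = "synthetic-01"
    hr_baseline: float = 1.69  # Hz
    sys_baseline: float = 105.39  # mmHg
    dia_baseline: float = 65.39  # mmHg
    tsi_baseline: float = 67.20  # %
    po2_baseline: float = 38.75  # mmHg
    arrest_time: float = 600.0  # s, infusion marker
    dose_note: str = "pentobarbital 120 mg/kg IV over 5 s"

    tau_map: float = 13.0  # s
    tau_tsi: float = 120.0  # s
    tau_po2: float = 30.0  # s
    map_lag: float = 9.85  # s, onset delay of the pressure collapse
    tsi_lag: float = 8.45  # s
    po2_lag: float = 23.8  # s

    tsi_drop: float = 14.50  # % drop reached at the 5-min evaluation point
    map_floor: float = 2.0  # mmHg
    po2_floor: float = 0.5  # mmHg

    resp_rate_hz: float = 0.2  # mechanical-ventilation rate (12 breaths/min)
    resp_amp: dict[str, float] = field(default_factory=_default_resp_amp)

    tachycardia: Tachycardia | None = field(default_factory=Tachycardia)
    residual_frac: float = 0.10  # residual pulse amplitude, fraction of baseline
    residual_cardiac_duration: float = 480.0  # s past the marker

    thb_baseline_uM: float = 60.0
    o2hb_pulse_uM: float = 0.30  # cardiac O2Hb amplitude at baseline

    noise_sd: dict[str, float] = field(default_factory=_default_noise)
    artifact_schedule: tuple[ArtifactEvent, ...] = field(default_factory=_default_artifacts)
    artifact_gain: dict[str, float] = field(default_factory=_default_artifact_gain)
    stream_offset_s: float = 0.0  # NIRS clock offset relative to the ABP clock
    detection_noise_sd: dict[str, float] = field(default_factory=_default_detection_noise)

    post_duration: float = 310.0  # s recorded past the marker
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.hr_baseline < 4.0):
            raise ValueError(f"hr_baseline must lie in (0.5, 4.0) Hz, got {self.hr_baseline}")
        if not (0 < self.dia_baseline < self.sys_baseline):
            raise ValueError(
                "require 0 < dia_baseline < sys_baseline, got "
                f"dia_baseline={self.dia_baseline}, sys_baseline={self.sys_baseline}"
            )
        if not (0 < self.tsi_baseline < 100):
            raise ValueError(f"tsi_baseline must lie in (0, 100), got {self.tsi_baseline}")
        for name in ("tau_map", "tau_tsi", "tau_po2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("map_lag", "tsi_lag", "po2_lag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.arrest_time <= 0:
            raise ValueError(f"arrest_time must be positive, got {self.arrest_time}")
        if self.post_duration <= 0:
            raise ValueError(f"post_duration must be positive, got {self.post_duration}")

    @property
    def map_baseline(self) -> float:
        return self.sys_baseline / 3.0 + 2.0 * self.dia_baseline / 3.0

    @property
    def pulse_pressure(self) -> float:
        return self.sys_baseline - self.dia_baseline

    @property
    def duration(self) -> float:
        return self.arrest_time + self.post_duration


def noiseless(config: AnimalConfig) -> AnimalConfig:
    """A twin with no measurement noise, respiration or artifacts.

    The respiration oscillation counts as a disturbance here: the noiseless
    twin carries only the deterministic collapse, so its post-arrest traces
    are monotone and define the ground-truth crossing times.
    """
    return replace(
        config,
        noise_sd={k: 0.0 for k in config.noise_sd},
        resp_amp={k: 0.0 for k in config.resp_amp},
        artifact_schedule=(),
        stream_offset_s=0.0,
    )


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _rng(config: AnimalConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _grid(config: AnimalConfig, fs: float) -> np.ndarray:
    n = int(round(config.duration * fs))
    if n <= 0:
        raise ValueError("duration must be positive (check arrest_time/post_duration)")
    return np.arange(n) / fs


def pulse_rate_trajectory(config: AnimalConfig, t: np.ndarray) -> np.ndarray:
    """Instantaneous cardiac rate (Hz) at times ``t``."""
    rate = np.full_like(t, config.hr_baseline, dtype=float)
    if config.tachycardia is not None:
        tk = config.tachycardia
        center = config.arrest_time + tk.duration_s / 3.0
        sigma = tk.duration_s / 4.0
        bump = tk.peak_hz * np.exp(-0.5 * ((t - center) / sigma) ** 2)
        rate = rate + np.where(t >= config.arrest_time, bump, 0.0)
    return rate


def _beat_template(config: AnimalConfig, t: np.ndarray, fs: float) -> np.ndarray:
    """Rectified-sinusoid beat waveform |sin(pi * phase)| on the grid."""
    rate = pulse_rate_trajectory(config, t)
    phase = np.cumsum(rate) / fs
    return np.abs(np.sin(np.pi * phase))


def map_mean_trajectory(config: AnimalConfig, t: np.ndarray) -> np.ndarray:
    onset = config.arrest_time + config.map_lag
    decayed = config.map_floor + (config.map_baseline - config.map_floor) * np.exp(
        -np.clip(t - onset, 0.0, None) / config.tau_map
    )
    return np.where(t < onset, config.map_baseline, decayed)


def _pulse_envelope(config: AnimalConfig, t: np.ndarray) -> np.ndarray:
    """Pulse-pressure envelope as a fraction of baseline (1 pre-arrest)."""
    onset = config.arrest_time + config.map_lag
    env = np.where(
        t < onset, 1.0, np.exp(-np.clip(t - onset, 0.0, None) / config.tau_map)
    )
    if config.residual_frac > 0 and config.residual_cardiac_duration > 0:
        end = config.arrest_time + config.residual_cardiac_duration
        taper = np.clip((end - t) / 5.0, 0.0, 1.0)  # 5-s fade-out at the end
        residual = np.where(t >= onset, config.residual_frac * taper, 0.0)
        env = np.maximum(env, residual)
    return env


def _respiration(
    config: AnimalConfig, t: np.ndarray, channel: str, envelope: np.ndarray | float
) -> np.ndarray:
    """Ventilator-locked oscillation, scaled by the channel's perfusion envelope."""
    amp = config.resp_amp.get(channel, 0.0)
    if amp == 0.0:
        return np.zeros_like(t)
    return amp * np.sin(TWO_PI * config.resp_rate_hz * t) * envelope


def _artifact_waveform(
    config: AnimalConfig, t: np.ndarray, gain: float, clock_offset: float = 0.0
) -> np.ndarray:
    """Sum of biphasic (Gaussian-derivative) transients on this stream's clock."""
    out = np.zeros_like(t)
    if gain == 0.0:
        return out
    for ev in config.artifact_schedule:
        s = (t - (ev.time_s + clock_offset)) / ev.width_s
        out += gain * ev.amplitude * (-s) * np.exp(0.5 * (1.0 - s**2))
    return out


# ---------------------------------------------------------------------------
# channel simulators
# ---------------------------------------------------------------------------

def simulate_abp(config: AnimalConfig, fs: float = 100.0) -> TimeSeries:
    """Arterial blood pressure waveform at 10 or 100 Hz.

    Pre-arrest the beats oscillate between ``dia_baseline`` and
    ``sys_baseline`` at ``hr_baseline``; post-arrest the mean pressure and
    the pulsatile envelope decay exponentially with ``tau_map`` toward a
    near-zero floor, modulated by the optional tachycardia transient and the
    residual post-death pulsation.
    """
    if float(fs) not in (10.0, 100.0):
        raise ValueError(f"fs must be 10 or 100 Hz, got {fs}")
    t = _grid(config, fs)
    template = _beat_template(config, t, fs)
    m = map_mean_trajectory(config, t)
    env = (m - config.map_floor) / (config.map_baseline - config.map_floor)
    m = m + _respiration(config, t, "map", env)
    pp = config.pulse_pressure * _pulse_envelope(config, t)
    # dia + pp * template has window extrema exactly (dia, sys) and a
    # sliding-window MAP of sys/3 + 2*dia/3 = m by construction.
    dia = m - pp / 3.0
    x = dia + pp * template
    sd = config.noise_sd.get("abp", 0.0)
    if sd > 0:
        x = x + sd * _rng(config, 0).standard_normal(t.size)
    x = x + _artifact_waveform(config, t, config.artifact_gain.get("abp", 0.0))
    return TimeSeries(x, fs=fs, units="mmHg", label="ABP")


def tsi_trajectory(config: AnimalConfig, t: np.ndarray) -> np.ndarray:
    """Noiseless tissue-saturation trajectory (%) at times ``t``.

    The asymptotic drop is sized so the trace sits ``tsi_drop`` below
    baseline at the midpoint of the final 10 s of the 5-min post window.
    """
    onset = config.arrest_time + config.tsi_lag
    t_eval = 295.0 - config.tsi_lag  # centre of the last-10-s window, from onset
    scale = 1.0 - np.exp(-max(t_eval, 1.0) / config.tau_tsi)
    drop_inf = config.tsi_drop / scale
    decayed = config.tsi_baseline - drop_inf * (
        1.0 - np.exp(-np.clip(t - onset, 0.0, None) / config.tau_tsi)
    )
    return np.where(t < onset, config.tsi_baseline, decayed)


def simulate_optics(
    config: AnimalConfig,
    geometry: OpticalGeometry | None = None,
    fs: float = 10.0,
) -> OpticalRecording:
    """Dual-wavelength multi-distance attenuation at 10 Hz.

    Latent O2Hb/HHb trajectories hold saturation at ``tsi_baseline``
    pre-arrest and decay with ``tau_tsi`` after the onset lag; a cardiac
    pulsatile component rides on O2Hb with an amplitude tracking the ABP
    pulse envelope.  The traces are converted to attenuation through
    :func:`arrestnirs.optics.forward_attenuation` (the exact forward twin of
    the SRS inversion), then measurement noise and the shared motion
    artifacts are added on the NIRS clock (shifted by ``stream_offset_s``).
    """
    geometry = geometry or OpticalGeometry()
    t = _grid(config, fs)
    # The NIRS acquisition runs on its own clock: every event (physiology and
    # artifacts alike) appears stream_offset_s later in NIRS timestamps.
    tt = t - config.stream_offset_s
    tsi = tsi_trajectory(config, tt)
    onset = config.arrest_time + config.tsi_lag
    resp_env = np.where(
        tt < onset, 1.0, np.exp(-np.clip(tt - onset, 0.0, None) / config.tau_tsi)
    )
    tsi = tsi + _respiration(config, tt, "tsi", resp_env)
    if np.any(tsi <= 0) or np.any(tsi >= 100):
        raise ValueError("saturation trajectory leaves (0, 100): check tsi_drop/tau_tsi")
    thb = config.thb_baseline_uM
    o2hb = thb * tsi / 100.0
    hhb = thb - o2hb
    rate = pulse_rate_trajectory(config, tt)
    template = np.abs(np.sin(np.pi * np.cumsum(rate) / fs))
    pulsatile = config.o2hb_pulse_uM * _pulse_envelope(config, tt) * (
        template - TEMPLATE_MEAN
    )
    rec = forward_attenuation(
        TimeSeries(o2hb, fs=fs, units="µM", label="O2Hb"),
        TimeSeries(hhb, fs=fs, units="µM", label="HHb"),
        geometry,
        pulsatile_o2hb=pulsatile,
    )
    sd = config.noise_sd.get("od", 0.0)
    if sd > 0:
        rec.attenuation += sd * _rng(config, 1).standard_normal(rec.attenuation.shape)
    artifact = _artifact_waveform(
        config, t, config.artifact_gain.get("od", 0.0), clock_offset=config.stream_offset_s
    )
    rec.attenuation += artifact[None, None, :]
    return rec


def simulate_po2(config: AnimalConfig) -> TimeSeries:
    """1-Hz tissue PO2: flat at baseline, then a lagged exponential decay."""
    fs = 1.0
    t = _grid(config, fs)
    onset = config.arrest_time + config.po2_lag
    decayed = config.po2_floor + (config.po2_baseline - config.po2_floor) * np.exp(
        -np.clip(t - onset, 0.0, None) / config.tau_po2
    )
    x = np.where(t < onset, config.po2_baseline, decayed)
    env = (x - config.po2_floor) / (config.po2_baseline - config.po2_floor)
    x = x + _respiration(config, t, "po2", env)
    sd = config.noise_sd.get("po2", 0.0)
    if sd > 0:
        x = x + sd * _rng(config, 2).standard_normal(t.size)
    x = x + _artifact_waveform(config, t, config.artifact_gain.get("po2", 0.0))
    return TimeSeries(x, fs=fs, units="mmHg", label="PO2")


# ---------------------------------------------------------------------------
# whole animals and cohorts
# ---------------------------------------------------------------------------

@dataclass
class AnimalRecording:
    """All recorded streams of one synthetic animal."""

    config: AnimalConfig
    abp: TimeSeries
    optics: OpticalRecording
    po2: TimeSeries | None
    has_map: bool = True
    has_po2: bool = True

    @property
    def marker_time(self) -> float:
        return self.config.arrest_time


@dataclass
class CohortTruth:
    """Ground truth for every simulated animal.

    ``table`` has one row per animal with the true arrest time, the true
    2-SD first-crossing time per derived channel (absolute seconds, from a
    brute-force scan of the noiseless traces), and the true baseline /
    euthanasia channel means.  ``pulse_rate`` maps animal id to the true
    pulse-rate trajectory (Hz vs time, zero where the pulse envelope is
    zero).
    """

    table: pd.DataFrame
    pulse_rate: dict[str, TimeSeries]


def _first_below(ts: TimeSeries, marker: float, threshold: float, post_s: float) -> float:
    """Brute-force scan: first time strictly below threshold after marker."""
    seg = ts.window(marker, min(marker + post_s, ts.t_end))
    below = np.flatnonzero(seg.data < threshold)
    return float(seg.times[below[0]]) if below.size else np.nan


def animal_truth(
    config: AnimalConfig, geometry: OpticalGeometry | None = None
) -> tuple[dict, TimeSeries]:
    """Noiseless-twin ground truth for one animal (row dict + rate trace)."""
    from .hemodynamics import map_trace
    from .preprocess import resample

    geometry = geometry or OpticalGeometry()
    quiet = noiseless(config)
    marker = config.arrest_time
    map10 = map_trace(simulate_abp(quiet, fs=100.0))
    tsi10 = srs_tsi(simulate_optics(quiet, geometry), geometry)
    po210 = resample(simulate_po2(quiet), 10.0)

    row: dict[str, float | str] = {"animal_id": config.animal_id, "arrest_time": marker}
    for name, ts in (("MAP", map10), ("TSI", tsi10), ("PO2", po210)):
        base = float(np.nanmean(ts.values_in(marker - 60.0, marker)))
        post = float(np.nanmean(ts.values_in(marker + 290.0, marker + 300.0)))
        k_sd = 2.0 * config.detection_noise_sd.get(name, 0.0)
        row[f"baseline_{name}"] = base
        row[f"euthanasia_{name}"] = post
        row[f"cross_{name}"] = _first_below(ts, marker, base - k_sd, 300.0)

    t = _grid(config, 10.0)
    rate = pulse_rate_trajectory(config, t) * (_pulse_envelope(config, t) > 0)
    rate_ts = TimeSeries(rate, fs=10.0, units="Hz", label="pulse_rate")
    return row, rate_ts


def simulate_animal(
    config: AnimalConfig,
    geometry: OpticalGeometry | None = None,
    abp_fs: float = 100.0,
    has_map: bool = True,
    has_po2: bool = True,
) -> AnimalRecording:
    geometry = geometry or OpticalGeometry()
    return AnimalRecording(
        config=config,
        abp=simulate_abp(config, fs=abp_fs),
        optics=simulate_optics(config, geometry),
        po2=simulate_po2(config) if has_po2 else None,
        has_map=has_map,
        has_po2=has_po2,
    )


def default_config_sampler(rng: np.random.Generator, index: int) -> AnimalConfig:
    """Draw one animal around the reference-cohort dispersion."""
    map_base = float(np.clip(rng.normal(78.72, 12.0), 45.0, 115.0))
    pp = float(np.clip(rng.normal(40.0, 6.0), 25.0, 60.0))
    return AnimalConfig(
        animal_id=f"sim-{index + 1:02d}",
        hr_baseline=float(np.clip(rng.normal(1.69, 0.35), 0.9, 3.3)),
        sys_baseline=map_base + 2.0 * pp / 3.0,
        dia_baseline=map_base - pp / 3.0,
        tsi_baseline=float(np.clip(rng.normal(67.20, 6.0), 45.0, 88.0)),
        po2_baseline=float(np.clip(rng.normal(38.75, 15.0), 8.0, 80.0)),
        tsi_drop=float(np.clip(rng.normal(14.5, 3.8), 5.0, 30.0)),
        map_lag=float(np.clip(rng.normal(9.85, 2.0), 3.0, 20.0)),
        tsi_lag=float(np.clip(rng.normal(8.45, 1.5), 3.0, 18.0)),
        po2_lag=float(np.clip(rng.normal(23.8, 6.0), 5.0, 45.0)),
        stream_offset_s=float(rng.uniform(-2.0, 2.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def cohort_preset_configs(seed: int = 0) -> list[tuple[AnimalConfig, bool, bool]]:
    """The eight-animal preset mirroring the published per-animal values.

    Returns ``(config, has_map, has_po2)`` per animal.  Baseline MAP / PO2 /
    TSI, the per-animal 5-min TSI drop and the pre-euthanasia pulse rates are
    taken from the reference grid; missing channels keep cohort-mean
    physiology but are flagged unavailable.
    """
    ref = cohort_data.prepost_reference()
    pulse = cohort_data.pulse_rate_reference()
    pre_abp = (
        pulse[(pulse.window == "pre") & (pulse.channel == "ABP")]
        .set_index("animal")["rate_hz"]
    )
    seeds = np.random.SeedSequence(seed).generate_state(len(ref)) % (2**31 - 1)
    out = []
    for i, (animal, row) in enumerate(ref.iterrows()):
        map_base = row[("MAP", "baseline")]
        po2_base = row[("PO2", "baseline")]
        tsi_base = row[("TSI", "baseline")]
        has_map = bool(np.isfinite(map_base))
        has_po2 = bool(np.isfinite(po2_base))
        if not has_map:
            map_base = 78.72
        if not has_po2:
            po2_base = 38.75
        map_floor = row[("MAP", "euthanasia")]
        po2_floor = row[("PO2", "euthanasia")]
        pp = 40.0
        cfg = AnimalConfig(
            animal_id=f"animal-{animal}",
            hr_baseline=float(pre_abp.loc[animal]),
            sys_baseline=float(map_base) + 2.0 * pp / 3.0,
            dia_baseline=float(map_base) - pp / 3.0,
            tsi_baseline=float(tsi_base),
            po2_baseline=float(po2_base),
            tsi_drop=float(-row[("TSI", "delta")]),
            map_floor=float(map_floor) if np.isfinite(map_floor) else 2.0,
            po2_floor=float(po2_floor) if np.isfinite(po2_floor) else 0.5,
            seed=int(seeds[i]),
        )
        out.append((cfg, has_map, has_po2))
    return out


def simulate_cohort(
    n_animals: int,
    config_sampler: Callable[[np.random.Generator, int], AnimalConfig] | None = None,
    seed: int = 0,
    preset: str | None = None,
    geometry: OpticalGeometry | None = None,
    abp_fs: float = 100.0,
) -> tuple[list[AnimalRecording], CohortTruth]:
    """Simulate ``n_animals`` experiments plus their ground truth.

    ``preset="cohort"`` draws the per-animal configurations from the
    published reference grid (n is capped at 8); otherwise ``config_sampler``
    (default: :func:`default_config_sampler`) is called once per animal with
    a seeded generator, making the cohort fully reproducible from ``seed``.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    geometry = geometry or OpticalGeometry()

    specs: list[tuple[AnimalConfig, bool, bool]]
    if preset is not None:
        if preset != "cohort":
            raise ValueError(f"unknown preset {preset!r}")
        specs = cohort_preset_configs(seed)[:n_animals]
    else:
        sampler = config_sampler or default_config_sampler
        rng = np.random.default_rng(seed)
        specs = [(sampler(rng, i), True, True) for i in range(n_animals)]

    recordings, rows, rates = [], [], {}
    for cfg, has_map, has_po2 in specs:
        recordings.append(
            simulate_animal(cfg, geometry, abp_fs=abp_fs, has_map=has_map, has_po2=has_po2)
        )
        row, rate_ts = animal_truth(cfg, geometry)
        if not has_map:
            row["cross_MAP"] = np.nan
        if not has_po2:
            row["cross_PO2"] = np.nan
        rows.append(row)
        rates[cfg.animal_id] = rate_ts
    truth = CohortTruth(table=pd.DataFrame(rows), pulse_rate=rates)
    return recordings, truth


def write_cohort(recordings: Sequence[AnimalRecording], truth: CohortTruth, outdir) -> None:
    """One CSV per channel per animal, plus events and the truth table."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    configs = {}
    for rec in recordings:
        adir = outdir / rec.config.animal_id
        adir.mkdir(exist_ok=True)
        rec.abp.to_csv(adir / "abp.csv", animal_id=rec.config.animal_id)
        rec.optics.to_csv(adir / "optics.csv")
        if rec.po2 is not None:
            rec.po2.to_csv(adir / "po2.csv", animal_id=rec.config.animal_id)
        pd.DataFrame(
            [{"marker": "pentobarbital_infusion", "time_s": rec.marker_time}]
        ).to_csv(adir / "events.csv", index=False)
        cfg = dataclasses.asdict(rec.config)
        cfg["artifact_schedule"] = [dataclasses.asdict(ev) for ev in rec.config.artifact_schedule]
        if rec.config.tachycardia is not None:
            cfg["tachycardia"] = dataclasses.asdict(rec.config.tachycardia)
        cfg["has_map"], cfg["has_po2"] = rec.has_map, rec.has_po2
        configs[rec.config.animal_id] = cfg
    truth.table.to_csv(outdir / "truth.csv", index=False, float_format="%.6f")
    with open(outdir / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(configs, fh, sort_keys=True)
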