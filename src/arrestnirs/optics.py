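"""Continuous-wave NIRS optics: spatially resolved spectroscopy and MBLL.

The sensor model is a dual-wavelength (765 / 850 nm) continuous-wave probe
with three source–detector separations (30 / 35 / 40 mm).  Two complementary
inversions are provided:

* **Spatially resolved spectroscopy (SRS)** uses the spatial slope of
  attenuation versus separation.  Under the diffusion approximation the slope
  satisfies ``ln(10) * dA/drho = sqrt(3 * mu_a * mu_s') + 2/rho_bar``, which
  yields the absorption coefficient up to a common scale factor; solving the
  two-wavelength extinction system gives scaled chromophore concentrations
  whose *ratio* — the tissue saturation index
  ``TSI% = O2Hb / (O2Hb + HHb) * 100`` — is absolute because the scale
  cancels.  Source-intensity changes add a separation-independent attenuation
  offset which the spatial slope annihilates, so TSI is also intensity
  invariant.

* **Modified Beer–Lambert law (MBLL)** converts attenuation *changes* at a
  single separation into relative chromophore concentration changes via the
  extinction matrix and the pathlength ``rho * DPF(lambda)``.

:func:`forward_attenuation` is the exact forward twin of the SRS inversion
and is what the synthetic-physiology generator uses, so forward → inverse
round trips are a first-class test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = [
    "OpticalGeometry",
    "OpticalRecording",
    "ChromophoreSet",
    "forward_attenuation",
    "srs_tsi",
    "mbll_delta",
]

LN10 = float(np.log(10.0))

# Decadic molar extinction coefficients for hemoglobin, 1/(mM cm), compiled
# from standard in-vitro tabulations.  Rows: wavelength; columns: (O2Hb, HHb).
DEFAULT_EXTINCTION = {
    765.0: (0.610, 1.426),
    850.0: (1.058, 0.691),
}


def _default_extinction_matrix(wavelengths) -> np.ndarray:
    return np.array([DEFAULT_EXTINCTION[float(w)] for w in wavelengths])


@dataclass
class OpticalGeometry:
    """Probe geometry and tissue optical constants.

    ``extinction`` has shape ``(n_wavelengths, 2)`` with columns (O2Hb, HHb)
    in 1/(mM cm).  ``mus_prime`` is the reduced scattering coefficient per
    wavelength in 1/cm, defaulting to a linear-in-wavelength model typical of
    human skeletal muscle; ``dpf`` is the differential pathlength factor per
    wavelength (dimensionless, affects only MBLL relative units, never TSI).
    """

    wavelengths: tuple[float, ...] = (765.0, 850.0)
    distances_mm: tuple[float, ...] = (30.0, 35.0, 40.0)
    extinction: np.ndarray | None = None
    dpf: tuple[float, ...] = (4.0, 3.8)
    mus_prime: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        self.distances_mm = tuple(float(d) for d in self.distances_mm)
        if len(self.wavelengths) != 2:
            raise ValueError("exactly 2 wavelengths are required")
        if len(self.distances_mm) < 2:
            raise ValueError("at least 2 source-detector distances are required")
        if any(b <= a for a, b in zip(self.distances_mm, self.distances_mm[1:])):
            raise ValueError("distances must be strictly increasing")
        if self.extinction is None:
            self.extinction = _default_extinction_matrix(self.wavelengths)
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction matrix must be 2x2 (wavelength x chromophore)")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        if self.mus_prime is None:
            # mu_s'(lambda) = 7.0 - 0.004 * (lambda - 800 nm), 1/cm
            self.mus_prime = tuple(7.0 - 0.004 * (w - 800.0) for w in self.wavelengths)
        self.mus_prime = tuple(float(m) for m in self.mus_prime)
        self.dpf = tuple(float(d) for d in self.dpf)
        if any(m <= 0 for m in self.mus_prime):
            raise ValueError("mus_prime must be positive")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("dpf must be positive")

    @property
    def distances_cm(self) -> np.ndarray:
        return np.asarray(self.distances_mm) / 10.0

    @property
    def rho_bar_cm(self) -> float:
        """Mean source-detector separation, used in the ``2/rho_bar`` term."""
        return float(np.mean(self.distances_cm))


@dataclass
class OpticalRecording:
    """Raw attenuation (optical density) traces per wavelength and distance.

    ``attenuation`` has shape ``(n_wavelengths, n_distances, n_samples)``.
    """

    attenuation: np.ndarray
    wavelengths: tuple[float, ...]
    distances_mm: tuple[float, ...]
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        expected = (len(self.wavelengths), len(self.distances_mm))
        if self.attenuation.shape[:2] != expected:
            raise ValueError(
                f"attenuation shape {self.attenuation.shape} does not match "
                f"{expected[0]} wavelengths x {expected[1]} distances"
            )
        if not (self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.attenuation.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def channel(self, wavelength: float, distance_mm: float) -> TimeSeries:
        iw = self.wavelengths.index(float(wavelength))
        idist = self.distances_mm.index(float(distance_mm))
        return TimeSeries(
            self.attenuation[iw, idist].copy(),
            fs=self.fs,
            t0=self.t0,
            units="OD",
            label=f"A_{wavelength:g}_{distance_mm:g}",
        )

    def shifted(self, dt: float) -> "OpticalRecording":
        return replace(self, attenuation=self.attenuation.copy(), t0=self.t0 + dt)

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.times}
        for iw, w in enumerate(self.wavelengths):
            for idist, d in enumerate(self.distances_mm):
                cols[f"A_{w:g}_{d:g}"] = self.attenuation[iw, idist]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# fs={self.fs!r}\n# t0={self.t0!r}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "OpticalRecording":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = float(value)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            frame = pd.read_csv(fh)
        wl: list[float] = []
        dist: list[float] = []
        for col in frame.columns:
            if not col.startswith("A_"):
                continue
            _, w, d = col.split("_")
            if float(w) not in wl:
                wl.append(float(w))
            if float(d) not in dist:
                dist.append(float(d))
        att = np.empty((len(wl), len(dist), len(frame)))
        for iw, w in enumerate(wl):
            for idist, d in enumerate(dist):
                att[iw, idist] = frame[f"A_{w:g}_{d:g}"].to_numpy()
        return cls(att, tuple(wl), tuple(dist), fs=meta["fs"], t0=meta.get("t0", 0.0))


@dataclass
class ChromophoreSet:
    """O2Hb / HHb traces plus the derived THb, Hbdiff and (optionally) TSI.

    The identities ``THb = O2Hb + HHb`` and ``Hbdiff = O2Hb - HHb`` hold
    exactly at every sample by construction.
    """

    o2hb: TimeSeries
    hhb: TimeSeries
    thb: TimeSeries
    hbdiff: TimeSeries
    tsi: TimeSeries | None = None

    @classmethod
    def from_pair(
        cls, o2hb: TimeSeries, hhb: TimeSeries, tsi: TimeSeries | None = None
    ) -> "ChromophoreSet":
        if o2hb.n != hhb.n or o2hb.fs != hhb.fs:
            raise ValueError("o2hb and hhb traces must share length and rate")
        thb = replace(o2hb, data=o2hb.data + hhb.data, label="THb")
        hbdiff = replace(o2hb, data=o2hb.data - hhb.data, label="Hbdiff")
        return cls(o2hb=o2hb, hhb=hhb, thb=thb, hbdiff=hbdiff, tsi=tsi)


def _as_array(trace) -> np.ndarray:
    return trace.data if isinstance(trace, TimeSeries) else np.asarray(trace, float)


def forward_attenuation(
    o2hb: TimeSeries,
    hhb: TimeSeries,
    geometry: OpticalGeometry,
    pulsatile_o2hb: np.ndarray | TimeSeries | None = None,
) -> OpticalRecording:
    """Attenuation per wavelength/distance from absolute chromophore traces.

    ``o2hb`` / ``hhb`` are in µM.  The spatial slope of the generated
    attenuation obeys the same diffusion-approximation relation that
    :func:`srs_tsi` inverts.  ``pulsatile_o2hb`` (µM), when given, is an
    additional cardiac O2Hb component injected as an MBLL term at the
    shortest separation only — emulating the superficial pulsatile signal a
    real probe sees most strongly on its shortest channel.
    """
    c_o2, c_hh = _as_array(o2hb), _as_array(hhb)
    if c_o2.shape != c_hh.shape:
        raise ValueError("o2hb and hhb traces must share length")
    fs = o2hb.fs if isinstance(o2hb, TimeSeries) else 10.0
    t0 = o2hb.t0 if isinstance(o2hb, TimeSeries) else 0.0

    eps = geometry.extinction  # (wl, chrom), 1/(mM cm)
    conc_mM = np.vstack([c_o2, c_hh]) / 1000.0  # (chrom, t)
    mua = LN10 * (eps @ conc_mM)  # (wl, t), 1/cm
    if np.any(mua < 0):
        raise ValueError("negative absorption: chromophore traces must be non-negative")
    mus = np.asarray(geometry.mus_prime)[:, None]
    slope_term = np.sqrt(3.0 * mua * mus) + 2.0 / geometry.rho_bar_cm  # (wl, t)

    rho = geometry.distances_cm  # (dist,)
    att = slope_term[:, None, :] * rho[None, :, None] / LN10  # (wl, dist, t)

    if pulsatile_o2hb is not None:
        pulse_mM = _as_array(pulsatile_o2hb) / 1000.0
        if pulse_mM.shape != c_o2.shape:
            raise ValueError("pulsatile_o2hb must share length with the chromophore traces")
        for iw in range(len(geometry.wavelengths)):
            att[iw, 0, :] += (
                eps[iw, 0] * pulse_mM * rho[0] * geometry.dpf[iw]
            )
    return OpticalRecording(
        att, geometry.wavelengths, geometry.distances_mm, fs=fs, t0=t0
    )


def attenuation_slopes(rec: OpticalRecording, geometry: OpticalGeometry) -> np.ndarray:
    """Per-wavelength OLS slope of attenuation vs separation, (wl, t) in OD/cm."""
    rho = np.asarray(rec.distances_mm) / 10.0
    x = rho - rho.mean()
    denom = float(np.sum(x**2))
    if denom <= 0:
        raise ValueError("at least 2 distinct distances are required")
    a = rec.attenuation
    return np.einsum("d,wdt->wt", x, a - a.mean(axis=1, keepdims=True)) / denom


def srs_tsi(rec: OpticalRecording, geometry: OpticalGeometry) -> TimeSeries:
    """Tissue saturation index (%) via spatially resolved spectroscopy.

    Per time point and wavelength the attenuation slope is converted to a
    scaled absorption ``k * mu_a``; the 2×2 extinction system then yields
    scaled chromophore concentrations whose ratio gives
    ``TSI = O2Hb / (O2Hb + HHb) * 100``.  Samples where the radicand
    ``ln(10)*slope - 2/rho_bar`` is negative (unphysical under the model) are
    flagged invalid (NaN), never clipped, so downstream windows can report
    coverage.
    """
    if len(rec.distances_mm) < 2:
        raise ValueError("SRS requires at least 2 source-detector distances")
    slopes = attenuation_slopes(rec, geometry)
    rho_bar = float(np.mean(np.asarray(rec.distances_mm) / 10.0))
    radicand = LN10 * slopes - 2.0 / rho_bar  # (wl, t)
    invalid = radicand < 0
    radicand = np.where(invalid, np.nan, radicand)
    mus = np.asarray(geometry.mus_prime)[:, None]
    k_mua = radicand**2 / (3.0 * mus)  # k * mu_a per wavelength

    # mu_a = ln(10) * E @ C  =>  k*C = E^-1 @ (k*mu_a / ln 10)
    e_inv = np.linalg.inv(geometry.extinction)
    k_conc = e_inv @ (k_mua / LN10)  # (chrom, t), scaled concentrations
    total = k_conc.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tsi = np.where(total > 0, k_conc[0] / total * 100.0, np.nan)
    tsi = np.where(invalid.any(axis=0), np.nan, tsi)
    return TimeSeries(tsi, fs=rec.fs, t0=rec.t0, units="%", label="TSI")


def mbll_delta(
    rec: OpticalRecording,
    geometry: OpticalGeometry,
    distance_mm: float,
    reference_window: tuple[float, float],
) -> ChromophoreSet:
    """Relative chromophore changes (µM) at one separation via the MBLL.

    ``delta_A(lambda, t)`` is taken against the mean over ``reference_window``
    (seconds, half-open); concentration changes follow from the extinction
    matrix and the effective pathlength ``rho * DPF(lambda)``.
    """
    if float(distance_mm) not in rec.distances_mm:
        raise ValueError(f"distance {distance_mm} mm not present in recording")
    idist = rec.distances_mm.index(float(distance_mm))
    t_a, t_b = reference_window
    i0 = int(np.ceil((t_a - rec.t0) * rec.fs - 1e-9))
    i1 = int(np.ceil((t_b - rec.t0) * rec.fs - 1e-9))
    if i0 < 0 or i1 > rec.n or i1 <= i0:
        raise ValueError("reference window outside recording")

    a = rec.attenuation[:, idist, :]  # (wl, t)
    delta_a = a - a[:, i0:i1].mean(axis=1, keepdims=True)
    pathlength = rec.distances_mm[idist] / 10.0 * np.asarray(geometry.dpf)  # (wl,) cm
    e_inv = np.linalg.inv(geometry.extinction)
    delta_c_mM = e_inv @ (delta_a / pathlength[:, None])
    delta_c_uM = delta_c_mM * 1000.0

    mk = lambda arr, name: TimeSeries(arr, fs=rec.fs, t0=rec.t0, units="µM", label=name)
    return ChromophoreSet.from_pair(mk(delta_c_uM[0], "O2Hb"), mk(delta_c_uM[1], "HHb"))
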