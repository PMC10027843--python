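# Methods

## The measurement model

### Spatially resolved spectroscopy (SRS)

The probe is a dual-wavelength (765, 850 nm) continuous-wave NIRS sensor with
three source–detector separations (30, 35, 40 mm). Under the diffusion
approximation, the spatial slope of attenuation (optical density) with
separation ρ satisfies

    ln10 · ∂A/∂ρ = √(3 μₐ(λ) μ′ₛ(λ)) + 2/ρ̄ ,

with μₐ the absorption and μ′ₛ the reduced scattering coefficient, and ρ̄ the
mean separation. Per time point the pipeline fits an ordinary-least-squares
slope of A against ρ at each wavelength, converts it to a *scaled* absorption
k·μₐ(λ) = (ln10·slope − 2/ρ̄)² / (3 μ′ₛ(λ)), and solves the 2×2 decadic
extinction system (μₐ = ln10 · E · C) for scaled concentrations k·[O₂Hb],
k·[HHb]. The tissue saturation index TSI% = O₂Hb/(O₂Hb+HHb)·100 is absolute
because k cancels; it is likewise invariant to source-intensity drift, which
adds a separation-independent attenuation offset that the spatial slope
annihilates. Samples whose radicand ln10·slope − 2/ρ̄ is negative are
physically inconsistent with the model and are *masked* (NaN), never clipped,
so window statistics can report coverage.

The forward model (`optics.forward_attenuation`) is the exact algebraic twin
of this inversion plus a modified-Beer–Lambert (MBLL) pulsatile O₂Hb term on
the shortest separation, which is where a real probe sees superficial
pulsation most strongly. Forward → inverse round trips recover programmed
saturation to numerical precision across 40–90 %, which is the package's
verification surface: the vendor's exact scattering correction and extinction
table are proprietary, so absolute agreement with any particular device is
not claimable — only internal consistency is.

Defaults: decadic extinction (1/(mM·cm)) O₂Hb/HHb = 0.610/1.426 at 765 nm and
1.058/0.691 at 850 nm, from standard in-vitro tabulations; μ′ₛ(λ) =
7.0 − 0.004·(λ − 800 nm) 1/cm, a linear model typical of human skeletal
muscle; DPF = 4.0/3.8. DPF scales only the MBLL relative units and never
affects TSI. All are overridable in `OpticalGeometry`.

### MAP and the pre/post summary

MAP = systolic/3 + 2·diastolic/3, with systolic/diastolic taken as max/min
over a sliding 1-s window. Sliding extrema rather than beat segmentation keep
the estimator defined when pulsation vanishes post-arrest: the extrema
converge and MAP tends to the instantaneous pressure, the physically correct
limit. The summary compares a 60-s pre-marker baseline mean with the mean of
the final 10 s of the 5-min post-marker window; cohort footers use the sample
(n−1) SD, and animals missing a channel are excluded channel-wise.

### Onset detection

The detection statistic is the time from the infusion marker to the first
sample *strictly* below baseline_mean − k·baseline_SD (k = 2), both moments
taken over the 60-s window immediately before the marker. Ties at the
threshold do not trigger. A `persistence` parameter (default 1, the strict
"first drop" reading) optionally requires a run of consecutive sub-threshold
samples, because a single-sample rule is sensitive to heavy-tailed noise; the
default is recorded in every result object. A 2-SD single-sample rule is
statistically meaningful only when baseline variability is *bounded* — for
unbounded white Gaussian noise the crossing probability per sample is 2.3 %
regardless of the noise level, and a false trigger arrives within seconds at
10 Hz. In these recordings the baseline variability is dominated by
ventilator-locked oscillation, which is bounded (a sinusoid of amplitude a
never exceeds 1.41·SD), and the generator reproduces exactly that structure.

### STFT pulse analysis

Pulse rate and amplitude come from a short-time Fourier transform of z-scored
10-Hz signals: FFT length 528 (bin width fs/NFFT ≈ 0.019 Hz), window overlap
24 % interpreted as hop = round(528 × 0.76) = 401 samples, Hann taper, partial
trailing frames dropped. Per frame the dominant frequency within the
physiological pulse band 0.5–4 Hz is taken; a frame is *pulseless* when its
in-band peak does not rise at least 12 dB above the median power of the
band's own bins. Two numerical choices here matter:

* the noise reference is the median over the band's bins (a pulse occupies a
  few of ~90 bins, so the median stays noise-dominated), not the full
  spectrum, so a band-limited (anti-alias-filtered) channel is not compared
  against its own stop-band floor;
* the 12 dB margin sits above the ≈8–9 dB peak-to-median excursion that pure
  white noise produces over ~90 χ²₂ bins, so noise-only segments report
  0 ± 0 Hz. A 6 dB margin — a natural first guess — declares noise "voiced"
  almost always.

A segment is reported pulseless when fewer than half its frames are voiced;
otherwise the rate is the mean over voiced frames with a t-based 95 % CI.
Amplitude is 10·log₁₀ of the mean in-band peak PSD, referenced to the unit
variance of the z-scored input — the only reference that keeps cross-channel
comparison meaningful after normalization; an all-zero spectrogram reports
−∞ ("no pulse"). The three analysis windows are the 60 s ending at the
marker, the 60 s starting at it, and the 60 s starting at marker + 240 s
(the end of the 5-min post window; configurable).

### Statistics

Normality is screened with the D'Agostino–Pearson K² omnibus test (skewness +
kurtosis, χ² with 2 df); below n = 8 the approximation is invalid and the
result is returned as *inapplicable*, not as a number. Paired and unpaired
Student's t are two-tailed; identical paired samples give t = 0, p = 1, while
zero-variance differences with non-zero mean (infinite t) are rejected in
`paired_t` and reported as the closed-form limit (|t| = ∞, p = 0) by the
latency table. One-way repeated-measures ANOVA requires a complete design;
post-hoc paired comparisons are Holm–Šídák-adjusted and the method name is
carried in every adjusted result. Recomputing the paired t on the six
reference PO₂ pairs gives a two-tailed p = 0.0055 whose one-tailed half,
0.0028, matches the published figure — the package reports two-tailed values
and notes the discrepancy rather than forcing agreement.

## The synthetic physiology generator

Each animal is an `AnimalConfig`. Pre-arrest, all channels are stationary:

* **ABP** — a rectified-sinusoid beat template |sin(π·phase)| scaled so every
  cycle spans exactly (diastolic, systolic); phase integrates an
  instantaneous-rate trajectory. The template is deliberately minimal: it is
  sufficient for window-extrema MAP and for spectral rate/amplitude
  estimation, and waveform morphology (dicrotic notch etc.) is a non-goal.
* **NIRS** — latent O₂Hb/HHb trajectories with constant THb (60 µM) and
  saturation at `tsi_baseline`, a cardiac O₂Hb pulsation (0.30 µM at
  baseline) whose amplitude tracks the ABP pulse envelope, pushed through the
  SRS forward model to per-wavelength/-distance attenuation.
* **PO₂** — flat at `po2_baseline`, sampled at 1 Hz.
* a shared ventilator-locked oscillation (0.2 Hz ≡ 12 breaths/min; amplitudes
  1.5 mmHg MAP, 0.45 % TSI, 1.2 mmHg PO₂) dominating baseline variability,
  scaled by each channel's perfusion envelope so it dies with the collapse;
* additive white Gaussian sensor noise per channel (0.3 mmHg ABP, 10⁻⁴ OD,
  0.10 mmHg PO₂) — small relative to the bounded physiological variability,
  as in the real recordings;
* shared biphasic motion artifacts (Gaussian-derivative transients) at
  scheduled times, with per-channel gain and a configurable inter-stream
  clock offset (`stream_offset_s`) that shifts *all* NIRS content, emulating
  independently clocked acquisition systems.

At the infusion marker each channel collapses along a single exponential
after a channel-specific onset lag modelling IV drug circulation:
MAP with τ = 13 s after a 9.85-s lag toward a 2-mmHg floor, TSI with
τ = 120 s after 8.45 s (asymptote sized so the trace sits `tsi_drop` below
baseline at the 5-min evaluation point), PO₂ with τ = 30 s after 23.8 s
toward 0.5 mmHg. The pulse-pressure envelope decays with the MAP time
constant; an optional tachycardia transient (Gaussian rate bump, +0.45 Hz
over ~60 s) perturbs the instantaneous rate, and a residual pulsation at 10 %
of baseline amplitude persists for 8 min past the marker before a 5-s
fade-out, mirroring reports of cardiac activity long after clinical death.

Single exponentials are used because only summary latencies and collapse
times are published, not trace shapes; the time constants and lags are free
parameters whose defaults are calibrated so the *pipeline output* lands on
the published summary numbers: MAP below 5 mmHg ≈ 52 s post-infusion, 2-SD
first-change latencies ≈ 10.4 s (MAP), ≈ 12.7 s (TSI) and ≈ 25.1 s (PO₂)
against published 10.43/12.04/25.02 s — the TSI latency quantizes at
respiration troughs, so its achievable means jump in ~2-s steps and the
nearest attainable value was kept — and a 14.5 % TSI drop at 5 min. The
"cohort" preset instantiates the eight published animals (per-animal
baselines, 5-min drops, post-euthanasia floors and pre-euthanasia pulse
rates); missing channels (MAP in one animal, PO₂ in two) are flagged
unavailable but simulated with cohort-mean physiology.

Ground truth (`CohortTruth`) records, per animal, the arrest time, the
baseline/euthanasia means, the 2-SD first-crossing time of each channel
computed by brute-force scan of the *noiseless twin* (measurement noise,
respiration and artifacts removed; thresholds use nominal per-channel
baseline SDs), and the true pulse-rate trajectory.

### What the generator does not emulate

Real arterial waveform morphology, beat-to-beat and respiratory-sinus rate
variability, baroreflex dynamics, slow vasomotion, probe-contact drift,
pigmentation/adipose effects on the optics, and respiratory-arrest
physiology are all absent. Passing tests therefore demonstrate that the
*analysis* is correct and well calibrated under the stated signal model —
stationary baselines with bounded quasi-periodic variability and exponential
collapse — not that the detector's sensitivity/specificity would transfer to
clinical recordings.

## Stream alignment

Streams from independent acquisition systems are aligned by their shared
motion artifacts: both traces are high-pass filtered at 0.5 Hz (above the
respiration band), rectified into transient envelopes, smoothed at 2 Hz and
cross-correlated over a bounded lag search (default ±10 s with a 0.2
normalized-peak confidence floor, below which alignment is declared
ambiguous). Correlating raw high-passed traces instead locks onto continuous
periodic physiology — respiration and the beat comb — whose phase carries no
inter-sensor timing information; the envelope step is what makes the artifact
transients decisive (recovery within ~0.12 s at default settings).
Artifacts are used for alignment and then retained; artifact removal is out
of scope. Resampling to the common 10-Hz grid uses linear interpolation
upward and a zero-phase Butterworth low-pass at 0.45 × target rate before
decimation, preserving detection timing. Recordings shorter than the 15-min
analysis window (10 min pre-, 5 min post-marker) are processed with a warning
and truncated windows.

## Problem sizes and determinism

The test suite and analysis scripts run full-length 15-min sessions (ABP at
100 Hz, NIRS at 10 Hz, PO₂ at 1 Hz); cohorts of 8–20 animals are simulated
in a few seconds. Every stochastic element derives from an integer seed:
per-animal streams use `default_rng([seed, stream])`, cohort samplers draw
per-animal seeds from a `SeedSequence`, and identical configuration plus seed
yields bit-identical arrays. Report CSVs use a fixed float format and
key-sorted JSON metadata, so re-running a report on the same inputs is
byte-identical.

## Known limitations

* Absolute TSI agreement with any vendor device is not claimable (proprietary
  extinction/scattering internals); the package's claim is forward/inverse
  consistency.
* The 2-SD detector is offline and single-channel by design; streaming
  detection with bounded delay and multi-channel fusion are out of scope.
* The ABP sampling-rate choice (10 vs 100 Hz) is exposed because the original
  protocol used either; the default is 100 Hz.
* ECG, ventilator dynamics and secondary (respiratory) cardiac arrest are not
  modelled.
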