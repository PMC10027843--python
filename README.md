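# arrestnirs

Sudden cardiac arrest is usually unwitnessed, and resuscitation succeeds
mostly when started within minutes — which is why wearable sensors that can
*detect* arrest are of clinical interest. Transcutaneous near-infrared
spectroscopy (NIRS) is a candidate: unlike photoplethysmography it does not
need a pulse to report tissue oxygenation, so it can both see the pulse
disappear and keep tracking the tissue afterwards.

`arrestnirs` is an analysis pipeline for the porcine euthanasia experiment
that tests this idea: eight anesthetized Yucatan minipigs receive IV
pentobarbital (120 mg/kg) while a hindlimb muscle NIRS probe (765/850 nm,
source–detector separations 30/35/40 mm), an invasive carotid pressure
catheter and an intraparenchymal spinal-cord PO₂ probe record the collapse.
Since the original recordings are not publicly deposited, the package ships a
synthetic-physiology generator that emulates the experiment with known ground
truth, calibrated to the published per-animal values; the analysis modules
are written against either source of data.

## What the pipeline computes

* **Optics** — spatially resolved spectroscopy (SRS): the spatial slope of
  attenuation A versus separation ρ obeys
  `ln10·∂A/∂ρ = √(3 μₐ μ′ₛ) + 2/ρ̄`; solving the two-wavelength extinction
  system for scaled chromophore concentrations gives the tissue saturation
  index `TSI% = O₂Hb/(O₂Hb+HHb)·100`, absolute because the scale cancels.
  The modified Beer–Lambert law yields relative ΔO₂Hb/ΔHHb (µM), with
  `THb = O₂Hb + HHb` and `Hbdiff = O₂Hb − HHb` as exact identities.
* **Hemodynamics** — `MAP = systolic/3 + 2·diastolic/3` from sliding
  beat-scale window extrema of the pressure waveform; baseline (60 s
  pre-marker) versus the final 10 s of the 5-min post window per animal and
  channel, with cohort Mean/SD footers.
* **Detection** — arrest onset as the time from the infusion marker to the
  first sample strictly below `baseline_mean − 2·baseline_SD`.
* **Pulse** — STFT (fs = 10 Hz, FFT length 528, 24 % overlap, Hann taper) on
  z-scored signals: per-window dominant in-band (0.5–4 Hz) frequency ± 95 %
  CI and pulse amplitude in dB, over three 60-s windows (pre-, during-,
  post-euthanasia).
* **Statistics** — D'Agostino–Pearson K² normality screen, paired/unpaired
  Student's t, one-way repeated-measures ANOVA with Holm–Šídák-adjusted
  post-hoc comparisons.

## Worked example

The analysis is a numbered sequence under `analysis/`; each script prints its
findings and writes tables under `results/`:

```bash
cd analysis
python 01_simulate_cohort.py      # eight-animal cohort + ground truth
python 02_optical_inversion.py    # SRS forward/inverse validation
python 03_prepost_tables.py       # baseline vs euthanasia tables + paired t
python 04_detection_latency.py    # 2-SD first-change latencies
python 05_pulse_stft.py           # three-window pulse rates/amplitudes
python 06_report.py               # report bundle (CSVs + plots)
```

Feeding the *published* per-animal baseline/euthanasia values through
`pre_post_summary` + `cohort_table` (script 03) prints

```
channel      MAP                        PO2                        TSI
field   baseline euthanasia  delta baseline euthanasia  delta baseline euthanasia  delta
Mean       78.72      14.04 -64.68    38.75       0.59 -38.16    67.20      52.71 -14.50
SD         17.66       7.83  13.08    19.86       0.23  20.04     6.54       6.51   3.80
paired t MAP: n=7 t=13.082 two-tailed p=1.23e-05
paired t PO2: n=6 t=4.665 two-tailed p=5.51e-03
paired t TSI: n=8 t=10.780 two-tailed p=1.30e-05
```

i.e. MAP drops 64.68 ± 13.08 mmHg (n = 7), spinal-cord PO₂ 38.16 ± 20.04 mmHg
(n = 6) and TSI 14.50 ± 3.80 % (n = 8) from baseline to five minutes after
infusion, all significant. Running the *simulated* cohort through the full
pipeline (optics inversion → alignment → MAP derivation → windows) lands on
the same footer to within a few hundredths, and script 04 reports the
first-change latencies

```
channel  n  mean   sd
    MAP  7 10.56 0.26
    PO2  6 25.68 1.39
    TSI  8 12.79 0.25
```

— pressure first, muscle TSI ~2 s later, tissue PO₂ slowest, with every
detection matched against the generator's programmed crossing times.
Script 05 shows ABP- and O₂Hb-derived pulse rates agreeing (p ≈ 1.0 between
channels), ABP pulse amplitudes exceeding the NIRS ones, and a significant
amplitude drop from baseline to euthanasia in both channels
(repeated-measures ANOVA, Holm–Šídák-adjusted p < 0.05).

A thin CLI wraps the same pipeline:
`arrestnirs simulate|process|detect|pulse|report` (see `--help`).

## Layout

```
src/arrestnirs/     library: timeseries, optics, synth, preprocess,
                    hemodynamics, detect, pulse, stats, pipeline, report, cli
analysis/           numbered narrative drivers (01…06)
tests/              pytest suite (unit, property and end-to-end tests)
docs/methods.md     model, parameters, calibration and limitations
```
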