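"""Synthetic-physiology generator: calibration, determinism, ground truth."""

import numpy as np
import pytest
from dataclasses import replace

from arrestnirs import synth
from arrestnirs.detect import first_change_time
from arrestnirs.hemodynamics import map_trace
from arrestnirs.optics import srs_tsi
from arrestnirs.preprocess import resample

from conftest import brute_force_first_crossing


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="hr_baseline"):
        synth.AnimalConfig(hr_baseline=5.0)
    with pytest.raises(ValueError, match="dia_baseline"):
        synth.AnimalConfig(sys_baseline=60.0, dia_baseline=80.0)
    with pytest.raises(ValueError, match="tau_map"):
        synth.AnimalConfig(tau_map=-1.0)
    with pytest.raises(ValueError, match="po2_lag"):
        synth.AnimalConfig(po2_lag=-0.1)


def test_abp_rejects_bad_rate_and_duration():
    with pytest.raises(ValueError, match="fs"):
        synth.simulate_abp(synth.AnimalConfig(), fs=50.0)
    with pytest.raises(ValueError, match="post_duration"):
        synth.AnimalConfig(post_duration=-5.0)


def test_noiseless_abp_cycles_span_dia_to_sys(default_config):
    """Pre-arrest beats oscillate between the configured dia and sys."""
    quiet = synth.noiseless(default_config)
    abp = synth.simulate_abp(quiet, fs=100.0)
    pre = abp.window(60.0, 540.0)
    n_beat = int(round(100.0 / quiet.hr_baseline))
    mins, maxs = [], []
    for k in range(0, pre.n - n_beat, n_beat):
        cycle = pre.data[k : k + n_beat + 2]
        mins.append(cycle.min())
        maxs.append(cycle.max())
    # discretization of the rectified-sine template bounds the error:
    # the sample nearest a beat boundary sits within half a grid step of the
    # zero, so the cycle minimum overshoots by <= pp * sin(pi / (2 n_beat))
    assert np.allclose(maxs, quiet.sys_baseline, atol=0.05)
    min_err = quiet.pulse_pressure * np.sin(np.pi / (2 * n_beat))
    assert np.allclose(mins, quiet.dia_baseline, atol=min_err + 0.05)


def test_map_collapse_calibration(default_config):
    """Simulated MAP falls below 5 mmHg close to the calibrated 52.6 s."""
    quiet = synth.noiseless(default_config)
    m = map_trace(synth.simulate_abp(quiet, fs=100.0))
    post = m.window(quiet.arrest_time, m.t_end)
    below = np.flatnonzero(post.data < 5.0)
    crossing = post.times[below[0]] - quiet.arrest_time
    assert crossing == pytest.approx(52.6, rel=0.10)


def test_same_seed_gives_bit_identical_traces(default_config):
    a = synth.simulate_abp(default_config, fs=100.0)
    b = synth.simulate_abp(default_config, fs=100.0)
    np.testing.assert_array_equal(a.data, b.data)
    ra = synth.simulate_optics(default_config)
    rb = synth.simulate_optics(default_config)
    np.testing.assert_array_equal(ra.attenuation, rb.attenuation)
    pa = synth.simulate_po2(default_config)
    pb = synth.simulate_po2(default_config)
    np.testing.assert_array_equal(pa.data, pb.data)


def test_optics_round_trip_recovers_baseline_saturation(default_config, geometry):
    tsi = srs_tsi(synth.simulate_optics(default_config, geometry), geometry)
    pre_mean = float(np.nanmean(tsi.values_in(60.0, 540.0)))
    assert pre_mean == pytest.approx(default_config.tsi_baseline, abs=0.67)  # 1 % of scale


def test_post_arrest_saturation_drop_matches_configured_delta(default_config, geometry):
    """Five minutes after infusion the TSI sits tsi_drop below baseline."""
    tsi = srs_tsi(synth.simulate_optics(default_config, geometry), geometry)
    marker = default_config.arrest_time
    post = float(np.nanmean(tsi.values_in(marker + 290.0, marker + 300.0)))
    drop = default_config.tsi_baseline - post
    assert drop == pytest.approx(default_config.tsi_drop, abs=0.15)  # 1 % relative


def test_saturation_out_of_range_rejected():
    cfg = synth.AnimalConfig(tsi_baseline=10.0, tsi_drop=25.0)
    with pytest.raises(ValueError, match="saturation"):
        synth.simulate_optics(cfg)


def test_po2_constant_when_decay_disabled():
    cfg = synth.noiseless(synth.AnimalConfig(po2_lag=0.0, tau_po2=1e12))
    po2 = synth.simulate_po2(cfg)
    np.testing.assert_allclose(po2.data, cfg.po2_baseline, rtol=1e-9)


def test_po2_baseline_mean_matches_configuration(default_config):
    po2 = synth.simulate_po2(default_config)
    base = po2.values_in(default_config.arrest_time - 60.0, default_config.arrest_time)
    assert base.mean() == pytest.approx(default_config.po2_baseline, abs=0.3)


def test_po2_default_first_change_near_25s(default_config):
    """Default lag/decay put the 2-SD crossing near 25 s post-infusion."""
    po2 = resample(synth.simulate_po2(default_config), 10.0)
    res = first_change_time(po2, default_config.arrest_time)
    assert res.latency == pytest.approx(25.02, abs=1.0)  # one native 1-Hz sample


def test_pre_arrest_stationarity(default_config, geometry):
    """Disjoint 60-s pre-arrest window means agree within noise."""
    abp = synth.simulate_abp(default_config, fs=100.0)
    tsi = srs_tsi(synth.simulate_optics(default_config, geometry), geometry)
    po2 = synth.simulate_po2(default_config)
    for ts, tol in ((abp, 1.0), (tsi, 0.3), (po2, 0.3)):
        m1 = float(np.nanmean(ts.values_in(60.0, 120.0)))
        m2 = float(np.nanmean(ts.values_in(420.0, 480.0)))
        assert abs(m1 - m2) < tol


def test_noiseless_post_arrest_collapse_is_monotone(default_config, geometry):
    """The latent physiological trajectories are non-increasing post-arrest.

    (The beat-scale MAP estimate and the pulsatile O2Hb component ride on
    top of these; monotonicity is a property of the underlying collapse.)
    """
    quiet = synth.noiseless(default_config)
    marker = quiet.arrest_time
    t = np.arange(int(marker + 0.5) * 10, int(marker + 295) * 10) / 10.0
    curves = [
        synth.map_mean_trajectory(quiet, t),
        synth.tsi_trajectory(quiet, t),
        synth.simulate_po2(quiet).values_in(marker + 0.5, marker + 295.0),
    ]
    for post in curves:
        assert np.all(np.diff(post) <= 1e-9)


def test_truth_crossings_match_brute_force_scan(geometry):
    cfg = synth.AnimalConfig(seed=21)
    row, _rate = synth.animal_truth(cfg, geometry)
    quiet = synth.noiseless(cfg)
    marker = cfg.arrest_time
    traces = {
        "MAP": map_trace(synth.simulate_abp(quiet, fs=100.0)),
        "TSI": srs_tsi(synth.simulate_optics(quiet, geometry), geometry),
        "PO2": resample(synth.simulate_po2(quiet), 10.0),
    }
    for name, ts in traces.items():
        thr = row[f"baseline_{name}"] - 2.0 * cfg.detection_noise_sd[name]
        oracle = brute_force_first_crossing(ts, marker, thr)
        assert row[f"cross_{name}"] - marker == pytest.approx(oracle, abs=0.11)


def test_cohort_preset_reproduces_reference_baselines(preset_cohort):
    recordings, truth = preset_cohort
    tsi_base = [rec.config.tsi_baseline for rec in recordings]
    np.testing.assert_allclose(
        tsi_base, [56.35, 61.52, 65.26, 70.96, 73.50, 69.55, 64.40, 76.08]
    )
    assert [rec.has_map for rec in recordings] == [True] * 7 + [False]
    assert [rec.has_po2 for rec in recordings] == [True] * 5 + [False, False, True]


def test_cohort_truth_reproducible_from_seed():
    _, t1 = synth.simulate_cohort(1, seed=5)
    _, t2 = synth.simulate_cohort(1, seed=5)
    assert t1.table.equals(t2.table)


def test_zero_variance_sampler_yields_identical_animals():
    sampler = lambda rng, i: synth.AnimalConfig(animal_id=f"a{i}", seed=0)
    recs, _ = synth.simulate_cohort(3, config_sampler=sampler, seed=1)
    for rec in recs[1:]:
        np.testing.assert_array_equal(rec.abp.data, recs[0].abp.data)


def test_cohort_written_to_disk(tmp_path):
    recs, truth = synth.simulate_cohort(
        2, config_sampler=lambda rng, i: synth.AnimalConfig(animal_id=f"a{i}", seed=i),
        seed=0,
    )
    synth.write_cohort(recs, truth, tmp_path / "cohort")
    assert (tmp_path / "cohort" / "truth.csv").exists()
    assert (tmp_path / "cohort" / "a0" / "abp.csv").exists()
    assert (tmp_path / "cohort" / "cohort_config.yaml").exists()
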