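"""Synthetic-data generator: schedules, rendering, noise models,
determinism, conservation, and ground-truth completeness."""

from __future__ import annotations

import json

import numpy as np
import pytest

from conftest import noiseless_config
from midzone.profiles import FWHM_FACTOR, AnaphaseProfileModel, gaussian
from midzone.simulate import (GroundTruth, SpindleSimConfig,
                              generate_comet_tracks, generate_ensemble,
                              generate_frap_curves, generate_profile,
                              generate_spindle_movie)


# ---------------------------------------------------------------------------
# config validation and schedules
# ---------------------------------------------------------------------------


def test_config_invariants():
    with pytest.raises(ValueError, match="plateau"):
        SpindleSimConfig(pole_distance_metaphase_um=20.0,
                         pole_distance_plateau_um=8.0)
    with pytest.raises(ValueError, match="overlap"):
        SpindleSimConfig(overlap_fwhm_initial_um=1.0, overlap_fwhm_final_um=2.0)
    with pytest.raises(ValueError, match="noise_model"):
        SpindleSimConfig(noise_model="cosmic")


def test_image_too_small_rejected():
    with pytest.raises(ValueError, match="too small"):
        SpindleSimConfig(image_shape=(48, 60))


def test_config_round_trip_and_unknown_keys():
    cfg = SpindleSimConfig(seed=5, rotation_deg=10.0)
    again = SpindleSimConfig.from_dict(cfg.to_dict())
    assert again == cfg
    with pytest.raises(ValueError, match="unknown config keys"):
        SpindleSimConfig.from_dict({"warp_speed": 9})


def test_schedules_hit_configured_endpoints():
    cfg = SpindleSimConfig()
    on = cfg.anaphase_onset_s
    assert cfg.pole_distance_um(0.0) == 8.0
    assert cfg.pole_distance_um(on + 5 * 60.0) == pytest.approx(20.0)
    assert cfg.pole_distance_um(on + 60 * 60.0) == pytest.approx(20.0)
    assert cfg.overlap_fwhm_um(on) == pytest.approx(6.0)
    assert cfg.overlap_fwhm_um(on + 1e6) == pytest.approx(1.7)
    assert cfg.dna_separation_um(on) == 0.0
    assert cfg.dna_separation_um(on + 5 * 60.0) == pytest.approx(12.0)
    # metaphase single-Gaussian FWHM equals the metaphase pole distance
    assert cfg.metaphase_sigma_um * FWHM_FACTOR == pytest.approx(8.0)


def test_conserving_mode_preserves_profile_mass():
    cfg = SpindleSimConfig()
    mass0 = cfg.total_profile_mass
    root2pi = np.sqrt(2 * np.pi)
    for t in (0.0, 200.0, 400.0, 800.0):
        m = cfg.protein_model(t)
        if isinstance(m, AnaphaseProfileModel):
            mass = root2pi * (m.amp_central * m.sigma_central
                              + 2 * m.amp_side * m.sigma_side)
        else:
            mass = root2pi * m.amplitude * m.sigma
        assert mass == pytest.approx(mass0, rel=1e-12)


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------


def test_noiseless_axial_mean_equals_model(noiseless_movie):
    cfg, stack, truth = noiseless_movie
    nx = cfg.image_shape[1]
    x = (np.arange(nx) - (nx - 1) / 2.0) * cfg.pixel_size_um
    for i in (0, 6, 15, stack.n_frames - 1):
        t = i * cfg.frame_interval_s
        want_p = cfg.protein_model(t)(x)
        want_d = cfg.dna_model(t)(x)
        assert np.max(np.abs(stack.data[i, 0].mean(axis=0) - want_p)) < 1e-9
        assert np.max(np.abs(stack.data[i, 1].mean(axis=0) - want_d)) < 1e-9


def test_noiseless_bleach_free_intensity_conserved(noiseless_movie):
    cfg, stack, truth = noiseless_movie
    totals = stack.data[:, 0].sum(axis=(1, 2))
    # constant up to the pixel-grid discretization of the moving peaks
    assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-4


def test_determinism_bit_identical():
    cfg = SpindleSimConfig(seed=99, duration_min=2.0)
    s1, t1 = generate_spindle_movie(cfg)
    s2, t2 = generate_spindle_movie(cfg)
    assert np.array_equal(s1.data, s2.data)
    assert t1.movie_frames == t2.movie_frames


def test_truth_completeness_one_record_per_frame(noisy_movie):
    cfg, stack, truth = noisy_movie
    assert len(truth.movie_frames) == stack.n_frames
    assert [f["frame"] for f in truth.movie_frames] == list(range(stack.n_frames))


def test_poles_follow_elongation_schedule(noisy_movie):
    cfg, stack, truth = noisy_movie
    for f in truth.movie_frames:
        want = cfg.pole_distance_um(f["time_s"])
        dx = f["pole_x2_px"] - f["pole_x1_px"]
        dy = f["pole_y2_px"] - f["pole_y1_px"]
        got = np.hypot(dx, dy) * cfg.pixel_size_um
        assert got == pytest.approx(want, rel=1e-9)


def test_poisson_noise_unbiased_monte_carlo():
    """Ensemble mean at one pixel stays within 3 SE of the noiseless value."""
    base = dict(duration_min=0.5, frame_interval_s=30.0,
                pixel_size_um=0.4, image_shape=(24, 70),
                background=0.05, bleach_rate_per_s=0.0)
    clean, _ = generate_spindle_movie(
        SpindleSimConfig(noise_model="none", **base))
    py, px = 12, 35  # bright central pixel
    want = clean.data[0, 0, py, px]
    vals = []
    for seed in range(1000):
        noisy, _ = generate_spindle_movie(
            SpindleSimConfig(noise_model="poisson", seed=seed, **base))
        vals.append(noisy.data[0, 0, py, px])
    vals = np.array(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - want) < 3 * se


def test_rotated_movie_truth_poles_match_angle():
    cfg = noiseless_config(rotation_deg=30.0, duration_min=1.0,
                           image_shape=(140, 160))
    stack, truth = generate_spindle_movie(cfg)
    f = truth.movie_frames[0]
    ang = np.degrees(np.arctan2(f["pole_y2_px"] - f["pole_y1_px"],
                                f["pole_x2_px"] - f["pole_x1_px"]))
    assert ang == pytest.approx(30.0, abs=1e-9)


# ---------------------------------------------------------------------------
# ground truth serialization
# ---------------------------------------------------------------------------


def test_ground_truth_json_round_trip(tmp_path, noisy_movie):
    cfg, stack, truth = noisy_movie
    p = tmp_path / "truth.json"
    truth.to_json(p)
    again = GroundTruth.from_json(p)
    assert again.movie_frames == json.loads(json.dumps(truth.movie_frames))
    assert SpindleSimConfig.from_dict(again.config) == cfg


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


def test_ensemble_variation_and_seed_bounds():
    cfgs = generate_ensemble(SpindleSimConfig(seed=1), n_cells=17)
    assert len(cfgs) == 17
    metas = [c.pole_distance_metaphase_um for c in cfgs]
    assert min(metas) >= 8.0 * 0.9 - 1e-9 and max(metas) <= 8.0 * 1.1 + 1e-9
    assert len(set(metas)) > 1
    for c in cfgs:
        assert 0 <= c.seed < 2**31
        # pole scaling is common to metaphase and plateau distances
        assert c.pole_distance_plateau_um / c.pole_distance_metaphase_um == \
            pytest.approx(20.0 / 8.0)


# ---------------------------------------------------------------------------
# FRAP curves
# ---------------------------------------------------------------------------


def test_frap_noiseless_equals_model():
    params = {"i0": 0.2, "tau_s": 12.0, "mf": 0.6}
    records, truths = generate_frap_curves(params, 3, noise_sd=0.0, seed=4)
    ia = 0.6 * 0.8
    for rec in records:
        t0 = rec.times_s[rec.bleach_index]
        post = rec.times_s >= t0
        want = 0.2 + ia * (1 - np.exp(-(rec.times_s[post] - t0) / 12.0))
        assert np.allclose(rec.roi_intensity[post], want)
        assert np.allclose(rec.roi_intensity[:rec.bleach_index], 1.0)
    assert len(truths) == 3


def test_frap_defaults_mirror_acquisition():
    records, _ = generate_frap_curves({"i0": 0.2, "tau_s": 10.0, "mf": 0.5}, 1)
    rec = records[0]
    dt = np.diff(rec.times_s)
    assert np.allclose(dt, 2.0)  # 30 frames per minute
    t0 = rec.times_s[rec.bleach_index]
    assert rec.times_s[-1] - t0 == pytest.approx(180.0)  # 3 min window


def test_frap_monte_carlo_mean_within_3_sem():
    params = {"i0": 0.2, "tau_s": 10.0, "mf": 0.5}
    records, _ = generate_frap_curves(params, 1000, noise_sd=0.02, seed=6)
    clean, _ = generate_frap_curves(params, 1, noise_sd=0.0, seed=6)
    arr = np.vstack([r.roi_intensity for r in records])
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    assert np.all(np.abs(mean - clean[0].roi_intensity) < 3 * sem)


def test_frap_overshoot_flagged():
    with pytest.warns(UserWarning, match="plateau exceeds"):
        generate_frap_curves({"i0": 0.2, "tau_s": 10.0, "mf": 1.1}, 1,
                             noise_sd=0.0)


def test_frap_parameter_validation():
    with pytest.raises(ValueError):
        generate_frap_curves({"i0": 1.2, "tau_s": 10.0, "mf": 0.5}, 1)
    with pytest.raises(ValueError):
        generate_frap_curves({"i0": 0.2, "tau_s": -1.0, "mf": 0.5}, 1)
    with pytest.raises(ValueError):
        generate_frap_curves({"i0": 0.2, "tau_s": 10.0, "mf": -0.1}, 1)


def test_frap_bleached_records_carry_reference():
    records, _ = generate_frap_curves({"i0": 0.2, "tau_s": 10.0, "mf": 0.5},
                                      2, bleach_rate_per_s=0.001, noise_sd=0.0)
    for rec in records:
        assert rec.reference_intensity is not None
        assert np.allclose(rec.reference_intensity,
                           np.exp(-0.001 * rec.times_s))


# ---------------------------------------------------------------------------
# comet tracks
# ---------------------------------------------------------------------------


def test_comet_truth_completeness_and_speeds():
    tracks, truths = generate_comet_tracks(0.3, 0.05, 25, seed=2)
    assert len(tracks) == len(truths) == 25
    for tr, truth in zip(tracks, truths):
        dx = abs(tr.x_um[-1] - tr.x_um[0])
        assert dx / tr.duration_s == pytest.approx(truth["speed_um_s"], rel=1e-9)


def test_comet_internal_tracks_stay_between_poles():
    tracks, truths = generate_comet_tracks(0.3, 0.05, 60, seed=13,
                                           pole_positions_um=(-8.0, 8.0))
    for tr, truth in zip(tracks, truths):
        if truth["label"] == "internal":
            assert np.all((tr.x_um > -8.0) & (tr.x_um < 8.0))
        else:
            assert np.all((tr.x_um >= 8.0) | (tr.x_um <= -8.0))


def test_comet_pole_validation():
    with pytest.raises(ValueError):
        generate_comet_tracks(0.3, 0.05, 5, pole_positions_um=(1.0, 1.0))
    with pytest.raises(ValueError):
        generate_comet_tracks(-0.3, 0.05, 5)


# ---------------------------------------------------------------------------
# profile generation
# ---------------------------------------------------------------------------


def test_generate_profile_metaphase_closed_form():
    x = np.linspace(-10, 10, 101)
    prof = generate_profile(lambda xv: gaussian(xv, 1.0, 0.0, 2.0), x)
    assert np.allclose(prof.intensity, np.exp(-0.5 * (x / 2.0) ** 2))


def test_generate_profile_noise_spread():
    x = np.linspace(-10, 10, 2001)
    model = AnaphaseProfileModel.from_widths(1.7, 20.0, 5.0, 1.0, 0.9)
    prof = generate_profile(model, x, noise_sd=0.05, seed=3)
    resid = prof.intensity - model(x)
    assert resid.std() == pytest.approx(0.05, rel=0.1)
    assert abs(resid.mean()) < 3 * 0.05 / np.sqrt(len(x))


def test_generate_profile_requires_increasing_grid():
    with pytest.raises(ValueError):
        generate_profile(lambda xv: xv, np.array([0.0, 0.0, 1.0]))
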