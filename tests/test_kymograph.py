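"""Kymograph alignment, band extraction, onset detection, averaging,
background/bleaching correction, and the rainbow time stack."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from matplotlib.colors import rgb_to_hsv

from conftest import noiseless_config
from midzone.core import CentrosomeTrack, ImageStack
from midzone.kymograph import (Kymograph, align_frame, build_cell_kymographs,
                               detect_anaphase_onset, extract_band_profile,
                               extract_kymograph, extract_profile,
                               fit_bleach_factors, normalize_and_average,
                               render_time_stack)
from midzone.profiles import DnaProfileModel, FitError
from midzone.simulate import generate_spindle_movie


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def blob_frame(ny, nx, cy, cx, sigma=2.0, amp=1.0):
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


def test_align_identity_for_centered_horizontal_poles():
    ny, nx = 41, 81
    img = blob_frame(ny, nx, 20.0, 40.0)
    poles = np.array([20.0, 20.0, 60.0, 20.0])  # x1, y1, x2, y2
    aligned, mask = align_frame(img, poles)
    assert np.allclose(aligned[mask], img[mask], atol=1e-9)


def test_align_rotated_offset_spindle_centres_poles():
    ny, nx = 101, 101
    cx1, cy1 = 30.0, 30.0
    cx2, cy2 = 30.0 + 30 * np.cos(np.pi / 6), 30.0 + 30 * np.sin(np.pi / 6)
    img = blob_frame(ny, nx, cy1, cx1, 1.5) + blob_frame(ny, nx, cy2, cx2, 1.5)
    aligned, mask = align_frame(img, np.array([cx1, cy1, cx2, cy2]))
    # after alignment the two blobs sit on the centre row, +/- 15 px
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    for want_col in (cx - 15.0, cx + 15.0):
        region = aligned[int(cy) - 4:int(cy) + 5,
                         int(round(want_col)) - 4:int(round(want_col)) + 5]
        iy, ix = np.unravel_index(np.argmax(region), region.shape)
        got_row = int(cy) - 4 + iy
        got_col = int(round(want_col)) - 4 + ix
        assert abs(got_row - cy) <= 0.5
        assert abs(got_col - want_col) <= 0.5


def test_align_preserves_integrated_intensity():
    ny, nx = 101, 101
    img = blob_frame(ny, nx, 50.0, 50.0, sigma=6.0)
    poles = np.array([35.0, 40.0, 70.0, 65.0])
    aligned, mask = align_frame(img, poles)
    # compare over the valid (in-field) region only
    assert abs(aligned[mask].sum() - img.sum()) / img.sum() < 0.01


def test_align_rejects_coincident_and_outside_poles():
    img = np.zeros((21, 21))
    with pytest.raises(ValueError, match="coincident"):
        align_frame(img, np.array([5.0, 5.0, 5.0, 5.0]))
    with pytest.raises(ValueError, match="outside"):
        align_frame(img, np.array([-3.0, 5.0, 10.0, 5.0]))


# ---------------------------------------------------------------------------
# band extraction
# ---------------------------------------------------------------------------


def test_band_profile_uniform_image():
    img = np.full((40, 60), 3.25)
    mask = np.ones_like(img, dtype=bool)
    prof = extract_band_profile(img, mask, pixel_size_um=0.2, line_width_um=8.0)
    assert np.allclose(prof, 3.25)


def test_band_profile_matches_brute_force_stripes():
    ny, nx, px = 41, 50, 0.2
    img = np.arange(ny, dtype=float)[:, None] * np.ones((1, nx))
    mask = np.ones_like(img, dtype=bool)
    prof = extract_band_profile(img, mask, px, line_width_um=8.0)
    cy = (ny - 1) / 2.0
    half = 8.0 / 2.0 / px
    lo, hi = int(round(cy - half)), int(round(cy + half)) + 1
    assert np.allclose(prof, img[lo:hi].mean(axis=0))


def test_band_profile_narrow_comet_width():
    img = np.zeros((41, 30))
    img[20] = 7.0  # only the centre row
    mask = np.ones_like(img, dtype=bool)
    prof = extract_band_profile(img, mask, pixel_size_um=0.2,
                                line_width_um=0.3)
    assert np.allclose(prof, 7.0)


def test_band_exceeding_image_clips_with_warning():
    img = np.ones((11, 20))
    mask = np.ones_like(img, dtype=bool)
    with pytest.warns(UserWarning, match="clipped"):
        prof = extract_band_profile(img, mask, pixel_size_um=0.2,
                                    line_width_um=8.0)
    assert np.allclose(prof, 1.0)


# ---------------------------------------------------------------------------
# kymograph construction and x = 0 convention
# ---------------------------------------------------------------------------


def test_extract_kymograph_uniform_stack():
    data = np.full((4, 1, 41, 61), 2.0)
    stack = ImageStack(data, 0.2, 30.0, ("protein",))
    track = CentrosomeTrack(np.arange(4),
                            np.tile([10.0, 20.0, 50.0, 20.0], (4, 1)))
    k = extract_kymograph(stack, track, 0)
    assert k.data.shape == (4, 61)
    assert np.allclose(k.data, 2.0)
    # x = 0 at the midpoint column
    assert k.x_um[np.argmin(np.abs(k.x_um))] == pytest.approx(0.0)


def test_reflected_movie_gives_reflected_kymograph(noiseless_movie):
    cfg, stack, truth = noiseless_movie
    track = truth.centrosome_track()
    k = extract_kymograph(stack, track, 0)
    nx = stack.data.shape[3]
    flipped = ImageStack(stack.data[..., ::-1].copy(), stack.pixel_size_um,
                         stack.frame_interval_s, stack.channel_names)
    poles_f = track.poles.copy()
    poles_f[:, 0] = nx - 1 - track.poles[:, 0]
    poles_f[:, 2] = nx - 1 - track.poles[:, 2]
    track_f = CentrosomeTrack(track.frames, poles_f)
    k_f = extract_kymograph(flipped, track_f, 0)
    assert np.allclose(k.data, k_f.data[:, ::-1], atol=1e-6)


# ---------------------------------------------------------------------------
# onset detection
# ---------------------------------------------------------------------------


def dna_kymo(separations, noise_sd=0.0, seed=0, sigma=1.5, amp=1.0):
    x = np.arange(-16.0, 16.0, 0.2)
    rng = np.random.default_rng(seed)
    rows = []
    for s in separations:
        y = DnaProfileModel(amp, 0.0, s, sigma)(x)
        if noise_sd:
            y = y + rng.normal(0, noise_sd, size=x.shape)
        rows.append(y)
    return Kymograph(np.array(rows), 0.2, 30.0, channel="dna")


def test_onset_none_when_never_separating():
    k = dna_kymo(np.zeros(20))
    assert detect_anaphase_onset(k, metaphase_pole_distance_um=8.0) is None


def test_onset_ramp_at_frame_40_within_one_frame():
    seps = np.concatenate([np.zeros(40), 1.2 * np.arange(1, 21)])
    k = dna_kymo(seps, noise_sd=0.0)
    got = detect_anaphase_onset(k, metaphase_pole_distance_um=8.0)
    assert abs(got - 40) <= 1


def test_onset_with_10pct_noise_within_one_frame():
    seps = np.concatenate([np.zeros(40), 1.2 * np.arange(1, 21)])
    for seed in range(3):
        k = dna_kymo(seps, noise_sd=0.1, seed=seed)  # 10% of DNA amplitude
        got = detect_anaphase_onset(k, metaphase_pole_distance_um=8.0)
        assert abs(got - 40) <= 1, f"seed {seed}: got {got}"


def test_onset_on_generator_movie_matches_truth(noisy_kymographs):
    cfg, truth, kymos = noisy_kymographs
    got = kymos["dna"].anaphase_onset_frame
    assert abs(got - cfg.anaphase_onset_frame) <= 1


def test_onset_errors_when_most_fits_fail():
    rng = np.random.default_rng(0)
    k = Kymograph(rng.random((10, 10)), 0.2, 30.0)  # too few usable columns
    data = np.full((10, 160), np.nan)
    k = Kymograph(data, 0.2, 30.0)
    with pytest.raises(FitError):
        detect_anaphase_onset(k, metaphase_pole_distance_um=8.0)


# ---------------------------------------------------------------------------
# normalization and averaging
# ---------------------------------------------------------------------------


def simple_kymo(seed=0, onset=5, meta=8.0):
    rng = np.random.default_rng(seed)
    data = rng.random((12, 81)) + 1.0
    return Kymograph(data, 0.2, 30.0, anaphase_onset_frame=onset,
                     metaphase_pole_distance_um=meta)


def test_average_of_identical_kymographs_is_identity():
    k = simple_kymo()
    avg = normalize_and_average([k, k, k])
    inside = ~np.isnan(avg.data)
    # on the common grid the average must reproduce each copy, SEM = 0
    want = np.array([np.interp(avg.x_um, k.x_um, row) for row in k.data])
    assert np.allclose(avg.data[inside], want[inside], atol=1e-9)
    # zero up to single-pass variance cancellation error
    assert np.allclose(avg.sem[inside], 0.0, atol=1e-6)
    assert np.all(avg.n[inside] == 3)


def test_average_time_zero_at_onset():
    k = simple_kymo(onset=5)
    avg = normalize_and_average([k])
    assert avg.times_s[5] == pytest.approx(0.0)


def test_average_onset_shift_alignment():
    base = simple_kymo(onset=5)
    shifted = Kymograph(np.roll(base.data, 2, axis=0), 0.2, 30.0,
                        anaphase_onset_frame=7,
                        metaphase_pole_distance_um=8.0)
    avg = normalize_and_average([base, shifted])
    # rows where both cells contribute must equal the single-cell rows
    both = avg.n.max(axis=1) == 2
    t_rows = np.flatnonzero(both)
    for r in t_rows:
        src = r - np.flatnonzero(avg.times_s == 0.0)[0] + 5
        if 0 <= src < base.n_frames:
            want = np.interp(avg.x_um, base.x_um, base.data[src])
            inside = ~np.isnan(avg.data[r]) & (avg.n[r] == 2)
            assert np.allclose(avg.data[r][inside], want[inside], atol=1e-9)


def test_average_permutation_invariant():
    ks = [simple_kymo(seed=i, onset=4 + i % 2, meta=7.5 + 0.5 * i)
          for i in range(5)]
    a1 = normalize_and_average(ks)
    a2 = normalize_and_average(ks[::-1])
    assert np.allclose(a1.data, a2.data, equal_nan=True)
    assert np.allclose(a1.sem, a2.sem, equal_nan=True)


def test_average_empty_input_errors():
    with pytest.raises(ValueError):
        normalize_and_average([])


def test_average_x_rescaling_uses_mean_metaphase_distance():
    k1 = simple_kymo(seed=1, meta=6.0)
    k2 = simple_kymo(seed=2, meta=10.0)
    avg = normalize_and_average([k1, k2])
    assert avg.mean_metaphase_distance_um == pytest.approx(8.0)
    assert np.max(np.abs(avg.x_normalized)) == pytest.approx(
        np.max(np.abs(avg.x_um)) / 8.0)


# ---------------------------------------------------------------------------
# profile extraction, background, bleaching
# ---------------------------------------------------------------------------


def test_extract_profile_equals_raw_row_when_clean():
    data = np.tile(np.exp(-0.5 * (np.linspace(-8, 8, 81) / 1.5) ** 2), (3, 1))
    k = Kymograph(data, 0.2, 30.0)
    prof = extract_profile(k, 1, subtract_background=False)
    assert np.allclose(prof.intensity, data[1])


def test_extract_profile_background_subtraction():
    data = np.tile(np.exp(-0.5 * (np.linspace(-8, 8, 81) / 1.5) ** 2), (3, 1))
    k = Kymograph(data + 0.07, 0.2, 30.0)
    prof = extract_profile(k, 1)
    # outer columns are ~0.07 above zero; they define the background
    assert abs(np.median(prof.intensity[:4])) < 1e-3


def test_bleach_correction_restores_amplitude_within_1pct():
    rate = 5e-4
    cfg = noiseless_config(bleach_rate_per_s=rate, duration_min=6.0,
                           anaphase_onset_min=100.0)  # static metaphase movie
    stack, truth = generate_spindle_movie(cfg)
    kymos = build_cell_kymographs(stack, truth.centrosome_track(),
                                  detect_onset=False)
    k = kymos["protein"]
    factors, fitted_rate = fit_bleach_factors(k)
    assert fitted_rate == pytest.approx(rate, rel=0.05)
    amps = []
    for i in range(k.n_frames):
        prof = extract_profile(k, i, bleach_factors=factors)
        amps.append(prof.intensity.max())
    amps = np.array(amps)
    assert np.max(np.abs(amps - amps[0])) / amps[0] < 0.01


# ---------------------------------------------------------------------------
# rainbow time stack
# ---------------------------------------------------------------------------


def test_time_stack_single_frame_is_red():
    frame = np.zeros((10, 10))
    frame[5, 5] = 1.0
    rgb = render_time_stack(frame)
    assert rgb.shape == (10, 10, 3)
    assert rgb[5, 5, 0] == pytest.approx(1.0)   # red channel
    assert rgb[5, 5, 1] == pytest.approx(0.0)
    assert rgb[5, 5, 2] == pytest.approx(0.0)


def test_time_stack_20_spots_monotone_hue():
    T, ny, nx = 20, 10, 60
    frames = np.zeros((T, ny, nx))
    for i in range(T):
        frames[i, 5, 2 + 3 * i] = 1.0
    rgb = render_time_stack(frames, n_frames=20)
    hues = []
    for i in range(T):
        hsv = rgb_to_hsv(rgb[5, 2 + 3 * i][None, None, :])
        hues.append(float(hsv[0, 0, 0]))
    assert np.count_nonzero(np.any(rgb > 0, axis=2)) == T
    assert np.all(np.diff(hues) > 0)         # red -> blue ordering
    assert hues[0] == pytest.approx(0.0)
    assert hues[-1] == pytest.approx(2.0 / 3.0)
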