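"""Kymograph construction, cross-cell averaging, and profile extraction.

A kymograph is a time x axial-position intensity map built along the
pole-to-pole (centrosomal) axis.  Per cell: each frame is translated and
rotated so the spindle midpoint sits at the image centre with the pole axis
horizontal, then intensities are averaged over a band of configurable width
(8 um for midzone profiles, 0.3 um for comet velocimetry).  Across cells:
the space axis is rescaled to the ensemble-average metaphase pole distance
and the time axis shifted so anaphase onset aligns, after which per-bin
mean, n and SEM are computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.optimize import curve_fit
from skimage.transform import AffineTransform, warp

from .core import CentrosomeTrack, ImageStack, IntensityProfile
from .profiles import FitError, fit_dna_profile


@dataclass
class Kymograph:
    """Single-cell, single-channel kymograph.

    ``data`` has shape (T, X); column ``midpoint_col`` maps to axial
    position x = 0 (the spindle midpoint).
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel: str = "protein"
    midpoint_col: float | None = None
    anaphase_onset_frame: int | None = None
    metaphase_pole_distance_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2-D (T, X)")
        if self.midpoint_col is None:
            self.midpoint_col = (self.data.shape[1] - 1) / 2.0
        if self.anaphase_onset_frame is not None and not (
            0 <= self.anaphase_onset_frame < self.data.shape[0]
        ):
            raise ValueError("onset frame out of range")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def x_um(self) -> np.ndarray:
        cols = np.arange(self.data.shape[1], dtype=float)
        return (cols - self.midpoint_col) * self.pixel_size_um

    @property
    def times_s(self) -> np.ndarray:
        t = np.arange(self.n_frames, dtype=float) * self.frame_interval_s
        if self.anaphase_onset_frame is not None:
            t = t - self.anaphase_onset_frame * self.frame_interval_s
        return t


@dataclass
class AverageKymograph:
    """Cross-cell average on a common axial grid, time zero at anaphase onset."""

    data: np.ndarray           # (T, X) mean intensity, NaN where no data
    sem: np.ndarray            # (T, X) standard error of the mean
    n: np.ndarray              # (T, X) cells contributing per bin
    x_um: np.ndarray           # common axial grid (rescaled micrometres)
    times_s: np.ndarray        # 0 at anaphase onset
    mean_metaphase_distance_um: float
    channel: str = "protein"

    def __post_init__(self) -> None:
        if np.any(self.n[np.isfinite(self.data)] < 1):
            raise ValueError("defined bins must have n >= 1")
        if np.any(self.sem[np.isfinite(self.sem)] < 0):
            raise ValueError("SEM must be non-negative")

    @property
    def x_normalized(self) -> np.ndarray:
        """Axial coordinate in units of the mean metaphase pole distance."""
        return self.x_um / self.mean_metaphase_distance_um


# ---------------------------------------------------------------------------
# Alignment and band extraction
# ---------------------------------------------------------------------------


def _alignment_transform(pole_pair: np.ndarray, shape_yx: tuple[int, int]
                         ) -> AffineTransform:
    """skimage transform mapping output (aligned) coords to input coords."""
    x1, y1, x2, y2 = (float(v) for v in pole_pair)
    if x1 == x2 and y1 == y2:
        raise ValueError("coincident poles")
    mx, my = (x1 + x2) / 2.0, (y1 + y2) / 2.0
    theta = math.atan2(y2 - y1, x2 - x1)
    ny, nx = shape_yx
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    c, s = math.cos(theta), math.sin(theta)
    # in = midpoint + R(theta) @ (out - center)
    matrix = np.array([
        [c, -s, mx - c * cx + s * cy],
        [s, c, my - s * cx - c * cy],
        [0, 0, 1],
    ])
    return AffineTransform(matrix=matrix)


def align_frame(frame: np.ndarray, pole_pair: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Centre the spindle midpoint and rotate the pole axis horizontal.

    Bilinear interpolation; pixels mapped from outside the field are zero
    and excluded by the returned boolean mask.

    Returns ``(aligned, mask)``.
    """
    frame = np.asarray(frame, dtype=float)
    ny, nx = frame.shape
    x1, y1, x2, y2 = (float(v) for v in pole_pair)
    for x, y in ((x1, y1), (x2, y2)):
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise ValueError(f"pole ({x}, {y}) outside the frame")
    tform = _alignment_transform(np.asarray(pole_pair), frame.shape)
    aligned = warp(frame, tform, order=1, cval=0.0, preserve_range=True)
    valid = warp(np.ones_like(frame), tform, order=1, cval=0.0,
                 preserve_range=True)
    mask = valid > 0.999
    return aligned, mask


def aligned_pole_columns(pole_pair: np.ndarray, shape_yx: tuple[int, int],
                         ) -> tuple[float, float]:
    """Column coordinates of the two poles after alignment (row = centre)."""
    x1, y1, x2, y2 = (float(v) for v in pole_pair)
    half = 0.5 * math.hypot(x2 - x1, y2 - y1)
    cx = (shape_yx[1] - 1) / 2.0
    return cx - half, cx + half


def extract_band_profile(aligned: np.ndarray, mask: np.ndarray,
                         pixel_size_um: float, line_width_um: float = 8.0
                         ) -> np.ndarray:
    """Per-column mean over the horizontal band centred on the pole axis."""
    if line_width_um < pixel_size_um:
        line_width_um = pixel_size_um  # at least one pixel row
    ny = aligned.shape[0]
    cy = (ny - 1) / 2.0
    half_rows = line_width_um / 2.0 / pixel_size_um
    if cy - half_rows < -0.5 or cy + half_rows > ny - 0.5:
        warnings.warn("band exceeds the image; clipped", stacklevel=2)
    # rows whose centres lie within the half-width of the pole axis
    rows = np.abs(np.arange(ny) - cy) <= half_rows + 1e-9
    if not rows.any():
        rows[int(round(cy))] = True
    band = aligned[rows]
    bmask = mask[rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.where(bmask.any(axis=0),
                       np.nansum(np.where(bmask, band, np.nan), axis=0)
                       / bmask.sum(axis=0),
                       np.nan)
    return out


def extract_kymograph(stack: ImageStack, track: CentrosomeTrack,
                      channel: int | str = 0,
                      line_width_um: float = 8.0) -> Kymograph:
    """Build one channel's kymograph from an annotated movie.

    Each annotated frame is aligned and the band mean taken as one row.
    """
    if isinstance(channel, str):
        ch = stack.channel_names.index(channel)
    else:
        ch = channel
    rows = []
    for i, frame_idx in enumerate(track.frames):
        img = stack.data[frame_idx, ch]
        aligned, mask = align_frame(img, track.poles[i])
        rows.append(extract_band_profile(aligned, mask, stack.pixel_size_um,
                                         line_width_um))
    return Kymograph(np.vstack(rows), stack.pixel_size_um,
                     stack.frame_interval_s,
                     channel=stack.channel_names[ch])


def build_cell_kymographs(stack: ImageStack, track: CentrosomeTrack,
                          line_width_um: float = 8.0,
                          detect_onset: bool = True) -> dict[str, Kymograph]:
    """Kymographs for all channels, with anaphase onset (from the DNA
    channel) and the metaphase pole distance attached to each."""
    kymos = {name: extract_kymograph(stack, track, name, line_width_um)
             for name in stack.channel_names}
    onset = None
    if detect_onset and "dna" in kymos:
        provisional = float(np.mean(track.distances_px()[:3])) * stack.pixel_size_um
        onset = detect_anaphase_onset(kymos["dna"],
                                      metaphase_pole_distance_um=provisional)
    dists_um = track.distances_px() * stack.pixel_size_um
    if onset is not None and onset > 0:
        meta = float(np.mean(dists_um[:onset]))
    else:
        meta = float(np.mean(dists_um[:3]))
    for k in kymos.values():
        k.anaphase_onset_frame = onset
        k.metaphase_pole_distance_um = meta
    return kymos


# ---------------------------------------------------------------------------
# Anaphase onset
# ---------------------------------------------------------------------------


def dna_separation_series(dna_kymo: Kymograph
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame two-Gaussian DNA separation (NaN where the fit fails).

    Returns ``(separations, resolved)``; unresolved fits (separation below
    one sigma, where the two masses overlap and the separation is poorly
    identified) are flagged False.
    """
    seps = np.full(dna_kymo.n_frames, np.nan)
    resolved = np.zeros(dna_kymo.n_frames, dtype=bool)
    x = dna_kymo.x_um
    for i in range(dna_kymo.n_frames):
        row = dna_kymo.data[i]
        good = np.isfinite(row)
        if good.sum() < 8:
            continue
        try:
            fit = fit_dna_profile(IntensityProfile(x[good], row[good]))
            seps[i] = fit.separation
            resolved[i] = fit.resolved
        except (FitError, ValueError):
            pass
    return seps, resolved


def detect_anaphase_onset(
    dna_kymo: Kymograph,
    metaphase_pole_distance_um: float | None = None,
    threshold_frac: float = 0.2,
    sustain_frames: int = 3,
    refine: bool = True,
) -> int | None:
    """First frame at which chromosome separation starts.

    The two-Gaussian DNA separation must exceed ``threshold_frac`` of the
    metaphase pole distance for at least ``sustain_frames`` consecutive
    frames; the crossing is then refined by back-extrapolating a linear fit
    of separation versus time to zero, which removes the lag the threshold
    alone introduces on a separation ramp.  Returns None if the masses
    never separate.
    """
    meta = metaphase_pole_distance_um or dna_kymo.metaphase_pole_distance_um
    if meta is None:
        raise ValueError("metaphase pole distance needed for the threshold")
    seps, resolved = dna_separation_series(dna_kymo)
    n_fail = int(np.sum(~np.isfinite(seps)))
    if n_fail > 0.5 * len(seps):
        raise FitError(f"DNA fit failed on {n_fail}/{len(seps)} frames")

    thr = threshold_frac * meta
    # Unresolved fits (coincident masses) yield spurious separations, so
    # only resolved fits can establish a crossing.
    above = np.isfinite(seps) & resolved & (seps > thr)
    crossing = None
    for i in range(len(seps) - sustain_frames + 1):
        if above[i:i + sustain_frames].all():
            crossing = i
            break
    if crossing is None:
        return None
    if not refine:
        return crossing

    # linear back-extrapolation of the early ramp to zero separation
    idx = np.arange(crossing, min(crossing + 4, len(seps)))
    idx = idx[np.isfinite(seps[idx]) & resolved[idx] & (seps[idx] > thr / 2)]
    if len(idx) >= 2:
        slope, intercept = np.polyfit(idx.astype(float), seps[idx], 1)
        if slope > 0:
            onset = int(round(-intercept / slope))
            return int(np.clip(onset, max(crossing - 5, 0), crossing))
    return crossing


# ---------------------------------------------------------------------------
# Cross-cell averaging
# ---------------------------------------------------------------------------


def normalize_and_average(
    kymographs: list[Kymograph],
    onsets: list[int] | None = None,
    metaphase_distances_um: list[float] | None = None,
    grid_step_um: float | None = None,
) -> AverageKymograph:
    """Average kymographs after spatial normalization and onset alignment.

    Each kymograph's x axis is rescaled by (mean metaphase distance / its
    own metaphase distance) via linear interpolation onto a common grid;
    rows are shifted so anaphase onset lands at time zero.  Per-bin mean,
    n and SEM are returned.  Averaging is permutation-invariant.
    """
    if not kymographs:
        raise ValueError("no kymographs to average")
    if onsets is None:
        onsets = [k.anaphase_onset_frame for k in kymographs]
    if metaphase_distances_um is None:
        metaphase_distances_um = [k.metaphase_pole_distance_um
                                  for k in kymographs]
    if any(o is None for o in onsets):
        raise ValueError("every kymograph needs an anaphase onset")
    if any(m is None for m in metaphase_distances_um):
        raise ValueError("every kymograph needs a metaphase pole distance")

    mean_meta = float(np.mean(metaphase_distances_um))
    dt = kymographs[0].frame_interval_s
    if grid_step_um is None:
        grid_step_um = min(k.pixel_size_um for k in kymographs)

    scaled_extents = []
    for k, m in zip(kymographs, metaphase_distances_um):
        scale = mean_meta / m
        scaled_extents.append(np.abs(k.x_um * scale).max())
    half = max(scaled_extents)
    grid = np.arange(-half, half + grid_step_um / 2, grid_step_um)

    pre = max(int(o) for o in onsets)
    post = max(k.n_frames - int(o) for k, o in zip(kymographs, onsets))
    n_rows = pre + post

    total = np.zeros((n_rows, len(grid)))
    total_sq = np.zeros_like(total)
    count = np.zeros_like(total, dtype=int)

    for k, onset, meta in zip(kymographs, onsets, metaphase_distances_um):
        scale = mean_meta / meta
        xk = k.x_um * scale
        for r in range(k.n_frames):
            out_row = r - int(onset) + pre
            row = k.data[r]
            good = np.isfinite(row)
            if good.sum() < 2:
                continue
            vals = np.interp(grid, xk[good], row[good])
            inside = (grid >= xk[good][0]) & (grid <= xk[good][-1])
            total[out_row, inside] += vals[inside]
            total_sq[out_row, inside] += vals[inside] ** 2
            count[out_row, inside] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        var = np.where(
            count > 1,
            (total_sq - count * mean**2) / np.maximum(count - 1, 1),
            0.0,
        )
        sem = np.where(count > 0, np.sqrt(np.clip(var, 0, None))
                       / np.sqrt(np.maximum(count, 1)), np.nan)

    times = (np.arange(n_rows) - pre) * dt
    return AverageKymograph(mean, sem, count, grid, times, mean_meta,
                            channel=kymographs[0].channel)


# ---------------------------------------------------------------------------
# Profile extraction, background and bleaching correction
# ---------------------------------------------------------------------------


def _background_per_frame(data: np.ndarray, outer_frac: float = 0.1
                          ) -> np.ndarray:
    """Median of the outermost columns (off-spindle region), per frame."""
    n_cols = data.shape[1]
    k = max(int(round(outer_frac * n_cols / 2)), 1)
    outer = np.concatenate([data[:, :k], data[:, -k:]], axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(outer, axis=1)


def fit_bleach_factors(kymo: Kymograph, outer_frac: float = 0.1
                       ) -> tuple[np.ndarray, float]:
    """Mono-exponential photobleaching factors from total in-band intensity.

    The background-subtracted row sums are fitted with C * exp(-k t); the
    returned factors are exp(-k t) normalized to 1 at the first frame.
    """
    bg = _background_per_frame(kymo.data, outer_frac)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        totals = np.nansum(kymo.data - bg[:, None], axis=1)
    t = np.arange(kymo.n_frames, dtype=float) * kymo.frame_interval_s
    good = np.isfinite(totals) & (totals > 0)
    if good.sum() < 3:
        raise FitError("too few frames to fit a bleaching factor")

    def model(tv, c, k):
        return c * np.exp(-k * tv)

    c0 = float(totals[good][0])
    try:
        popt, _ = curve_fit(model, t[good], totals[good], p0=[c0, 1e-5],
                            bounds=([0, 0], [np.inf, 1.0]), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"bleach fit failed: {exc}") from exc
    rate = float(popt[1])
    return np.exp(-rate * t), rate


def correct_bleaching(kymo: Kymograph) -> Kymograph:
    """Divide each row by the fitted global photobleaching factor."""
    factors, _ = fit_bleach_factors(kymo)
    return replace(kymo, data=kymo.data / factors[:, None])


def extract_profile(
    kymo: Kymograph | AverageKymograph,
    time_index: int,
    window: int = 1,
    subtract_background: bool = True,
    bleach_factors: np.ndarray | None = None,
    outer_frac: float = 0.1,
) -> IntensityProfile:
    """One background-subtracted axial profile (row or window mean).

    For averaged kymographs, per-point standard errors propagate into the
    profile.  If ``bleach_factors`` is given, the profile is divided by the
    factor at that time.
    """
    data = kymo.data
    if not (0 <= time_index < data.shape[0]):
        raise IndexError("time index out of range")
    lo = max(time_index - window // 2, 0)
    hi = min(lo + window, data.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row = np.nanmean(data[lo:hi], axis=0)
    sem = None
    if isinstance(kymo, AverageKymograph):
        sem = np.sqrt(np.nansum(kymo.sem[lo:hi] ** 2, axis=0)) / (hi - lo)

    if subtract_background:
        bg = _background_per_frame(data[lo:hi], outer_frac)
        row = row - float(np.nanmean(bg))
    if bleach_factors is not None:
        row = row / float(np.mean(bleach_factors[lo:hi]))

    good = np.isfinite(row)
    x = kymo.x_um[good]
    return IntensityProfile(x, row[good],
                            sem[good] if sem is not None else None)


# ---------------------------------------------------------------------------
# Rainbow time stack
# ---------------------------------------------------------------------------


def render_time_stack(frames: np.ndarray, n_frames: int = 20,
                      hue_range: tuple[float, float] = (0.0, 2.0 / 3.0)
                      ) -> np.ndarray:
    """Rainbow-coded maximum projection of a time series.

    Each frame is tinted with a hue proportional to its index, running from
    red (first frame) to blue (last), then the tinted frames are
    max-projected.  Returns an (Y, X, 3) RGB float image in [0, 1].
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < 1:
        raise ValueError("need at least one frame")
    use = frames[:n_frames]
    T = use.shape[0]
    peak = float(np.max(use))
    norm = use / peak if peak > 0 else use

    out = np.zeros(use.shape[1:] + (3,))
    for i in range(T):
        frac = i / (T - 1) if T > 1 else 0.0
        hue = hue_range[0] + frac * (hue_range[1] - hue_range[0])
        rgb = hsv_to_rgb([hue, 1.0, 1.0])
        tinted = norm[i][..., None] * rgb[None, None, :]
        out = np.maximum(out, tinted)
    return out
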