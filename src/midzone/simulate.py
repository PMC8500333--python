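"""Synthetic ground-truth generators for every pipeline stage.

The movie generator renders an elongating bipolar spindle as seen in a
two-channel (crosslinker + DNA) time-lapse: the axial crosslinker profile
evolves from a single metaphase Gaussian into a central peak flanked by two
identical side peaks whose separation tracks pole elongation, while the DNA
channel shows two separating identical Gaussian masses.  The axial profile
is multiplied by a transverse Gaussian envelope (normalized to unit mean
over the image height, so that the noiseless column mean reproduces the
scheduled axial model exactly), scaled by a global photobleaching factor,
and corrupted by additive Gaussian or scaled-Poisson noise.

By default the generator conserves the integrated axial profile mass: the
protein is redistributed between the central overlap and the flanking
regions via a central-mass-fraction schedule, so peak amplitudes emerge
from compaction rather than being dialled in.  An explicit-amplitude,
non-conserving mode is available.

Every generated frame, FRAP curve, and comet track is recorded exactly once
in a :class:`GroundTruth` object that round-trips through JSON.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np

from .comets import CometTrajectory
from .core import CentrosomeTrack, ImageStack, IntensityProfile
from .frap import FrapRecord
from .profiles import (FWHM_FACTOR, AnaphaseProfileModel, DnaProfileModel,
                       GaussianPeak)


#: Midzone-protein turnover kinetics used as default ground truth for
#: synthetic FRAP ensembles: recovery time tau (s), mobile fraction mf,
#: and post-bleach intensity i0, per mitotic stage, as measured in
#: gene-edited RPE1 cells.  Intermediate-stage PRC1 mobile fractions
#: interpolate linearly between the measured metaphase and telophase ends;
#: the CLASP1 stage assignment pairs the fast end of its measured range
#: with early anaphase and the slow end with telophase.
FRAP_STAGE_KINETICS: dict[str, dict[str, dict[str, float]]] = {
    "PRC1": {
        "metaphase": {"tau_s": 6.0, "mf": 0.55, "i0": 0.2},
        "early anaphase": {"tau_s": 11.0, "mf": 0.48, "i0": 0.2},
        "mid anaphase": {"tau_s": 11.0, "mf": 0.41, "i0": 0.2},
        "late anaphase": {"tau_s": 44.0, "mf": 0.34, "i0": 0.2},
        "telophase": {"tau_s": 124.0, "mf": 0.27, "i0": 0.2},
    },
    "KIF4A": {
        "late anaphase": {"tau_s": 5.9, "mf": 0.95, "i0": 0.2},
        "telophase": {"tau_s": 30.0, "mf": 0.71, "i0": 0.2},
    },
    "CLASP1": {
        "early anaphase": {"tau_s": 1.3, "mf": 0.79, "i0": 0.2},
        "telophase": {"tau_s": 2.9, "mf": 0.64, "i0": 0.2},
    },
}

#: Default plus-end comet growth speeds (um/s) per mitotic stage for the
#: track generator: microtubule growth slows by roughly a third from
#: metaphase to telophase in RPE1 cells.
COMET_STAGE_SPEEDS: dict[str, float] = {
    "metaphase": 0.30,
    "early anaphase": 0.28,
    "mid anaphase": 0.25,
    "late anaphase": 0.20,
    "telophase": 0.18,
}


@dataclass
class SpindleSimConfig:
    """Parameters of the synthetic spindle movie.

    Lengths in micrometres, times in the units the field name states.
    Defaults encode an RPE1-like cell: an 8 um metaphase spindle elongating
    to a 20 um plateau over the first 5 min of anaphase, a central overlap
    whose FWHM decays mono-exponentially toward 1.7 um, and DNA masses
    separating at the elongation rate.
    """

    duration_min: float = 15.0
    frame_interval_s: float = 30.0
    pixel_size_um: float = 0.2
    image_shape: tuple[int, int] = (48, 160)  # (Y, X) pixels

    pole_distance_metaphase_um: float = 8.0
    pole_distance_plateau_um: float = 20.0
    elongation_duration_min: float = 5.0
    anaphase_onset_min: float = 3.0

    overlap_fwhm_initial_um: float = 6.0
    overlap_fwhm_final_um: float = 1.7
    overlap_decay_tau_min: float = 2.0

    # conserving mode: amplitudes derived from mass partition
    conserve_total_intensity: bool = True
    central_mass_frac_initial: float = 0.5
    central_mass_frac_final: float = 0.85
    central_mass_frac_tau_min: float = 3.0
    # explicit-amplitude (non-conserving) mode
    central_amp_initial: float = 1.0
    central_amp_final: float = 5.0
    central_amp_tau_min: float = 3.0
    side_amp: float = 1.0

    metaphase_amp: float = 1.0
    side_sigma_um: float = 0.9
    transverse_sigma_um: float = 1.5

    dna_amp: float = 1.0
    dna_sigma_um: float = 1.5
    dna_separation_frac: float = 1.0
    dna_transverse_sigma_um: float = 2.0

    background: float = 0.05
    bleach_rate_per_s: float = 1e-4
    noise_model: str = "gaussian"  # gaussian | poisson | none
    noise_sd: float = 0.02
    poisson_gain: float = 100.0

    rotation_deg: float = 0.0
    center_offset_px: tuple[float, float] = (0.0, 0.0)  # (dy, dx)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pole_distance_plateau_um > self.pole_distance_metaphase_um > 0):
            raise ValueError("need plateau > metaphase pole distance > 0")
        if not (self.overlap_fwhm_final_um < self.overlap_fwhm_initial_um):
            raise ValueError("final overlap FWHM must be below the initial one")
        for name in ("overlap_fwhm_final_um", "side_sigma_um", "dna_sigma_um",
                     "transverse_sigma_um", "dna_transverse_sigma_um",
                     "metaphase_amp", "overlap_decay_tau_min",
                     "frame_interval_s", "pixel_size_um", "duration_min"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.noise_model not in ("gaussian", "poisson", "none"):
            raise ValueError("noise_model must be gaussian, poisson or none")
        ny, nx = self.image_shape
        width_um = nx * self.pixel_size_um
        needed = self.pole_distance_plateau_um + 6 * self.side_sigma_um
        if width_um < needed:
            raise ValueError(
                f"image too small to contain the plateau spindle: width "
                f"{width_um:.1f} um < required {needed:.1f} um "
                f"(plateau pole distance + side-peak margin)"
            )
        if ny * self.pixel_size_um < 6 * self.transverse_sigma_um:
            raise ValueError("image too small for the transverse envelope")

    # -- schedules (t in seconds from movie start) --------------------------

    @property
    def anaphase_onset_s(self) -> float:
        return self.anaphase_onset_min * 60.0

    @property
    def anaphase_onset_frame(self) -> int:
        """First frame index whose time is at or after anaphase onset."""
        return int(math.ceil(self.anaphase_onset_s / self.frame_interval_s - 1e-9))

    def pole_distance_um(self, t_s: float) -> float:
        t_on = self.anaphase_onset_s
        if t_s < t_on:
            return self.pole_distance_metaphase_um
        frac = min((t_s - t_on) / (self.elongation_duration_min * 60.0), 1.0)
        return self.pole_distance_metaphase_um + frac * (
            self.pole_distance_plateau_um - self.pole_distance_metaphase_um
        )

    def overlap_fwhm_um(self, t_s: float) -> float:
        dt = max(t_s - self.anaphase_onset_s, 0.0)
        tau = self.overlap_decay_tau_min * 60.0
        return self.overlap_fwhm_final_um + (
            self.overlap_fwhm_initial_um - self.overlap_fwhm_final_um
        ) * math.exp(-dt / tau)

    def dna_separation_um(self, t_s: float) -> float:
        return self.dna_separation_frac * (
            self.pole_distance_um(t_s) - self.pole_distance_metaphase_um
        )

    @property
    def metaphase_sigma_um(self) -> float:
        """Metaphase single-Gaussian sigma: its FWHM equals the pole distance."""
        return self.pole_distance_metaphase_um / FWHM_FACTOR

    @property
    def total_profile_mass(self) -> float:
        """Integrated axial metaphase profile (conserved in default mode)."""
        return self.metaphase_amp * self.metaphase_sigma_um * math.sqrt(2 * math.pi)

    def protein_model(self, t_s: float):
        """Scheduled axial model: GaussianPeak before anaphase onset,
        AnaphaseProfileModel afterwards."""
        if t_s < self.anaphase_onset_s:
            return GaussianPeak(self.metaphase_amp, 0.0, self.metaphase_sigma_um)
        sigma_c = self.overlap_fwhm_um(t_s) / FWHM_FACTOR
        d = 0.5 * (self.pole_distance_um(t_s) - FWHM_FACTOR * self.side_sigma_um)
        dt = t_s - self.anaphase_onset_s
        if self.conserve_total_intensity:
            tau = self.central_mass_frac_tau_min * 60.0
            phi = self.central_mass_frac_initial + (
                self.central_mass_frac_final - self.central_mass_frac_initial
            ) * (1.0 - math.exp(-dt / tau))
            mass = self.total_profile_mass
            amp_c = phi * mass / (sigma_c * math.sqrt(2 * math.pi))
            amp_s = (1 - phi) * mass / (2 * self.side_sigma_um * math.sqrt(2 * math.pi))
        else:
            tau = self.central_amp_tau_min * 60.0
            amp_c = self.central_amp_initial + (
                self.central_amp_final - self.central_amp_initial
            ) * (1.0 - math.exp(-dt / tau))
            amp_s = self.side_amp
        return AnaphaseProfileModel(amp_c, 0.0, sigma_c, amp_s, d,
                                    self.side_sigma_um, 0.0)

    def dna_model(self, t_s: float) -> DnaProfileModel:
        return DnaProfileModel(self.dna_amp, 0.0, self.dna_separation_um(t_s),
                               self.dna_sigma_um, 0.0)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["center_offset_px"] = list(self.center_offset_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpindleSimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("image_shape", "center_offset_px"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-entity truth records; serializes losslessly to JSON."""

    movie_frames: list[dict] = field(default_factory=list)
    frap_curves: list[dict] = field(default_factory=list)
    comet_tracks: list[dict] = field(default_factory=list)
    config: dict | None = None

    def centrosome_track(self) -> CentrosomeTrack:
        if not self.movie_frames:
            raise ValueError("no movie frames in truth")
        frames = [f["frame"] for f in self.movie_frames]
        poles = [[f["pole_x1_px"], f["pole_y1_px"],
                  f["pole_x2_px"], f["pole_y2_px"]] for f in self.movie_frames]
        return CentrosomeTrack(np.array(frames), np.array(poles))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """One master seed, deterministically derived per-entity child streams."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def _apply_noise(image: np.ndarray, model: str, sd: float, gain: float,
                 rng: np.random.Generator) -> np.ndarray:
    if model == "none" or (model == "gaussian" and sd == 0):
        return image
    if model == "gaussian":
        return image + rng.normal(0.0, sd, size=image.shape)
    # scaled Poisson: shot noise at the configured camera gain
    return rng.poisson(np.clip(image, 0, None) * gain) / gain


def generate_spindle_movie(config: SpindleSimConfig
                           ) -> tuple[ImageStack, GroundTruth]:
    """Render the two-channel spindle movie and its complete ground truth."""
    ny, nx = config.image_shape
    n_frames = int(round(config.duration_min * 60.0 / config.frame_interval_s))
    dy, dx = config.center_offset_px
    cy, cx = (ny - 1) / 2.0 + dy, (nx - 1) / 2.0 + dx
    theta = math.radians(config.rotation_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    # axial (u) and transverse (v) coordinates in um
    u = (cos_t * (xx - cx) + sin_t * (yy - cy)) * config.pixel_size_um
    v = (-sin_t * (xx - cx) + cos_t * (yy - cy)) * config.pixel_size_um

    def envelope(sigma: float) -> np.ndarray:
        env = np.exp(-0.5 * (v / sigma) ** 2)
        # normalize so the transverse mean is 1: the noiseless column mean
        # then equals the scheduled axial model exactly (at zero rotation)
        rows_v = ((np.arange(ny) - cy) * config.pixel_size_um)
        norm = np.mean(np.exp(-0.5 * (rows_v / sigma) ** 2))
        return env / norm

    env_p = envelope(config.transverse_sigma_um)
    env_d = envelope(config.dna_transverse_sigma_um)

    rng_p, rng_d = _spawn_rngs(config.seed, 2)
    data = np.empty((n_frames, 2, ny, nx), dtype=np.float64)
    truth = GroundTruth(config=config.to_dict())

    for i in range(n_frames):
        t = i * config.frame_interval_s
        bleach = math.exp(-config.bleach_rate_per_s * t)
        pmodel = config.protein_model(t)
        dmodel = config.dna_model(t)

        prot = bleach * (pmodel(u) * env_p + config.background)
        dna = bleach * (dmodel(u) * env_d + config.background)
        data[i, 0] = _apply_noise(prot, config.noise_model, config.noise_sd,
                                  config.poisson_gain, rng_p)
        data[i, 1] = _apply_noise(dna, config.noise_model, config.noise_sd,
                                  config.poisson_gain, rng_d)

        half_px = config.pole_distance_um(t) / 2.0 / config.pixel_size_um
        rec = {
            "frame": i,
            "time_s": t,
            "phase": "metaphase" if t < config.anaphase_onset_s else "anaphase",
            "bleach_factor": bleach,
            "pole_distance_um": config.pole_distance_um(t),
            "pole_x1_px": cx - half_px * cos_t,
            "pole_y1_px": cy - half_px * sin_t,
            "pole_x2_px": cx + half_px * cos_t,
            "pole_y2_px": cy + half_px * sin_t,
            "dna_separation_um": dmodel.separation,
            "dna_sigma_um": dmodel.sigma,
            "dna_amp": dmodel.amplitude,
        }
        if isinstance(pmodel, AnaphaseProfileModel):
            rec.update(
                amp_central=pmodel.amp_central, center_um=pmodel.center,
                sigma_central_um=pmodel.sigma_central, amp_side=pmodel.amp_side,
                side_offset_um=pmodel.side_offset,
                sigma_side_um=pmodel.sigma_side, baseline=pmodel.baseline,
                overlap_fwhm_um=pmodel.overlap_length,
                total_width_um=pmodel.total_width,
            )
        else:
            rec.update(
                amp_central=pmodel.amplitude, center_um=pmodel.center,
                sigma_central_um=pmodel.sigma, amp_side=0.0,
                side_offset_um=None, sigma_side_um=None, baseline=0.0,
                overlap_fwhm_um=None, total_width_um=pmodel.fwhm,
            )
        truth.movie_frames.append(rec)

    stack = ImageStack(data, config.pixel_size_um, config.frame_interval_s,
                       ("protein", "dna"))
    return stack, truth


def generate_ensemble(
    config: SpindleSimConfig,
    n_cells: int = 17,
    pole_jitter_frac: float = 0.1,
    onset_jitter_frames: int = 1,
    seed: int | None = None,
) -> list[SpindleSimConfig]:
    """Per-cell config variants: metaphase and plateau pole distances scaled
    by a common random factor, anaphase onset jittered by whole frames."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for i in range(n_cells):
        scale = 1.0 + rng.uniform(-pole_jitter_frac, pole_jitter_frac)
        jit = rng.integers(-onset_jitter_frames, onset_jitter_frames + 1)
        onset = config.anaphase_onset_min + jit * config.frame_interval_s / 60.0
        out.append(replace(
            config,
            pole_distance_metaphase_um=config.pole_distance_metaphase_um * scale,
            pole_distance_plateau_um=config.pole_distance_plateau_um * scale,
            anaphase_onset_min=onset,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return out


def generate_frap_curves(
    stage_params: dict,
    n_curves: int,
    frame_interval_s: float = 2.0,
    duration_s: float = 180.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    stage: str = "unknown",
    n_prebleach: int = 4,
    bleach_rate_per_s: float = 0.0,
    raw_scale: float = 1.0,
) -> tuple[list[FrapRecord], list[dict]]:
    """Simulate normalized-scale FRAP curves obeying I0 + Ia(1 - e^{-t/tau}).

    ``stage_params`` holds ``i0``, ``tau_s`` and ``mf`` (the recovery
    fraction); the recovery amplitude is Ia = mf * (1 - I0).  Each curve has
    ``n_prebleach`` pre-bleach points near 1 followed by the bleach frame
    (the drop to ~I0) and the recovery sampled every ``frame_interval_s``
    for ``duration_s``.  A positive ``bleach_rate_per_s`` multiplies the
    whole curve by exp(-k t) and attaches the matching reference series, so
    the bleach-correction path can be exercised with known truth.
    """
    i0 = float(stage_params["i0"])
    tau = float(stage_params["tau_s"])
    mf = float(stage_params["mf"])
    if not (0 <= i0 < 1):
        raise ValueError("need 0 <= i0 < 1")
    if not (tau > 0):
        raise ValueError("tau_s must be positive")
    if mf < 0:
        raise ValueError("mf must be non-negative")
    ia = mf * (1.0 - i0)
    # mf > 1 (plateau above the pre-bleach level) is tolerated but flagged
    if i0 + ia > 1 + 1e-12:
        warnings.warn("recovery plateau exceeds the pre-bleach level "
                      "(unphysical for normalized data)", stacklevel=2)

    n_post = int(round(duration_s / frame_interval_s))
    bleach_index = n_prebleach
    times = np.arange(n_prebleach + 1 + n_post) * frame_interval_s
    t_bleach = times[bleach_index]

    ideal = np.empty_like(times)
    ideal[:bleach_index] = 1.0
    ideal[bleach_index:] = i0 + ia * (1.0 - np.exp(-(times[bleach_index:] - t_bleach) / tau))

    rngs = _spawn_rngs(seed, n_curves)
    records, truths = [], []
    for k, rng in enumerate(rngs):
        y = ideal.copy()
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        reference = None
        if bleach_rate_per_s > 0:
            decay = np.exp(-bleach_rate_per_s * times)
            y = y * decay
            reference = decay.copy()
        records.append(FrapRecord(
            times_s=times.copy(), roi_intensity=raw_scale * y,
            bleach_index=bleach_index, reference_intensity=reference,
            stage=stage,
        ))
        truths.append({"curve_id": k, "i0": i0, "tau_s": tau, "mf": mf,
                       "stage": stage})
    return records, truths


def generate_comet_tracks(
    stage_speed_um_per_s: float,
    speed_sd: float,
    n_tracks: int,
    duration_range_s: tuple[float, float] = (2.0, 10.0),
    frame_interval_s: float = 0.25,
    pole_positions_um: tuple[float, float] = (-10.0, 10.0),
    internal_fraction: float = 0.7,
    seed: int = 0,
    stage: str = "unknown",
) -> tuple[list[CometTrajectory], list[dict]]:
    """Constant-velocity comet tracks with known speeds and classes.

    Internal tracks are confined strictly between the poles (their duration
    is truncated before they would cross a pole); external tracks start
    beyond a pole and move away from the spindle.
    """
    if stage_speed_um_per_s < 0 or speed_sd < 0:
        raise ValueError("speeds must be non-negative")
    lo, hi = sorted(pole_positions_um)
    if lo == hi:
        raise ValueError("poles must be distinct")

    rngs = _spawn_rngs(seed, n_tracks)
    tracks, truths = [], []
    margin = 0.02 * (hi - lo)
    for k, rng in enumerate(rngs):
        speed = max(float(rng.normal(stage_speed_um_per_s, speed_sd)), 0.0)
        duration = float(rng.uniform(*duration_range_s))
        internal = bool(rng.random() < internal_fraction)
        direction = 1.0 if rng.random() < 0.5 else -1.0
        if internal:
            x0 = float(rng.uniform(lo + margin, hi - margin))
            if speed > 0:
                room = (hi - margin - x0) if direction > 0 else (x0 - lo - margin)
                duration = min(duration, room / speed)
        else:
            off = float(rng.uniform(margin, 0.3 * (hi - lo)))
            beyond_hi = rng.random() < 0.5
            x0 = hi + off if beyond_hi else lo - off
            direction = 1.0 if beyond_hi else -1.0
        n_frames = max(2, int(round(duration / frame_interval_s)) + 1)
        t = np.arange(n_frames) * frame_interval_s
        x = x0 + direction * speed * t
        label = "internal" if internal else "external"
        tracks.append(CometTrajectory(k, t, x, label=label))
        truths.append({"track_id": k, "speed_um_s": speed, "label": label,
                       "duration_s": float(t[-1]), "stage": stage})
    return tracks, truths


def generate_profile(
    model,
    x_grid_um: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IntensityProfile:
    """Evaluate any callable profile model on a grid, plus i.i.d. noise."""
    x = np.asarray(x_grid_um, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("x_grid must be strictly increasing")
    y = np.asarray(model(x), dtype=float)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
    return IntensityProfile(x, y)
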