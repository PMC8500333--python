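"""Shared calibrated data containers for movies, profiles, and pole annotations.

All lengths are micrometres, all times seconds, unless a name says otherwise.
Frame indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CalibrationError(ValueError):
    """An image stack is missing pixel-size or frame-interval calibration."""


@dataclass
class ImageStack:
    """A calibrated T x C x Y x X intensity movie.

    Parameters
    ----------
    data:
        Intensity array, axes (time, channel, y, x).
    pixel_size_um:
        Lateral pixel size in micrometres (isotropic).
    frame_interval_s:
        Time between consecutive frames in seconds.
    channel_names:
        One name per channel, e.g. ``("protein", "dna")``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: tuple[str, ...] = ("protein", "dna")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack must be 4-D (T, C, Y, X), got shape {self.data.shape}"
            )
        if not (self.pixel_size_um > 0):
            raise CalibrationError("pixel_size_um must be positive")
        if not (self.frame_interval_s > 0):
            raise CalibrationError("frame_interval_s must be positive")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class CentrosomeTrack:
    """Per-frame manually annotated spindle-pole coordinates, in pixels.

    ``frames[i]`` is the frame index of row i; ``poles[i]`` is
    ``(x1, y1, x2, y2)``.
    """

    frames: np.ndarray
    poles: np.ndarray  # (N, 4) columns x1, y1, x2, y2

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.poles = np.asarray(self.poles, dtype=float)
        if self.poles.ndim != 2 or self.poles.shape[1] != 4:
            raise ValueError("poles must have shape (N, 4): x1, y1, x2, y2")
        if len(self.frames) != len(self.poles):
            raise ValueError("frames and poles length mismatch")
        same = np.all(self.poles[:, :2] == self.poles[:, 2:], axis=1)
        if np.any(same):
            bad = self.frames[same]
            raise ValueError(f"coincident poles in frame(s) {bad.tolist()}")

    def for_frame(self, frame: int) -> np.ndarray:
        idx = np.flatnonzero(self.frames == frame)
        if idx.size == 0:
            raise KeyError(f"no pole annotation for frame {frame}")
        return self.poles[idx[0]]

    def distances_px(self) -> np.ndarray:
        dx = self.poles[:, 2] - self.poles[:, 0]
        dy = self.poles[:, 3] - self.poles[:, 1]
        return np.hypot(dx, dy)


@dataclass
class IntensityProfile:
    """A 1-D axial intensity profile, optionally with per-point uncertainty."""

    x_um: np.ndarray
    intensity: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x_um.shape != self.intensity.shape:
            raise ValueError("x_um and intensity must have the same shape")
        if np.any(np.diff(self.x_um) <= 0):
            raise ValueError("x_um must be strictly increasing")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.x_um.shape:
                raise ValueError("sem shape mismatch")
            if np.any(self.sem < 0):
                raise ValueError("sem must be non-negative")

    def __len__(self) -> int:
        return len(self.x_um)
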