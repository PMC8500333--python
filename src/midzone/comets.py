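"""Plus-end comet trajectory statistics.

Trajectories arrive in kymograph space (time, axial position along the
pole-to-pole axis) from an external tracker.  Operations: a minimum-length
filter, endpoint average speed, internal/external classification relative
to the poles, per-stage speed summaries, a track-duration survival curve,
and a position histogram along the normalized pole-to-pole coordinate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class CometTrajectory:
    """One comet track: strictly time-ordered samples along the spindle axis."""

    track_id: int | str
    times_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray | None = None
    label: str = "unclassified"  # internal | external | unclassified

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        if self.times_s.shape != self.x_um.shape:
            raise ValueError("times and positions must match in length")
        if len(self.times_s) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.y_um is not None:
            self.y_um = np.asarray(self.y_um, dtype=float)
            if self.y_um.shape != self.times_s.shape:
                raise ValueError("y_um length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


def filter_tracks(tracks: list[CometTrajectory], min_frames: int = 3
                  ) -> list[CometTrajectory]:
    """Drop tracks with fewer than ``min_frames`` samples (boundary kept)."""
    kept = [t for t in tracks if t.n_frames >= min_frames]
    removed = len(tracks) - len(kept)
    if removed:
        warnings.warn(f"filtered out {removed} track(s) shorter than "
                      f"{min_frames} frames", stacklevel=2)
    return kept


def comet_speed(track: CometTrajectory) -> float:
    """Endpoint average speed: first-to-last displacement over elapsed time."""
    dt = track.duration_s
    if dt <= 0:
        raise ValueError("zero elapsed time")
    dx = track.x_um[-1] - track.x_um[0]
    if track.y_um is not None:
        dy = track.y_um[-1] - track.y_um[0]
        return math.hypot(dx, dy) / dt
    return abs(dx) / dt


def classify_comet(track: CometTrajectory,
                   pole_positions_um: tuple[float, float]) -> str:
    """"internal" if the majority of samples lie strictly between the poles."""
    lo, hi = sorted(pole_positions_um)
    if lo == hi:
        raise ValueError("poles must be distinct")
    inside = np.sum((track.x_um > lo) & (track.x_um < hi))
    return "internal" if inside > track.n_frames / 2 else "external"


def classify_tracks(tracks: list[CometTrajectory],
                    pole_positions_um: tuple[float, float]
                    ) -> list[CometTrajectory]:
    return [replace(t, label=classify_comet(t, pole_positions_um))
            for t in tracks]


@dataclass
class StageSpeedSummary:
    stage: str
    n_tracks: int
    median_um_s: float
    mean_um_s: float
    sem_um_s: float          # SEM of the mean, as paired with medians in plots
    mad_um_s: float          # median absolute deviation alternative
    q25_um_s: float
    q75_um_s: float
    n_cells: int | None = None


def summarize_speeds(tracks_by_stage: dict[str, list[CometTrajectory]],
                     cells_by_stage: dict[str, int] | None = None
                     ) -> pd.DataFrame:
    """Per-stage speed statistics (median, mean, SEM, MAD, quartiles).

    Empty stages are omitted with a warning.  Returns a DataFrame indexed
    by stage, in the input order.
    """
    rows = []
    for stage, tracks in tracks_by_stage.items():
        if not tracks:
            warnings.warn(f"stage {stage!r} has no tracks; omitted", stacklevel=2)
            continue
        v = np.array([comet_speed(t) for t in tracks])
        n = len(v)
        sem = float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(StageSpeedSummary(
            stage=stage, n_tracks=n,
            median_um_s=float(np.median(v)),
            mean_um_s=float(v.mean()),
            sem_um_s=sem,
            mad_um_s=float(np.median(np.abs(v - np.median(v)))),
            q25_um_s=float(np.percentile(v, 25)),
            q75_um_s=float(np.percentile(v, 75)),
            n_cells=None if cells_by_stage is None else cells_by_stage.get(stage),
        ))
    if not rows:
        raise ValueError("no stage has any tracks")
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("stage")
    return df


@dataclass
class SurvivalCurve:
    """S(t): fraction of tracks whose duration is at least t."""

    durations_s: np.ndarray   # sorted unique evaluation points
    survival: np.ndarray
    durations_frames: np.ndarray
    survival_frames: np.ndarray

    def at(self, t_s: float) -> float:
        return float(np.mean(self._all_durations >= t_s))

    _all_durations: np.ndarray = field(default=None, repr=False)


def survival_curve(tracks: list[CometTrajectory],
                   frame_interval_s: float | None = None) -> SurvivalCurve:
    """Empirical survival function of track duration, in seconds and frames.

    S(t) = fraction of tracks with duration >= t; starts at 1 and is
    non-increasing.  Frame durations count samples (a track spanning k
    frame intervals has k+1 frames).
    """
    if not tracks:
        raise ValueError("no tracks")
    dur_s = np.array([t.duration_s for t in tracks])
    n_frames = np.array([t.n_frames for t in tracks])
    if frame_interval_s is None:
        steps = np.concatenate([np.diff(t.times_s) for t in tracks])
        frame_interval_s = float(np.min(steps))

    ts = np.unique(np.concatenate([[0.0], dur_s]))
    surv_s = np.array([np.mean(dur_s >= t) for t in ts])
    fr = np.unique(np.concatenate([[0], n_frames]))
    surv_f = np.array([np.mean(n_frames >= f) for f in fr])
    return SurvivalCurve(ts, surv_s, fr.astype(float), surv_f,
                         _all_durations=dur_s)


def position_histogram(tracks: list[CometTrajectory],
                       pole_positions_um: tuple[float, float],
                       bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of comet locations on the [0, 1] pole-to-pole axis.

    Each comet contributes one location (its mean axial position), so counts
    sum to the number of tracks.  Returns (counts, bin_edges).  Locations
    outside the poles are clipped into the boundary bins.
    """
    lo, hi = sorted(pole_positions_um)
    if lo == hi:
        raise ValueError("poles must be distinct")
    xs = np.array([float(np.mean(t.x_um)) for t in tracks])
    frac = np.clip((xs - lo) / (hi - lo), 0.0, 1.0)
    counts, edges = np.histogram(frac, bins=bins, range=(0.0, 1.0))
    return counts, edges
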