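"""Readers and writers for movies, kymographs, tracks, FRAP curves and results.

Conventions: lengths are stored in micrometres and times in seconds; CSVs
use a decimal point, UTF-8 and a mandatory header row.  Image stacks are
multi-page TIFFs with a JSON metadata sidecar (same stem, ``.json``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .comets import CometTrajectory
from .core import CalibrationError, CentrosomeTrack, ImageStack
from .frap import FrapRecord
from .kymograph import AverageKymograph, Kymograph

CANONICAL_AXES = "TCYX"


def _sidecar(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a TIFF plus JSON sidecar (pixel size, interval, channels, axes)."""
    path = Path(path)
    tifffile.imwrite(path, stack.data)
    meta = {
        "axes": CANONICAL_AXES,
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "channel_names": list(stack.channel_names),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_image_stack(path: str | Path) -> ImageStack:
    """Read a TIFF + sidecar into a calibrated T x C x Y x X stack.

    The sidecar's ``axes`` string may declare any permutation of TCYX; the
    data are transposed to canonical order.  Missing calibration raises
    :class:`CalibrationError` rather than silently assuming pixel units.
    """
    path = Path(path)
    data = tifffile.imread(path)
    side = _sidecar(path)
    if not side.exists():
        raise CalibrationError(f"no metadata sidecar found at {side}")
    meta = json.loads(side.read_text())
    for key in ("pixel_size_um", "frame_interval_s"):
        if key not in meta:
            raise CalibrationError(f"sidecar missing {key!r}")

    axes = meta.get("axes", CANONICAL_AXES).upper()
    if sorted(axes) != sorted(CANONICAL_AXES):
        raise ValueError(f"axes {axes!r} are not a permutation of TCYX")
    if data.ndim != 4:
        raise ValueError(
            f"stack with declared axes {axes!r} must be 4-D, got {data.ndim}-D"
        )
    order = [axes.index(a) for a in CANONICAL_AXES]
    data = np.transpose(data, order)
    return ImageStack(
        data,
        float(meta["pixel_size_um"]),
        float(meta["frame_interval_s"]),
        tuple(meta.get("channel_names",
                       [f"ch{i}" for i in range(data.shape[1])])),
    )


# ---------------------------------------------------------------------------
# Pole annotations
# ---------------------------------------------------------------------------

POLE_COLUMNS = ["frame", "x1", "y1", "x2", "y2"]


def write_poles_csv(track: CentrosomeTrack, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(track.poles, columns=POLE_COLUMNS[1:])
    df.insert(0, "frame", track.frames)
    df.to_csv(path, index=False)
    return path


def read_poles_csv(path: str | Path) -> CentrosomeTrack:
    df = _read_numeric_csv(path, POLE_COLUMNS)
    return CentrosomeTrack(df["frame"].to_numpy(dtype=int),
                           df[POLE_COLUMNS[1:]].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Comet tracks
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_um"]


def _read_numeric_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    """Read a CSV, checking required columns and reporting malformed rows
    by 1-based file line number (header is line 1)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    numeric_cols = [c for c in df.columns if c != "track_id" or True]
    bad_lines: list[int] = []
    for col in numeric_cols:
        if col == "track_id":
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        bad_lines.extend((df.index[bad] + 2).tolist())
        df[col] = coerced
    if bad_lines:
        raise ValueError(
            f"{path}: non-numeric values at line(s) {sorted(set(bad_lines))}"
        )
    if df.drop(columns=["track_id"], errors="ignore").isna().any().any():
        rows = df.index[df.isna().any(axis=1)] + 2
        raise ValueError(f"{path}: missing values at line(s) {rows.tolist()}")
    return df


def read_tracks_csv(path: str | Path) -> list[CometTrajectory]:
    """Load comet trajectories from tracker-output CSV
    (track_id, frame, time_s, x_um[, y_um])."""
    df = _read_numeric_csv(path, TRACK_COLUMNS)
    has_y = "y_um" in df.columns
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("time_s")
        tracks.append(CometTrajectory(
            tid,
            grp["time_s"].to_numpy(dtype=float),
            grp["x_um"].to_numpy(dtype=float),
            grp["y_um"].to_numpy(dtype=float) if has_y else None,
        ))
    return tracks


def write_tracks_csv(tracks: list[CometTrajectory], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for t in tracks:
        for i in range(t.n_frames):
            row = {"track_id": t.track_id, "frame": i,
                   "time_s": t.times_s[i], "x_um": t.x_um[i]}
            if t.y_um is not None:
                row["y_um"] = t.y_um[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# FRAP curves
# ---------------------------------------------------------------------------


def write_frap_csv(record: FrapRecord, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": record.times_s, "roi": record.roi_intensity})
    if record.reference_intensity is not None:
        df["reference"] = record.reference_intensity
    df.to_csv(path, index=False)
    return path


def read_frap_csv(path: str | Path, bleach_index: int,
                  stage: str = "unknown") -> FrapRecord:
    df = _read_numeric_csv(path, ["time_s", "roi"])
    ref = df["reference"].to_numpy(float) if "reference" in df.columns else None
    return FrapRecord(df["time_s"].to_numpy(float), df["roi"].to_numpy(float),
                      bleach_index, reference_intensity=ref, stage=stage)


# ---------------------------------------------------------------------------
# Kymographs
# ---------------------------------------------------------------------------


def write_kymograph(kymo: Kymograph | AverageKymograph, path: str | Path) -> Path:
    """Matrix CSV plus JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, kymo.data, delimiter=",")
    if isinstance(kymo, AverageKymograph):
        meta = {
            "kind": "average",
            "x_um": kymo.x_um.tolist(),
            "times_s": kymo.times_s.tolist(),
            "mean_metaphase_distance_um": kymo.mean_metaphase_distance_um,
            "channel": kymo.channel,
        }
        np.savetxt(path.with_suffix(".sem.csv"), kymo.sem, delimiter=",")
        np.savetxt(path.with_suffix(".n.csv"), kymo.n, delimiter=",", fmt="%d")
    else:
        meta = {
            "kind": "single",
            "pixel_size_um": kymo.pixel_size_um,
            "frame_interval_s": kymo.frame_interval_s,
            "channel": kymo.channel,
            "midpoint_col": kymo.midpoint_col,
            "anaphase_onset_frame": kymo.anaphase_onset_frame,
            "metaphase_pole_distance_um": kymo.metaphase_pole_distance_um,
        }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_kymograph(path: str | Path) -> Kymograph | AverageKymograph:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") == "average":
        sem = np.loadtxt(path.with_suffix(".sem.csv"), delimiter=",", ndmin=2)
        n = np.loadtxt(path.with_suffix(".n.csv"), delimiter=",", ndmin=2).astype(int)
        return AverageKymograph(data, sem, n, np.asarray(meta["x_um"]),
                                np.asarray(meta["times_s"]),
                                meta["mean_metaphase_distance_um"],
                                channel=meta.get("channel", "protein"))
    return Kymograph(data, meta["pixel_size_um"], meta["frame_interval_s"],
                     channel=meta.get("channel", "protein"),
                     midpoint_col=meta.get("midpoint_col"),
                     anaphase_onset_frame=meta.get("anaphase_onset_frame"),
                     metaphase_pole_distance_um=meta.get(
                         "metaphase_pole_distance_um"))


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------


def config_hash(config: dict) -> str:
    """Stable SHA-256 hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_results(record: dict, path: str | Path,
                  config: dict | None = None, seed: int | None = None) -> Path:
    """Write a result JSON with provenance (config hash, seed, version)."""
    path = Path(path)
    out = {
        "provenance": {
            "software": "midzone",
            "version": __version__,
            "config_hash": config_hash(config or {}),
            "seed": seed,
        },
        "results": _jsonify(record),
    }
    path.write_text(json.dumps(out, indent=1, sort_keys=True))
    return path


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonify(asdict(obj))
    return obj
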