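"""File formats: track CSV, TIFF movies with JSON sidecars, configs.

Trajectories interchange as plain CSV (columns ``track_id, frame, t_s,
x_um, y_um``) for diff-ability; movies as 16-bit multi-page TIFF with a
JSON sidecar carrying ground truth and camera metadata. All lengths are μm
internally — pixel conversion happens only at the image boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import FrameStack
from .tracks import Trajectory, TrackSet

__all__ = ["read_tracks", "write_tracks", "write_frames", "read_frames", "load_config"]

_TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]
_DT_RTOL = 1e-6


def read_tracks(path: str | Path) -> TrackSet:
    """Read a track CSV into a TrackSet.

    Rows are grouped by ``track_id`` and sorted by ``frame`` (input order
    does not matter). The frame interval is inferred from ``t_s`` and
    checked to be uniform across the file.

    Raises
    ------
    ValueError
        Naming the offending column or row for: missing columns, duplicate
        (track_id, frame) pairs, or a non-uniform frame interval.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return TrackSet(tracks=[], dt_s=1.0, metadata={"source": str(path)})
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (track_id, frame) = ({row['track_id']}, {row['frame']})"
        )
    df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)

    dt = None
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        frames = g["frame"].to_numpy(dtype=int)
        times = g["t_s"].to_numpy(dtype=float)
        if len(frames) >= 2:
            steps = np.diff(times) / np.diff(frames)
            dt_track = float(np.median(steps))
            if not np.allclose(steps, dt_track, rtol=1e-3, atol=1e-9):
                bad = int(np.argmax(np.abs(steps - dt_track)))
                raise ValueError(
                    f"{path}: non-uniform frame interval in track {tid} near frame {frames[bad]}"
                )
            if dt is None:
                dt = dt_track
            elif not np.isclose(dt, dt_track, rtol=_DT_RTOL):
                raise ValueError(
                    f"{path}: track {tid} interval {dt_track} differs from {dt}"
                )
        tracks.append(
            Trajectory(
                track_id=int(tid),
                frames=frames,
                x_um=g["x_um"].to_numpy(dtype=float),
                y_um=g["y_um"].to_numpy(dtype=float),
                dt_s=dt if dt is not None else 1.0,
            )
        )
    return TrackSet(tracks=tracks, dt_s=dt if dt is not None else 1.0, metadata={"source": str(path)})


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    """Write a TrackSet to CSV, deterministically.

    Rows ordered by (track_id, frame); coordinates at fixed 6-decimal μm
    precision so two writes of the same TrackSet are byte-identical.
    """
    rows = []
    for t in sorted(ts.tracks, key=lambda t: t.track_id):
        for f, time, x, y in zip(t.frames, t.times_s, t.x_um, t.y_um):
            rows.append((t.track_id, int(f), time, x, y))
    df = pd.DataFrame(rows, columns=_TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def write_frames(stack: FrameStack, path: str | Path) -> None:
    """Write a FrameStack as 16-bit multi-page TIFF + JSON sidecar.

    Intensities are clipped to the uint16 range; the sidecar (``<path>.json``)
    holds pixel size, frame interval, per-frame ground truth and the render
    metadata.
    """
    path = Path(path)
    data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "pixel_size_nm": stack.pixel_size_nm,
        "dt_s": stack.dt_s,
        "ground_truth": [g.tolist() for g in stack.ground_truth],
        "metadata": _jsonable(stack.metadata),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_frames(path: str | Path) -> FrameStack:
    """Read a TIFF movie written by :func:`write_frames` (sidecar required)."""
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sc = json.loads(sidecar_path.read_text())
    return FrameStack(
        frames=frames,
        pixel_size_nm=sc["pixel_size_nm"],
        dt_s=sc["dt_s"],
        ground_truth=[np.asarray(g, dtype=float).reshape(-1, 3) for g in sc["ground_truth"]],
        metadata=sc.get("metadata", {}),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
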