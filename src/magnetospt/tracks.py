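"""Trajectory containers shared by the simulator, tracker and estimators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np


@dataclass
class Trajectory:
    """One particle's time-ordered 2D path at a uniform frame interval.

    Attributes
    ----------
    track_id : int
        Unique identifier within a :class:`TrackSet`.
    frames : ndarray of int
        Strictly increasing frame indices.
    x_um, y_um : ndarray of float
        Positions in micrometres (x rightward, y downward, image convention).
    dt_s : float
        Frame interval in seconds; times are ``frames * dt_s``.
    """

    track_id: int
    frames: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    dt_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = len(self.frames)
        if n < 2:
            raise ValueError(f"track {self.track_id}: length {n} < 2")
        if len(self.x_um) != n or len(self.y_um) != n:
            raise ValueError(f"track {self.track_id}: coordinate/frame length mismatch")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")
        if not self.dt_s > 0:
            raise ValueError("dt_s must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return self.frames * self.dt_s

    @property
    def xy(self) -> np.ndarray:
        """(N, 2) position array in μm."""
        return np.column_stack([self.x_um, self.y_um])

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def net_displacement_um(self) -> float:
        """Start-to-end Euclidean distance in μm."""
        return float(np.hypot(self.x_um[-1] - self.x_um[0], self.y_um[-1] - self.y_um[0]))


@dataclass
class TrackSet:
    """A collection of trajectories sharing one frame interval.

    ``metadata`` carries provenance (pixel size, generator parameters, seed)
    and travels with the tracks through I/O round trips.
    """

    tracks: list[Trajectory]
    dt_s: float
    pixel_size_nm: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValueError("track_ids must be unique")
        for t in self.tracks:
            if not np.isclose(t.dt_s, self.dt_s):
                raise ValueError(
                    f"track {t.track_id} dt {t.dt_s} differs from TrackSet dt {self.dt_s}"
                )

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.tracks)

    def __getitem__(self, track_id: int) -> Trajectory:
        for t in self.tracks:
            if t.track_id == track_id:
                return t
        raise KeyError(track_id)
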