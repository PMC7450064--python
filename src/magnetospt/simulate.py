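"""Synthetic drift-diffusion trajectories, camera frames and fiducial pairs.

This module produces the ground-truth inputs for every downstream stage:

* :func:`simulate_tracks` integrates 2D Brownian motion with a
  force-induced drift toward a magnetized needle tip (Euler-Maruyama, one
  step per camera frame), then adds independent localization noise to the
  reported positions — noise observes the path, it does not feed back into
  the dynamics.
* :func:`render_frames` draws each particle as an integrated Gaussian PSF
  on a camera with Poisson shot noise and Gaussian read noise.
* :func:`make_fiducial_pair` produces matched point sets related by a known
  nonreflective similarity transform, for registration round-trips.

Defaults reflect membrane SPT conditions: lipid-scale diffusivity around
0.13 μm²/s, ~10 nm localization noise, 99 or 217 nm camera pixels, frame
intervals from 5 ms (fast SPT) to 1 s (force calibration).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .physics import NeedleGeometry, PhysicalParams, drift_velocity, force_field
from .register import SimilarityTransform, apply_transform
from .tracks import Trajectory, TrackSet

__all__ = [
    "SimulationConfig",
    "CameraModel",
    "FrameStack",
    "simulate_tracks",
    "render_frames",
    "make_fiducial_pair",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a drift-diffusion tracking simulation.

    Attributes
    ----------
    D_true : float
        Diffusion coefficient, μm²/s. Membrane lipids in supported bilayers
        diffuse at roughly 0.03-0.15 μm²/s; default 0.13.
    dt_s : float
        Frame interval in seconds (also the integration step).
    n_frames, n_tracks : int
        Frames per track and number of tracks.
    sigma_loc_um : float
        Localization noise s.d. per axis added to reported positions
        (default 0.01 μm = 10 nm, typical bright-particle precision).
    arena_um : (xmin, ymin, xmax, ymax)
        Bounding box for starting positions; a track that leaves the arena
        is truncated there (the particle left the field of view).
    seed : int
        Seed for the generator; identical configs and seeds give identical
        output bit for bit.
    """

    D_true: float = 0.13
    dt_s: float = 0.02
    n_frames: int = 500
    n_tracks: int = 100
    sigma_loc_um: float = 0.01
    arena_um: tuple[float, float, float, float] = (0.0, 0.0, 200.0, 200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_true < 0:
            raise ValueError("D_true must be >= 0")
        if not self.dt_s > 0:
            raise ValueError("dt_s must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.sigma_loc_um < 0:
            raise ValueError("sigma_loc_um must be >= 0")
        xmin, ymin, xmax, ymax = self.arena_um
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("arena must have positive extent")


@dataclass(frozen=True)
class CameraModel:
    """Camera and PSF parameters for frame rendering.

    ``pixel_size_nm`` presets of 99 (unbinned sCMOS) and 217 (2x2-binned)
    correspond to the two microscopes used for SPT and force calibration.
    """

    pixel_size_nm: float = 99.0
    psf_sigma_nm: float = 130.0
    photons_per_spot: float = 5000.0
    background: float = 20.0
    read_noise: float = 1.5
    frame_shape: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not self.psf_sigma_nm > 0:
            raise ValueError("psf_sigma_nm must be > 0")
        if not self.photons_per_spot > 0:
            raise ValueError("photons_per_spot must be > 0")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm


@dataclass
class FrameStack:
    """Synthetic movie plus the ground truth that generated it.

    ``ground_truth[i]`` is an (n_i, 3) array of (track_id, x_um, y_um) for
    the emitters present in frame ``i``.
    """

    frames: np.ndarray  # (T, rows, cols) float photons or uint16 counts
    pixel_size_nm: float
    dt_s: float
    ground_truth: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) array")
        if len(self.ground_truth) != self.frames.shape[0]:
            raise ValueError("ground_truth length must equal frame count")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.frames.shape[0]


def _inside(arena: tuple[float, float, float, float], pos: np.ndarray) -> bool:
    xmin, ymin, xmax, ymax = arena
    return bool(xmin <= pos[0] <= xmax and ymin <= pos[1] <= ymax)


def simulate_tracks(
    config: SimulationConfig,
    needle: NeedleGeometry | None = None,
    phys: PhysicalParams = PhysicalParams(),
    start_positions: np.ndarray | None = None,
) -> TrackSet:
    """Simulate drift-diffusion trajectories under an optional needle field.

    Each step integrates ``Δr = v(r)·dt + sqrt(2 D dt)·ξ`` (Euler-Maruyama,
    ξ standard bivariate normal), with the drift ``v(r) = F(r)·D/(k_B T)``
    evaluated at the step start. Localization noise ``N(0, σ_loc²)`` per
    axis is added to the reported coordinates afterwards and never feeds
    back into the dynamics. Tracks are truncated where they leave the
    arena; truncated stubs shorter than 2 frames are dropped.

    Parameters
    ----------
    config : SimulationConfig
    needle : NeedleGeometry, optional
        Absent needle means free diffusion.
    phys : PhysicalParams
    start_positions : (n_tracks, 2) array, optional
        Fixed starting points; default uniform in the arena.

    Returns
    -------
    TrackSet with per-track noisy positions; ``metadata['true_positions']``
    maps track_id to the noise-free path for ground-truth comparisons.
    """
    rng = np.random.default_rng(config.seed)
    if start_positions is None:
        xmin, ymin, xmax, ymax = config.arena_um
        starts = rng.uniform([xmin, ymin], [xmax, ymax], size=(config.n_tracks, 2))
    else:
        starts = np.asarray(start_positions, dtype=float)
        if starts.shape != (config.n_tracks, 2):
            raise ValueError("start_positions must be (n_tracks, 2)")

    step_sd = math.sqrt(2.0 * config.D_true * config.dt_s)
    tracks: list[Trajectory] = []
    true_positions: dict[int, np.ndarray] = {}
    for tid in range(config.n_tracks):
        pos = starts[tid].copy()
        path = np.empty((config.n_frames, 2))
        path[0] = pos
        n_kept = config.n_frames
        # draw the full noise block up front so truncation does not shift
        # the random stream of later tracks
        noise = rng.standard_normal((config.n_frames - 1, 2)) * step_sd
        for i in range(1, config.n_frames):
            if needle is not None and needle.F0_fN > 0:
                v = drift_velocity(force_field(needle, pos), config.D_true, phys)
            else:
                v = 0.0
            pos = pos + v * config.dt_s + noise[i - 1]
            if not _inside(config.arena_um, pos):
                n_kept = i
                break
            path[i] = pos
        loc_noise = rng.standard_normal((config.n_frames, 2)) * config.sigma_loc_um
        if n_kept < 2:
            continue
        observed = path[:n_kept] + loc_noise[:n_kept]
        tracks.append(
            Trajectory(
                track_id=tid,
                frames=np.arange(n_kept),
                x_um=observed[:, 0],
                y_um=observed[:, 1],
                dt_s=config.dt_s,
            )
        )
        true_positions[tid] = path[:n_kept].copy()

    metadata = {
        "generator": "simulate_tracks",
        "seed": config.seed,
        "D_true": config.D_true,
        "sigma_loc_um": config.sigma_loc_um,
        "needle": None
        if needle is None
        else {"tip_um": list(needle.tip_um), "F0_fN": needle.F0_fN, "d0_um": needle.d0_um, "p": needle.p},
        "temperature_K": phys.temperature_K,
        "true_positions": true_positions,
    }
    return TrackSet(tracks=tracks, dt_s=config.dt_s, metadata=metadata)


def _integrated_gaussian(shape: tuple[int, int], x_px: float, y_px: float, sigma_px: float) -> np.ndarray:
    """Fraction of a unit-intensity PSF collected by each pixel.

    Integrates the 2D Gaussian over each pixel area using erf differences;
    pixel (row, col) spans [col-0.5, col+0.5] x [row-0.5, row+0.5] because
    pixel centers sit on integer coordinates.
    """
    rows, cols = shape
    s = sigma_px * math.sqrt(2.0)
    cx = np.arange(cols + 1) - 0.5
    cy = np.arange(rows + 1) - 0.5
    fx = 0.5 * (erf((cx[1:] - x_px) / s) - erf((cx[:-1] - x_px) / s))
    fy = 0.5 * (erf((cy[1:] - y_px) / s) - erf((cy[:-1] - y_px) / s))
    return np.outer(fy, fx)


def render_frames(
    ts: TrackSet,
    cam: CameraModel = CameraModel(),
    seed: int = 0,
    noise: bool = True,
) -> FrameStack:
    """Render a TrackSet into a synthetic camera movie.

    Each emitter contributes an integrated 2D Gaussian of width
    ``psf_sigma`` with expected total intensity ``photons_per_spot``, on a
    constant background. With ``noise=True``, Poisson shot noise is applied
    to signal+background and Gaussian read noise added on top (clipped at
    zero). Emitters whose center falls outside the frame are skipped with a
    warning and recorded in ``metadata['clipped']``.
    """
    rng = np.random.default_rng(seed)
    n_frames = max((int(t.frames[-1]) + 1 for t in ts.tracks), default=1)
    rows, cols = cam.frame_shape
    px = cam.pixel_size_um
    frames = np.full((n_frames, rows, cols), float(cam.background))
    ground_truth: list[list[tuple[float, float, float]]] = [[] for _ in range(n_frames)]
    clipped: list[tuple[int, int]] = []

    for t in ts.tracks:
        for f, x, y in zip(t.frames, t.x_um, t.y_um):
            x_px, y_px = x / px, y / px
            if not (-0.5 <= x_px < cols - 0.5 and -0.5 <= y_px < rows - 0.5):
                clipped.append((t.track_id, int(f)))
                continue
            frames[f] += cam.photons_per_spot * _integrated_gaussian(
                (rows, cols), x_px, y_px, cam.psf_sigma_px
            )
            ground_truth[f].append((float(t.track_id), float(x), float(y)))

    if clipped:
        warnings.warn(
            f"{len(clipped)} emitter positions fell outside the frame and were clipped",
            stacklevel=2,
        )
    if noise:
        frames = rng.poisson(frames).astype(float)
        if cam.read_noise > 0:
            frames += rng.normal(0.0, cam.read_noise, size=frames.shape)
        frames = np.clip(frames, 0.0, None)

    gt = [
        np.array(g, dtype=float).reshape(-1, 3) for g in ground_truth
    ]
    return FrameStack(
        frames=frames,
        pixel_size_nm=cam.pixel_size_nm,
        dt_s=ts.dt_s,
        ground_truth=gt,
        metadata={
            "camera": {
                "pixel_size_nm": cam.pixel_size_nm,
                "psf_sigma_nm": cam.psf_sigma_nm,
                "photons_per_spot": cam.photons_per_spot,
                "background": cam.background,
                "read_noise": cam.read_noise,
            },
            "seed": seed,
            "noise": noise,
            "clipped": clipped,
        },
    )


def make_fiducial_pair(
    t: SimilarityTransform,
    n: int,
    noise_sd_um: float = 0.0,
    seed: int = 0,
    box_um: tuple[float, float, float, float] = (0.0, 0.0, 50.0, 50.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Matched fiducial point sets related by a known similarity transform.

    ``src`` is sampled uniformly in ``box_um``; ``dst = t(src)`` plus
    isotropic Gaussian noise of s.d. ``noise_sd_um`` per axis.
    """
    if n < 2:
        raise ValueError("need at least 2 fiducials (transform underdetermined)")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = box_um
    src = rng.uniform([xmin, ymin], [xmax, ymax], size=(n, 2))
    dst = apply_transform(t, src)
    if noise_sd_um > 0:
        dst = dst + rng.normal(0.0, noise_sd_um, size=dst.shape)
    return src, dst
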