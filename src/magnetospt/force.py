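"""Femtonewton force estimation from magnet-pulled trajectories.

A membrane-bound magnetic particle pulled by a needle moves with a drift
velocity v on top of its Brownian motion. In the overdamped regime the
force follows from the Einstein relation,

    F = k_B T * v_x / D,

where v_x is the mean velocity along the pull direction and D the
diffusion coefficient. Decomposing each trajectory window into the
component toward the needle tip (directed) and perpendicular to it
(Brownian) gives both ingredients from the same data: v_x as the OLS slope
of the parallel coordinate against time, and D from the lag-1 fluctuations
of the perpendicular coordinate, D_perp = <Δy⊥²>/(2 dt). Forces are
computed over sliding windows so the force-distance relation can be mapped
along each track, then averaged per track for ensemble statistics.

The window estimator is exposed both as plain functions and through
:class:`ForceModel` / :class:`ForceResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .physics import NeedleGeometry, PhysicalParams, force_from_velocity
from .tracks import Trajectory, TrackSet

__all__ = [
    "ForceEstimate",
    "needle_frame",
    "window_force",
    "track_forces",
    "per_track_force",
    "force_distance_profile",
    "ensemble_force_stats",
    "ForceModel",
    "ForceResults",
]

#: default sliding-window length (frames) and advance step (50% overlap)
DEFAULT_WINDOW = 50
DEFAULT_STEP = 25
#: smallest window the estimator accepts
MIN_WINDOW = 20


@dataclass(frozen=True)
class ForceEstimate:
    """Force estimate for one sliding window of one track.

    Attributes
    ----------
    F_x_fN : float
        Estimated force along the pull direction (positive toward the tip).
    v_x_um_s : float
        Drift velocity toward the tip (OLS slope of x∥ vs time).
    D_perp_um2_s : float
        Diffusion coefficient from perpendicular lag-1 fluctuations.
    d_x_um : float
        Mean Euclidean distance to the tip over the window.
    """

    track_id: int
    window: tuple[int, int]
    F_x_fN: float
    v_x_um_s: float
    D_perp_um2_s: float
    d_x_um: float


def needle_frame(
    xy: np.ndarray, needle: NeedleGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotate coordinates into the needle frame of a trajectory (window).

    The +x∥ axis points from the centroid of the coordinates toward the
    tip; y⊥ is perpendicular to it (right-handed in the image convention).

    Parameters
    ----------
    xy : (N, 2) positions in μm.
    needle : NeedleGeometry

    Returns
    -------
    x_par, y_perp : ndarray
        Coordinates relative to the centroid in the rotated frame.
    dist : ndarray
        Per-frame Euclidean distance to the tip, μm.

    Raises
    ------
    ValueError
        If the tip coincides with the centroid (pull direction undefined).
    """
    xy = np.asarray(xy, dtype=float)
    centroid = xy.mean(axis=0)
    to_tip = needle.tip - centroid
    norm = np.hypot(*to_tip)
    if norm == 0:
        raise ValueError("needle tip coincides with trajectory centroid")
    u = to_tip / norm
    u_perp = np.array([-u[1], u[0]])
    rel = xy - centroid
    x_par = rel @ u
    y_perp = rel @ u_perp
    dist = np.hypot(xy[:, 0] - needle.tip[0], xy[:, 1] - needle.tip[1])
    return x_par, y_perp, dist


def window_force(
    x_par: np.ndarray,
    y_perp: np.ndarray,
    dt_s: float,
    phys: PhysicalParams = PhysicalParams(),
    d_x_um: float = float("nan"),
    track_id: int = -1,
    window: tuple[int, int] = (0, 0),
    sigma_loc_um: float | None = None,
    min_len: int = 3,
) -> ForceEstimate:
    """Apply F = k_B T v_x / D to one rotated window.

    v_x is the OLS slope of x∥ against time; D_perp the mean squared lag-1
    perpendicular step over 2 dt. ``sigma_loc_um``, if given, subtracts the
    localization-noise contribution σ² / dt from D_perp (off by default —
    raw fluctuations are used unless the caller opts in). ``min_len`` is the
    hard floor on points per window; :func:`track_forces` additionally
    enforces ``MIN_WINDOW`` on its sliding windows.

    Raises
    ------
    ValueError
        If the window is shorter than ``min_len`` frames or the
        perpendicular fluctuations vanish (force undefined).
    """
    x_par = np.asarray(x_par, dtype=float)
    y_perp = np.asarray(y_perp, dtype=float)
    n = len(x_par)
    if n < min_len:
        raise ValueError(f"window of {n} frames is below the minimum of {min_len}")
    t = np.arange(n) * dt_s
    v_x = float(np.polyfit(t, x_par, 1)[0])
    dy = np.diff(y_perp)
    D_perp = float(np.mean(dy * dy)) / (2.0 * dt_s)
    if sigma_loc_um is not None:
        D_perp -= sigma_loc_um**2 / dt_s
    if D_perp <= 0:
        raise ValueError("perpendicular fluctuations vanish; force undefined")
    return ForceEstimate(
        track_id=track_id,
        window=window,
        F_x_fN=force_from_velocity(v_x, D_perp, phys),
        v_x_um_s=v_x,
        D_perp_um2_s=D_perp,
        d_x_um=float(d_x_um),
    )


def track_forces(
    traj: Trajectory,
    needle: NeedleGeometry,
    window_len: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    phys: PhysicalParams = PhysicalParams(),
    sigma_loc_um: float | None = None,
) -> list[ForceEstimate]:
    """Sliding-window force estimates along one trajectory.

    Windows of ``window_len`` frames advance by ``step``; each is rotated
    into its own needle frame (pull direction recomputed from the window
    centroid) and passed through :func:`window_force`, carrying the mean
    tip distance of the window as d_x. A track shorter than one window
    yields an empty list.
    """
    if window_len < MIN_WINDOW:
        raise ValueError(f"window_len must be >= {MIN_WINDOW}")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(traj)
    if n < window_len:
        return []
    xy = traj.xy
    estimates = []
    for start in range(0, n - window_len + 1, step):
        stop = start + window_len
        x_par, y_perp, dist = needle_frame(xy[start:stop], needle)
        estimates.append(
            window_force(
                x_par,
                y_perp,
                traj.dt_s,
                phys,
                d_x_um=float(np.mean(dist)),
                track_id=traj.track_id,
                window=(int(traj.frames[start]), int(traj.frames[stop - 1])),
                sigma_loc_um=sigma_loc_um,
            )
        )
    return estimates


def per_track_force(estimates: list[ForceEstimate]) -> float:
    """Unweighted mean of the window forces of one track, fN."""
    if not estimates:
        raise ValueError("no window estimates to average")
    return float(np.mean([e.F_x_fN for e in estimates]))


def force_distance_profile(
    estimates: list[ForceEstimate], bin_edges_um: np.ndarray
) -> pd.DataFrame:
    """Binned mean ± s.d. of window forces against tip distance.

    Returns one row per non-empty bin (columns: d_lo_um, d_hi_um,
    d_center_um, mean_F_fN, sd_F_fN, count); estimates outside the edges
    are counted in the frame attribute ``attrs['n_excluded']``.
    """
    edges = np.asarray(bin_edges_um, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges_um must be 1D and strictly increasing")
    if not estimates:
        raise ValueError("no estimates to bin")
    d = np.array([e.d_x_um for e in estimates])
    F = np.array([e.F_x_fN for e in estimates])
    idx = np.digitize(d, edges) - 1
    in_range = (idx >= 0) & (idx < len(edges) - 1)
    rows = []
    for b in range(len(edges) - 1):
        mask = in_range & (idx == b)
        k = int(mask.sum())
        if k == 0:
            continue
        rows.append(
            {
                "d_lo_um": edges[b],
                "d_hi_um": edges[b + 1],
                "d_center_um": 0.5 * (edges[b] + edges[b + 1]),
                "mean_F_fN": float(F[mask].mean()),
                "sd_F_fN": float(F[mask].std(ddof=1)) if k > 1 else float("nan"),
                "count": k,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = int((~in_range).sum())
    return out


def ensemble_force_stats(per_track_forces: np.ndarray) -> tuple[float, float | None, int]:
    """(mean fN, sample s.d. fN or None if n = 1, n) of per-track forces."""
    F = np.asarray(per_track_forces, dtype=float)
    if F.size == 0:
        raise ValueError("no per-track forces")
    sd = float(np.std(F, ddof=1)) if F.size > 1 else None
    return float(np.mean(F)), sd, int(F.size)


class ForceModel:
    """Sliding-window force calibration of a TrackSet against a needle tip.

    Parameters
    ----------
    trackset : TrackSet
    needle : NeedleGeometry
        Only the tip position is used by the estimator; field parameters
        are irrelevant here.
    phys : PhysicalParams
        Temperature enters through k_B T.
    window_len, step : int
        Sliding-window geometry (defaults 50 frames, 50% overlap).
    sigma_loc_um : float, optional
        Opt-in localization-noise correction for D_perp.
    """

    def __init__(
        self,
        trackset: TrackSet,
        needle: NeedleGeometry,
        phys: PhysicalParams = PhysicalParams(),
        window_len: int = DEFAULT_WINDOW,
        step: int = DEFAULT_STEP,
        sigma_loc_um: float | None = None,
    ):
        self.trackset = trackset
        self.needle = needle
        self.phys = phys
        self.window_len = window_len
        self.step = step
        self.sigma_loc_um = sigma_loc_um

    def fit(self) -> "ForceResults":
        all_windows: list[ForceEstimate] = []
        track_rows = []
        n_too_short = 0
        for t in self.trackset:
            est = track_forces(
                t,
                self.needle,
                self.window_len,
                self.step,
                self.phys,
                self.sigma_loc_um,
            )
            if not est:
                n_too_short += 1
                continue
            all_windows.extend(est)
            track_rows.append(
                {
                    "track_id": t.track_id,
                    "n_windows": len(est),
                    "F_fN": per_track_force(est),
                    "mean_d_um": float(np.mean([e.d_x_um for e in est])),
                }
            )
        windows = pd.DataFrame(
            [
                {
                    "track_id": e.track_id,
                    "start_frame": e.window[0],
                    "end_frame": e.window[1],
                    "F_x_fN": e.F_x_fN,
                    "v_x_um_s": e.v_x_um_s,
                    "D_perp_um2_s": e.D_perp_um2_s,
                    "d_x_um": e.d_x_um,
                }
                for e in all_windows
            ],
            columns=[
                "track_id",
                "start_frame",
                "end_frame",
                "F_x_fN",
                "v_x_um_s",
                "D_perp_um2_s",
                "d_x_um",
            ],
        )
        per_track = pd.DataFrame(
            track_rows, columns=["track_id", "n_windows", "F_fN", "mean_d_um"]
        )
        return ForceResults(self, all_windows, windows, per_track, n_too_short)


class ForceResults:
    """Window- and track-level force estimates with ensemble statistics."""

    def __init__(
        self,
        model: ForceModel,
        estimates: list[ForceEstimate],
        windows: pd.DataFrame,
        per_track: pd.DataFrame,
        n_too_short: int,
    ):
        self.model = model
        self.estimates = estimates
        self.windows = windows
        self.per_track = per_track
        self.n_too_short = n_too_short

    def ensemble(self) -> tuple[float, float | None, int]:
        """(mean, s.d., n) over per-track forces, fN."""
        return ensemble_force_stats(self.per_track["F_fN"].to_numpy())

    def profile(self, bin_edges_um: np.ndarray) -> pd.DataFrame:
        """Force-distance profile over all windows."""
        return force_distance_profile(self.estimates, bin_edges_um)

    def summary(self) -> str:
        mean, sd, n = self.ensemble()
        sd_txt = f"{sd:.3g}" if sd is not None else "n/a"
        lines = [
            "Force calibration (F = k_B T v_x / D_perp)",
            "==========================================",
            f"tracks with windows  : {n}",
            f"tracks too short     : {self.n_too_short}",
            f"windows              : {len(self.windows)}",
            f"mean force F_x       : {mean:.3g} fN",
            f"s.d. of F_x          : {sd_txt} fN",
            f"window / step        : {self.model.window_len} / {self.model.step} frames",
            f"temperature          : {self.model.phys.temperature_K} K",
            f"tip position         : {tuple(self.model.needle.tip_um)} um",
        ]
        return "\n".join(lines)

    def plot_profile(self, bin_edges_um: np.ndarray, ax=None):
        """Errorbar plot of the force-distance profile."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.profile(bin_edges_um)
        ax.errorbar(
            prof["d_center_um"], prof["mean_F_fN"], yerr=prof["sd_F_fN"], fmt="o-"
        )
        ax.set_xlabel("distance to tip ($\\mu$m)")
        ax.set_ylabel("apparent force $F_x$ (fN)")
        return ax

    def plot_force_histogram(self, ax=None, bins=30):
        """Histogram of per-track forces."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.per_track["F_fN"], bins=bins)
        ax.set_xlabel("per-track force $F_x$ (fN)")
        ax.set_ylabel("tracks")
        return ax
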