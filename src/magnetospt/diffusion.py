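"""MSD-based diffusion estimation, track filtering and log(D) statistics.

For 2D Brownian motion the time-averaged mean squared displacement grows
linearly, MSD(τ) = 4Dτ (+ a constant offset absorbing localization noise).
Per-track D is the slope/4 of an ordinary least-squares line through the
first few lags — short-lag fitting limits the bias from correlated MSD
points. Because per-track D values are approximately log-normal across an
ensemble, summary statistics and the before/after comparison are computed
on ln D; the paired comparison is a two-tailed paired Student's t-test on
ln(before) − ln(after).

Filtering follows two named presets used in practice:

* ``spt``: drop immobile particles (D < 0.005 μm²/s) and tracks shorter
  than 50 frames.
* ``force``: for force calibration, additionally demanding D ≥ 0.01 μm²/s,
  ≥ 200 frames and a net displacement ≥ 10 μm (magnet-pulled tracks are
  nearly straight, so net start-to-end distance is used).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import Trajectory, TrackSet

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "FilterSpec",
    "TTestResult",
    "compute_msd",
    "fit_diffusion",
    "apply_filters",
    "summarize_D",
    "paired_logD_test",
    "students_t_pvalue",
    "DiffusionModel",
    "DiffusionResults",
]


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD of one trajectory.

    ``values[k]`` is the mean of |r(i+lag_k) − r(i)|² over all start points
    i; ``counts[k]`` the number of displacement pairs entering that mean.
    """

    lags_s: np.ndarray
    values_um2: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.lags_s) <= 0) or np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be positive and increasing")
        if np.any(np.asarray(self.counts) < 1):
            raise ValueError("each lag needs at least one displacement pair")


@dataclass(frozen=True)
class DiffusionEstimate:
    """Fitted diffusion coefficient of one track.

    ``D_um2_s`` may be non-positive for noisy short tracks; ``valid`` flags
    a positive estimate usable in log statistics.
    """

    D_um2_s: float
    intercept_um2: float
    n_fit_lags: int
    track_id: int | None = None

    @property
    def valid(self) -> bool:
        return self.D_um2_s > 0


@dataclass(frozen=True)
class FilterSpec:
    """Track selection rule: minimum length, minimum D, optional minimum net displacement."""

    min_length_frames: int = 50
    D_min_um2_s: float = 0.005
    min_displacement_um: float | None = None

    def __post_init__(self) -> None:
        if self.min_length_frames < 2:
            raise ValueError("min_length_frames must be >= 2")
        if self.D_min_um2_s < 0:
            raise ValueError("D_min_um2_s must be >= 0")

    @classmethod
    def spt(cls) -> "FilterSpec":
        """Standard SPT cleanup: >= 50 frames, D >= 0.005 μm²/s."""
        return cls(min_length_frames=50, D_min_um2_s=0.005, min_displacement_um=None)

    @classmethod
    def force_calibration(cls) -> "FilterSpec":
        """Force-calibration cleanup: >= 200 frames, D >= 0.01 μm²/s, net displacement >= 10 μm."""
        return cls(min_length_frames=200, D_min_um2_s=0.01, min_displacement_um=10.0)


PRESETS: dict[str, FilterSpec] = {
    "spt": FilterSpec.spt(),
    "force": FilterSpec.force_calibration(),
}


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def compute_msd(traj: Trajectory, max_lag: int) -> MSDCurve:
    """Time-averaged MSD over all start points, for lags 1..max_lag frames."""
    n = len(traj)
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be < track length {n}")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    xy = traj.xy
    values = np.empty(max_lag)
    counts = np.empty(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        d = xy[k:] - xy[:-k]
        values[k - 1] = np.mean(np.sum(d * d, axis=1))
        counts[k - 1] = n - k
    lags = np.arange(1, max_lag + 1) * traj.dt_s
    return MSDCurve(lags_s=lags, values_um2=values, counts=counts)


def fit_diffusion(msd: MSDCurve, n_fit_lags: int = 4, track_id: int | None = None) -> DiffusionEstimate:
    """OLS line through the first ``n_fit_lags`` MSD points; D = slope / 4.

    The intercept is retained (it absorbs the 4σ_loc² offset from
    localization noise) rather than forced through the origin. A negative
    slope is reported as fitted — the ``valid`` flag marks it unusable for
    log statistics.
    """
    if n_fit_lags < 2:
        raise ValueError("n_fit_lags must be >= 2")
    if n_fit_lags > len(msd.lags_s):
        raise ValueError(
            f"n_fit_lags {n_fit_lags} exceeds available lags {len(msd.lags_s)}"
        )
    lags = np.asarray(msd.lags_s[:n_fit_lags])
    vals = np.asarray(msd.values_um2[:n_fit_lags])
    slope, intercept = np.polyfit(lags, vals, 1)
    return DiffusionEstimate(
        D_um2_s=float(slope) / 4.0,
        intercept_um2=float(intercept),
        n_fit_lags=n_fit_lags,
        track_id=track_id,
    )


def apply_filters(
    ts: TrackSet, spec: FilterSpec, D_by_track: Mapping[int, float]
) -> TrackSet:
    """Keep tracks meeting length, D and (optional) net-displacement thresholds.

    Order is preserved; applying the same spec twice is a no-op. Every track
    must have an entry in ``D_by_track``.
    """
    kept = []
    for t in ts.tracks:
        if t.track_id not in D_by_track:
            raise KeyError(f"no diffusion estimate for track {t.track_id}")
        if len(t) < spec.min_length_frames:
            continue
        if D_by_track[t.track_id] < spec.D_min_um2_s:
            continue
        if (
            spec.min_displacement_um is not None
            and t.net_displacement_um < spec.min_displacement_um
        ):
            continue
        kept.append(t)
    return TrackSet(
        tracks=kept,
        dt_s=ts.dt_s,
        pixel_size_nm=ts.pixel_size_nm,
        metadata={**ts.metadata, "filter": spec},
    )


def summarize_D(Ds: Sequence[float]) -> dict:
    """Ensemble summary of diffusion coefficients.

    Returns arithmetic mean/median/n of D plus mean and s.d. of ln D over
    the positive values; non-positive values are excluded from the log
    moments and counted in ``n_excluded_nonpositive``.
    """
    D = np.asarray(list(Ds), dtype=float)
    if D.size == 0:
        raise ValueError("empty diffusion-coefficient list")
    pos = D[D > 0]
    logs = np.log(pos) if pos.size else np.array([])
    return {
        "mean": float(np.mean(D)),
        "median": float(np.median(D)),
        "n": int(D.size),
        "mean_logD": float(np.mean(logs)) if logs.size else float("nan"),
        "sd_logD": float(np.std(logs, ddof=1)) if logs.size > 1 else 0.0,
        "n_excluded_nonpositive": int(D.size - pos.size),
    }


def paired_logD_test(before: Sequence[float], after: Sequence[float]) -> TTestResult:
    """Two-tailed paired Student's t-test on ln(before) − ln(after).

    D values across particles are close to log-normal, so the paired
    differences of logs are the natural test variable; the t statistic is
    invariant to rescaling all D by a common positive factor.
    """
    b = np.asarray(list(before), dtype=float)
    a = np.asarray(list(after), dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("before and after must be equal-length 1D sequences")
    if b.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(b <= 0) or np.any(a <= 0):
        raise ValueError("log statistics require positive diffusion coefficients")
    res = stats.ttest_rel(np.log(b), np.log(a))
    d = np.log(b) - np.log(a)
    t = float(res.statistic) if np.std(d, ddof=1) > 0 else 0.0
    p = float(res.pvalue) if np.std(d, ddof=1) > 0 else 1.0
    return TTestResult(t=t, df=b.size - 1, p=p)


def students_t_pvalue(t: float, df: int) -> float:
    """Two-sided tail probability of Student's t distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * stats.t.sf(abs(t), df))


class DiffusionModel:
    """Per-track MSD/diffusion analysis of a TrackSet.

    Parameters
    ----------
    trackset : TrackSet
    n_fit_lags : int
        MSD lags entering the OLS line (default 4; short-lag fitting limits
        correlated-lag bias).
    max_lag : int, optional
        Lags to tabulate per MSD curve; default ``4 * n_fit_lags`` capped at
        track length − 1.

    Examples
    --------
    >>> model = DiffusionModel(ts)
    >>> res = model.fit()
    >>> res.summary()            # doctest: +SKIP
    """

    def __init__(self, trackset: TrackSet, n_fit_lags: int = 4, max_lag: int | None = None):
        self.trackset = trackset
        self.n_fit_lags = n_fit_lags
        self.max_lag = max_lag

    def fit(self) -> "DiffusionResults":
        rows = []
        msds: dict[int, MSDCurve] = {}
        for t in self.trackset:
            max_lag = self.max_lag or min(4 * self.n_fit_lags, len(t) - 1)
            max_lag = min(max_lag, len(t) - 1)
            if max_lag < self.n_fit_lags:
                continue
            msd = compute_msd(t, max_lag)
            est = fit_diffusion(msd, self.n_fit_lags, track_id=t.track_id)
            msds[t.track_id] = msd
            rows.append(
                {
                    "track_id": t.track_id,
                    "n_frames": len(t),
                    "D_um2_s": est.D_um2_s,
                    "intercept_um2": est.intercept_um2,
                    "net_displacement_um": t.net_displacement_um,
                    "valid": est.valid,
                }
            )
        table = pd.DataFrame(
            rows,
            columns=[
                "track_id",
                "n_frames",
                "D_um2_s",
                "intercept_um2",
                "net_displacement_um",
                "valid",
            ],
        )
        return DiffusionResults(self, table, msds)


class DiffusionResults:
    """Fitted per-track diffusion coefficients and ensemble statistics."""

    def __init__(self, model: DiffusionModel, per_track: pd.DataFrame, msds: dict[int, MSDCurve]):
        self.model = model
        self.per_track = per_track
        self.msds = msds

    @property
    def D_by_track(self) -> dict[int, float]:
        return dict(zip(self.per_track["track_id"], self.per_track["D_um2_s"]))

    def ensemble(self) -> dict:
        """Mean/median D and ln D moments over all fitted tracks."""
        return summarize_D(self.per_track["D_um2_s"].to_numpy())

    def filter(self, spec: FilterSpec) -> TrackSet:
        """Apply a FilterSpec to the model's TrackSet using these estimates."""
        return apply_filters(self.model.trackset, spec, self.D_by_track)

    def pooled_D(self, n_fit_lags: int | None = None) -> DiffusionEstimate:
        """D fitted to the count-weighted pooled MSD of all tracks."""
        if not self.msds:
            raise ValueError("no fitted tracks to pool")
        n_fit = n_fit_lags or self.model.n_fit_lags
        n_lags = min(len(m.lags_s) for m in self.msds.values())
        vals = np.zeros(n_lags)
        counts = np.zeros(n_lags)
        lags = next(iter(self.msds.values())).lags_s[:n_lags]
        for m in self.msds.values():
            vals += m.values_um2[:n_lags] * m.counts[:n_lags]
            counts += m.counts[:n_lags]
        pooled = MSDCurve(lags_s=lags, values_um2=vals / counts, counts=counts.astype(int))
        return fit_diffusion(pooled, n_fit)

    def summary(self) -> str:
        s = self.ensemble()
        lines = [
            "Diffusion analysis",
            "==================",
            f"tracks fitted        : {s['n']}",
            f"mean D               : {s['mean']:.4g} um^2/s",
            f"median D             : {s['median']:.4g} um^2/s",
            f"mean ln D            : {s['mean_logD']:.4g}",
            f"s.d. ln D            : {s['sd_logD']:.4g}",
            f"non-positive D       : {s['n_excluded_nonpositive']}",
            f"MSD lags in fit      : {self.model.n_fit_lags}",
        ]
        return "\n".join(lines)

    def plot_msd(self, ax=None, max_tracks: int = 50):
        """Plot per-track MSD curves and the pooled fit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for tid, m in list(self.msds.items())[:max_tracks]:
            ax.plot(m.lags_s, m.values_um2, color="0.7", lw=0.5)
        est = self.pooled_D()
        lags = next(iter(self.msds.values())).lags_s
        ax.plot(lags, 4 * est.D_um2_s * lags + est.intercept_um2, "r-",
                label=f"pooled D = {est.D_um2_s:.3g} $\\mu$m$^2$/s")
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("MSD ($\\mu$m$^2$)")
        ax.legend()
        return ax
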