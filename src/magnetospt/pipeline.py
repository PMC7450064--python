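"""Configurable pipeline tying simulate → track → diffuse → force → register.

A pipeline run is described by a plain dict (typically loaded from YAML):

.. code-block:: yaml

    seed: 1
    temperature_K: 298
    stages: [simulate, diffuse, force]
    simulate:
      D_true: 0.13
      dt_s: 0.1
      n_frames: 500
      n_tracks: 100
      needle: {tip_um: [1000.0, 100.0], F0_fN: 13.4, d0_um: 50.0, p: 0.0}
    diffuse:
      preset: spt
    force:
      window_len: 50
      step: 25

Each stage records its parameters and in/out counts in the JSON-able report
returned by :func:`run_pipeline`; every number in the report is reproducible
from the seed and config alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .diffusion import PRESETS, DiffusionModel, FilterSpec, summarize_D
from .force import ForceModel
from .io import read_tracks, write_tracks
from .localize import link_localizations, localize_stack
from .physics import NeedleGeometry, PhysicalParams
from .register import fit_similarity, registration_residual
from .simulate import CameraModel, SimulationConfig, render_frames, simulate_tracks

__all__ = ["run_pipeline", "validate_config"]

_KNOWN_STAGES = ("simulate", "render", "track", "diffuse", "force", "register")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _needle_from_cfg(cfg: dict | None) -> NeedleGeometry | None:
    if cfg is None:
        return None
    return NeedleGeometry(
        tip_um=tuple(cfg.get("tip_um", (0.0, 0.0))),
        F0_fN=cfg.get("F0_fN", 13.4),
        d0_um=cfg.get("d0_um", 50.0),
        p=cfg.get("p", 1.0),
    )


def validate_config(config: dict) -> None:
    """Fail fast on unknown stages or presets, before any stage runs."""
    for stage in config.get("stages", []):
        if stage not in _KNOWN_STAGES:
            raise PipelineError(f"unknown stage '{stage}' (known: {_KNOWN_STAGES})")
    for key in ("diffuse", "force"):
        preset = config.get(key, {}).get("preset")
        if preset is not None and preset not in PRESETS:
            raise PipelineError(
                f"unknown filter preset '{preset}' (known: {sorted(PRESETS)})"
            )


def run_pipeline(config: dict, workdir: str | Path | None = None) -> dict:
    """Execute the configured stages in order and return a JSON-able report.

    Stage outputs flow in memory from one stage to the next; if ``workdir``
    is given, track CSVs are also written there. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    validate_config(config)
    seed = int(config.get("seed", 0))
    phys = PhysicalParams(temperature_K=float(config.get("temperature_K", 298.0)))
    workdir = Path(workdir) if workdir is not None else None
    if workdir is not None:
        workdir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "temperature_K": phys.temperature_K,
        "stages": {},
    }
    ts = None
    stack = None
    diffusion_results = None

    for stage in config.get("stages", []):
        params = dict(config.get(stage, {}))
        try:
            if stage == "simulate":
                needle = _needle_from_cfg(params.pop("needle", None))
                sim_cfg = SimulationConfig(seed=seed, **params)
                ts = simulate_tracks(sim_cfg, needle, phys)
                report["stages"]["simulate"] = {
                    "params": {**params, "seed": seed, "needle": config.get(stage, {}).get("needle")},
                    "n_tracks": len(ts),
                }
                if workdir is not None:
                    write_tracks(ts, workdir / "simulated_tracks.csv")

            elif stage == "render":
                if ts is None:
                    raise PipelineError("render requires tracks from a prior stage")
                cam = CameraModel(**params.get("camera", {}))
                stack = render_frames(ts, cam, seed=seed)
                report["stages"]["render"] = {
                    "params": params,
                    "n_frames": len(stack),
                }

            elif stage == "track":
                if stack is None:
                    raise PipelineError("track requires rendered or loaded frames")
                cam = CameraModel(
                    pixel_size_nm=stack.pixel_size_nm, **params.get("camera", {})
                )
                per_frame = localize_stack(
                    stack, cam, params.get("detect_threshold", 5.0)
                )
                ts = link_localizations(
                    per_frame, params.get("max_disp_um", 1.0), stack.dt_s
                )
                report["stages"]["track"] = {
                    "params": params,
                    "n_localizations": int(sum(len(p) for p in per_frame)),
                    "n_tracks": len(ts),
                }
                if workdir is not None:
                    write_tracks(ts, workdir / "linked_tracks.csv")

            elif stage == "diffuse":
                if ts is None and "input" in params:
                    ts = read_tracks(params["input"])
                if ts is None:
                    raise PipelineError("diffuse requires tracks")
                model = DiffusionModel(ts, n_fit_lags=params.get("n_fit_lags", 4))
                diffusion_results = model.fit()
                n_in = len(ts)
                entry: dict[str, Any] = {
                    "params": params,
                    "n_tracks_in": n_in,
                    "summary": diffusion_results.ensemble(),
                }
                preset = params.get("preset")
                if preset is not None:
                    filtered = diffusion_results.filter(PRESETS[preset])
                    entry["n_tracks_out"] = len(filtered)
                    kept = {t.track_id for t in filtered}
                    entry["summary_filtered"] = summarize_D(
                        [d for tid, d in diffusion_results.D_by_track.items() if tid in kept]
                    ) if kept else None
                    ts = filtered
                report["stages"]["diffuse"] = entry

            elif stage == "force":
                if ts is None:
                    raise PipelineError("force requires tracks")
                preset = params.get("preset")
                if preset is not None:
                    if diffusion_results is None:
                        diffusion_results = DiffusionModel(ts).fit()
                    ts = diffusion_results.filter(PRESETS[preset])
                needle = _needle_from_cfg(params.get("needle")) or NeedleGeometry(
                    tip_um=tuple(params.get("tip_um", (0.0, 0.0)))
                )
                model = ForceModel(
                    ts,
                    needle,
                    phys,
                    window_len=params.get("window_len", 50),
                    step=params.get("step", 25),
                )
                res = model.fit()
                mean, sd, n = res.ensemble()
                report["stages"]["force"] = {
                    "params": {
                        "window_len": model.window_len,
                        "step": model.step,
                        "tip_um": list(needle.tip_um),
                        "temperature_K": phys.temperature_K,
                        "preset": preset,
                    },
                    "n_tracks": n,
                    "n_windows": int(len(res.windows)),
                    "mean_F_fN": mean,
                    "sd_F_fN": sd,
                }

            elif stage == "register":
                src = np.asarray(params["src"], dtype=float)
                dst = np.asarray(params["dst"], dtype=float)
                t = fit_similarity(src, dst)
                report["stages"]["register"] = {
                    "scale": t.scale,
                    "rotation_rad": t.rotation,
                    "translation_um": list(t.translation),
                    "rms_residual_um": registration_residual(t, src, dst),
                }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    if workdir is not None:
        (workdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
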