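# magnetospt

Analysis toolkit for single-particle tracking (SPT) of membrane-bound
magnetic nanoparticles pulled by a magnetized needle: femtonewton force
calibration from trajectories, MSD-based diffusion analysis with the
standard filtering and log-normal statistics, sub-pixel spot localization
and linking, fiducial-based image registration — and a drift–diffusion
simulator that provides ground truth for validating every stage without
experimental data.

## Who this is for

Membrane biophysicists and microscopists who track fluorescent magnetic
nanoparticles (or any SPT probe under a weak directed pull) and want to
quantify the applied force, characterize diffusion before/during/after
manipulation, and overlay trajectories onto a second imaging modality.

## The model

A particle bound to a membrane lipid or protein and pulled by a needle tip
moves with a drift velocity v on top of Brownian motion. In the overdamped
regime the Einstein relation converts the drift-to-diffusion ratio into a
force:

    F = k_B T · v_x / D

Decomposing each trajectory window into the component toward the tip
(directed) and perpendicular to it (Brownian) yields both ingredients from
the same data:

* **v_x** — ordinary least-squares slope of the parallel coordinate
  against time ("linear movement toward the tip"),
* **D** — from the perpendicular fluctuations, D⊥ = ⟨Δy⊥²⟩ / 2Δt, which
  are untouched by the pull.

Forces are estimated over sliding windows (default 50 frames, 50 %
overlap), averaged per track, and mapped against the window's mean
distance to the tip to give a force–distance profile. At k_BT ≈ 4.11 zJ
(298 K), a particle with D = 0.13 μm²/s drifting at 0.42 μm/s experiences
13.4 fN — forces small enough to leave molecular interactions intact,
which is the point of the technique.

The companion pieces are standard SPT machinery: time-averaged MSD with
slope 4D (2D), per-track D from a 4-lag OLS fit with free intercept,
immobile/short-track filtering, log(D) statistics with a paired t-test for
before/after comparisons, Gaussian PSF fitting for ~10 nm localization
precision, mutual-nearest-neighbor linking, and a closed-form
nonreflective similarity (scale–rotation–translation) fit to fiducial
pairs.

## Worked example

Simulate 100 tracks pulled by a constant 13.4 fN force (500 frames at
10 Hz, D = 0.13 μm²/s, 10 nm localization noise) and calibrate the force
back out:

```python
import numpy as np
import magnetospt as m

cfg = m.SimulationConfig(D_true=0.13, dt_s=0.1, n_frames=500, n_tracks=100,
                         sigma_loc_um=0.01, arena_um=(-1e7, -1e7, 1e7, 1e7),
                         seed=0)
needle = m.NeedleGeometry(tip_um=(1e5, 0.0), F0_fN=13.4, d0_um=50.0, p=0.0)
starts = np.zeros((100, 2)); starts[:, 1] = np.arange(100) * 10.0
ts = m.simulate_tracks(cfg, needle, start_positions=starts)

res = m.ForceModel(ts, needle).fit()
print(res.summary())
```

```
Force calibration (F = k_B T v_x / D_perp)
==========================================
tracks with windows  : 100
tracks too short     : 0
windows              : 1900
mean force F_x       : 13.7 fN
s.d. of F_x          : 2.44 fN
window / step        : 50 / 25 frames
temperature          : 298.0 K
tip position         : (100000.0, 0.0) um
```

The ensemble mean (13.7 fN) recovers the injected 13.4 fN to ~2 %; the
small upward shift is the expected finite-window bias of dividing by an
estimated D⊥ (see `docs/methods.md`). Running `m.DiffusionModel(ts).fit()`
on the same pulled tracks reports a mean D of 0.153 μm²/s — inflated above
the true 0.13 because the directed motion contributes a quadratic term to
the MSD. That inflation is exactly why the force estimator takes D from
the perpendicular component only.

The same stages are available from a shell:

```sh
magnetospt simulate --seed 0 --tip 100000,0 --decay 0 --dt 0.1 \
    --n-frames 500 -o tracks.csv
magnetospt force tracks.csv --tip 100000,0 --no-filter -o force
magnetospt diffuse tracks.csv -o D.csv --summary D.json
```

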