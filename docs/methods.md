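# Methods

## Force estimation from drift–diffusion trajectories

The estimator assumes overdamped motion of a membrane-bound particle in a
slowly varying force field. With drift velocity v and diffusion
coefficient D, the Einstein relation gives F = k_B T v / D. Each
trajectory is cut into sliding windows (default 50 frames advanced by 25;
both configurable and recorded in output metadata). For every window:

1. the pull axis is taken as the unit vector from the window centroid to
   the needle tip — recomputed per window, so a long track curving toward
   the tip keeps a locally correct decomposition;
2. v_x is the OLS slope of the parallel coordinate against time;
3. D⊥ is the mean squared lag-1 perpendicular displacement over 2Δt,
   with no localization-noise correction by default (an opt-in correction
   subtracting σ_loc²/Δt exists, `sigma_loc_um` on the model), because the
   perpendicular fluctuations are taken at face value in routine practice
   and the correction is below 1 % at the calibration frame rates;
4. F_x = k_B T v_x / D⊥, reported in fN, positive toward the tip, with
   the window's mean Euclidean distance to the tip recorded as d_x.

Per-track forces are unweighted means of window forces; ensemble
statistics are mean ± sample s.d. over tracks. The force–distance profile
bins window estimates by d_x.

**Known bias.** Dividing by an estimated D⊥ incurs a Jensen-type upward
bias of roughly k/(k−2) with k = window_len − 1 independent perpendicular
steps (~4 % at the default 50-frame window). This is visible as the ~0.3 fN
upward shift in the worked example and stays well inside the 10 % recovery
tolerance the tests enforce. It shrinks with window length; no correction
is applied because the window length also controls how locally the
force–distance relation is sampled.

**Choice of D.** Whether the denominator D should be per-window, per-track
or a global average is genuinely open; per-window D⊥ is the default here
because it keeps each window self-contained and robust against slow
heterogeneity of the membrane. d_x is the full Euclidean distance to the
tip (not its projection on the pull axis); for the nearly straight pulled
tracks the two coincide to first order.

## Diffusion analysis

Time-averaged MSD over all start points; per-track D = slope/4 of an OLS
line through the first 4 lags with a free intercept. Four lags keeps the
variance low and limits the bias from correlations between overlapping
displacements; the free intercept absorbs the static localization-noise
offset 4σ_loc². Negative fitted D is possible for short noisy tracks and
is reported as fitted, flagged invalid, and excluded (with a count) from
log statistics rather than silently dropped.

Two named filter presets reflect common practice: `spt` discards immobile
particles (D < 0.005 μm²/s) and tracks shorter than 50 frames; `force`
(applied before force calibration) additionally requires D ≥ 0.01 μm²/s,
≥ 200 frames and a net start-to-end displacement ≥ 10 μm. "Displacement"
is interpreted as net Euclidean distance, not path length — magnet-pulled
tracks are nearly straight, so the two nearly coincide, and net
displacement is the conventional reading.

Because per-track D is approximately log-normal across an ensemble,
summaries report moments of ln D alongside the arithmetic mean/median, and
the before/after comparison is a two-tailed paired Student's t-test on
ln(before) − ln(after) (natural log; the statistic is base-invariant).

## Simulator

Euler–Maruyama with the frame interval as the step: Δr = v(r)Δt +
√(2DΔt)·ξ, drift evaluated at the step start — adequate because the
needle field varies over tens of μm while a step moves the particle tens
of nm. The needle field is F(d) = F0·(d0/d)^p pointing at the tip, a
deliberately simple monotone decay (p = 0 gives the constant-force mode
used for calibration studies); it is a stand-in, not a claim about real
needle magnetostatics. Localization noise is added to reported positions
only and never feeds back into the dynamics, matching how a camera
observes a physical path. Tracks leaving the arena are truncated, not
reflected — truncation mimics particles leaving the field of view.
Coordinates are continuous μm, x rightward, y downward (image
convention), pixel (0,0) centered at the origin.

Default conditions mirror membrane SPT: D = 0.13 μm²/s (supported-bilayer
lipid scale; live-cell probes run 0.03–0.05), σ_loc = 10 nm, frame
intervals 20 ms (tracking) to 100 ms–1 s (force calibration), camera
pixels 99 or 217 nm. At 13.4 fN and D = 0.13 μm²/s the drift per second
(0.42 μm) is comparable to the r.m.s. Brownian step (0.72 μm) — the
regime where directed and random motion are both visible in a trajectory.

The renderer integrates a Gaussian PSF over pixel areas (erf differences),
applies Poisson shot noise to signal + background and additive Gaussian
read noise. It does **not** model blinking, photobleaching, 3D defocus,
or membrane barriers, so passing tests demonstrate estimator correctness
under ideal point-emitter imaging, not robustness to those effects.

## Localization and linking

Detection: difference-of-Gaussians band-pass at 1× and 2× the PSF width,
local maxima above a robust threshold (median + k·1.4826·MAD, default
k = 5). Refinement: least-squares 2D Gaussian in a window of ~3 PSF
widths; the width is free by default since ~100 nm particles slightly
broaden the PSF (a fixed-width option exists). Fits that diverge or run to
the window edge are flagged and excluded downstream. Linking is
mutual-nearest-neighbor between consecutive frames with a hard
displacement gate, duplicate candidates resolved by smaller distance, no
gap closing — intentionally minimal, adequate at SPT densities, and exact
on well-separated emitters. Localization precision is the sample standard
deviation (n−1) of repeated fixes of an immobile particle; immobility is
caller-asserted, mirroring the deliberate use of stuck particles.

## Registration

Nonreflective similarity (uniform scale, rotation, translation) fitted in
closed form: with centered point sets, the linear part a + ib solves a
complex least-squares regression, which excludes reflections by
construction and is exact for two points. Fiducial correspondence is given
by input order; no automatic matching. The expected r.m.s. residual after
fitting 4 parameters to n noisy pairs is σ√2·√(1 − 2/n), which the tests
verify.

## Problem sizes and numerical choices

Validation ensembles are 100 tracks × 500 frames (forces, diffusion), 178
tracks for the null calibration, 3000 localizations for precision, 1000
random point sets for the reflection-exclusion property — sizes at which
Monte-Carlo error is a few percent and a full run takes seconds.
Statistical checks use 2–3 standard-error bands; exact identities
(ballistic MSD, noise-free registration) are asserted to machine
tolerance. Degenerate inputs fail loudly: zero distance to the tip,
vanishing perpendicular fluctuations, coincident fiducials, non-uniform
frame intervals in CSV input.

## Limitations

* The force estimator assumes a locally constant pull over a window;
  strong field curvature within a window biases v_x.
* D⊥ uses lag-1 displacements only; correlated noise (e.g., motion blur)
  would bias it and is not modeled.
* The needle field's power law is a modeling convenience; only its
  monotone decay is used by any test.
* No 3D localization, drift correction, gap closing, anomalous-diffusion
  exponents or confinement analysis.
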