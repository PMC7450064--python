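import numpy as np
import pytest

import magnetospt as m
from magnetospt.force import window_force


def _drift_track(track_id=0, n=200, v=0.2, dt=0.1, perp_amp=0.1, seed=0):
    """Constant drift along +x with synthetic perpendicular noise."""
    rng = np.random.default_rng(seed)
    frames = np.arange(n)
    x = v * frames * dt
    y = rng.normal(0, perp_amp, n)
    return m.Trajectory(track_id, frames, x, y, dt)


class TestNeedleFrame:
    def test_tip_due_east_keeps_axes(self):
        xy = np.column_stack([np.linspace(0, 1, 30), np.zeros(30)])
        needle = m.NeedleGeometry(tip_um=(100.0, 0.5 * 0))
        x_par, y_perp, _ = m.needle_frame(xy, needle)
        assert np.all(np.diff(x_par) > 0)
        np.testing.assert_allclose(y_perp, 0.0, atol=1e-12)

    def test_tip_due_north_rotates_by_quarter_turn(self):
        # y is downward in the image convention; a tip at smaller y is "north"
        xy = np.column_stack([np.linspace(0, 1, 30), np.zeros(30)])
        needle = m.NeedleGeometry(tip_um=(0.5, -100.0))
        x_par, y_perp, _ = m.needle_frame(xy, needle)
        # prior x motion now lives in the perpendicular coordinate
        assert np.ptp(y_perp) == pytest.approx(1.0, rel=1e-6)
        assert np.ptp(x_par) == pytest.approx(0.0, abs=1e-4)

    def test_three_four_five_distance(self):
        xy = np.array([[0.0, 0.0], [0.0, 0.0]])
        needle = m.NeedleGeometry(tip_um=(30.0, 40.0))
        _, _, dist = m.needle_frame(xy, needle)
        np.testing.assert_allclose(dist, 50.0)

    def test_tip_on_centroid_rejected(self):
        xy = np.array([[0.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            m.needle_frame(xy, m.NeedleGeometry(tip_um=(1.0, 0.0)))


class TestWindowForce:
    def test_hand_computed_example(self, phys):
        # 11 points, v_x = 0.2 um/s, alternating y gives D_perp ~ 0.1 um^2/s
        x = 0.02 * np.arange(11)
        y = np.array([0.0, 0.1414] * 6)[:11]
        est = window_force(x, y, dt_s=0.1, phys=phys)
        assert est.v_x_um_s == pytest.approx(0.2)
        assert est.D_perp_um2_s == pytest.approx(0.1, rel=1e-3)
        assert est.F_x_fN == pytest.approx(8.23, rel=1e-2)

    def test_zero_velocity_gives_zero_force(self, phys):
        x = np.zeros(30)
        y = np.array([0.0, 0.1] * 15)
        assert window_force(x, y, 0.1, phys).F_x_fN == pytest.approx(0.0, abs=1e-12)

    def test_thermal_energy_scale(self, phys):
        # v = 0.1 um/s over D = 0.1 um^2/s is k_B T per um ~ 4.11 fN
        n = 30
        x = 0.01 * np.arange(n)
        y = np.array([0.0, np.sqrt(0.02)] * (n // 2))
        est = window_force(x, y, 0.1, phys)
        assert est.F_x_fN == pytest.approx(4.11, rel=1e-2)

    def test_flat_perpendicular_is_an_error(self, phys):
        with pytest.raises(ValueError, match="undefined"):
            window_force(np.arange(30.0), np.zeros(30), 0.1, phys)


class TestTrackForces:
    def test_window_count_with_overlap(self):
        traj = _drift_track(n=200)
        needle = m.NeedleGeometry(tip_um=(1e4, 0.0))
        est = m.track_forces(traj, needle, window_len=50, step=25)
        assert len(est) == 7  # floor((200-50)/25)+1

    def test_window_count_without_overlap(self):
        traj = _drift_track(n=200)
        needle = m.NeedleGeometry(tip_um=(1e4, 0.0))
        est = m.track_forces(traj, needle, window_len=50, step=50)
        assert len(est) == 4

    def test_short_track_yields_empty(self):
        traj = _drift_track(n=30)
        assert m.track_forces(traj, m.NeedleGeometry(tip_um=(1e4, 0.0))) == []

    def test_constant_drift_gives_consistent_windows(self, phys):
        traj = _drift_track(n=400, v=0.2, perp_amp=0.1, seed=5)
        needle = m.NeedleGeometry(tip_um=(1e6, 0.0))
        est = m.track_forces(traj, needle, window_len=100, step=100, phys=phys)
        forces = [e.F_x_fN for e in est]
        assert np.std(forces) / np.mean(forces) < 0.5
        assert np.mean(forces) > 0

    def test_estimates_carry_mean_tip_distance(self):
        traj = _drift_track(n=100, v=0.0, perp_amp=0.05, seed=1)
        needle = m.NeedleGeometry(tip_um=(50.0, 0.0))
        est = m.track_forces(traj, needle, window_len=50, step=50)
        for e in est:
            assert 45.0 < e.d_x_um < 55.0


class TestAggregation:
    def test_per_track_force_is_plain_mean(self):
        ests = [m.ForceEstimate(0, (0, 1), F, 0.0, 0.1, 10.0) for F in (10.0, 12.0, 14.0)]
        assert m.per_track_force(ests) == pytest.approx(12.0)
        assert m.per_track_force(ests[:1]) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            m.per_track_force([])

    def test_ensemble_stats(self):
        mean, sd, n = m.ensemble_force_stats(np.array([1.0, 2.0, 3.0]))
        assert (mean, sd, n) == (pytest.approx(2.0), pytest.approx(1.0), 3)
        mean1, sd1, n1 = m.ensemble_force_stats(np.array([5.0]))
        assert sd1 is None and n1 == 1
        with pytest.raises(ValueError):
            m.ensemble_force_stats(np.array([]))

    def test_profile_single_bin_equals_global_mean(self):
        ests = [m.ForceEstimate(0, (0, 1), F, 0.0, 0.1, d)
                for F, d in [(10.0, 5.0), (20.0, 7.0), (30.0, 9.0)]]
        prof = m.force_distance_profile(ests, np.array([0.0, 10.0]))
        assert len(prof) == 1
        assert prof["mean_F_fN"].iloc[0] == pytest.approx(20.0)

    def test_profile_excludes_out_of_range(self):
        ests = [m.ForceEstimate(0, (0, 1), 10.0, 0.0, 0.1, d) for d in (5.0, 15.0, 120.0)]
        prof = m.force_distance_profile(ests, np.array([0.0, 10.0, 20.0]))
        assert prof["count"].sum() == 2
        assert prof.attrs["n_excluded"] == 1

    def test_profile_requires_sorted_edges(self):
        ests = [m.ForceEstimate(0, (0, 1), 10.0, 0.0, 0.1, 5.0)]
        with pytest.raises(ValueError):
            m.force_distance_profile(ests, np.array([10.0, 0.0]))

    def test_profile_recovers_injected_decay(self, phys):
        # inverse-distance field: binned mean force decreases with distance
        from scipy.stats import spearmanr

        cfg = m.SimulationConfig(D_true=0.13, dt_s=0.1, n_frames=300, n_tracks=40,
                                 sigma_loc_um=0.0, arena_um=(-1e5, -1e5, 1e5, 1e5),
                                 seed=23)
        needle = m.NeedleGeometry(tip_um=(0.0, 0.0), F0_fN=30.0, d0_um=20.0, p=1.0)
        starts = np.column_stack([np.linspace(15.0, 90.0, 40), np.zeros(40)])
        ts = m.simulate_tracks(cfg, needle, phys, start_positions=starts)
        res = m.ForceModel(ts, needle, phys).fit()
        prof = res.profile(np.arange(0.0, 100.0, 20.0))
        rho, _ = spearmanr(prof["d_center_um"], prof["mean_F_fN"])
        assert rho < 0


class TestEstimatorProperties:
    def test_null_force_distribution_centered_at_zero(self, phys):
        cfg = m.SimulationConfig(D_true=0.13, dt_s=0.1, n_frames=300, n_tracks=60,
                                 sigma_loc_um=0.01, arena_um=(-1e6, -1e6, 1e6, 1e6),
                                 seed=31)
        ts = m.simulate_tracks(cfg)
        res = m.ForceModel(ts, m.NeedleGeometry(tip_um=(1e5, 0.0))).fit()
        mean, sd, n = res.ensemble()
        assert abs(mean) < 3 * sd / np.sqrt(n)

    @pytest.mark.parametrize("F_true", [5.0, 13.4, 30.0])
    def test_constant_force_recovered_within_ten_percent(self, F_true, phys):
        cfg = m.SimulationConfig(D_true=0.13, dt_s=0.1, n_frames=500, n_tracks=100,
                                 sigma_loc_um=0.01, arena_um=(-1e7, -1e7, 1e7, 1e7),
                                 seed=int(F_true * 10))
        needle = m.NeedleGeometry(tip_um=(1e5, 0.0), F0_fN=F_true, p=0.0)
        starts = np.zeros((100, 2))
        starts[:, 1] = np.arange(100) * 10.0
        ts = m.simulate_tracks(cfg, needle, phys, start_positions=starts)
        mean, sd, n = m.ForceModel(ts, needle, phys).fit().ensemble()
        # bias bound of 10% plus the Monte-Carlo error of a finite ensemble
        assert abs(mean - F_true) < 0.10 * F_true + 3 * sd / np.sqrt(n)

    def test_doubling_diffusivity_leaves_force_centered(self, phys):
        # doubling D halves nothing in F = kT v/D: v doubles too
        means = []
        for D in (0.13, 0.26):
            cfg = m.SimulationConfig(D_true=D, dt_s=0.1, n_frames=500, n_tracks=50,
                                     sigma_loc_um=0.0, arena_um=(-1e7, -1e7, 1e7, 1e7),
                                     seed=77)
            needle = m.NeedleGeometry(tip_um=(1e5, 0.0), F0_fN=13.4, p=0.0)
            starts = np.zeros((50, 2))
            starts[:, 1] = np.arange(50) * 10.0
            ts = m.simulate_tracks(cfg, needle, phys, start_positions=starts)
            mean, _, _ = m.ForceModel(ts, needle, phys).fit().ensemble()
            means.append(mean)
        assert means[0] == pytest.approx(13.4, rel=0.15)
        assert means[1] == pytest.approx(13.4, rel=0.15)

    def test_frame_invariance_under_global_rotation(self, phys):
        traj = _drift_track(n=150, v=0.15, perp_amp=0.08, seed=9)
        needle = m.NeedleGeometry(tip_um=(1e4, 0.0))
        base = [e.F_x_fN for e in m.track_forces(traj, needle, phys=phys)]
        theta = np.radians(37.0)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy_rot = traj.xy @ R.T
        tip_rot = R @ np.array(needle.tip_um)
        traj_rot = m.Trajectory(0, traj.frames, xy_rot[:, 0], xy_rot[:, 1], traj.dt_s)
        needle_rot = m.NeedleGeometry(tip_um=(tip_rot[0], tip_rot[1]))
        rotated = [e.F_x_fN for e in m.track_forces(traj_rot, needle_rot, phys=phys)]
        np.testing.assert_allclose(rotated, base, rtol=1e-9)
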