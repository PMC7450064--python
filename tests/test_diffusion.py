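import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import magnetospt as m
from conftest import straight_track


class TestMSD:
    def test_ballistic_track_is_quadratic(self):
        # x = v t -> MSD(tau) = v^2 tau^2 exactly
        v, dt = 1.0, 0.1
        msd = m.compute_msd(straight_track(v=v, dt=dt, n=50), max_lag=10)
        np.testing.assert_allclose(msd.values_um2, (v * msd.lags_s) ** 2, rtol=1e-12)

    def test_single_step_track(self):
        t = m.Trajectory(0, np.arange(2), np.array([0.0, 0.3]), np.array([0.0, 0.4]), 0.1)
        msd = m.compute_msd(t, max_lag=1)
        assert msd.values_um2[0] == pytest.approx(0.5**2)
        assert msd.counts[0] == 1

    def test_pooled_brownian_msd_recovers_D(self, free_trackset):
        res = m.DiffusionModel(free_trackset, n_fit_lags=4).fit()
        pooled = res.pooled_D()
        # s.e. of the pooled estimate from the per-track spread
        Ds = res.per_track["D_um2_s"].to_numpy()
        se = Ds.std(ddof=1) / np.sqrt(len(Ds))
        assert abs(pooled.D_um2_s - 0.13) < 3 * se

    def test_max_lag_bounds_enforced(self):
        t = straight_track(n=20)
        with pytest.raises(ValueError):
            m.compute_msd(t, max_lag=20)
        with pytest.raises(ValueError):
            m.compute_msd(t, max_lag=0)


class TestFitDiffusion:
    def test_exact_line_recovered(self):
        lags = np.arange(1, 6) * 0.1
        msd = m.MSDCurve(lags, 4 * 0.13 * lags, np.full(5, 100))
        est = m.fit_diffusion(msd, n_fit_lags=4)
        assert est.D_um2_s == pytest.approx(0.13)
        assert est.intercept_um2 == pytest.approx(0.0, abs=1e-12)

    def test_intercept_absorbs_offset_without_biasing_slope(self):
        # MSD = 4 D tau + 4 sigma^2 with sigma = 10 nm
        lags = np.arange(1, 6) * 0.1
        offset = 4 * (0.01) ** 2
        msd = m.MSDCurve(lags, 4 * 0.13 * lags + offset, np.full(5, 100))
        est = m.fit_diffusion(msd, n_fit_lags=4)
        assert est.D_um2_s == pytest.approx(0.13)
        assert est.intercept_um2 == pytest.approx(4e-4)

    def test_median_recovery_on_simulated_tracks(self, free_trackset):
        res = m.DiffusionModel(free_trackset, n_fit_lags=4).fit()
        assert np.median(res.per_track["D_um2_s"]) == pytest.approx(0.13, rel=0.10)

    def test_negative_slope_reported_and_flagged(self):
        lags = np.arange(1, 5) * 0.1
        msd = m.MSDCurve(lags, np.array([0.4, 0.3, 0.2, 0.1]), np.full(4, 10))
        est = m.fit_diffusion(msd, n_fit_lags=4)
        assert est.D_um2_s < 0 and not est.valid


class TestFilters:
    def _toy_trackset(self, specs, dt=0.1):
        tracks = []
        for tid, (length, disp) in enumerate(specs):
            x = np.linspace(0.0, disp, length)
            tracks.append(m.Trajectory(tid, np.arange(length), x, np.zeros(length), dt))
        return m.TrackSet(tracks=tracks, dt_s=dt)

    def test_spt_preset_survivor_count(self):
        # (length, D): (40, 0.002), (60, 0.02), (300, 0.05) -> 2 survive
        ts = self._toy_trackset([(40, 1.0), (60, 1.0), (300, 1.0)])
        D = {0: 0.002, 1: 0.02, 2: 0.05}
        kept = m.apply_filters(ts, m.FilterSpec.spt(), D)
        assert [t.track_id for t in kept] == [1, 2]

    def test_force_preset_rejects_short_displacement(self):
        # 300 frames but only 4 um net displacement -> discarded
        ts = self._toy_trackset([(300, 4.0)])
        kept = m.apply_filters(ts, m.FilterSpec.force_calibration(), {0: 0.05})
        assert len(kept) == 0

    def test_force_preset_keeps_qualifying_track(self):
        ts = self._toy_trackset([(300, 15.0)])
        kept = m.apply_filters(ts, m.FilterSpec.force_calibration(), {0: 0.05})
        assert len(kept) == 1

    def test_empty_trackset_passes_through(self):
        ts = m.TrackSet(tracks=[], dt_s=0.1)
        assert len(m.apply_filters(ts, m.FilterSpec.spt(), {})) == 0

    def test_missing_estimate_is_an_error(self):
        ts = self._toy_trackset([(60, 1.0)])
        with pytest.raises(KeyError):
            m.apply_filters(ts, m.FilterSpec.spt(), {})

    def test_filtering_is_idempotent_and_never_grows(self):
        ts = self._toy_trackset([(40, 1.0), (60, 12.0), (300, 20.0), (250, 5.0)])
        D = {0: 0.1, 1: 0.02, 2: 0.05, 3: 0.002}
        spec = m.FilterSpec.force_calibration()
        once = m.apply_filters(ts, spec, D)
        twice = m.apply_filters(once, spec, D)
        assert len(once) <= len(ts)
        assert [t.track_id for t in twice] == [t.track_id for t in once]


class TestSummaries:
    def test_constant_sample(self):
        s = m.summarize_D([0.1, 0.1, 0.1])
        assert s["mean"] == pytest.approx(0.1)
        assert s["median"] == pytest.approx(0.1)
        assert s["sd_logD"] == 0.0

    def test_two_values(self):
        s = m.summarize_D([0.05, 0.15])
        assert s["mean"] == pytest.approx(0.10)
        assert s["median"] == pytest.approx(0.10)

    def test_lognormal_sample_centered_on_mu(self):
        rng = np.random.default_rng(0)
        Ds = np.exp(rng.normal(np.log(0.13), 0.5, size=1000))
        s = m.summarize_D(Ds)
        se = 0.5 / np.sqrt(1000)
        assert abs(s["mean_logD"] - np.log(0.13)) < 3 * se

    def test_nonpositive_excluded_and_counted(self):
        s = m.summarize_D([0.1, -0.05, 0.2, 0.0])
        assert s["n"] == 4
        assert s["n_excluded_nonpositive"] == 2
        assert np.isfinite(s["mean_logD"])

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            m.summarize_D([])


class TestPairedTest:
    def test_identical_samples_give_t_zero_p_one(self):
        r = m.paired_logD_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_symmetric_log_differences_cancel(self):
        # ln-differences {+0.1, -0.1} -> t = 0
        before = [0.1 * np.exp(0.1), 0.1 * np.exp(-0.1)]
        after = [0.1, 0.1]
        r = m.paired_logD_test(before, after)
        assert r.t == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_reported_statistic_reproduces_published_p(self):
        # construct 10 pairs whose paired t on logs equals 0.63 -> p = 0.54
        n = 10
        base = np.full(n, 0.046)
        diffs = np.linspace(-1.0, 1.0, n)
        diffs = diffs - diffs.mean()
        sd = diffs.std(ddof=1)
        target_mean = 0.63 * sd / np.sqrt(n)
        logafter = np.log(base) - (diffs + target_mean)
        r = m.paired_logD_test(base, np.exp(logafter))
        assert r.t == pytest.approx(0.63, abs=1e-9)
        assert r.df == 9
        assert round(r.p, 2) == 0.54

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        b = np.exp(rng.normal(-3, 0.5, 10))
        a = np.exp(rng.normal(-3, 0.5, 10))
        r1 = m.paired_logD_test(b, a)
        r2 = m.paired_logD_test(7.3 * b, 7.3 * a)
        assert r1.t == pytest.approx(r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.paired_logD_test([0.1, 0.2], [0.1])
        with pytest.raises(ValueError):
            m.paired_logD_test([0.1, -0.2], [0.1, 0.2])


class TestStudentsT:
    def test_zero_statistic_gives_p_one(self):
        assert m.students_t_pvalue(0.0, 5) == pytest.approx(1.0)

    def test_published_value(self):
        assert round(m.students_t_pvalue(0.63, 9), 2) == 0.54

    def test_large_t_limit(self):
        assert m.students_t_pvalue(1e6, 9) < 1e-10

    def test_df_validated(self):
        with pytest.raises(ValueError):
            m.students_t_pvalue(1.0, 0)

    @given(t=st.floats(-50, 50), df=st.integers(1, 200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_in_sign(self, t, df):
        assert m.students_t_pvalue(t, df) == pytest.approx(m.students_t_pvalue(-t, df))

    @given(df=st.integers(1, 100), lo=st.floats(0.0, 10.0), delta=st.floats(0.01, 10.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_magnitude(self, df, lo, delta):
        assert m.students_t_pvalue(lo + delta, df) < m.students_t_pvalue(lo, df)
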