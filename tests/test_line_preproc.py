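"""The line-scanning signal chain, step by step and end to end."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from linetarget.preproc import (
    CHAIN_ORDER,
    MultiCoilLineSeries,
    PreprocChain,
    average_iterations,
    combine_coils,
    combine_echoes,
    dct_highpass,
    detect_elbow,
    line_acompcor,
    percent_signal_change,
    savgol_smooth,
    svd_denoise,
)


class TestElbowDetection:
    def test_clear_drop_retains_three(self):
        # max chord distance sits at the drop; components before it survive
        assert detect_elbow([10, 9.5, 9, 1, 0.9, 0.8]) == 3

    def test_linear_decay_ties_toward_retaining_more(self):
        n = 8
        s = np.linspace(10, 1, n)
        assert detect_elbow(s) == n - 1

    def test_two_values_retain_one(self):
        assert detect_elbow([5.0, 1.0]) == 1

    def test_constant_spectrum_retains_all_with_warning(self):
        with pytest.warns(UserWarning, match="elbow undefined"):
            assert detect_elbow([2.0, 2.0, 2.0, 2.0]) == 4

    def test_increasing_values_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            detect_elbow([1.0, 2.0, 3.0])


class TestSVDDenoise:
    @staticmethod
    def rank3(rng, p=24, t=400, scale=(10, 8, 6)):
        u = np.linalg.qr(rng.standard_normal((p, 3)))[0]
        v = np.linalg.qr(rng.standard_normal((t, 3)))[0]
        return (u * np.array(scale)) @ v.T

    def test_exact_low_rank_reconstructed(self):
        m = self.rank3(np.random.default_rng(0))
        out, rank = svd_denoise(m)
        assert rank == 3
        np.testing.assert_allclose(out, m, atol=1e-9)

    def test_zero_matrix_passthrough(self):
        out, rank = svd_denoise(np.zeros((5, 9)))
        assert rank == 0
        np.testing.assert_array_equal(out, 0.0)

    def test_noise_suppression_improves_every_seed(self):
        improved = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth = self.rank3(rng)
            noisy = truth + rng.normal(0, 0.05, truth.shape)
            den, _ = svd_denoise(noisy)
            if (np.linalg.norm(den - truth) < np.linalg.norm(noisy - truth)):
                improved += 1
        assert improved == 20


class TestCoilCombination:
    def _series(self, data, dt=0.105, te=(0.006,)):
        return MultiCoilLineSeries(data=data, dt=dt, echo_times=te)

    def test_single_coil_returns_magnitude(self):
        rng = np.random.default_rng(1)
        data = (rng.standard_normal((1, 1, 4, 50))
                + 1j * rng.standard_normal((1, 1, 4, 50)))
        series = self._series(data)
        out, _ = combine_coils(series, np.ones((1, 4)), tsnr=np.ones((1, 4)),
                               denoise=False)
        np.testing.assert_allclose(out[0], np.abs(data[0, 0]), atol=1e-12)

    def test_uniform_weights_reduce_to_rms(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 1, 6, 30))
        series = self._series(data)
        out, _ = combine_coils(series, np.ones((4, 6)), tsnr=np.ones((4, 6)),
                               denoise=False)
        rms = np.sqrt(np.mean(data[:, 0] ** 2, axis=0))
        np.testing.assert_allclose(out[0], rms, atol=1e-12)

    def test_two_coil_hand_weights_match_formula(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((2, 1, 3, 20))
        sens = np.array([[1.0, 2.0, 0.5]] * 2) * np.array([[1.0], [0.7]])
        tsnr = np.array([[3.0, 1.0, 2.0], [1.5, 2.5, 0.5]])
        series = self._series(data)
        out, _ = combine_coils(series, sens, tsnr=tsnr, denoise=False)
        w = (tsnr * sens) ** 2
        w = w / w.sum(axis=0)
        expected = np.sqrt(np.einsum("cp,cpt->pt", w, data[:, 0] ** 2))
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_combination_is_one_homogeneous(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((3, 2, 5, 40))
        series = self._series(data, te=(0.006, 0.014))
        sens = np.abs(rng.standard_normal((3, 5))) + 0.1
        tsnr = np.abs(rng.standard_normal((3, 5))) + 0.1
        out1, _ = combine_coils(series, sens, tsnr=tsnr, denoise=False)
        out2, _ = combine_coils(self._series(3.0 * data, te=(0.006, 0.014)),
                                sens, tsnr=tsnr, denoise=False)
        np.testing.assert_allclose(out2, 3.0 * out1, atol=1e-9)

    def test_all_zero_weights_fall_back_with_warning(self):
        data = np.ones((2, 1, 3, 10))
        series = self._series(data)
        with pytest.warns(UserWarning, match="root-sum-of-squares"):
            out, _ = combine_coils(series, np.zeros((2, 3)), tsnr=np.ones((2, 3)),
                                   denoise=False)
        np.testing.assert_allclose(out[0], np.sqrt(2) / np.sqrt(2) * np.ones((3, 10)))


class TestEchoCombination:
    def test_single_echo_identity(self):
        rng = np.random.default_rng(5)
        x = np.abs(rng.standard_normal((1, 4, 20)))
        np.testing.assert_allclose(combine_echoes(x), x[0])

    def test_five_equal_echoes_scale_sqrt5(self):
        v = np.full((5, 3, 7), 2.0)
        np.testing.assert_allclose(combine_echoes(v), np.sqrt(5) * 2.0)

    def test_matches_elementwise_bruteforce(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((3, 4, 15))
        expected = np.sqrt(x[0] ** 2 + x[1] ** 2 + x[2] ** 2)
        np.testing.assert_allclose(combine_echoes(x), expected, atol=1e-12)

    def test_output_dominates_each_echo(self):
        rng = np.random.default_rng(7)
        x = np.abs(rng.standard_normal((4, 5, 30)))
        out = combine_echoes(x)
        assert np.all(out >= x.max(axis=0) - 1e-12)


class TestDCTHighpass:
    def test_linear_drift_removed_mean_preserved(self):
        # long enough that ~16 drift regressors exist below the cutoff
        dt = 0.105
        t = np.arange(8000) * dt
        drift = 0.02 * t
        ts = 5.0 + drift[None, :]
        out, nuis = dct_highpass(ts, dt, cutoff_hz=0.01)
        r = np.corrcoef(out[0], drift)[0, 1]
        assert abs(r) < 0.01
        assert out[0].mean() == pytest.approx(5.0 + drift.mean(), abs=1e-9)
        # projection idempotence: residual has no content on the regressors
        proj = nuis.regressors.T @ (out[0] - out[0].mean())
        assert np.max(np.abs(proj)) < 1e-6 * np.abs(ts).max()

    def test_constant_series_unchanged(self):
        out, _ = dct_highpass(np.full((2, 1200), 3.0), 0.105)
        np.testing.assert_allclose(out, 3.0)

    def test_fast_oscillation_preserved(self):
        dt = 0.105
        t = np.arange(3000) * dt
        sig = np.sin(2 * np.pi * 0.2 * t)
        out, _ = dct_highpass(sig[None, :], dt, cutoff_hz=0.01)
        # amplitude at 0.2 Hz via quadrature projection
        basis = np.column_stack([np.sin(2 * np.pi * 0.2 * t),
                                 np.cos(2 * np.pi * 0.2 * t)])
        amp = np.hypot(*np.linalg.lstsq(basis, out[0], rcond=None)[0])
        assert abs(amp - 1.0) < 0.01

    def test_too_short_series_warns_identity(self):
        ts = np.random.default_rng(0).standard_normal((1, 50))
        with pytest.warns(UserWarning, match="unchanged"):
            out, nuis = dct_highpass(ts, 0.105, cutoff_hz=0.01)
        np.testing.assert_array_equal(out, ts)
        assert nuis.regressors.shape[1] == 0


class TestLineACompCor:
    def test_physiology_removed_task_preserved(self):
        dt = 0.105
        T = 4000
        t = np.arange(T) * dt
        rng = np.random.default_rng(8)
        cardiac = np.sin(2 * np.pi * 1.0 * t + 0.3)
        task = np.sin(2 * np.pi * 0.05 * t)
        seg = np.array(["CSF"] * 3 + ["GM"] * 6 + ["WM"] * 3)
        mask = np.ones(12, dtype=bool)
        ts = 0.8 * cardiac + 0.05 * rng.standard_normal((12, T))
        ts[seg == "GM"] += task

        def band_power(x, f):
            basis = np.column_stack([np.sin(2 * np.pi * f * t),
                                     np.cos(2 * np.pi * f * t)])
            a = np.linalg.lstsq(basis, x, rcond=None)[0]
            return float(a @ a)

        before_card = band_power(ts[4], 1.0)
        before_task = band_power(ts[4], 0.05)
        out, _ = line_acompcor(ts, seg, mask, dt, n_components=5)
        assert band_power(out[4], 1.0) <= 0.1 * before_card
        assert abs(band_power(out[4], 0.05) - before_task) <= 0.1 * before_task

    def test_orthogonal_series_untouched(self):
        # WM pool spans integer-frequency cosines; a GM sine at another
        # integer frequency is exactly orthogonal to them (and to the mean)
        T = 100
        n = np.arange(T)
        seg = np.array(["GM", "WM", "WM"])
        mask = np.ones(3, dtype=bool)
        gm = np.sin(2 * np.pi * 5 * n / T)
        wm1 = np.cos(2 * np.pi * 3 * n / T)
        wm2 = np.cos(2 * np.pi * 7 * n / T)
        ts = np.vstack([gm, wm1, wm2])
        # dt chosen so no DCT high-pass regressor exists below the cutoff
        out, nuis = line_acompcor(ts, seg, mask, dt=0.02, n_components=2)
        np.testing.assert_allclose(out[0], gm, atol=1e-9)

    def test_zero_components_identity(self):
        rng = np.random.default_rng(9)
        ts = rng.standard_normal((4, 300))
        seg = np.array(["GM", "GM", "WM", "CSF"])
        out, nuis = line_acompcor(ts, seg, np.ones(4, bool), 0.105, n_components=0)
        np.testing.assert_array_equal(out, ts)
        assert nuis.regressors.shape[1] == 0

    def test_missing_noise_pool_reports_labels(self):
        ts = np.zeros((2, 300))
        seg = np.array(["GM", "GM"])
        with pytest.raises(ValueError, match="GM"):
            line_acompcor(ts, seg, np.ones(2, bool), 0.105)

    def test_regressor_projection_idempotent(self):
        rng = np.random.default_rng(10)
        ts = rng.standard_normal((6, 500))
        seg = np.array(["GM"] * 3 + ["WM"] * 2 + ["CSF"])
        out, nuis = line_acompcor(ts, seg, np.ones(6, bool), 0.105, n_components=3)
        resid = out - out.mean(axis=1, keepdims=True)
        proj = nuis.regressors.T @ resid.T
        assert np.max(np.abs(proj)) < 1e-9 * np.abs(ts).max() * ts.shape[1]


class TestSavGol:
    def test_cubic_polynomial_reproduced(self):
        t = np.linspace(0, 1, 200)
        ts = 2 - t + 0.5 * t**2 + 3 * t**3
        np.testing.assert_allclose(savgol_smooth(ts[None, :])[0], ts, atol=1e-9)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(savgol_smooth(np.full((1, 50), 4.0)), 4.0)

    def test_noise_variance_matches_theory(self):
        # interior variance gain of an (11, 3) smoother is sum(c^2)
        factor = float(np.sum(savgol_coeffs(11, 3) ** 2))
        rng = np.random.default_rng(12)
        noise = rng.standard_normal((40, 4000))
        sm = savgol_smooth(noise)
        ratio = sm[:, 20:-20].var() / noise[:, 20:-20].var()
        assert abs(ratio - factor) / factor < 0.2

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            savgol_smooth(np.zeros((1, 5)))


class TestPercentSignalChange:
    def test_constant_series_is_zero(self):
        np.testing.assert_allclose(percent_signal_change(np.full((2, 10), 200.0)), 0.0)

    def test_two_percent_above_baseline(self):
        ts = np.full((1, 10), 100.0)
        ts[0, 5] = 102.0
        out = percent_signal_change(ts, baseline_frames=np.r_[0:5, 6:10])
        assert out[0, 5] == pytest.approx(2.0 * 100 / 100, rel=1e-9)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(13)
        ts = 100 + rng.standard_normal((3, 60))
        idx = np.arange(0, 60, 7)
        mu = ts[:, idx].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(percent_signal_change(ts, idx),
                                   100 * (ts - mu) / mu, atol=1e-12)

    def test_zero_baseline_rejected(self):
        ts = np.zeros((1, 10))
        with pytest.raises(ValueError, match="zero baseline"):
            percent_signal_change(ts)


class TestAverageIterations:
    def test_identical_iterations_returned(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((2, 30))
        both = np.concatenate([x, x], axis=1)
        np.testing.assert_allclose(average_iterations(both, [0, 30]), x)

    def test_opposite_iterations_cancel(self):
        x = np.random.default_rng(15).standard_normal((1, 20))
        both = np.concatenate([x, -x], axis=1)
        np.testing.assert_allclose(average_iterations(both, [0, 20]), 0.0,
                                   atol=1e-12)

    def test_three_segments_match_bruteforce(self):
        rng = np.random.default_rng(16)
        segs = [rng.standard_normal((2, 11)) for _ in range(3)]
        ts = np.concatenate(segs, axis=1)
        np.testing.assert_allclose(average_iterations(ts, [0, 11, 22]),
                                   np.mean(segs, axis=0), atol=1e-12)

    def test_ragged_segments_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            average_iterations(np.zeros((1, 10)), [0, 4])


class TestChain:
    def _session(self, seed=0, snr=5.0, n_iterations=2):
        from linetarget.prf import PRFParams, build_bar_design
        from linetarget.synthetic import default_ground_truth, simulate_line_session

        design = build_bar_design([0.0, 90.0], directions=(1, -1),
                                  bar_widths=(1.25,), grid_extent=8.0, step=0.5,
                                  tr=0.105, blank_s=5.0, n_pix=16)
        gt = default_ground_truth(PRFParams(1.0, -1.0, 0.8), seed=seed,
                                  thermal_snr=snr)
        return simulate_line_session(gt, design, dt=design.tr,
                                     n_iterations=n_iterations), design

    def test_order_is_enforced(self):
        chain = PreprocChain()
        chain._advance("svd_denoise")
        with pytest.raises(RuntimeError, match="order violation"):
            chain._advance("dct_highpass")

    def test_full_run_produces_finite_percent_change(self):
        session, design = self._session()
        chain = PreprocChain()
        bounds = [0, design.n_frames]
        clean = chain.run(session.series, session.sensitivities, session.seg,
                          session.line_mask,
                          baseline_frames=design.blank_frames,
                          iteration_boundaries=bounds)
        assert clean.data.shape == (session.series.n_positions, design.n_frames)
        assert np.all(np.isfinite(clean.data))
        assert [e["step"] for e in chain.log] == list(CHAIN_ORDER)

    def test_chain_improves_prf_recovery(self, line_design, line_grid):
        """Per-voxel fits on chain-processed data beat fits on the raw
        (unweighted, undenoised, unfiltered, single-iteration) data."""
        from linetarget.prf import PRFParams, fit_prf
        from linetarget.synthetic import default_ground_truth, simulate_line_session

        true = PRFParams(1.2, -0.9, 0.7)
        wins = 0
        for seed in range(20):
            gt = default_ground_truth(true, seed=seed, thermal_snr=5.0)
            session = simulate_line_session(gt, line_design, dt=line_design.tr,
                                            n_iterations=2)
            gm = np.flatnonzero(session.seg == "GM")
            picks = [gm[1], gm[-2]]  # a superficial and a deep voxel
            bounds = [0, line_design.n_frames]
            blanks = np.concatenate([line_design.blank_frames,
                                     line_design.blank_frames + line_design.n_frames])

            chain = PreprocChain()
            clean = chain.run(session.series, session.sensitivities, session.seg,
                              session.line_mask, baseline_frames=blanks,
                              iteration_boundaries=bounds)
            flat_sens = np.ones_like(session.sensitivities)
            raw_echo, _ = combine_coils(session.series, flat_sens, tsnr=flat_sens,
                                        denoise=False)
            raw = combine_echoes(raw_echo)[:, :line_design.n_frames]

            err_c, err_r = [], []
            for p in picks:
                fit_c = fit_prf(clean.data[p], line_design, grid=line_grid)
                fit_r = fit_prf(raw[p], line_design, grid=line_grid)
                err_c.append(np.hypot(fit_c.x0 - true.x0, fit_c.y0 - true.y0))
                err_r.append(np.hypot(fit_r.x0 - true.x0, fit_r.y0 - true.y0))
            if np.mean(err_c) < np.mean(err_r):
                wins += 1
        assert wins >= 18
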