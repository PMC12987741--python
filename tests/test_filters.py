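"""Temporal/spatial filter behaviour against closed-form and brute-force oracles."""

import numpy as np
import pytest
import scipy.ndimage

import fpetconn as fp
from fpetconn.filters import butterworth_magnitude


def _design_from(columns, n_frames):
    blocks = np.column_stack(columns) if columns else None
    return fp.assemble_design(wm_components=blocks, n_frames=n_frames)


def _fit_amplitude(signal, f, t):
    basis = np.column_stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
    coef, *_ = np.linalg.lstsq(basis, signal, rcond=None)
    return float(np.hypot(*coef))


class TestCompCorResidualize:
    def test_design_column_projects_to_zero(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=40)
        design = _design_from([col], 40)
        resid = fp.compcor_residualize(col[:, None], design)
        assert np.max(np.abs(resid)) < 1e-10

    def test_orthogonal_course_only_demeaned(self):
        t = np.arange(64.0)
        col = np.cos(2 * np.pi * 4 * t / 64)
        signal = np.cos(2 * np.pi * 9 * t / 64) + 3.0
        design = _design_from([col], 64)
        resid = fp.compcor_residualize(signal[:, None], design)[:, 0]
        np.testing.assert_allclose(resid, signal - signal.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        x_cols = rng.normal(size=(30, 4))
        y = rng.normal(size=(30, 7))
        design = _design_from(list(x_cols.T), 30)
        resid = fp.compcor_residualize(y, design)
        x = design.values
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(resid, y - x @ beta, atol=1e-9)

    def test_residuals_orthogonal_and_zero_mean(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(100, 20))
        design = _design_from(list(rng.normal(size=(100, 5)).T), 100)
        resid = fp.compcor_residualize(y, design)
        dots = np.abs(design.values.T @ resid)
        norms = (np.linalg.norm(design.values, axis=0)[:, None]
                 * np.linalg.norm(resid, axis=0)[None, :])
        assert np.max(dots / norms) < 1e-8
        assert np.max(np.abs(resid.mean(axis=0))) < 1e-10

    def test_linearity(self):
        rng = np.random.default_rng(3)
        design = _design_from(list(rng.normal(size=(50, 3)).T), 50)
        x1, x2 = rng.normal(size=(2, 50, 4))
        lhs = fp.compcor_residualize(2.0 * x1 - 0.5 * x2, design)
        rhs = (2.0 * fp.compcor_residualize(x1, design)
               - 0.5 * fp.compcor_residualize(x2, design))
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_frame_mismatch_rejected(self):
        design = _design_from([np.ones(10)], 10)
        with pytest.raises(ValueError, match=r"frames|rows"):
            fp.compcor_residualize(np.zeros((12, 2)), design)

    def test_report_variance_removed_in_unit_interval(self):
        rng = np.random.default_rng(4)
        design = _design_from(list(rng.normal(size=(40, 3)).T), 40)
        _, report = fp.compcor_residualize(rng.normal(size=(40, 6)), design,
                                           return_report=True)
        assert report.method == "compcor"
        assert np.all(report.variance_removed >= 0)
        assert np.all(report.variance_removed <= 1)


class TestButterworthBandpass:
    BAND = fp.FrequencyBand(0.01, 0.1)

    @staticmethod
    def _two_rows(signal):
        return fp.RegionTimeSeries(np.vstack([signal, signal]), [1, 2], 1.0)

    def test_zero_in_zero_out(self):
        out = fp.butterworth_bandpass(self._two_rows(np.zeros(1500)), self.BAND)
        assert np.max(np.abs(out.values)) < 1e-12

    def test_passband_center_amplitude_preserved(self):
        t = np.arange(1500.0)
        f0 = np.sqrt(self.BAND.low * self.BAND.high)  # geometric band center
        sig = np.sin(2 * np.pi * f0 * t)
        out = fp.butterworth_bandpass(self._two_rows(sig), self.BAND)
        amp = _fit_amplitude(out.values[0, 250:1250], f0, t[250:1250])
        assert 0.95 <= amp <= 1.05

    def test_stopband_attenuation_matches_analytic_response(self):
        t = np.arange(1500.0)
        sig = np.sin(2 * np.pi * 0.45 * t)
        out = fp.butterworth_bandpass(self._two_rows(sig), self.BAND)
        amp = _fit_amplitude(out.values[0, 250:1250], 0.45, t[250:1250])
        assert amp <= 0.01
        assert butterworth_magnitude(0.45, self.BAND) <= 0.01

    def test_forty_db_at_ten_times_high_edge(self):
        band = fp.FrequencyBand(0.01, 0.04)
        t = np.arange(3000.0)
        sig = np.sin(2 * np.pi * 0.4 * t)
        out = fp.butterworth_bandpass(self._two_rows(sig), band)
        amp = _fit_amplitude(out.values[0, 500:2500], 0.4, t[500:2500])
        assert 20 * np.log10(max(amp, 1e-300)) <= -40.0

    def test_matches_analytic_magnitude_across_sweep(self):
        """Bidirectional response vs the squared analytic order-4 curve."""
        t = np.arange(6000.0)
        for f in [0.005, 0.01, 0.02, 0.05, 0.08, 0.1, 0.12, 0.15, 0.2, 0.3]:
            sig = np.sin(2 * np.pi * f * t)
            out = fp.butterworth_bandpass(self._two_rows(sig[:6000]), self.BAND)
            amp = _fit_amplitude(out.values[0, 1500:4500], f, t[1500:4500])
            assert amp == pytest.approx(butterworth_magnitude(f, self.BAND),
                                        abs=0.02)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 2, 1500))
        ra = fp.RegionTimeSeries(a, [1, 2], 1.0)
        rb = fp.RegionTimeSeries(b, [1, 2], 1.0)
        rab = fp.RegionTimeSeries(3.0 * a + 0.5 * b, [1, 2], 1.0)
        lhs = fp.butterworth_bandpass(rab, self.BAND).values
        rhs = (3.0 * fp.butterworth_bandpass(ra, self.BAND).values
               + 0.5 * fp.butterworth_bandpass(rb, self.BAND).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_band_above_nyquist_rejected(self):
        rts = self._two_rows(np.zeros(1500))
        with pytest.raises(ValueError, match="Nyquist"):
            fp.butterworth_bandpass(
                fp.RegionTimeSeries(rts.values, [1, 2], 3.0),
                fp.FrequencyBand(0.01, 0.2))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fp.butterworth_bandpass(self._two_rows(np.zeros(50)), self.BAND)

    def test_causal_mode_differs_from_zero_phase(self):
        rng = np.random.default_rng(6)
        rts = self._two_rows(rng.normal(size=1500))
        zp = fp.butterworth_bandpass(rts, self.BAND)
        ca = fp.butterworth_bandpass(rts, self.BAND, causal=True)
        assert not np.allclose(zp.values, ca.values)


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(7)
        s = fp.DynamicSeries(rng.normal(size=(6, 6, 6, 3)), 1.0)
        out = fp.gaussian_smooth(s, 0.0)
        np.testing.assert_array_equal(out.data, s.data)

    def test_constant_frame_unchanged(self):
        s = fp.DynamicSeries(np.full((8, 8, 8, 2), 2.5), 1.0, voxel_size=(2, 2, 2))
        out = fp.gaussian_smooth(s, 8.0)
        np.testing.assert_allclose(out.data, 2.5, atol=1e-10)

    def test_frame_sum_preserved(self):
        rng = np.random.default_rng(8)
        s = fp.DynamicSeries(rng.normal(size=(16, 16, 16, 2)) + 5.0, 1.0,
                             voxel_size=(2, 2, 2))
        out = fp.gaussian_smooth(s, 8.0)
        for f in range(2):
            assert out.data[..., f].sum() == pytest.approx(
                s.data[..., f].sum(), rel=1e-6)

    def test_impulse_response_fwhm(self):
        # brute-force profile scan through the impulse response
        data = np.zeros((33, 33, 33, 2))
        data[16, 16, 16, :] = 1.0
        s = fp.DynamicSeries(data, 1.0, voxel_size=(1, 1, 1))
        profile = fp.gaussian_smooth(s, 8.0).data[:, 16, 16, 0]
        above = np.flatnonzero(profile >= profile.max() / 2)
        width = above[-1] - above[0] + 1
        assert abs(width - 8) <= 1


class TestEdnlm:
    def test_constant_series_unchanged(self):
        s = fp.DynamicSeries(np.full((4, 4, 4, 6), 3.7), 1.0)
        out = fp.ednlm_filter(s, temporal_frames=3, h=1.0, smoothing_fwhm_mm=0.0)
        np.testing.assert_allclose(out.data, 3.7, atol=1e-10)

    def test_infinite_h_equals_window_mean(self):
        rng = np.random.default_rng(9)
        s = fp.DynamicSeries(rng.normal(size=(6, 6, 5, 8)), 1.0)
        out = fp.ednlm_filter(s, temporal_frames=3, h=1e9, smoothing_fwhm_mm=0.0)
        oracle = scipy.ndimage.uniform_filter(s.data, size=(3, 3, 3, 3),
                                              mode="reflect")
        assert np.max(np.abs(out.data - oracle)) < 1e-6

    def test_matches_brute_force_nlm_oracle(self):
        """Direct quadruple-loop NLM on a tiny array, interior voxels."""
        rng = np.random.default_rng(10)
        data = rng.normal(size=(5, 5, 5, 5))
        h = 3.0
        out = fp.ednlm_filter(fp.DynamicSeries(data, 1.0), temporal_frames=3,
                              h=h, smoothing_fwhm_mm=0.0)

        def patch(i, j, k, t):
            return np.array([
                data[i + a, j + b, k + c, t + d]
                for a in (-1, 0, 1) for b in (-1, 0, 1)
                for c in (-1, 0, 1) for d in (-1, 0, 1)
            ])

        center = (2, 2, 2, 2)
        p0 = patch(*center)
        num = den = 0.0
        for a in (-1, 0, 1):
            for b in (-1, 0, 1):
                for c in (-1, 0, 1):
                    for d in (-1, 0, 1):
                        pj = patch(2 + a, 2 + b, 2 + c, 2 + d)
                        w = np.exp(-np.sum((p0 - pj) ** 2) / h ** 2)
                        num += w * data[2 + a, 2 + b, 2 + c, 2 + d]
                        den += w
        assert out.data[center] == pytest.approx(num / den, abs=1e-10)

    def test_series_shorter_than_kernel_rejected(self):
        s = fp.DynamicSeries(np.zeros((4, 4, 4, 3)), 1.0)
        with pytest.raises(ValueError, match="shorter"):
            fp.ednlm_filter(s, temporal_frames=5)


class TestDownsampleAndExclusion:
    def test_downsample_identity(self):
        rng = np.random.default_rng(11)
        s = fp.DynamicSeries(rng.normal(size=(3, 3, 3, 9)), 1.0)
        out = fp.downsample_frames(s, 1)
        np.testing.assert_array_equal(out.data, s.data)

    def test_downsample_1500_to_500(self):
        s = fp.DynamicSeries(np.zeros((2, 2, 2, 1500)), 1.0)
        out = fp.downsample_frames(s, 3)
        assert out.n_frames == 500
        assert out.frame_duration == 3.0

    def test_downsample_block_means(self):
        data = np.arange(1.0, 7.0).reshape(1, 1, 1, 6)
        out = fp.downsample_frames(fp.DynamicSeries(data, 1.0), 3)
        np.testing.assert_array_equal(out.data.ravel(), [2.0, 5.0])

    def test_downsample_drops_remainder(self):
        s = fp.DynamicSeries(np.zeros((2, 2, 2, 10)), 1.0)
        assert fp.downsample_frames(s, 3).n_frames == 3

    def test_downsample_bad_factor(self):
        s = fp.DynamicSeries(np.zeros((2, 2, 2, 10)), 1.0)
        with pytest.raises(ValueError, match="factor"):
            fp.downsample_frames(s, 0)

    @pytest.mark.parametrize("n, dt, expected", [(1500, 1.0, 900), (400, 3.0, 200)])
    def test_exclusion_frame_counts(self, n, dt, expected):
        s = fp.DynamicSeries(np.zeros((2, 2, 2, n)), dt)
        out = fp.exclude_uptake_window(s, 600.0)
        assert out.n_frames == expected
        assert out.frame_onsets[0] >= 600.0

    def test_exclusion_zero_is_identity(self):
        rng = np.random.default_rng(12)
        s = fp.DynamicSeries(rng.normal(size=(2, 2, 2, 8)), 1.0)
        out = fp.exclude_uptake_window(s, 0.0)
        np.testing.assert_array_equal(out.data, s.data)

    def test_exclusion_preserves_absolute_times(self):
        rts = fp.RegionTimeSeries(np.random.default_rng(0).normal(size=(3, 20)),
                                  [1, 2, 3], 2.0)
        out = fp.exclude_uptake_window(rts, 10.0)
        np.testing.assert_allclose(out.frame_onsets,
                                   np.arange(5, 20) * 2.0)

    def test_exclusion_nothing_left(self):
        s = fp.DynamicSeries(np.zeros((2, 2, 2, 5)), 1.0)
        with pytest.raises(ValueError, match="leaves"):
            fp.exclude_uptake_window(s, 100.0)
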