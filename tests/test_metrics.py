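"""PSNR/SSIM oracles, df/f extraction, and transient SNR."""

import numpy as np
import pytest

from caldenoise import (
    DegenerateBaselineError,
    Movie,
    Trace,
    TransientWindow,
    extract_trace,
    find_peak,
    movie_quality,
    psnr,
    ssim,
    transient_snr,
)


class TestPSNR:
    def test_identical_images_infinite(self, rng):
        x = rng.random((32, 32))
        assert psnr(x, x) == np.inf

    def test_uniform_offset_closed_form(self):
        ref = np.full((64, 64), 0.4)
        assert psnr(ref, ref + 0.1) == pytest.approx(20.0, abs=1e-12)

    def test_matches_brute_force_mse(self, rng):
        a, b = rng.random((2, 64, 64))
        mse = sum(
            (a[i, j] - b[i, j]) ** 2 for i in range(64) for j in range(64)
        ) / 4096.0
        assert psnr(a, b) == pytest.approx(10 * np.log10(1.0 / mse), abs=1e-10)

    def test_strictly_decreasing_in_mse(self, rng):
        ref = rng.random((32, 32))
        vals = [psnr(ref, np.clip(ref + eps, 0, 1.5)) for eps in (0.01, 0.05, 0.2)]
        assert vals[0] > vals[1] > vals[2]

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            psnr(rng.random((8, 8)), rng.random((9, 9)))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((32, 32))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_images_closed_form(self):
        a = np.full((32, 32), 0.4)
        b = np.full((32, 32), 0.5)
        c1 = 0.01**2
        expected = (2 * 0.4 * 0.5 + c1) / (0.4**2 + 0.5**2 + c1)
        assert ssim(a, b) == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_reference_implementation(self, rng):
        skimage_metrics = pytest.importorskip("skimage.metrics")
        for _ in range(20):
            a = rng.random((48, 48))
            b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
            expected = skimage_metrics.structural_similarity(
                a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False,
            )
            assert ssim(a, b) == pytest.approx(expected, abs=1e-6)

    def test_bounded_by_one_with_equality_iff_identical(self, rng):
        a = rng.random((32, 32))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        assert ssim(a, b) < 1.0 - 1e-12
        assert ssim(a, a) >= 1.0 - 1e-12

    def test_small_image_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.random((8, 8)), rng.random((8, 8)))


class TestExtractTrace:
    def test_constant_movie_zero_dff(self):
        movie = Movie(np.full((10, 16, 16), 0.5), 40.0)
        mask = np.zeros((16, 16), bool)
        mask[4:8, 4:8] = True
        tr = extract_trace(movie, mask)
        assert tr.f0 == pytest.approx(0.5)
        np.testing.assert_allclose(tr.dff, 0.0, atol=1e-12)

    def test_f0_is_25th_percentile_linear_interpolation(self):
        # f = [10, 10, 10, 20] -> f0 = 10, dff = [0, 0, 0, 1]
        data = np.zeros((4, 16, 16))
        for t, v in enumerate([10.0, 10.0, 10.0, 20.0]):
            data[t] = v
        movie = Movie(data, 40.0)
        mask = np.ones((16, 16), bool)
        tr = extract_trace(movie, mask)
        assert tr.f0 == pytest.approx(10.0, abs=1e-12)
        np.testing.assert_allclose(tr.dff, [0, 0, 0, 1], atol=1e-12)

    def test_empty_mask_rejected(self, flat_movie):
        with pytest.raises(ValueError):
            extract_trace(flat_movie, np.zeros((16, 16), bool))

    def test_nonpositive_baseline_rejected(self):
        movie = Movie(np.zeros((5, 16, 16)), 40.0)
        with pytest.raises(DegenerateBaselineError):
            extract_trace(movie, np.ones((16, 16), bool))

    def test_dff_invariant_to_positive_scaling(self, rng):
        data = rng.random((30, 16, 16)) * 0.5 + 0.2
        mask = np.ones((16, 16), bool)
        tr1 = extract_trace(Movie(data, 40.0), mask)
        tr2 = extract_trace(Movie(3.0 * data, 40.0), mask)
        np.testing.assert_allclose(tr1.dff, tr2.dff, atol=1e-12)


class TestTransientSNR:
    def test_window_frame_counts_at_40hz(self):
        w = TransientWindow(peak_index=100)
        assert w.frames(40.0) == (3, 80)

    def test_recovers_amplitude_over_sigma(self):
        # baseline N(0, 0.1), peak constant 1.0 -> SNR ~ 10
        rng = np.random.default_rng(7)
        snrs = []
        for _ in range(200):
            dff = np.zeros(100)
            dff[:95] = rng.normal(0, 0.1, 95)
            dff[95:] = 1.0
            tr = Trace(f=dff + 1.0, rate_hz=40.0, f0=1.0, dff=dff)
            w = TransientWindow(peak_index=96, baseline_window_s=95 / 40.0)
            snrs.append(transient_snr(tr, w))
        assert np.mean(snrs) == pytest.approx(10.0, rel=0.15)

    def test_zero_baseline_sd_rejected(self):
        dff = np.zeros(200)
        dff[159:] = 1.0  # baseline window [79:159) is exactly zero
        tr = Trace(f=dff + 1, rate_hz=40.0, f0=1.0, dff=dff)
        with pytest.raises(DegenerateBaselineError):
            transient_snr(tr, TransientWindow(peak_index=160))

    def test_out_of_range_window_rejected(self):
        tr = Trace(f=np.ones(50), rate_hz=40.0, f0=1.0, dff=np.zeros(50))
        with pytest.raises(ValueError):
            transient_snr(tr, TransientWindow(peak_index=10))  # 2 s baseline can't fit

    def test_snr_invariant_to_trace_scaling(self, rng):
        f = rng.random(200) * 0.2 + 0.5
        f[150:153] += 1.0
        movie_like = lambda vec: Trace(
            f=vec, rate_hz=40.0, f0=float(np.percentile(vec, 25)),
            dff=(vec - np.percentile(vec, 25)) / np.percentile(vec, 25),
        )
        w = TransientWindow(peak_index=151)
        assert transient_snr(movie_like(f), w) == pytest.approx(
            transient_snr(movie_like(4.0 * f), w), rel=1e-9
        )

    def test_find_peak_helper(self):
        dff = np.zeros(100)
        dff[42] = 2.0
        tr = Trace(f=dff + 1, rate_hz=40.0, f0=1.0, dff=dff)
        assert find_peak(tr) == 42


class TestMovieQuality:
    def test_identity_movie_all_ssim_one(self, rng):
        movie = Movie(rng.random((4, 32, 32)), 40.0)
        report = movie_quality(movie, movie)
        assert np.allclose(report.per_frame.ssim, 1.0)
        assert report.ssim_mean == pytest.approx(1.0)

    def test_summary_matches_per_frame_stats(self, rng):
        ref = Movie(rng.random((5, 32, 32)), 40.0)
        test = Movie(np.clip(ref.data + rng.normal(0, 0.05, ref.data.shape), 0, 1), 40.0)
        report = movie_quality(ref, test)
        assert len(report.per_frame) == 5
        assert report.psnr_mean == pytest.approx(report.per_frame.psnr_db.mean())
        assert report.ssim_sd == pytest.approx(report.per_frame.ssim.std(ddof=1))

    def test_single_reference_frame_broadcasts(self, rng):
        ref = rng.random((32, 32))
        test = Movie(np.stack([ref, ref, ref]), 40.0)
        report = movie_quality(ref, test)
        assert np.allclose(report.per_frame.ssim, 1.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            movie_quality(Movie(rng.random((2, 16, 16)), 40), Movie(rng.random((3, 16, 16)), 40))
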