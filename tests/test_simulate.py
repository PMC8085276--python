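"""Simulator: ground-truth rendering, the Poisson+Gaussian model, motion, averaging."""

import numpy as np
import pytest

from caldenoise import (
    MotionParams,
    NoiseParams,
    SceneConfig,
    add_motion,
    average_reference,
    corrupt,
    generate_ground_truth_movie,
    random_nonuniform_motion,
)
from caldenoise.movie import Movie


class TestGroundTruth:
    def test_no_cells_gives_constant_background(self):
        scene = SceneConfig(n_cells=0, background_level=0.2, seed=0)
        movie, masks, traces = generate_ground_truth_movie(scene, 5, 40.0, 32, 32)
        assert np.all(movie.data == 0.2)
        assert masks.shape == (0, 32, 32)

    def test_full_scale_fov_accepted(self):
        scene = SceneConfig(n_cells=3, seed=1)
        movie, _, _ = generate_ground_truth_movie(scene, 2, 40.0, 500, 500)
        assert movie.frame_shape == (500, 500)
        assert movie.rate_hz == 40.0

    def test_mask_mean_matches_returned_trace(self, small_truth):
        movie, masks, traces = small_truth
        for c in range(masks.shape[0]):
            extracted = movie.data[:, masks[c]].mean(axis=1)
            np.testing.assert_allclose(extracted, traces[c], atol=1e-9)

    def test_intensities_in_unit_interval(self, small_truth):
        movie, _, _ = small_truth
        assert movie.data.min() >= 0.0
        assert movie.data.max() <= 1.0

    def test_invalid_args_rejected(self, small_scene):
        with pytest.raises(ValueError):
            generate_ground_truth_movie(small_scene, 0, 40.0, 64, 64)
        with pytest.raises(ValueError):
            generate_ground_truth_movie(small_scene, 5, -1.0, 64, 64)
        with pytest.raises(ValueError):
            generate_ground_truth_movie(small_scene, 5, 40.0, 4, 64)

    def test_bit_reproducible_under_seed(self, small_scene):
        a = generate_ground_truth_movie(small_scene, 10, 40.0, 64, 64)
        b = generate_ground_truth_movie(small_scene, 10, 40.0, 64, 64)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[2], b[2])


class TestCorrupt:
    def test_zero_noise_is_identity(self):
        frame = np.random.default_rng(0).random((16, 16))
        out = corrupt(frame, NoiseParams(poisson_magnitude=0.0, gaussian_sd=0.0, seed=1))
        np.testing.assert_array_equal(out, frame)

    def test_moments_match_closed_form(self):
        # constant frame t=0.5: mean 0.5, var = t/B + sd^2
        t, budget, sd = 0.5, 1000.0, 0.02
        n = 100_000
        frame = np.full((250, 400), t)
        out = corrupt(frame, NoiseParams(1.0, budget, sd, seed=42))
        var_true = t / budget + sd**2  # 9.0e-4
        se_mean = np.sqrt(var_true / n)
        se_var = var_true * np.sqrt(2.0 / n)
        assert abs(out.mean() - t) < 4 * se_mean
        assert abs(out.var() - var_true) < 4 * se_var

    def test_magnitude_scales_shot_noise_variance(self):
        frame = np.full((200, 200), 0.5)
        v1 = corrupt(frame, NoiseParams(1.0, 1000.0, 0.0, seed=5)).var()
        v2 = corrupt(frame, NoiseParams(2.0, 1000.0, 0.0, seed=5)).var()
        assert v2 / v1 == pytest.approx(4.0, rel=0.1)

    def test_negative_intensities_rejected(self):
        frame = np.full((16, 16), -0.1)
        with pytest.raises(ValueError):
            corrupt(frame, NoiseParams())

    def test_output_not_clipped(self):
        frame = np.zeros((64, 64))
        out = corrupt(frame, NoiseParams(0.0, 1000.0, 0.3, seed=0))
        assert out.min() < 0  # Gaussian noise on zeros must go negative

    def test_reproducible_under_seed(self):
        frame = np.random.default_rng(1).random((16, 16))
        p = NoiseParams(1.0, 1000.0, 0.05, seed=9)
        np.testing.assert_array_equal(corrupt(frame, p), corrupt(frame, p))


class TestAddMotion:
    def test_zero_displacement_is_identity(self, small_truth):
        movie = small_truth[0]
        out = add_motion(movie, MotionParams(shifts=np.zeros((movie.n_frames, 2))))
        np.testing.assert_array_equal(out.data, movie.data)
        fields = np.zeros((movie.n_frames, 64, 64, 2))
        out2 = add_motion(movie, MotionParams(fields=fields))
        np.testing.assert_array_equal(out2.data, movie.data)

    def test_integer_rigid_shift_is_exact_translation(self):
        rng = np.random.default_rng(0)
        data = rng.random((2, 32, 32))
        movie = Movie(data, 40.0)
        shifts = np.tile([3.0, 0.0], (2, 1))  # dy=3, dx=0
        out = add_motion(movie, MotionParams(shifts=shifts, fill_value=0.0))
        # pull convention: output(y, x) = input(y+3, x)
        np.testing.assert_allclose(out.data[0, :-3, :], data[0, 3:, :], atol=1e-12)
        np.testing.assert_allclose(out.data[0, -3:, :], 0.0, atol=1e-12)

    def test_nonuniform_field_moves_cell_off_its_mask(self, small_truth):
        movie, masks, _ = small_truth
        motion = random_nonuniform_motion(
            movie.n_frames, 64, 64, amplitude_px=3.0, seed=4, fill_value=0.1
        )
        out = add_motion(movie, motion)
        cell = 0
        base = movie.data[0, masks[cell]].sum()
        moved = out.data[0, masks[cell]].sum()
        assert moved != pytest.approx(base, rel=1e-6)

    def test_shape_mismatch_rejected(self, small_truth):
        movie = small_truth[0]
        with pytest.raises(ValueError):
            add_motion(movie, MotionParams(shifts=np.zeros((3, 2))))
        with pytest.raises(ValueError):
            add_motion(movie, MotionParams(fields=np.zeros((movie.n_frames, 8, 8, 2))))


class TestAverageReference:
    def test_identical_frames_average_to_themselves(self):
        frame = np.random.default_rng(0).random((32, 32))
        out = average_reference([frame] * 100)
        np.testing.assert_allclose(out, frame, atol=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            average_reference([])

    @pytest.mark.parametrize("n", [1, 10, 100])
    def test_residual_follows_sqrt_n_law(self, n):
        # Gaussian-only corruption, sd 0.05: RMS residual ~ 0.05 / sqrt(N)
        clean = np.random.default_rng(2).random((128, 128)) * 0.5 + 0.25
        rng = np.random.default_rng(100 + n)
        p = NoiseParams(0.0, 1000.0, 0.05, seed=0)
        frames = [corrupt(clean, p, rng=rng) for _ in range(n)]
        rms = np.sqrt(np.mean((average_reference(frames) - clean) ** 2))
        assert rms == pytest.approx(0.05 / np.sqrt(n), rel=0.30)
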