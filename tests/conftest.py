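import numpy as np
import pytest

from caldenoise import Movie, NoiseParams, SceneConfig, generate_ground_truth_movie


@pytest.fixture(scope="session")
def small_scene():
    return SceneConfig(n_cells=4, cell_radius_px=4.0, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_scene):
    """64x64, 40 Hz noiseless movie with 4 cells (session-wide)."""
    return generate_ground_truth_movie(small_scene, n_frames=60, rate_hz=40.0, height=64, width=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_movie():
    """Constant mid-gray movie (degenerate but valid)."""
    return Movie(np.full((5, 16, 16), 0.5), rate_hz=40.0)


@pytest.fixture()
def default_noise():
    return NoiseParams(poisson_magnitude=1.0, photon_budget=1000.0, gaussian_sd=0.02, seed=3)
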