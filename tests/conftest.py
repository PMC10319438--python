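import numpy as np
import pytest

from ddrdyn import RenderParams, SimulationConfig, render_movie, \
    simulate_state_trajectories


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim():
    """Small mixed-state simulation with everything switched on."""
    cfg = SimulationConfig(n_particles=30, duration_frames=200, seed=7,
                           field_size=(64, 64))
    return cfg, simulate_state_trajectories(cfg)


@pytest.fixture
def sparse_noiseless_movie():
    """A few well-separated particles rendered without noise."""
    cfg = SimulationConfig(n_particles=5, duration_frames=60, seed=3,
                           field_size=(128, 128), F_bound=0.5, D_free=1.0,
                           D_bound=0.01, dZ=1e9, nuclear_depth=np.inf,
                           bleach_halflife=np.inf, loc_error_sigma=0.0)
    gt = simulate_state_trajectories(cfg)
    movie = render_movie(gt, cfg, RenderParams(photons=1000, background=5,
                                               noise="none"))
    return cfg, gt, movie
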