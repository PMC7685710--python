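import numpy as np
import pytest

from endosim.config import ExperimentConfig
from endosim.runner import simulate_fov


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced scene/FOV for rendering tests: 150 µm FOV, 80 frames."""
    return ExperimentConfig(
        n_frames=80,
        volume_extent_um=(150.0, 150.0, 80.0),
        fov_size_um=150.0,
        edge_radius_um=65.0,
        n_fov=1,
    )


@pytest.fixture(scope="session")
def small_renders(small_cfg):
    """Matched corrected/uncorrected renders of one small ground-truth scene."""
    out = {}
    for probe in ("corrected", "uncorrected"):
        out[probe] = simulate_fov(small_cfg, probe, seed=7)
    return out
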