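import numpy as np
import pytest

from ddrquant.motility import MicrotubulePath
from ddrquant.simulate import MotilityParams, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cfg():
    """8x8 um field, 20 frames: fast to render."""
    return SimulationConfig(field_size_um=(8.0, 8.0), n_frames=20,
                            frame_interval_s=0.5, rng_seed=7)


@pytest.fixture
def full_cfg():
    """Assay-scale geometry (40x40 um, 5 min) without rendering."""
    return SimulationConfig(rng_seed=7)


@pytest.fixture
def diagonal_path(small_cfg):
    return MicrotubulePath(vertices=np.array([[1000.0, 1000.0],
                                              [7000.0, 7000.0]]), id=0)


@pytest.fixture
def default_motility_params():
    return MotilityParams(landing_rate_per_um_s=2e-3)
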