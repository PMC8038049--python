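import numpy as np
import pytest

from gmnet.synthetic import SimulationConfig


def reduced_config(**overrides) -> SimulationConfig:
    """A small study configuration used throughout the tests.

    24^3 voxel volumes (2 mm grid) with GM-volume targets scaled to the
    grid's capacity; everything else keeps the package defaults unless
    overridden.
    """
    params = dict(
        n_patients=4,
        n_controls=4,
        volume_shape=(24, 24, 24),
        gm_volume_means_sds={"patient": (28.0, 1.2), "control": (28.6, 1.2)},
        n_regions=16,
        seed=0,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_config():
    return reduced_config()
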