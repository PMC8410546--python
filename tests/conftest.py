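import numpy as np
import pytest

import meginverse as mi


@pytest.fixture(scope="session")
def small_config():
    return mi.SimulationConfig(n_sensors=40, n_dipoles=120, duration_s=6.0, seed=11)


@pytest.fixture(scope="session")
def small_head(small_config):
    return mi.build_spherical_head(small_config)


@pytest.fixture(scope="session")
def small_leadfield(small_head):
    return mi.compute_leadfield(small_head)


@pytest.fixture(scope="session")
def small_sources(small_head, small_config):
    return mi.simulate_sources(small_head, small_config)


@pytest.fixture(scope="session")
def small_recording(small_leadfield, small_sources):
    return mi.simulate_recording(small_leadfield, small_sources, snr_db=2.5, seed=77)


@pytest.fixture(scope="session")
def small_atlas(small_head):
    return mi.build_synthetic_atlas(small_head, n_rois=10, n_clusters=3, seed=5)


@pytest.fixture(scope="session")
def identity_noise(small_leadfield):
    return mi.NoiseModel.identity(small_leadfield.n_sensors)
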