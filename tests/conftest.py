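import numpy as np
import pytest

from biosonar.scene import SensorArray, make_grid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_grid():
    """10-voxel strip used for the small inversion oracles."""
    return make_grid((-0.05, 0.05, -0.02, 0.02), spacing=0.025)


@pytest.fixture(scope="session")
def line_array():
    """Six-sensor line array for the small scenes."""
    return SensorArray(np.column_stack([np.linspace(-0.3, 0.3, 6),
                                        np.zeros(6), np.full(6, 0.2)]))


def random_instance(rng, n_sensors, n_voxels, n_freqs, n_clicks=1,
                    mode="known"):
    """Random small steering/data pair for oracle-equivalence tests.

    Entries are unit-modulus phasors with random phases (the structure the
    physical steering matrices have), data is random complex.
    """
    def phasors(*shape):
        return np.exp(2j * np.pi * rng.uniform(size=shape))

    freqs = np.sort(rng.uniform(105e3, 140e3, n_freqs))
    data = (rng.standard_normal((n_sensors, n_freqs, n_clicks))
            + 1j * rng.standard_normal((n_sensors, n_freqs, n_clicks)))
    if mode == "known":
        a = phasors(n_clicks, n_freqs, n_sensors, n_voxels)
        return freqs, a, data
    b = phasors(n_freqs, n_sensors, n_voxels)
    return freqs, b, data
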