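import numpy as np
import pytest

from cfosmap.synth import PhantomSpec, generate_phantom, generate_toy_atlas


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 50-cell phantom without vessels (exact spot ground truth)."""
    spec = PhantomSpec(
        shape=(32, 96, 96), n_cells=50, n_vessels=0, noise_sd=0.0, seed=11
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def vessel_phantom():
    """Noise-free phantom with 200 cells and 10 dual-channel vessels."""
    spec = PhantomSpec(
        shape=(64, 160, 160), n_cells=200, n_vessels=10, noise_sd=0.0, seed=5
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def toy_atlas():
    return generate_toy_atlas(shape=(24, 24, 24), n_superregions=2, n_children_per=2, seed=3)


@pytest.fixture(scope="session")
def layered_atlas():
    return generate_toy_atlas(
        shape=(24, 30, 30), n_superregions=2, n_children_per=2, with_layers=True, seed=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
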