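import numpy as np
import pytest

from cytoblot import synthetic


@pytest.fixture(scope="session")
def small_population():
    """60 cells with the default (study-condition) generator parameters."""
    return synthetic.sample_population(synthetic.PopulationSpec(n_cells=60, seed=7))


@pytest.fixture(scope="session")
def noiseless_render(small_population):
    spec = synthetic.RenderSpec(noise_sd=0.0, grid=(10, 6))
    image, truth = synthetic.render_array(small_population, spec, seed=11)
    return image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
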