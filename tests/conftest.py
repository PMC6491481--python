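import numpy as np
import pytest

from orchard_phenomics import synthdata as sd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170727)


@pytest.fixture(scope="session")
def small_orchard():
    """A small noisy orchard shared across imagery tests."""
    design = sd.OrchardDesign(n_rows=2, trees_per_row=4, seed=11)
    stack, thermal, truth = sd.generate_orchard_images(design)
    return design, stack, thermal, truth


@pytest.fixture(scope="session")
def noiseless_orchard():
    design = sd.OrchardDesign(
        n_rows=2, trees_per_row=4, band_noise_sd=0.0, thermal_noise_sd=0.0, seed=7
    )
    stack, thermal, truth = sd.generate_orchard_images(design)
    return design, stack, thermal, truth
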