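import numpy as np
import pytest

from dopascreen import AssayNoiseModel, make_screen


@pytest.fixture(scope="session")
def small_screen():
    """A 64-compound screen with default noise and a fixed seed."""
    dataset, truth = make_screen(n_compounds=64, seed=11)
    return dataset, truth


@pytest.fixture(scope="session")
def noiseless_screen():
    """A 32-compound screen with all noise sources off."""
    noise = AssayNoiseModel(well_noise_cv=0.0, plate_effect_sd=0.0)
    dataset, truth = make_screen(
        n_compounds=32, noise=noise, seed=5, control_inhibition_sd=0.0
    )
    return dataset, truth
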