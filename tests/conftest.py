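import numpy as np
import pytest

from promscreen.landscape import FitnessLandscape, LandscapeConfig, make_landscape


@pytest.fixture
def simple_landscape() -> FitnessLandscape:
    """Baseline 1, one motif ACGT of weight 2, deterministic."""
    return FitnessLandscape(motifs=(("ACGT", 2.0),), baseline=1.0, noise_sd=0.0)


@pytest.fixture
def noiseless_random_landscape() -> FitnessLandscape:
    return make_landscape(LandscapeConfig(noise_sd=0.0), seed=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
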