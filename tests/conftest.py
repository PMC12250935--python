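import numpy as np
import pytest

from glandseg import RunConfig, SynthSpec, generate_tile


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    return RunConfig.tiny()


@pytest.fixture(scope="session")
def synth_pair():
    """One deterministic 96x96 synthetic tile with its instance map."""
    return generate_tile(SynthSpec(tile_size=96, seed=0), 7)
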