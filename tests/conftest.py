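import pytest

import meriptools as mt


@pytest.fixture(scope="session")
def default_config():
    """The simulated study conditions used across the suite."""
    return mt.SimConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    """Full synthetic study: annotation, sequences, truth peaks, reads."""
    return mt.generate_dataset(default_config)
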