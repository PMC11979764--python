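import numpy as np
import pytest

from ctrdseq import SimulationConfig, generate_transcriptome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_transcripts=20)


@pytest.fixture(scope="session")
def small_transcripts(small_config):
    return generate_transcriptome(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
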