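import pytest

from glycotrace.synth import SpectrumSynthConfig


@pytest.fixture
def synth_config():
    """Default synthesis parameters with a fixed seed."""
    return SpectrumSynthConfig(seed=1234)


@pytest.fixture
def noiseless_config():
    return SpectrumSynthConfig(seed=0, noise_sd=0.0, nmr_noise_sd=0.0)
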