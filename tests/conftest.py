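import logging

import pytest

from ihcquant import synth


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # alpha-fit fallbacks log warnings routinely on step-like metric curves
    logging.getLogger("ihcquant").setLevel(logging.ERROR)
    yield


@pytest.fixture
def small_field_config():
    """A fast 128x128 field with the default stains and mild shading."""
    return synth.SynthIHCConfig(width=128, height=128, seed=7)


@pytest.fixture
def clean_field_config():
    """Noise-free, evenly lit field for closed-form checks."""
    return synth.SynthIHCConfig(
        width=128, height=128, seed=7, noise_sd=0.0, illum_gradient=1.0
    )
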