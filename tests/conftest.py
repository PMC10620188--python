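import numpy as np
import pytest

from smsers.core import make_axis
from smsers.synth import NOISELESS, NoiseModel, render_spectrum


@pytest.fixture(scope="session")
def axis():
    return make_axis(400.0, 1800.0, 2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def render_clean(axis):
    """Render a template noise-free on the default axis."""

    def _render(template, amplitude_scale=1.0):
        return render_spectrum(template, axis, NOISELESS, amplitude_scale, seed=0)

    return _render


@pytest.fixture
def noise_model():
    return NoiseModel(additive_sd=0.125)
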