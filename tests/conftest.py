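import hypothesis
import numpy as np
import pytest

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noisy_line(rng):
    """50 points on y = 1.5x + 4 with Gaussian noise."""
    x = np.linspace(0, 10, 50)
    y = 1.5 * x + 4.0 + rng.normal(0, 0.8, size=50)
    return x, y


@pytest.fixture
def tanh_dataset(rng):
    """Moderate-noise tanh-curve dataset spanning the bend."""
    from nutrireq import TanhParams

    params = TanhParams(A=1.8, b=-13.0, c=0.03, B=3.6)
    x = rng.uniform(300, 560, size=400)
    y = params.predict(x) + rng.normal(0, 0.15, size=400)
    return x, y, params
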