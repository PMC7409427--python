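import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octachoroid.phantom import PhantomConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """Fast 64 x 64 phantom with vessels keyed at the default CVD depth."""
    return PhantomConfig(
        sct=300.0,
        grid_nx=64,
        grid_ny=64,
        lumen_fraction_by_depth={98.8: 0.55},
        seed=1,
    )
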