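import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """A compact synthetic reach reused by tests that only need plausibility."""
    from hydromorph.synthetic import SceneSpec, generate_scene

    return generate_scene(SceneSpec(seed=7, height=320, width=400,
                                    truth_grid_spacing=0.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
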