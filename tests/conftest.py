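import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Noise-free planted-rule dataset shared by featurizer/diversity tests."""
    from hergstack.synthetic import SyntheticSpec, generate_synthetic_dataset

    return generate_synthetic_dataset(
        SyntheticSpec(n=120, positive_fraction=0.5, noise_rate=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
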